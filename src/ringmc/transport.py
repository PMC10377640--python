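"""Weighted-photon Monte Carlo transport through the finger model.

The kernel implements the canonical hop-drop-spin scheme for multilayer
tissue optics: exponential free paths with the local extinction coefficient,
partial absorption of the packet weight at every interaction, Henyey-
Greenstein deflection sampling, and Russian roulette for unbiased
termination of low-weight packets.  The surrounding ring surface is either a
perfect absorber (rho = 0, the uncoated device), a perfect specular mirror
(rho = 1, the mirror-coated device), or anything in between; the
photodetector is a rectangular patch of the cylinder surface that captures
the full remaining weight of any packet crossing it.

Geometry is handled analytically (no voxelization): free paths are marched
with a conservative lower bound on the distance to the nearest tissue
boundary, and outer-surface crossings are resolved by exact ray-cylinder /
ray-plane intersection.  Layer changes mid-hop rescale the remaining path by
the ratio of extinction coefficients, which preserves the sampled optical
depth.

Single-threaded and bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .properties import LAYER_INDEX
from .tissue import FingerGeometry, TissueMap, OUTSIDE

__all__ = [
    "PhotonState", "SourceConfig", "DetectorConfig", "BoundaryConfig",
    "TransportResult", "launch", "step_length", "drop_weight", "spin",
    "surround_interaction", "detect", "roulette", "run_simulation",
]

_EPS_ADVANCE = 1.0e-4   # forced march advance near boundaries (1 um)
_SURF_PULL = 1.0e-7     # radial pull-back inside the surface after launch
                        # and after a mirror reflection


# --------------------------------------------------------------------------
# configuration / result containers
# --------------------------------------------------------------------------

@dataclass
class PhotonState:
    """Position (cm), unit direction, and statistical weight of a packet."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"|direction| = {norm} != 1")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight {self.weight} outside [0, 1]")


@dataclass(frozen=True)
class SourceConfig:
    """LED source on the ring rim at angular position 0 degrees."""

    wavelength_nm: float = 660.0
    angle_deg: float = 0.0
    radius_cm: float = 0.15
    profile: str = "lambertian"   # or "normal" (pencil beam)

    def __post_init__(self):
        if self.profile not in ("lambertian", "normal"):
            raise ValueError(f"unknown emission profile {self.profile!r}")


@dataclass(frozen=True)
class DetectorConfig:
    """Photodiode aperture on the rim at angular separation theta_PL."""

    theta_pl_deg: float = 25.0
    size_cm: tuple[float, float] = (0.3, 0.3)   # (arc, axial)
    enabled: bool = True


@dataclass(frozen=True)
class BoundaryConfig:
    """Optical behaviour of the ring inner surface around the finger."""

    rho: float = 0.0                  # surround reflectance, 0..1
    index_handling: str = "matched"   # or "fresnel"
    n_outside: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho={self.rho} outside [0, 1]")
        if self.index_handling not in ("matched", "fresnel"):
            raise ValueError("index_handling must be 'matched' or 'fresnel'")


@dataclass
class TransportResult:
    """Detected fraction and energy-balance ledger of one run.

    The ledger is normalized per unit launched weight and sums to 1:
    roulette kills and survival boosts are folded into ``absorbed_tissue``
    so that the balance is exact for every run (raw totals are kept in
    ``extras``).
    """

    detected_fraction: float
    ledger: dict[str, float]
    n_photons: int
    seed: int
    wavelength_nm: float
    theta_pl_deg: float
    rho: float
    extras: dict = field(default_factory=dict)
    fluence: np.ndarray | None = None
    fluence_extent_cm: tuple[float, float, float, float] | None = None

    @property
    def detected_percent(self) -> float:
        return 100.0 * self.detected_fraction

    def ledger_sum(self) -> float:
        return float(sum(self.ledger.values()))

    def summary_row(self) -> dict:
        row = {"theta_deg": self.theta_pl_deg,
               "wavelength_nm": self.wavelength_nm, "rho": self.rho,
               "n_photons": self.n_photons, "seed": self.seed,
               "detected_fraction": self.detected_fraction}
        row.update({f"ledger_{k}": v for k, v in self.ledger.items()})
        return row


# --------------------------------------------------------------------------
# elementary operations (python mirrors of the compiled kernel steps)
# --------------------------------------------------------------------------

def launch(source: SourceConfig, rng: np.random.Generator,
           geometry: FingerGeometry | None = None) -> PhotonState:
    """Sample one packet: position uniform on the LED disk, direction from
    the configured emission profile (inward)."""
    geo = geometry if geometry is not None else FingerGeometry()
    R = geo.radius_cm
    u1, u2 = rng.random(), rng.random()
    rad = source.radius_cm * math.sqrt(u1)
    ang = 2.0 * math.pi * u2
    arc, z0 = rad * math.cos(ang), rad * math.sin(ang)
    phi = math.radians(source.angle_deg) + arc / R
    pos = np.array([(R - _SURF_PULL) * math.sin(phi),
                    (R - _SURF_PULL) * math.cos(phi), z0])
    normal_in = np.array([-math.sin(phi), -math.cos(phi), 0.0])
    if source.profile == "normal":
        direction = normal_in
    else:
        ct = math.sqrt(rng.random())
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        psi = 2.0 * math.pi * rng.random()
        t1 = np.array([math.cos(phi), -math.sin(phi), 0.0])
        t2 = np.array([0.0, 0.0, 1.0])
        direction = ct * normal_in + st * (math.cos(psi) * t1
                                           + math.sin(psi) * t2)
        direction /= np.linalg.norm(direction)
    return PhotonState(position=pos, direction=direction, weight=1.0)


def step_length(mu_t: float, rng: np.random.Generator) -> float:
    """Exponential free path s = -ln(xi) / mu_t (cm)."""
    if mu_t <= 0:
        raise ValueError(f"mu_t={mu_t} must be > 0 in a non-vacuum layer")
    return -math.log(rng.random() or np.nextafter(0.0, 1.0)) / mu_t


def drop_weight(photon: PhotonState, mu_a: float,
                mu_t: float) -> tuple[PhotonState, float]:
    """Deposit the absorbed share W * mu_a / mu_t of the packet weight."""
    if not 0.0 <= mu_a <= mu_t:
        raise ValueError(f"need 0 <= mu_a <= mu_t, got {mu_a}, {mu_t}")
    absorbed = photon.weight * mu_a / mu_t
    return (PhotonState(position=photon.position,
                        direction=photon.direction,
                        weight=photon.weight - absorbed), absorbed)


def _hg_cos(g: float, xi: float) -> float:
    if abs(g) < 1e-6:
        return 1.0 - 2.0 * xi
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)


def spin(photon: PhotonState, g: float,
         rng: np.random.Generator) -> PhotonState:
    """Henyey-Greenstein deflection with uniform azimuth."""
    if not -1.0 < g < 1.0:
        raise ValueError(f"g={g} outside (-1, 1)")
    ct = _hg_cos(g, rng.random())
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    psi = 2.0 * math.pi * rng.random()
    cp, sp = math.cos(psi), math.sin(psi)
    ux, uy, uz = photon.direction
    if abs(uz) > 0.99999:
        nd = np.array([st * cp, st * sp, ct * math.copysign(1.0, uz)])
    else:
        den = math.sqrt(1.0 - uz * uz)
        nd = np.array([
            st * (ux * uz * cp - uy * sp) / den + ux * ct,
            st * (uy * uz * cp + ux * sp) / den + uy * ct,
            -st * cp * den + uz * ct,
        ])
    nd /= np.linalg.norm(nd)
    return PhotonState(position=photon.position, direction=nd,
                       weight=photon.weight)


def _surface_phi(position, geometry: FingerGeometry) -> float:
    return math.atan2(position[0], position[1])


def detect(photon: PhotonState, detector: DetectorConfig,
           geometry: FingerGeometry | None = None) -> bool:
    """True iff the surface crossing point lies within the PD aperture."""
    if not detector.enabled:
        return False
    geo = geometry if geometry is not None else FingerGeometry()
    phi = _surface_phi(photon.position, geo)
    dphi = (phi - math.radians(detector.theta_pl_deg)
            + math.pi) % (2.0 * math.pi) - math.pi
    half_arc = 0.5 * detector.size_cm[0] / geo.radius_cm
    half_z = 0.5 * detector.size_cm[1]
    return abs(dphi) <= half_arc and abs(photon.position[2]) <= half_z


def surround_interaction(photon: PhotonState, boundary: BoundaryConfig,
                         rng: np.random.Generator,
                         geometry: FingerGeometry | None = None
                         ) -> PhotonState | None:
    """Specular reflection with probability rho, otherwise termination.

    Returns the reflected packet (weight preserved) or None when the
    surround absorbs it.
    """
    geo = geometry if geometry is not None else FingerGeometry()
    if rng.random() >= boundary.rho:
        return None
    x, y, z = photon.position
    r = math.hypot(x, y)
    nx, ny = x / r, y / r
    ux, uy, uz = photon.direction
    dot = ux * nx + uy * ny
    new_dir = np.array([ux - 2.0 * dot * nx, uy - 2.0 * dot * ny, uz])
    fac = (geo.radius_cm - _SURF_PULL) / r
    return PhotonState(position=np.array([x * fac, y * fac, z]),
                       direction=new_dir / np.linalg.norm(new_dir),
                       weight=photon.weight)


def roulette(photon: PhotonState, threshold: float, survival: float,
             rng: np.random.Generator) -> PhotonState | None:
    """Unbiased low-weight termination: survive with probability
    ``survival`` and weight W/survival, else terminate."""
    if photon.weight >= threshold:
        return photon
    if rng.random() < survival:
        return PhotonState(position=photon.position,
                           direction=photon.direction,
                           weight=min(photon.weight / survival, 1.0))
    return None


# --------------------------------------------------------------------------
# compiled kernel
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _rnd(rs):
    """xorshift128+ uniform double in [0, 1); rs is the 2-word uint64 state."""
    s0 = rs[0]
    s1 = rs[1]
    rs[0] = s1
    s0 ^= s0 << np.uint64(23)
    s0 ^= s0 >> np.uint64(17)
    s0 ^= s1 ^ (s1 >> np.uint64(26))
    rs[1] = s0
    return ((s0 + s1) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True, inline="always")
def _probe_k(x, y, z, R, half_len, shell_inner,
             bcx, bcy, ba, bb, ax, ay, ar, core_r, art_rmax, bone_rmax):
    """Fused point classification + conservative boundary-distance bound.

    Returns (layer, bound).  layer = -1 outside the finger.  The bound is a
    lower bound on the euclidean distance to the nearest surface of any
    kind, so a move shorter than it cannot change the layer (the ellipse
    bound uses |grad f| <= 1/b for f = sqrt((x/a)^2 + (y/b)^2))."""
    r2 = x * x + y * y
    if r2 >= R * R or abs(z) >= half_len:
        return -1, 0.0
    r = math.sqrt(r2)
    d = R - r
    dd = half_len - abs(z)
    if dd < d:
        d = dd
    if r >= core_r:
        # concentric-shell region: the bone and arteries cannot reach here
        if r >= shell_inner[0]:
            lay = 0
        elif r >= shell_inner[1]:
            lay = 1
        elif r >= shell_inner[2]:
            lay = 2
        elif r >= shell_inner[3]:
            lay = 3
        else:
            lay = 4
        for i in range(5):
            dd = abs(r - shell_inner[i])
            if dd < d:
                d = dd
        dd = r - art_rmax
        if dd < d:
            d = dd
        dd = r - bone_rmax
        if dd < d:
            d = dd
        return lay, d
    dd = core_r - r
    if dd < d:
        d = dd
    dx = x - ax
    dy = y - ay
    da = math.sqrt(dx * dx + dy * dy)
    if da <= ar:
        dd = ar - da
        return 7, dd if dd < d else d
    dd = da - ar
    if dd < d:
        d = dd
    dx = x + ax
    da = math.sqrt(dx * dx + dy * dy)
    if da <= ar:
        dd = ar - da
        return 7, dd if dd < d else d
    dd = da - ar
    if dd < d:
        d = dd
    ex = (x - bcx) / ba
    ey = (y - bcy) / bb
    q = math.sqrt(ex * ex + ey * ey)
    if q <= 1.0:
        dd = (1.0 - q) * bb
        return 6, dd if dd < d else d
    dd = (q - 1.0) * bb
    if dd < d:
        d = dd
    return 5, d


@njit(cache=True)
def _run_kernel(rs, n_photons,
                R, half_len, shell_inner,
                bcx, bcy, ba, bb, ax, ay, ar,
                mu_a, mu_s, mu_t, g_arr, n_arr,
                led_angle, led_r, pencil,
                det_on, det_angle, det_half_arc, det_half_z,
                rho, fresnel_on, n_out,
                rr_threshold, rr_survival,
                fluence, fluence_on, grid_n,
                max_steps):
    detected = 0.0
    deposits = 0.0
    surround = 0.0
    caps = 0.0
    killed = 0.0
    boosted = 0.0
    overflow = 0.0
    n_detect_events = 0
    n_overflow = 0
    cell = 2.0 * R / grid_n
    core_r = shell_inner[4]
    art_rmax = math.sqrt(ax * ax + ay * ay) + ar
    bone_rmax = math.sqrt(bcx * bcx + bcy * bcy) + max(ba, bb)

    for _ in range(n_photons):
        # ---- launch -----------------------------------------------------
        rad = led_r * math.sqrt(_rnd(rs))
        ang = 2.0 * math.pi * _rnd(rs)
        phi = led_angle + rad * math.cos(ang) / R
        sphi = math.sin(phi)
        cphi = math.cos(phi)
        x = (R - 1.0e-7) * sphi
        y = (R - 1.0e-7) * cphi
        z = rad * math.sin(ang)
        if pencil:
            ux, uy, uz = -sphi, -cphi, 0.0
        else:
            ct = math.sqrt(_rnd(rs))
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            psi = 2.0 * math.pi * _rnd(rs)
            ux = ct * (-sphi) + st * math.cos(psi) * cphi
            uy = ct * (-cphi) + st * math.cos(psi) * (-sphi)
            uz = st * math.sin(psi)
        w = 1.0
        lay, d_b = _probe_k(x, y, z, R, half_len, shell_inner, bcx, bcy,
                            ba, bb, ax, ay, ar, core_r, art_rmax, bone_rmax)
        if lay < 0:
            lay = 0
            d_b = 0.0
        p_dep = 0.0
        alive = True
        steps = 0

        while alive:
            steps += 1
            if steps > max_steps:
                p_dep += w
                n_overflow += 1
                overflow += w
                break
            # ---- hop (conservative-distance march) ----------------------
            s_rem = -math.log(_rnd(rs) + 1.0e-300) / mu_t[lay]
            while True:
                adv = d_b if d_b > 1.0e-4 else 1.0e-4
                if adv >= s_rem:
                    # cannot reach any boundary: free move, same layer
                    x += s_rem * ux
                    y += s_rem * uy
                    z += s_rem * uz
                    d_b -= s_rem
                    break
                x += adv * ux
                y += adv * uy
                z += adv * uz
                s_rem -= adv
                lay2, nb = _probe_k(x, y, z, R, half_len, shell_inner,
                                    bcx, bcy, ba, bb, ax, ay, ar,
                                    core_r, art_rmax, bone_rmax)
                if lay2 == lay:
                    d_b = nb
                    continue
                if lay2 >= 0:
                    # internal boundary: rescale the remaining path so the
                    # sampled optical depth is preserved
                    s_rem *= mu_t[lay] / mu_t[lay2]
                    lay = lay2
                    d_b = nb
                    continue
                # ---- crossed the outer boundary: exact intersection -----
                x -= adv * ux
                y -= adv * uy
                z -= adv * uz
                s_rem += adv
                aq = ux * ux + uy * uy
                t_side = 1.0e30
                if aq > 0.0:
                    bq = 2.0 * (x * ux + y * uy)
                    cq = x * x + y * y - R * R
                    disc = bq * bq - 4.0 * aq * cq
                    if disc > 0.0:
                        t_side = (-bq + math.sqrt(disc)) / (2.0 * aq)
                t_cap = 1.0e30
                if uz > 1.0e-300:
                    t_cap = (half_len - z) / uz
                elif uz < -1.0e-300:
                    t_cap = (-half_len - z) / uz
                if t_cap < t_side:
                    caps += w
                    alive = False
                    break
                t = t_side
                if t < 0.0:
                    t = 0.0
                x += t * ux
                y += t * uy
                z += t * uz
                s_rem -= t
                if det_on:
                    phi_s = math.atan2(x, y)
                    dphi = (phi_s - det_angle + math.pi) \
                        % (2.0 * math.pi) - math.pi
                    if abs(dphi) <= det_half_arc and abs(z) <= det_half_z:
                        detected += w
                        n_detect_events += 1
                        alive = False
                        break
                p_back = rho
                if fresnel_on:
                    r_s = math.sqrt(x * x + y * y)
                    cos_i = abs(ux * x / r_s + uy * y / r_s)
                    ni = n_arr[0]
                    sin_t2 = (ni / n_out) ** 2 * (1.0 - cos_i * cos_i)
                    if sin_t2 >= 1.0:
                        rf = 1.0
                    else:
                        cos_t = math.sqrt(1.0 - sin_t2)
                        f_s = ((ni * cos_i - n_out * cos_t)
                               / (ni * cos_i + n_out * cos_t)) ** 2
                        f_p = ((ni * cos_t - n_out * cos_i)
                               / (ni * cos_t + n_out * cos_i)) ** 2
                        rf = 0.5 * (f_s + f_p)
                    p_back = rf + (1.0 - rf) * rho
                if _rnd(rs) < p_back:
                    r_s = math.sqrt(x * x + y * y)
                    nxs = x / r_s
                    nys = y / r_s
                    dot = ux * nxs + uy * nys
                    ux -= 2.0 * dot * nxs
                    uy -= 2.0 * dot * nys
                    fac = (R - 1.0e-7) / r_s
                    x *= fac
                    y *= fac
                    lay, d_b = _probe_k(x, y, z, R, half_len, shell_inner,
                                        bcx, bcy, ba, bb, ax, ay, ar,
                                        core_r, art_rmax, bone_rmax)
                    if lay < 0:
                        lay = 0
                        d_b = 0.0
                    continue
                surround += w
                alive = False
                break
            if not alive:
                break
            # ---- drop ---------------------------------------------------
            dw = w * mu_a[lay] / mu_t[lay]
            w -= dw
            p_dep += dw
            if fluence_on:
                ix = int((x + R) / cell)
                iy = int((y + R) / cell)
                if 0 <= ix < grid_n and 0 <= iy < grid_n:
                    fluence[iy, ix] += dw
            if w <= 1.0e-300:
                break
            # ---- roulette -----------------------------------------------
            if w < rr_threshold:
                if _rnd(rs) < rr_survival:
                    nw = w / rr_survival
                    if nw > 1.0:
                        nw = 1.0
                    boosted += nw - w
                    w = nw
                else:
                    killed += w
                    break
            # ---- spin ---------------------------------------------------
            gg = g_arr[lay]
            xi = _rnd(rs)
            if gg > 1.0e-6 or gg < -1.0e-6:
                tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * xi)
                ct = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
            else:
                ct = 1.0 - 2.0 * xi
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            st = math.sqrt(1.0 - ct * ct)
            psi = 2.0 * math.pi * _rnd(rs)
            cp = math.cos(psi)
            sp = math.sin(psi)
            if uz > 0.99999 or uz < -0.99999:
                sign = 1.0 if uz > 0.0 else -1.0
                ux = st * cp
                uy = st * sp
                uz = ct * sign
            else:
                den = math.sqrt(1.0 - uz * uz)
                nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                nuz = -st * cp * den + uz * ct
                ux, uy, uz = nux, nuy, nuz
            norm = math.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm

        deposits += p_dep

    out = np.empty(9)
    out[0] = detected
    out[1] = deposits
    out[2] = surround
    out[3] = caps
    out[4] = killed
    out[5] = boosted
    out[6] = overflow
    out[7] = n_detect_events
    out[8] = n_overflow
    return out


def _rng_state(seed: int) -> np.ndarray:
    """splitmix64 expansion of a small seed into the xorshift128+ state."""
    mask = (1 << 64) - 1
    z = int(seed) & mask
    words = []
    for _ in range(2):
        z = (z + 0x9E3779B97F4A7C15) & mask
        t = z
        t = ((t ^ (t >> 30)) * 0xBF58476D1CE4E5B9) & mask
        t = ((t ^ (t >> 27)) * 0x94D049BB133111EB) & mask
        t ^= t >> 31
        words.append(t)
    if words[0] == 0 and words[1] == 0:
        words[0] = 1
    return np.array(words, dtype=np.uint64)


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

def run_simulation(tissue_map: TissueMap,
                   source: SourceConfig,
                   detector: DetectorConfig,
                   boundary: BoundaryConfig,
                   n_photons: int,
                   seed: int,
                   *,
                   fluence: bool = False,
                   fluence_resolution: int = 200,
                   rr_threshold: float = 0.1,
                   rr_survival: float = 0.1,
                   max_steps: int = 500_000) -> TransportResult:
    """Run one Monte Carlo transport experiment.

    Returns the detected weight fraction at the PD together with the
    energy-balance ledger (detected + absorbed_tissue + absorbed_surround +
    lost_caps == 1 per unit launched weight).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    geo = tissue_map.geometry
    mu_a = np.ascontiguousarray(tissue_map.mu_a)
    mu_s = np.ascontiguousarray(tissue_map.mu_s)
    mu_t = mu_a + mu_s
    if np.any(mu_t <= 0.0):
        raise ValueError("every layer needs mu_a + mu_s > 0")
    grid_n = int(fluence_resolution)
    flu = np.zeros((grid_n, grid_n)) if fluence else np.zeros((1, 1))
    raw = _run_kernel(
        _rng_state(seed), int(n_photons),
        geo.radius_cm, geo.half_length_cm,
        np.ascontiguousarray(geo.shell_inner_radii_cm),
        geo.bone_center_cm[0], geo.bone_center_cm[1],
        geo.bone_semi_axes_cm[0], geo.bone_semi_axes_cm[1],
        geo.artery_abs_x_cm, geo.artery_y_cm,
        tissue_map.state.artery_radius_cm,
        mu_a, mu_s, mu_t,
        np.ascontiguousarray(tissue_map.g),
        np.ascontiguousarray(tissue_map.n),
        math.radians(source.angle_deg), source.radius_cm,
        source.profile == "normal",
        detector.enabled, math.radians(detector.theta_pl_deg),
        0.5 * detector.size_cm[0] / geo.radius_cm,
        0.5 * detector.size_cm[1],
        boundary.rho, boundary.index_handling == "fresnel",
        boundary.n_outside,
        rr_threshold, rr_survival,
        flu, fluence, grid_n,
        max_steps)
    n = float(n_photons)
    det, deposits, surround, caps, kill, boost, overflow = raw[:7]
    ledger = {
        "detected": det / n,
        "absorbed_tissue": (deposits + kill - boost) / n,
        "absorbed_surround": surround / n,
        "lost_caps": caps / n,
    }
    extras = {
        "raw_deposits": deposits / n,
        "roulette_killed": kill / n,
        "roulette_boosted": boost / n,
        "max_steps_weight": overflow / n,
        "n_detect_events": int(raw[7]),
        "n_max_steps_hits": int(raw[8]),
        "rr_threshold": rr_threshold,
        "rr_survival": rr_survival,
    }
    R = geo.radius_cm
    return TransportResult(
        detected_fraction=det / n,
        ledger=ledger,
        n_photons=int(n_photons),
        seed=int(seed),
        wavelength_nm=tissue_map.wavelength_nm,
        theta_pl_deg=detector.theta_pl_deg,
        rho=boundary.rho,
        extras=extras,
        fluence=flu if fluence else None,
        fluence_extent_cm=(-R, R, -R, R) if fluence else None,
    )
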