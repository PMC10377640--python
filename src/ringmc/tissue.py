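"""Layered finger cross-section and wavelength/state-resolved optical maps.

The finger is a circular cylinder (axis = z) whose cross-section holds, from
the surface inward, five concentric skin shells (epidermis, papillary dermis,
upper blood net dermis, reticular dermis, deep blood net dermis), a
subcutaneous-fat core, an elliptical bone, and two mirrored digital arteries.
The +y axis points from the finger center toward the LED-bearing surface, so
the bone (0, 0.3) and the arteries (+/-0.4, 0.45) sit between the center and
the LED.

A :class:`TissueMap` freezes one wavelength and one physiological state
(SpO2, cardiac phase) into per-layer absorption/scattering arrays plus a
deterministic point -> layer classification used by the transport kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .properties import DEFAULT_LAYER_TABLE, LAYERS, LAYER_INDEX, SKIN_SHELLS
from .spectra import ChromophoreSpectra

OUTSIDE = -1

__all__ = [
    "OUTSIDE", "LayerComposition", "FingerGeometry", "PhysiologicalState",
    "TissueMap", "FingerModel", "mix_absorption", "build_tissue_map",
    "classify_point", "default_compositions",
]


class CompositionError(ValueError):
    """Volume fractions violate 0 <= f and sum(f) <= 1."""


class GeometryError(ValueError):
    """Finger geometry is not physically realizable."""


@dataclass(frozen=True)
class LayerComposition:
    """Chromophore volume fractions and scattering properties of one layer.

    ``fractions`` uses the key ``"blood"`` for whole blood; at mix time it is
    split into oxy/deoxy hemoglobin by the SpO2 fraction.  ``mu_s_per_cm``
    maps wavelength (nm) to the scattering coefficient; other wavelengths are
    interpolated as a power law (log-log linear).
    """

    layer: str
    fractions: dict[str, float]
    mu_s_per_cm: dict[float, float]
    g: float
    n: float
    thickness_cm: float | None = None

    def __post_init__(self):
        if self.layer not in LAYER_INDEX:
            raise ValueError(f"unknown layer id {self.layer!r}")
        for name, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise CompositionError(
                    f"{self.layer}: fraction {name}={f} outside [0, 1]")
        if sum(self.fractions.values()) > 1.0 + 1e-12:
            raise CompositionError(
                f"{self.layer}: fractions sum to "
                f"{sum(self.fractions.values()):.4f} > 1")
        for lam, mus in self.mu_s_per_cm.items():
            if mus < 0:
                raise CompositionError(
                    f"{self.layer}: mu_s({lam}) = {mus} < 0")
        if not -1.0 < self.g < 1.0:
            raise CompositionError(f"{self.layer}: g={self.g} outside (-1, 1)")
        if self.n < 1.0:
            raise CompositionError(f"{self.layer}: n={self.n} < 1")

    def mu_s_at(self, wavelength_nm: float) -> float:
        """Scattering coefficient (1/cm), power-law interpolated."""
        pts = sorted(self.mu_s_per_cm.items())
        if len(pts) == 1:
            return float(pts[0][1])
        lam = np.log([p[0] for p in pts])
        mus = np.log([max(p[1], 1e-300) for p in pts])
        # linear in log-log space, linearly extrapolated outside the nodes
        slope_lo = (mus[1] - mus[0]) / (lam[1] - lam[0])
        slope_hi = (mus[-1] - mus[-2]) / (lam[-1] - lam[-2])
        x = math.log(wavelength_nm)
        if x <= lam[0]:
            y = mus[0] + slope_lo * (x - lam[0])
        elif x >= lam[-1]:
            y = mus[-1] + slope_hi * (x - lam[-1])
        else:
            y = float(np.interp(x, lam, mus))
        return math.exp(y)


def default_compositions() -> list[LayerComposition]:
    """One :class:`LayerComposition` per layer from the packaged defaults."""
    out = []
    for name in LAYERS:
        row = DEFAULT_LAYER_TABLE[name]
        out.append(LayerComposition(
            layer=name,
            fractions=dict(row["fractions"]),
            mu_s_per_cm={float(k): float(v)
                         for k, v in row["mu_s_per_cm"].items()},
            g=row["g"], n=row["n"], thickness_cm=row["thickness_cm"]))
    return out


@dataclass(frozen=True)
class FingerGeometry:
    """Finger/ring geometry (cm).  Defaults follow the modelled device.

    The ring inner surface coincides with the finger surface (diameter
    1.7 cm).  ``skin_thickness_cm`` lists the five shell thicknesses from
    the epidermis inward; subcutaneous fat fills the remainder.
    """

    ring_diameter_cm: float = 1.7
    bone_center_cm: tuple[float, float] = (0.0, 0.3)
    bone_semi_axes_cm: tuple[float, float] = (0.25, 0.15)
    artery_abs_x_cm: float = 0.4
    artery_y_cm: float = 0.45
    artery_radius_cm: float = 0.08
    skin_thickness_cm: tuple[float, ...] = (0.010, 0.020, 0.008, 0.080, 0.030)
    cylinder_length_cm: float = 4.0
    pd_size_cm: tuple[float, float] = (0.3, 0.3)
    led_radius_cm: float = 0.15

    @property
    def radius_cm(self) -> float:
        return self.ring_diameter_cm / 2.0

    @property
    def half_length_cm(self) -> float:
        return self.cylinder_length_cm / 2.0

    @property
    def shell_inner_radii_cm(self) -> np.ndarray:
        """Inner radius of each skin shell, outermost shell first."""
        return self.radius_cm - np.cumsum(self.skin_thickness_cm)

    def artery_centers_cm(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return ((-self.artery_abs_x_cm, self.artery_y_cm),
                (self.artery_abs_x_cm, self.artery_y_cm))

    def validate(self, artery_radius_cm: float | None = None) -> None:
        r = self.radius_cm
        ra = self.artery_radius_cm if artery_radius_cm is None \
            else artery_radius_cm
        if sum(self.skin_thickness_cm) >= r:
            raise GeometryError("skin shells thicker than the finger radius")
        core = self.shell_inner_radii_cm[-1]
        bx, by = self.bone_center_cm
        a, b = self.bone_semi_axes_cm
        if math.hypot(abs(bx) + a, abs(by) + b) > core:
            raise GeometryError("bone extends outside the subcutaneous core")
        ax, ay = self.artery_abs_x_cm, self.artery_y_cm
        if math.hypot(ax, ay) + ra > core:
            raise GeometryError("artery extends outside the subcutaneous core")
        # artery must not intersect the bone ellipse (conservative check on
        # the artery point nearest the bone center)
        d = math.hypot(ax - bx, ay - by)
        if d <= ra + min(a, b):
            ex = (ax - bx) / d * max(d - ra, 0.0) + bx
            ey = (ay - by) / d * max(d - ra, 0.0) + by
            if ((ex - bx) / a) ** 2 + ((ey - by) / b) ** 2 <= 1.0:
                raise GeometryError("artery overlaps the bone")


@dataclass(frozen=True)
class PhysiologicalState:
    """SpO2 plus the cardiac-phase parameters that change during a cycle."""

    spo2: float = 1.0
    phase: str = "diastolic"
    artery_radius_cm: float = 0.092
    capillary_multiplier: float = 1.5

    def __post_init__(self):
        if not 0.0 <= self.spo2 <= 1.0:
            raise ValueError(f"spo2={self.spo2} outside [0, 1]")
        if self.phase not in ("systolic", "diastolic"):
            raise ValueError(f"phase must be systolic|diastolic, "
                             f"got {self.phase!r}")
        if self.artery_radius_cm <= 0 or self.capillary_multiplier <= 0:
            raise ValueError("artery radius and capillary multiplier "
                             "must be > 0")

    @classmethod
    def systolic(cls, spo2: float = 1.0) -> "PhysiologicalState":
        return cls(spo2=spo2, phase="systolic",
                   artery_radius_cm=0.08, capillary_multiplier=1.0)

    @classmethod
    def diastolic(cls, spo2: float = 1.0) -> "PhysiologicalState":
        return cls(spo2=spo2, phase="diastolic",
                   artery_radius_cm=0.092, capillary_multiplier=1.5)


def mix_absorption(composition: LayerComposition,
                   spectra: ChromophoreSpectra,
                   wavelength_nm: float,
                   spo2: float,
                   phase_multiplier: float = 1.0) -> float:
    """Absorption coefficient (1/cm) of a layer by volume-fraction mixing.

    mu_a = f_blood * m * [s * mu_oxy + (1-s) * mu_deoxy] + sum_i f_i * mu_i

    where ``m`` is the cardiac-phase capillary blood-volume multiplier
    (applied to the blood fraction only) and ``s`` the SpO2 fraction.
    """
    if not 0.0 <= spo2 <= 1.0:
        raise ValueError(f"spo2={spo2} outside [0, 1]")
    if phase_multiplier <= 0:
        raise ValueError("phase_multiplier must be > 0")
    f = composition.fractions
    f_blood = f.get("blood", 0.0) * phase_multiplier
    total = f_blood + sum(v for k, v in f.items() if k != "blood")
    if total > 1.0 + 1e-12:
        raise CompositionError(
            f"{composition.layer}: fractions with blood multiplier "
            f"{phase_multiplier} sum to {total:.4f} > 1")
    mu = f_blood * (spo2 * spectra.absorption("oxy_hb", wavelength_nm)
                    + (1.0 - spo2)
                    * spectra.absorption("deoxy_hb", wavelength_nm))
    for name, frac in f.items():
        if name == "blood" or frac == 0.0:
            continue
        mu += frac * spectra.absorption(name, wavelength_nm)
    return mu


@dataclass(frozen=True)
class TissueMap:
    """Geometry + per-layer optical properties at one wavelength and state.

    ``mu_a``, ``mu_s``, ``g``, ``n`` are arrays indexed by the canonical
    layer order of :data:`ringmc.properties.LAYERS`.
    """

    geometry: FingerGeometry
    state: PhysiologicalState
    wavelength_nm: float
    mu_a: np.ndarray
    mu_s: np.ndarray
    g: np.ndarray
    n: np.ndarray
    layer_names: tuple[str, ...] = field(default=LAYERS)

    def classify_xy(self, x, y):
        """Vectorized cross-section classification (layer index or OUTSIDE).

        Priority: artery > bone > skin shell by radial depth > fat;
        points at or beyond the finger surface are OUTSIDE.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        geo = self.geometry
        r = np.hypot(x, y)
        out = np.full(np.broadcast(x, y).shape, OUTSIDE, dtype=np.int64)
        inside = r < geo.radius_cm
        # fat core default, then shells
        shell_inner = geo.shell_inner_radii_cm
        out[inside] = LAYER_INDEX["subcutaneous_fat"]
        for i in range(len(shell_inner) - 1, -1, -1):
            hi = geo.radius_cm if i == 0 else shell_inner[i - 1]
            sel = inside & (r >= shell_inner[i]) & (r < hi)
            out[sel] = i
        bx, by = geo.bone_center_cm
        a, b = geo.bone_semi_axes_cm
        bone = inside & (((x - bx) / a) ** 2 + ((y - by) / b) ** 2 <= 1.0)
        out[bone] = LAYER_INDEX["bone"]
        ra = self.state.artery_radius_cm
        for cx, cy in geo.artery_centers_cm():
            art = inside & ((x - cx) ** 2 + (y - cy) ** 2 <= ra ** 2)
            out[art] = LAYER_INDEX["artery_blood"]
        return out if out.shape else int(out)

    def classify(self, position) -> int:
        """Layer index of one 3D point (cm); OUTSIDE beyond the surface."""
        x, y, z = position
        if abs(z) >= self.geometry.half_length_cm:
            return OUTSIDE
        return int(self.classify_xy(x, y))

    def layer_name(self, index: int) -> str:
        return "outside" if index == OUTSIDE else self.layer_names[index]


def classify_point(tissue_map: TissueMap, position) -> str:
    """Layer id (name) of a 3D point; ``"outside"`` beyond the surface."""
    return tissue_map.layer_name(tissue_map.classify(position))


@dataclass(frozen=True)
class FingerModel:
    """Bundle of geometry, layer compositions and chromophore spectra.

    This is the state-independent part of the model; resolve a concrete
    :class:`TissueMap` for a wavelength + physiological state with
    :meth:`map_for`.
    """

    geometry: FingerGeometry
    compositions: tuple[LayerComposition, ...]
    spectra: ChromophoreSpectra

    @classmethod
    def default(cls) -> "FingerModel":
        return cls(geometry=FingerGeometry(),
                   compositions=tuple(default_compositions()),
                   spectra=ChromophoreSpectra.default())

    def map_for(self, state: PhysiologicalState,
                wavelength_nm: float) -> TissueMap:
        return build_tissue_map(self.geometry, list(self.compositions),
                                self.spectra, state, wavelength_nm)


def build_tissue_map(geometry: FingerGeometry,
                     compositions: list[LayerComposition],
                     spectra: ChromophoreSpectra,
                     state: PhysiologicalState,
                     wavelength_nm: float) -> TissueMap:
    """Resolve per-layer optical properties for one wavelength and state.

    The cardiac capillary multiplier scales the blood fraction of every
    tissue layer except the arteries, whose pulsation is geometric (radius).
    """
    by_name = {c.layer: c for c in compositions}
    missing = [n for n in LAYERS if n not in by_name]
    if missing:
        raise ValueError(f"missing composition for layers: {missing}")
    geometry.validate(artery_radius_cm=state.artery_radius_cm)

    mu_a = np.empty(len(LAYERS))
    mu_s = np.empty(len(LAYERS))
    g = np.empty(len(LAYERS))
    n = np.empty(len(LAYERS))
    for i, name in enumerate(LAYERS):
        comp = by_name[name]
        mult = 1.0 if name == "artery_blood" else state.capillary_multiplier
        mu_a[i] = mix_absorption(comp, spectra, wavelength_nm,
                                 state.spo2, mult)
        mu_s[i] = comp.mu_s_at(wavelength_nm)
        g[i] = comp.g
        n[i] = comp.n
    return TissueMap(geometry=geometry, state=state,
                     wavelength_nm=wavelength_nm,
                     mu_a=mu_a, mu_s=mu_s, g=g, n=n)
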