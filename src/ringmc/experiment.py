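"""Numerical oximetry experiments on the finger model.

This module turns raw transport runs into the quantities a pulse-oximeter
designer cares about:

* paired systolic/diastolic runs -> dc and ac detected intensity,
* perfusion index PI = ac/dc per wavelength,
* R ratio = PI(red) / PI(near-infrared),
* the SpO2 calibration curve (mean R over the PD-angle grid per SpO2 level)
  and its reliability limits L_R1 < L_R2 < L_R3 (midpoints of adjacent
  calibration R values),
* per-angle reliability classification and the maximum reliable PD-LED
  separation theta_max (= theta_opt, since PI grows with the angle inside
  the reliable range),
* repetition statistics (spread of the detected intensity over repeated
  runs, reported as a 3-sigma band of the mean-normalized intensity),
* simple relative-enhancement arithmetic for mirror-coated vs. absorbing
  surrounds.

Sign convention for ac: more blood is present in the diastolic column of the
cardiac-phase table, so the diastolic intensity is the lower one.  By
default ac = |I_diastolic - I_systolic| and dc = max of the two; the signed
raw difference is always recorded, and ``strict_phase_convention=True``
switches to the literal "dc = diastolic, ac = diastolic - systolic" reading.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tissue import FingerModel, PhysiologicalState
from .transport import (BoundaryConfig, DetectorConfig, SourceConfig,
                        run_simulation)

log = logging.getLogger(__name__)

__all__ = [
    "THETA_GRID_DEG", "REFERENCE_CALIBRATION_R", "PairedIntensity",
    "CalibrationCurve", "ReliabilityLimits", "paired_run",
    "perfusion_index", "r_ratio", "angle_sweep", "calibration_curve",
    "reliability_limits", "classify_reliable", "theta_max",
    "repetition_statistics", "enhancement", "led_duty_cycle",
]

#: PD-LED angular separations of the reference sweep (degrees)
THETA_GRID_DEG = tuple(range(25, 100, 5))

#: Published reference calibration curve (SpO2 % -> R ratio) for the
#: 1e8-photon absorbing-surround condition; shipped for downstream
#: reliability arithmetic and as a regression anchor.
REFERENCE_CALIBRATION_R = {100: 0.9, 90: 1.25, 80: 1.5, 70: 1.9}


class UndefinedRatioError(ZeroDivisionError):
    """dc or PI denominator is non-positive; ratio undefined."""


@dataclass(frozen=True)
class PairedIntensity:
    """Systolic/diastolic detected fractions at one condition."""

    i_systolic: float
    i_diastolic: float
    wavelength_nm: float
    theta_pl_deg: float
    rho: float
    spo2: float
    n_photons: int
    seeds: tuple[int, int]
    strict_phase_convention: bool = False

    @property
    def ac_signed(self) -> float:
        """Literal diastolic - systolic difference."""
        return self.i_diastolic - self.i_systolic

    @property
    def dc(self) -> float:
        if self.strict_phase_convention:
            return self.i_diastolic
        return max(self.i_systolic, self.i_diastolic)

    @property
    def ac(self) -> float:
        if self.strict_phase_convention:
            return self.ac_signed
        return abs(self.ac_signed)


@dataclass(frozen=True)
class CalibrationCurve:
    """Mean R ratio over the PD-angle grid at each SpO2 level."""

    spo2_percent: tuple[float, ...]
    r: tuple[float, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        order = np.argsort(self.spo2_percent)[::-1]  # 100 -> 70
        object.__setattr__(self, "spo2_percent",
                           tuple(float(self.spo2_percent[i]) for i in order))
        object.__setattr__(self, "r",
                           tuple(float(self.r[i]) for i in order))
        if not all(b > a for a, b in zip(self.r, self.r[1:])):
            raise ValueError(
                f"calibration R must strictly increase as SpO2 decreases, "
                f"got {self.r} at {self.spo2_percent}%")

    def as_dict(self) -> dict[float, float]:
        return dict(zip(self.spo2_percent, self.r))


@dataclass(frozen=True)
class ReliabilityLimits:
    """R-value bin boundaries between adjacent SpO2 levels."""

    l_r1: float
    l_r2: float
    l_r3: float

    def __post_init__(self):
        if not self.l_r1 < self.l_r2 < self.l_r3:
            raise ValueError("need L_R1 < L_R2 < L_R3")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.l_r1, self.l_r2, self.l_r3)


# --------------------------------------------------------------------------
# simulation-backed operations
# --------------------------------------------------------------------------

def paired_run(model: FingerModel, theta_pl_deg: float, wavelength_nm: float,
               spo2: float, rho: float, n_photons: int, seed: int,
               *, strict_phase_convention: bool = False,
               states: dict[str, PhysiologicalState] | None = None,
               **run_kwargs) -> PairedIntensity:
    """Run the systolic and the diastolic state back to back.

    The two runs share the same seed (common random numbers), so the small
    ac difference between the nearly identical states is estimated with far
    less Monte Carlo noise than with independent streams.  ``states`` can
    replace the default cardiac-phase parameter pair (keys ``"systolic"``
    and ``"diastolic"``).
    """
    source = SourceConfig(wavelength_nm=wavelength_nm)
    detector = DetectorConfig(theta_pl_deg=theta_pl_deg)
    boundary = BoundaryConfig(rho=rho)
    results = {}
    for phase in ("systolic", "diastolic"):
        if states is not None:
            state = states[phase]
        else:
            state = getattr(PhysiologicalState, phase)(spo2=spo2)
        tmap = model.map_for(state, wavelength_nm)
        results[phase] = run_simulation(tmap, source, detector, boundary,
                                        n_photons, seed, **run_kwargs)
    pair = PairedIntensity(
        i_systolic=results["systolic"].detected_fraction,
        i_diastolic=results["diastolic"].detected_fraction,
        wavelength_nm=wavelength_nm, theta_pl_deg=theta_pl_deg, rho=rho,
        spo2=spo2, n_photons=n_photons, seeds=(seed, seed),
        strict_phase_convention=strict_phase_convention)
    if pair.dc <= 0.0:
        log.warning("zero dc at theta=%s deg, lambda=%s nm: PI undefined",
                    theta_pl_deg, wavelength_nm)
    return pair


def perfusion_index(pair: PairedIntensity) -> float:
    """PI = ac / dc of one paired run."""
    if pair.dc <= 0.0:
        raise UndefinedRatioError("dc <= 0: perfusion index undefined")
    return pair.ac / pair.dc


def r_ratio(pi_red: float, pi_nir: float) -> float:
    """Ratio of ratios R = PI(660 nm) / PI(940 nm)."""
    if pi_nir <= 0.0:
        raise UndefinedRatioError("PI at the NIR wavelength must be > 0")
    return pi_red / pi_nir


def angle_sweep(model: FingerModel, *, thetas_deg=THETA_GRID_DEG,
                wavelengths_nm=(660.0, 940.0), spo2: float = 1.0,
                rho: float = 0.0, n_photons: int = 100_000,
                n_repeats: int = 1, seed: int = 0,
                **run_kwargs) -> pd.DataFrame:
    """Paired runs over the PD-angle grid at both wavelengths.

    Repeats use consecutive seeds (seed + repeat index).  Returns one row
    per (theta, wavelength) with mean dc, mean ac, PI, the relative std of
    dc over repeats, and the per-angle R ratio across the two wavelengths.
    """
    rows = []
    for theta in thetas_deg:
        per_lambda = {}
        for lam in wavelengths_nm:
            dcs, acs = [], []
            for rep in range(n_repeats):
                pair = paired_run(model, theta, lam, spo2, rho,
                                  n_photons, seed + rep, **run_kwargs)
                dcs.append(pair.dc)
                acs.append(pair.ac)
            dc_mean = float(np.mean(dcs))
            ac_mean = float(np.mean(acs))
            pi = ac_mean / dc_mean if dc_mean > 0 else math.nan
            if dc_mean <= 0:
                log.warning("dc = 0 at theta=%s, lambda=%s: excluded from "
                            "PI/R downstream", theta, lam)
            rel_std = (float(np.std(dcs, ddof=1)) / dc_mean
                       if n_repeats > 1 and dc_mean > 0 else math.nan)
            per_lambda[lam] = (dc_mean, ac_mean, pi, rel_std)
        pis = [per_lambda[lam][2] for lam in wavelengths_nm]
        r = (pis[0] / pis[1]
             if len(pis) == 2 and np.isfinite(pis[1]) and pis[1] > 0
             else math.nan)
        for lam in wavelengths_nm:
            dc_mean, ac_mean, pi, rel_std = per_lambda[lam]
            rows.append({"theta_deg": theta, "wavelength_nm": lam,
                         "rho": rho, "spo2": spo2, "n_photons": n_photons,
                         "n_repeats": n_repeats, "dc_mean": dc_mean,
                         "ac_mean": ac_mean, "pi": pi, "rel_std": rel_std,
                         "r_ratio": r})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# calibration and reliability
# --------------------------------------------------------------------------

def calibration_curve(per_angle_r: pd.DataFrame,
                      *, thetas_deg=THETA_GRID_DEG,
                      meta: dict | None = None) -> CalibrationCurve:
    """Average the per-angle R ratios into one R per SpO2 level.

    ``per_angle_r`` needs columns ``theta_deg``, ``spo2`` (fraction or
    percent) and ``r_ratio``; every angle of the grid must be present for
    every SpO2 level.
    """
    df = per_angle_r.copy()
    spo2_pct = df["spo2"].astype(float)
    if spo2_pct.max() <= 1.0:
        spo2_pct = spo2_pct * 100.0
    df["spo2_pct"] = spo2_pct.round(6)
    levels, means = [], []
    for level, sub in df.groupby("spo2_pct"):
        sub = sub.drop_duplicates(subset="theta_deg")
        missing = sorted(set(thetas_deg) - set(sub["theta_deg"]))
        if missing:
            raise ValueError(
                f"incomplete sweep at SpO2={level}%: missing angles "
                f"{missing}")
        sel = sub[sub["theta_deg"].isin(thetas_deg)]
        levels.append(float(level))
        means.append(float(sel["r_ratio"].mean()))
    return CalibrationCurve(spo2_percent=tuple(levels), r=tuple(means),
                            meta=meta or {})


def reliability_limits(curve: CalibrationCurve) -> ReliabilityLimits:
    """Midpoints of adjacent calibration R values: the SpO2 bin boundaries."""
    r = curve.r  # ordered for SpO2 100 -> 70
    if len(r) != 4:
        raise ValueError("reliability limits need the four-level curve")
    return ReliabilityLimits(l_r1=(r[0] + r[1]) / 2.0,
                             l_r2=(r[1] + r[2]) / 2.0,
                             l_r3=(r[2] + r[3]) / 2.0)


def classify_reliable(r: float, true_spo2_percent: float,
                      limits: ReliabilityLimits) -> bool:
    """True iff R falls inside the open bin assigned to the true SpO2.

    Bins: SpO2 100% -> R < L_R1; 90% -> L_R1 < R < L_R2;
    80% -> L_R2 < R < L_R3; 70% -> R > L_R3.  Values exactly on a limit
    classify as unreliable (strict inequalities).
    """
    l1, l2, l3 = limits.as_tuple()
    level = round(float(true_spo2_percent))
    if level == 100:
        return r < l1
    if level == 90:
        return l1 < r < l2
    if level == 80:
        return l2 < r < l3
    if level == 70:
        return r > l3
    raise ValueError(f"true SpO2 must be one of 70/80/90/100%, got "
                     f"{true_spo2_percent}")


def theta_max(reliability: pd.DataFrame) -> float | None:
    """Largest grid angle whose whole prefix is reliable at all SpO2 levels.

    ``reliability`` needs columns ``theta_deg``, ``spo2`` and ``reliable``
    (bool).  Returns None ("not measurable") when even the smallest angle
    fails for some SpO2 level.
    """
    ok_by_theta = reliability.groupby("theta_deg")["reliable"].all()
    ok_by_theta = ok_by_theta.sort_index()
    best = None
    for theta, ok in ok_by_theta.items():
        if not ok:
            break
        best = float(theta)
    return best


# --------------------------------------------------------------------------
# repetition statistics and arithmetic helpers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RepetitionStatistics:
    """Spread of the detected intensity over repeated seeded runs."""

    values: tuple[float, ...]        # raw detected fractions
    normalized: tuple[float, ...]    # values / mean(values)
    mean: float
    std_normalized: float
    three_sigma_percent: float       # 3*std of the normalized values, in %
    seeds: tuple[int, ...]

    def histogram(self, bins: int = 21):
        return np.histogram(self.normalized, bins=bins)


def repetition_statistics(model: FingerModel, *, theta_pl_deg: float = 25.0,
                          wavelength_nm: float = 660.0, rho: float = 0.0,
                          spo2: float = 1.0, phase: str = "diastolic",
                          n_photons: int = 100_000, n_repeats: int = 100,
                          seed: int = 0,
                          **run_kwargs) -> RepetitionStatistics:
    """Repeat one transport condition with consecutive seeds.

    The per-repeat detected fractions are normalized by their mean; the
    sample standard deviation of the normalized values gives the 3-sigma
    band (in percent of the mean) that bounds 99.73% of repeats for a
    Gaussian spread.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    state = getattr(PhysiologicalState, phase)(spo2=spo2)
    tmap = model.map_for(state, wavelength_nm)
    source = SourceConfig(wavelength_nm=wavelength_nm)
    detector = DetectorConfig(theta_pl_deg=theta_pl_deg)
    boundary = BoundaryConfig(rho=rho)
    seeds = tuple(seed + i for i in range(n_repeats))
    vals = []
    for s in seeds:
        res = run_simulation(tmap, source, detector, boundary,
                             n_photons, s, **run_kwargs)
        if res.detected_fraction == 0.0:
            log.warning("zero detection in repeat seed=%s (theta=%s deg); "
                        "retained as 0", s, theta_pl_deg)
        vals.append(res.detected_fraction)
    vals = np.asarray(vals)
    mean = float(vals.mean())
    norm = vals / mean if mean > 0 else np.full_like(vals, np.nan)
    std = float(np.std(norm, ddof=1))
    return RepetitionStatistics(values=tuple(float(v) for v in vals),
                                normalized=tuple(float(v) for v in norm),
                                mean=mean, std_normalized=std,
                                three_sigma_percent=300.0 * std,
                                seeds=seeds)


def enhancement(v0: float, v1: float) -> float:
    """Relative enhancement 100 * (v1 - v0) / v0 in percent."""
    if v0 <= 0.0:
        raise UndefinedRatioError("reference value must be > 0")
    return 100.0 * (v1 - v0) / v0


def led_duty_cycle(on_time_s: float = 50e-6,
                   period_s: float = 40e-3) -> float:
    """LED duty cycle in percent (default: one 50-us pulse per 40-ms frame)."""
    if period_s <= 0 or on_time_s < 0 or on_time_s > period_s:
        raise ValueError("need 0 <= on_time <= period and period > 0")
    return 100.0 * on_time_s / period_s
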