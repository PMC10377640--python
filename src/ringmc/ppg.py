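"""Two-wavelength PPG waveform processing and a synthetic-signal generator.

The measured-signal chain mirrors standard pulse-oximeter practice:

1. zero-phase band-pass filtering over the cardiac band (0.7-4 Hz) to
   strip baseline drift and high-frequency system noise,
2. envelope extraction — local minima/maxima of the filtered trace; the dc
   level is the mean of the raw signal at the bottom-envelope samples, the
   ac amplitude is the mean top-minus-bottom spread of the filtered trace,
3. band-ratio SNR: total power in 0.7-4 Hz over total power in 7-10 Hz,
   in dB, with a 15-dB nominal reliability floor,
4. PI = ac/dc per wavelength and R = PI(red)/PI(nir), flagged reliable for
   healthy subjects (SpO2 > 95%) when 0.5 < R < 0.7.

The generator produces a cardiac oscillation riding on a dc level with
optional low-frequency baseline drift and white noise, and records its
ground-truth dc/ac/PI so recovery can be tested quantitatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "PPGTrace", "EnvelopeResult", "SNRResult", "bandpass",
    "extract_envelopes", "snr_db", "pi_and_r", "synth_ppg",
    "read_trace_csv", "write_trace_csv",
]

SIGNAL_BAND_HZ = (0.7, 4.0)
NOISE_BAND_HZ = (7.0, 10.0)
SNR_LIMIT_DB = 15.0
R_WINDOW = (0.5, 0.7)     # reliable R range for SpO2 > 95%


def r_window_reliable(r: float) -> bool:
    """True iff R is strictly inside the healthy-subject window (0.5, 0.7)."""
    return R_WINDOW[0] < r < R_WINDOW[1]


class FlatSignalError(ValueError):
    """No cardiac peaks found in the trace."""


class InsufficientDataError(ValueError):
    """Trace too short for the requested operation."""


@dataclass(frozen=True)
class PPGTrace:
    """Uniformly sampled single-wavelength PPG time series."""

    time_s: np.ndarray
    values: np.ndarray
    wavelength_nm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValueError("time and values must be matching 1-D arrays")
        dt = np.diff(t)
        if np.ptp(dt) > 1e-9:
            raise ValueError("sampling must be uniform within 1e-9 s")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "values", v)

    @property
    def fs_hz(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def with_values(self, values: np.ndarray) -> "PPGTrace":
        return PPGTrace(time_s=self.time_s, values=np.asarray(values),
                        wavelength_nm=self.wavelength_nm, meta=dict(self.meta))


@dataclass(frozen=True)
class EnvelopeResult:
    """dc/ac extracted from the filtered trace's envelopes."""

    dc: float
    ac: float
    max_indices: np.ndarray
    min_indices: np.ndarray

    @property
    def n_peaks(self) -> int:
        return int(min(len(self.max_indices), len(self.min_indices)))


@dataclass(frozen=True)
class SNRResult:
    """Band-power ratio of the cardiac band over the noise band."""

    signal_power: float
    noise_power: float
    snr_db: float
    infinite: bool = False

    @property
    def reliable(self) -> bool:
        return (not self.infinite and self.snr_db >= SNR_LIMIT_DB) \
            or self.infinite


def bandpass(trace: PPGTrace, low_hz: float = SIGNAL_BAND_HZ[0],
             high_hz: float = SIGNAL_BAND_HZ[1]) -> PPGTrace:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward).

    Peak positions are preserved (no group delay); the dc offset is removed
    by construction.
    """
    fs = trace.fs_hz
    if fs <= 2.0 * high_hz:
        raise ValueError(f"sampling rate {fs} Hz must exceed twice the "
                         f"upper band edge {high_hz} Hz")
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=fs,
                     output="sos")
    # sosfiltfilt pads with ~3x the effective impulse-response length
    min_len = 3 * (2 * 4 + 1)
    if trace.values.size < 3 * min_len:
        raise InsufficientDataError(
            f"trace of {trace.values.size} samples too short to filter")
    out = trace.with_values(sps.sosfiltfilt(sos, trace.values))
    out.meta["bandpass_sos"] = sos   # for passband-gain compensation
    return out


def _refined_mean(values: np.ndarray, idx: np.ndarray) -> float:
    """Mean peak height with 3-point parabolic interpolation."""
    heights = []
    n = len(values)
    for i in idx:
        if 0 < i < n - 1:
            a, b, c = values[i - 1], values[i], values[i + 1]
            denom = a - 2.0 * b + c
            if denom < 0:   # proper local maximum of the parabola
                heights.append(b - (a - c) ** 2 / (8.0 * denom))
                continue
        heights.append(values[i])
    return float(np.mean(heights))


def _estimate_heart_rate(filtered: PPGTrace) -> float:
    """Spectral-peak heart-rate estimate within the cardiac band (Hz)."""
    f, p = sps.periodogram(filtered.values, fs=filtered.fs_hz)
    band = (f >= SIGNAL_BAND_HZ[0]) & (f <= SIGNAL_BAND_HZ[1])
    if not band.any() or not np.any(p[band] > 0):
        return 1.0
    return float(f[band][np.argmax(p[band])])


def extract_envelopes(filtered: PPGTrace,
                      raw: PPGTrace) -> EnvelopeResult:
    """dc/ac from the filtered trace's local extrema.

    Peaks are local extrema of the filtered trace with a minimum separation
    of a quarter cardiac period and a prominence of 10% of the trace's
    interquartile range.  dc is the mean of the *raw* signal sampled at the
    bottom-envelope (local-minimum) instants — the filtered trace has no
    baseline left to average; ac is the mean top envelope minus mean bottom
    envelope of the filtered trace, corrected for the band-pass filter's
    passband gain at the estimated heart rate (forward-backward filtering
    applies the magnitude response twice).
    """
    fv = filtered.values
    if np.ptp(fv) <= 0:
        raise FlatSignalError("constant trace: no envelopes")
    hr = _estimate_heart_rate(filtered)
    distance = max(1, int(0.25 / hr * filtered.fs_hz))
    q75, q25 = np.percentile(fv, [75, 25])
    prominence = 0.1 * (q75 - q25)
    if prominence <= 0:
        raise FlatSignalError("zero interquartile range: no envelopes")
    max_idx, _ = sps.find_peaks(fv, distance=distance, prominence=prominence)
    min_idx, _ = sps.find_peaks(-fv, distance=distance, prominence=prominence)
    if len(max_idx) == 0 or len(min_idx) == 0:
        raise FlatSignalError("no cardiac peaks found")
    # drop extrema inside the filter's edge-transient zone (two cardiac
    # periods at each end) when enough interior peaks remain
    margin = int(2.0 / hr * filtered.fs_hz)
    n = fv.size
    for name, idx in (("max", max_idx), ("min", min_idx)):
        interior = idx[(idx >= margin) & (idx < n - margin)]
        if len(interior) >= 3:
            if name == "max":
                max_idx = interior
            else:
                min_idx = interior
    dc = float(np.mean(raw.values[min_idx]))
    # parabolic refinement: the sampled extremum under-estimates the true
    # peak of a band-limited oscillation between samples
    ac = float(_refined_mean(fv, max_idx) + _refined_mean(-fv, min_idx))
    sos = filtered.meta.get("bandpass_sos")
    if sos is not None:
        _, h = sps.sosfreqz(sos, worN=[hr], fs=filtered.fs_hz)
        gain = float(np.abs(h[0])) ** 2
        if gain > 0.1:
            ac /= gain
    return EnvelopeResult(dc=dc, ac=ac, max_indices=max_idx,
                          min_indices=min_idx)


def snr_db(trace: PPGTrace) -> SNRResult:
    """Band-ratio SNR from the Welch power spectrum.

    Mean periodogram over 10-s segments with 50% overlap; powers are the
    integrated PSD over 0.7-4 Hz (signal) and 7-10 Hz (noise).
    """
    if trace.duration_s < 10.0:
        raise InsufficientDataError("need >= 10 s for 0.1-Hz resolution")
    fs = trace.fs_hz
    nperseg = min(int(10.0 * fs), trace.values.size)
    f, psd = sps.welch(trace.values, fs=fs, nperseg=nperseg,
                       noverlap=nperseg // 2)
    sig_band = (f >= SIGNAL_BAND_HZ[0]) & (f <= SIGNAL_BAND_HZ[1])
    noise_band = (f >= NOISE_BAND_HZ[0]) & (f <= NOISE_BAND_HZ[1])
    p_sig = float(np.trapezoid(psd[sig_band], f[sig_band]))
    p_noise = float(np.trapezoid(psd[noise_band], f[noise_band]))
    if p_noise <= 0.0:
        return SNRResult(signal_power=p_sig, noise_power=0.0,
                         snr_db=math.inf, infinite=True)
    return SNRResult(signal_power=p_sig, noise_power=p_noise,
                     snr_db=10.0 * math.log10(p_sig / p_noise))


def pi_and_r(trace_red: PPGTrace, trace_nir: PPGTrace) -> dict:
    """Full two-wavelength analysis: PI per wavelength, R, reliability flags.

    Returns a dict with dc/ac/pi per wavelength, ``r_ratio``, per-trace SNR
    (dB) and the two reliability flags (SNR >= 15 dB on both wavelengths;
    0.5 < R < 0.7, open interval).
    """
    out = {}
    pis = {}
    for tag, tr in (("red", trace_red), ("nir", trace_nir)):
        filt = bandpass(tr)
        env = extract_envelopes(filt, tr)
        if env.dc <= 0:
            raise FlatSignalError(f"non-positive dc on the {tag} trace")
        pi = env.ac / env.dc
        snr = snr_db(tr)
        pis[tag] = pi
        out[f"dc_{tag}"] = env.dc
        out[f"ac_{tag}"] = env.ac
        out[f"pi_{tag}"] = pi
        out[f"snr_db_{tag}"] = snr.snr_db
        out[f"snr_reliable_{tag}"] = bool(snr.reliable)
    if pis["nir"] <= 0:
        raise FlatSignalError("PI at the NIR wavelength must be > 0")
    r = pis["red"] / pis["nir"]
    out["r_ratio"] = r
    out["r_reliable"] = r_window_reliable(r)
    out["reliable"] = bool(out["r_reliable"]
                           and out["snr_reliable_red"]
                           and out["snr_reliable_nir"])
    return out


def synth_ppg(duration_s: float = 30.0, rate_hz: float = 25.0,
              heart_rate_hz: float = 1.2, dc_level: float = 100.0,
              pi: float = 0.02, drift_amplitude: float = 0.0,
              drift_hz: float = 0.05, noise_std: float = 0.0,
              seed: int = 0, wavelength_nm: float = 660.0,
              harmonic: float = 0.0) -> PPGTrace:
    """Synthesize a PPG trace with known ground truth.

    The cardiac waveform is a raised sinusoid (optionally with a second
    harmonic of relative amplitude ``harmonic`` for a more pulse-like
    shape), normalized to [0, 1], so the bottom envelope sits exactly at
    ``dc_level`` and the top at ``dc_level * (1 + pi)``.  Baseline drift
    is a slow sinusoid with random phase; noise is white Gaussian.
    Ground truth (dc, ac, pi, ...) is recorded in ``meta``.
    """
    if not SIGNAL_BAND_HZ[0] <= heart_rate_hz <= SIGNAL_BAND_HZ[1]:
        raise ValueError(f"heart rate {heart_rate_hz} Hz outside the "
                         f"cardiac band {SIGNAL_BAND_HZ}")
    # second harmonic is the highest generated frequency
    if rate_hz <= 2.0 * (2.0 * heart_rate_hz):
        raise ValueError(f"rate {rate_hz} Hz aliases the second harmonic "
                         f"of {heart_rate_hz} Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    phase0 = 2.0 * math.pi * rng.random()
    w = (np.sin(2.0 * math.pi * heart_rate_hz * t + phase0)
         + harmonic * np.sin(4.0 * math.pi * heart_rate_hz * t
                             + 2.0 * phase0))
    w = (w - w.min()) / np.ptp(w)
    ac = pi * dc_level
    drift_phase = 2.0 * math.pi * rng.random()
    drift = drift_amplitude * np.sin(2.0 * math.pi * drift_hz * t
                                     + drift_phase)
    noise = noise_std * rng.standard_normal(n)
    values = dc_level + ac * w + drift + noise
    meta = {"dc": dc_level, "ac": ac, "pi": pi,
            "heart_rate_hz": heart_rate_hz, "drift_amplitude":
            drift_amplitude, "drift_hz": drift_hz, "noise_std": noise_std,
            "seed": seed}
    return PPGTrace(time_s=t, values=values, wavelength_nm=wavelength_nm,
                    meta=meta)


# --------------------------------------------------------------------------
# trace I/O (comma-separated sample tables)
# --------------------------------------------------------------------------

def write_trace_csv(trace: PPGTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "value": trace.values,
                  "wavelength_nm": trace.wavelength_nm}).to_csv(
        path, index=False)


def read_trace_csv(path: str | Path) -> list[PPGTrace]:
    """Read one or more traces (split by wavelength) from a sample table."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty trace file: {path}")
    required = {"time_s", "value", "wavelength_nm"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    traces = []
    for lam, sub in df.groupby("wavelength_nm"):
        traces.append(PPGTrace(time_s=sub["time_s"].to_numpy(),
                               values=sub["value"].to_numpy(),
                               wavelength_nm=float(lam)))
    return traces
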