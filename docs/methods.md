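# Methods

## Finger model

The finger is a circular cylinder of diameter 1.7 cm (coincident with the
ring inner surface, no air gap), length 4.0 cm, axis along z. The
cross-section holds, outermost first:

| region | default thickness / size | note |
|---|---|---|
| epidermis | 100 µm | melanin-bearing |
| papillary dermis | 200 µm | |
| upper blood net dermis | 80 µm | blood-rich |
| reticular dermis | 800 µm | |
| deep blood net dermis | 300 µm | blood-rich |
| subcutaneous fat | fills the remainder | |
| bone | ellipse, semi-axes 0.25 × 0.15 cm at (0, 0.3) cm | |
| digital arteries | two circles, r = 0.08 cm at (±0.4, 0.45) cm | pulsatile |

The +y axis points from the finger center toward the LED-bearing surface,
so the bone and, beneath it on the LED side, the two arteries sit between
the center and the LED. Veins are omitted (their distribution varies too
much between people to assign a canonical geometry). θ_PL is measured along
the rim from the LED; the coordinate convention and every geometric number
are configurable.

### Optical properties

Layer absorption is mixed from chromophore volume fractions:

μa(λ) = f_blood·m·[s·μa,HbO₂(λ) + (1−s)·μa,Hb(λ)] + Σᵢ fᵢ·μa,i(λ)

with s the SpO₂ fraction and m the cardiac capillary blood-volume
multiplier (applied to every tissue layer except the arteries, whose
pulsation is geometric). The packaged chromophore table
(`ringmc/data/chromophores.csv`, 600–1000 nm) is assembled from standard
literature sources: hemoglobin molar extinctions converted to whole blood
at 150 g/L; water in the Hale–Querry range; melanosome melanin
1.70·10¹² λ⁻³·⁴⁸ cm⁻¹; a featureless skin baseline
0.244 + 85.3·exp(−(λ−154)/66.2) cm⁻¹; smooth lipid and collagen stand-ins.
Scattering coefficients are tabulated per layer at 660 and 940 nm
(dermis ≈ 190/125 cm⁻¹, g = 0.85; whole blood 800/650 cm⁻¹, g = 0.98;
etc., see `ringmc.properties`) and interpolated as a power law in between.

These defaults are *typical-literature stand-ins*, not a fitted dataset.
Quantities that depend on the absolute attenuation budget — detected
fractions, the mirror-enhancement factor, the absolute calibration R values
— inherit a factor-of-a-few uncertainty from them. Orderings (red vs. NIR
hemoglobin absorption, monotone angular decay, mirror ≥ absorber at every
angle, R rising as SpO₂ falls) do not.

### Cardiac states

Systole: artery radius 0.08 cm, capillary multiplier 1. Diastole: 0.092 cm,
1.5. With this parameterization the diastolic state carries *more* blood
and therefore detects *less* light, so the raw diastolic-minus-systolic
difference is negative. The package reports ac = |I_dia − I_sys| and
dc = max(I_sys, I_dia) by default, always records the signed raw value, and
offers `strict_phase_convention=True` for the literal
"dc = diastolic, ac = diastolic − systolic" reading.

## Transport kernel

Weighted-packet hop–drop–spin with Henyey–Greenstein scattering and Russian
roulette, compiled with numba (single thread, xorshift128+ RNG seeded via
splitmix64 from the user seed; bitwise reproducible).

* **Hop.** s = −ln ξ/μt, marched through the analytic geometry with a
  conservative lower bound on the distance to the nearest surface
  (concentric shells and outer cylinder: radial differences; end caps:
  axial distance; arteries: circle distance; bone: the gradient bound
  |∇f| ≤ 1/b for f = √((x/a)² + (y/b)²), giving distance ≥ |f−1|·b). A
  move shorter than the bound cannot change layers; near boundaries the
  march falls back to 1-µm forced advances, so boundary crossings are
  localized to ≤1 µm — small against the 80-µm thinnest layer and the
  ~50-µm mean free path. Crossing into another layer rescales the
  remaining path by μt,old/μt,new, preserving the sampled optical depth.
  Outer-surface crossings are resolved exactly (ray–cylinder/plane).
* **Drop.** ΔW = W·μa/μt deposited at each interaction (optionally into a
  200 × 200 cross-sectional fluence grid).
* **Spin.** Henyey–Greenstein inverse-CDF deflection cosine, uniform
  azimuth; g = 0 reduces to isotropic.
* **Surface.** A packet crossing the PD aperture (0.3 cm of arc × 0.3 cm
  axially, centered at θ_PL, all arrival angles) deposits its full weight
  and terminates; detection takes precedence over the surround. Otherwise
  the surround reflects it specularly with probability ρ and absorbs it
  otherwise. Interior refractive-index mismatches are ignored
  (index-matched interior); an optional Fresnel mode adds unpolarized
  Fresnel reflection at the finger surface. End caps absorb (the 4-cm
  cylinder makes this loss ~0.2% of launched weight even under the
  mirror).
* **Roulette.** Below threshold 0.1 a packet survives with probability 0.1
  and weight W/0.1 (≤ 1 by construction). Roulette is unbiased at any
  threshold; this aggressive default trades a modest variance increase for
  a ~5× shorter packet lifetime in the weakly absorbing red-wavelength
  tissue (albedo ≈ 0.999), and both knobs are configurable
  (`transport.rr_threshold/rr_survival`).

**Energy accounting.** The ledger {detected, absorbed-in-tissue,
absorbed-at-surround, lost-at-end-caps} sums to exactly 1 per launched unit
weight: roulette kills add to, and survival boosts subtract from, the
tissue-absorption bin (their expectations cancel; raw totals are reported
separately). Per-photon weights are accumulated locally before entering the
global sums, keeping the closure at the 10⁻⁹ level even for 10⁷-photon
runs; the test suite enforces 10⁻⁶.

## Experiment layer

* **Paired runs** share one seed between the systolic and diastolic arm
  (common random numbers): the two geometries differ only in the artery
  annulus and capillary fractions, so the paired difference (ac) is
  estimated with far less noise than with independent streams. Repeats use
  consecutive seeds (base + index), all recorded.
* **Calibration.** R per angle = PI₆₆₀/PI₉₄₀; the calibration curve is the
  mean of the 15 per-angle R values per SpO₂ level and must decrease
  strictly with SpO₂. Reliability limits are midpoints of adjacent curve
  values; an R exactly on a limit classifies as *unreliable* (open
  intervals). θ_max is the largest grid angle whose entire prefix has all
  four SpO₂ levels reliable; if 25° already fails, the configuration is
  "not measurable". The published reference curve
  (R = 0.9/1.25/1.5/1.9 at SpO₂ = 100/90/80/70%) ships as
  `REFERENCE_CALIBRATION_R` for downstream arithmetic.
* **Repetition statistics** normalize per-repeat detected fractions by
  their mean and report the sample std and the ±3σ percentage band
  (99.73% coverage under Gaussian spread). Zero-detection repeats are
  retained as 0 and logged.

## PPG analysis

* **Filter:** 4th-order Butterworth 0.7–4 Hz applied forward–backward
  (zero phase, so envelope peak positions do not shift); dc offset removed
  by construction.
* **Envelopes:** local extrema of the filtered trace, minimum separation a
  quarter of the spectral-peak cardiac period, prominence 10% of the
  interquartile range; extrema within two cardiac periods of either trace
  end are dropped (filter edge transients). dc = mean of the *raw* trace
  at the bottom-envelope instants (the filtered trace has no baseline
  left); ac = mean top minus mean bottom envelope of the filtered trace,
  with 3-point parabolic peak interpolation (the sampled extremum of a
  25-Hz trace underestimates the continuous peak by ~1%) and a correction
  for the filter's squared passband gain at the estimated heart rate.
* **SNR:** Welch spectrum (10-s segments, 50% overlap); band powers
  integrated over 0.7–4 Hz and 7–10 Hz; dB = 10·log₁₀ of the power ratio
  (power, not amplitude, spectra). 15 dB is the nominal reliability floor.
* **Generator:** raised sinusoid (optional second harmonic) scaled so the
  bottom envelope is exactly `dc` and the top `dc·(1+pi)`, plus a
  slow-drift sinusoid and white Gaussian noise, all seeded; ground truth
  recorded in the trace metadata. It emulates baseline wander and wideband
  noise but not motion artifacts, waveform-morphology variability
  (dicrotic notch), or sensor nonlinearity — passing recovery tests bounds
  estimator bias under the modelled disturbances only. The two wavelengths
  are treated as aligned 25-Hz streams; the sub-millisecond intra-frame
  pulse offset of a real interleaved driver is ignored as it is five
  orders of magnitude below cardiac timescales.

## Problem sizes and tolerances

Default-suite simulations use 10⁴–10⁶ packets per run (seconds each on one
core): 10⁶ per angle for the angular-decay check, 2.5·10⁵ for the mirror
arm of the enhancement check, and {10⁵, 10⁶, 10⁷} × {12, 10, 6} repeats of
the non-scattering closed-form configuration for the variance-scaling law.
`scripts/acceptance.py` uses 10⁷ (absorbing) and 4·10⁶ (mirror) packets.
The full-scale reference protocols of 10⁸ photons × 100 repeats (repetition
histograms, the simulated calibration curve, the θ_max-vs-photon-number
ladder) are reachable through `ringmc sweep`/`ringmc calibrate` with
`sweep.n_photons=100000000`, at hours of single-core runtime.

Monte Carlo assertions use 3 standard errors (closed-form or sample-based);
exact arithmetic (reliability limits, enhancement percentages, duty cycle,
3σ band) is asserted at printed precision.

## Known limitations

* Absolute detected fractions depend on the stand-in property table; the
  default model detects ~0.95% at θ_PL = 25° (absorbing surround) versus
  the reference 0.356%, and its perfect-mirror dc enhancement at 25° is
  ~210% versus the reported ~130% — same sign and order, different
  constant. A measured per-layer dataset can be dropped in via the layer
  configuration to recalibrate.
* No polarization, coherence, fluorescence or time-resolved transport; no
  PD responsivity/acceptance-angle model (intensity is a weight fraction).
* The gap between finger and ring is assumed zero; the gap-induced dc
  offset seen in worn devices is out of scope.
* Interior refractive-index mismatches between tissue layers are ignored
  (the surround model dominates surface behaviour in both device
  variants).
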