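"""Default per-layer optical properties for the layered finger model.

The skin is a seven-constituent mixture per layer: blood (split into oxy/
deoxy hemoglobin by SpO2 at mix time), water, fat, melanin, skin baseline and
collagen.  Scattering coefficients are tabulated at the two oximetry
wavelengths (660 and 940 nm) and interpolated as a power law in between.

These defaults are literature-typical values for Caucasian/Asian finger skin
(epidermis + four dermal sublayers), subcutaneous fat, cortical bone and
whole arterial blood.  Every number can be overridden through the experiment
configuration; the table here is a documented, reproducible starting point,
not a measurement.

Units: volume fractions dimensionless, mu_s in 1/cm, thickness in cm.
"""

from __future__ import annotations

#: canonical layer ordering; indices are used by the transport kernel
LAYERS = (
    "epidermis",
    "papillary_dermis",
    "upper_blood_net_dermis",
    "reticular_dermis",
    "deep_blood_net_dermis",
    "subcutaneous_fat",
    "bone",
    "artery_blood",
)

LAYER_INDEX = {name: i for i, name in enumerate(LAYERS)}

#: default layer table.  fractions: volume fraction of each chromophore;
#: mu_s_per_cm: scattering coefficient keyed by wavelength (nm);
#: g: scattering anisotropy; n: refractive index;
#: thickness_cm: radial shell thickness (skin layers only).
DEFAULT_LAYER_TABLE: dict[str, dict] = {
    "epidermis": {
        "fractions": {"blood": 0.0, "water": 0.20, "fat": 0.0,
                      "melanin": 0.03, "baseline": 0.37, "collagen": 0.25},
        "mu_s_per_cm": {660: 300.0, 940: 180.0},
        "g": 0.80, "n": 1.45, "thickness_cm": 0.010,
    },
    "papillary_dermis": {
        "fractions": {"blood": 0.02, "water": 0.50, "fat": 0.0,
                      "melanin": 0.0, "baseline": 0.18, "collagen": 0.25},
        "mu_s_per_cm": {660: 190.0, 940: 125.0},
        "g": 0.85, "n": 1.40, "thickness_cm": 0.020,
    },
    "upper_blood_net_dermis": {
        "fractions": {"blood": 0.08, "water": 0.55, "fat": 0.0,
                      "melanin": 0.0, "baseline": 0.12, "collagen": 0.20},
        "mu_s_per_cm": {660: 190.0, 940: 125.0},
        "g": 0.85, "n": 1.40, "thickness_cm": 0.008,
    },
    "reticular_dermis": {
        "fractions": {"blood": 0.03, "water": 0.60, "fat": 0.0,
                      "melanin": 0.0, "baseline": 0.10, "collagen": 0.25},
        "mu_s_per_cm": {660: 190.0, 940: 125.0},
        "g": 0.85, "n": 1.40, "thickness_cm": 0.080,
    },
    "deep_blood_net_dermis": {
        "fractions": {"blood": 0.06, "water": 0.60, "fat": 0.0,
                      "melanin": 0.0, "baseline": 0.09, "collagen": 0.22},
        "mu_s_per_cm": {660: 190.0, 940: 125.0},
        "g": 0.85, "n": 1.40, "thickness_cm": 0.030,
    },
    "subcutaneous_fat": {
        "fractions": {"blood": 0.02, "water": 0.15, "fat": 0.70,
                      "melanin": 0.0, "baseline": 0.08, "collagen": 0.03},
        "mu_s_per_cm": {660: 120.0, 940: 100.0},
        "g": 0.85, "n": 1.44, "thickness_cm": None,
    },
    "bone": {
        "fractions": {"blood": 0.03, "water": 0.25, "fat": 0.35,
                      "melanin": 0.0, "baseline": 0.07, "collagen": 0.28},
        "mu_s_per_cm": {660: 180.0, 940: 150.0},
        "g": 0.90, "n": 1.55, "thickness_cm": None,
    },
    "artery_blood": {
        "fractions": {"blood": 1.0, "water": 0.0, "fat": 0.0,
                      "melanin": 0.0, "baseline": 0.0, "collagen": 0.0},
        "mu_s_per_cm": {660: 800.0, 940: 650.0},
        "g": 0.98, "n": 1.40, "thickness_cm": None,
    },
}

#: order of the concentric skin shells, outermost first
SKIN_SHELLS = LAYERS[:5]
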