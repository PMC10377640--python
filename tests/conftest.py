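import numpy as np
import pandas as pd
import pytest

from ringmc import (ChromophoreSpectra, FingerModel, LayerComposition,
                    default_compositions)
from ringmc.properties import LAYERS


@pytest.fixture(scope="session")
def model() -> FingerModel:
    """Default finger model (embedded property table)."""
    return FingerModel.default()


@pytest.fixture(scope="session")
def spectra() -> ChromophoreSpectra:
    return ChromophoreSpectra.default()


def uniform_model(mu_a: float, mu_s: float, g: float = 0.5) -> FingerModel:
    """Finger-shaped but optically homogeneous model.

    A single-chromophore spectrum is scaled so that every layer has exactly
    the requested absorption and scattering; useful for closed-form checks
    (Beer-Lambert, variance scaling) where layer structure must not matter.
    """
    table = pd.DataFrame({
        "wavelength_nm": [600.0, 1000.0],
        "oxy_hb": [0.0, 0.0], "deoxy_hb": [0.0, 0.0],
        "water": [mu_a, mu_a], "fat": [0.0, 0.0], "melanin": [0.0, 0.0],
        "baseline": [0.0, 0.0], "collagen": [0.0, 0.0],
    })
    comps = []
    for name, base in zip(LAYERS, default_compositions()):
        comps.append(LayerComposition(
            layer=name, fractions={"water": 1.0},
            mu_s_per_cm={660.0: mu_s, 940.0: mu_s}, g=g, n=1.4,
            thickness_cm=base.thickness_cm))
    return FingerModel(geometry=FingerModel.default().geometry,
                       compositions=tuple(comps),
                       spectra=ChromophoreSpectra(table))


@pytest.fixture(scope="session")
def beer_lambert_model() -> FingerModel:
    """Non-scattering absorber (mu_a = 1/cm, mu_s = 0)."""
    return uniform_model(mu_a=1.0, mu_s=0.0)


@pytest.fixture(scope="session")
def fast_scattering_model() -> FingerModel:
    """Cheap scattering medium for estimator-statistics checks."""
    return uniform_model(mu_a=1.0, mu_s=20.0, g=0.5)
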