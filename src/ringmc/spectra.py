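"""Chromophore absorption spectra.

Tissue absorption is modelled as a volume-fraction mixture of chromophores:
oxygenated and deoxygenated whole blood, water, fat, melanin, a featureless
"skin baseline", and collagen.  The packaged default table
(``data/chromophores.csv``) stores the absorption coefficient of each pure
chromophore in 1/cm on a 600-1000 nm grid.  The ``oxy_hb`` / ``deoxy_hb``
columns are for whole blood at 150 g/L hemoglobin, so a layer's blood
contribution is simply ``f_blood * (s * mu_oxy + (1 - s) * mu_deoxy)`` with
``s`` the oxygen saturation fraction.

Users can load their own table from any plain-text columnar file with a
``wavelength_nm`` column and one column per chromophore.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

#: chromophore names expected by the layer-mixing code
CHROMOPHORES = ("oxy_hb", "deoxy_hb", "water", "fat", "melanin",
                "baseline", "collagen")


class SpectrumRangeError(ValueError):
    """Requested wavelength falls outside the tabulated range."""


class ChromophoreSpectra:
    """Tabulated absorption coefficients (1/cm) versus wavelength (nm).

    Lookup at a tabulated wavelength returns the stored value exactly;
    between nodes the table is interpolated linearly.  Lookups outside the
    tabulated range raise :class:`SpectrumRangeError`.
    """

    def __init__(self, table: pd.DataFrame):
        if "wavelength_nm" not in table.columns:
            raise ValueError("table must have a 'wavelength_nm' column")
        table = table.sort_values("wavelength_nm").reset_index(drop=True)
        if (table.drop(columns="wavelength_nm").to_numpy() < 0).any():
            raise ValueError("absorption coefficients must be >= 0")
        self._table = table
        self._lam = table["wavelength_nm"].to_numpy(dtype=float)

    @classmethod
    def default(cls) -> "ChromophoreSpectra":
        """The packaged literature-based default table."""
        ref = importlib.resources.files("ringmc").joinpath(
            "data/chromophores.csv")
        with importlib.resources.as_file(ref) as path:
            return cls(pd.read_csv(path))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChromophoreSpectra":
        return cls(pd.read_csv(path))

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self._lam.copy()

    @property
    def chromophores(self) -> tuple[str, ...]:
        return tuple(c for c in self._table.columns if c != "wavelength_nm")

    def absorption(self, chromophore: str, wavelength_nm: float) -> float:
        """Absorption coefficient (1/cm) of one chromophore at one wavelength."""
        if chromophore not in self._table.columns:
            raise KeyError(f"unknown chromophore {chromophore!r}")
        lam = self._lam
        if not (lam[0] <= wavelength_nm <= lam[-1]):
            raise SpectrumRangeError(
                f"wavelength {wavelength_nm} nm outside tabulated range "
                f"[{lam[0]}, {lam[-1]}] nm")
        col = self._table[chromophore].to_numpy(dtype=float)
        return float(np.interp(wavelength_nm, lam, col))

    def to_frame(self) -> pd.DataFrame:
        return self._table.copy()
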