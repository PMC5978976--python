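"""Photon interaction data for beam-quality modelling.

Mass attenuation coefficients (mu/rho) and mass energy-absorption
coefficients (mu_en/rho) are bundled as package data on a log-spaced
diagnostic-energy grid (10-150 keV) and interpolated log-log, the
standard treatment for smoothly varying photon cross sections.

Materials provided:

``Al``, ``Cu``
    Beam filters and the HVL reference material.
``air``
    Dry air near sea level; the kerma-weighting medium.
``soft_tissue``
    Water-equivalent soft tissue (density 1.06 g/cm3); water data are
    within ~2% of ICRU average soft tissue over this energy range.
``table_composite``
    Carbon-fibre tabletop material (graphite cross sections, bulk
    density 1.6 g/cm3).
``pad_foam``
    Low-density tissue-equivalent mattress foam (0.030 g/cm3).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ExtrapolationError

__all__ = ["AttenuationTable", "load_attenuation_table", "available_materials"]

_DATA_PACKAGE = "ripsa.data"
_COEFF_FILE = "attenuation_coefficients.csv"


@dataclass(frozen=True)
class AttenuationTable:
    """Tabulated photon coefficients for one material.

    Energies in keV (strictly increasing), coefficients in cm^2/g,
    density in g/cm^3.
    """

    material: str
    energies: np.ndarray
    mu_over_rho: np.ndarray
    mu_en_over_rho: np.ndarray
    density: float

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or e.size < 2 or not np.all(np.diff(e) > 0):
            raise ValueError("energy grid must be 1-D and strictly increasing")
        for name in ("mu_over_rho", "mu_en_over_rho"):
            c = np.asarray(getattr(self, name), dtype=float)
            if c.shape != e.shape or not np.all(c > 0):
                raise ValueError(f"{name} must be positive and match the energy grid")
        if self.density <= 0:
            raise ValueError("density must be positive")

    def _interp(self, table: np.ndarray, energies_kev) -> np.ndarray:
        e = np.atleast_1d(np.asarray(energies_kev, dtype=float))
        lo, hi = self.energies[0], self.energies[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ExtrapolationError(
                f"energy outside tabulated range [{lo}, {hi}] keV for {self.material}"
            )
        return np.exp(np.interp(np.log(e), np.log(self.energies), np.log(table)))

    def mu_over_rho_at(self, energies_kev) -> np.ndarray:
        """Mass attenuation coefficient, cm^2/g, log-log interpolated."""
        return self._interp(self.mu_over_rho, energies_kev)

    def mu_en_over_rho_at(self, energies_kev) -> np.ndarray:
        """Mass energy-absorption coefficient, cm^2/g, log-log interpolated."""
        return self._interp(self.mu_en_over_rho, energies_kev)

    def linear_mu_at(self, energies_kev) -> np.ndarray:
        """Linear attenuation coefficient, 1/cm, at bulk density."""
        return self.mu_over_rho_at(energies_kev) * self.density


def _load_frame() -> pd.DataFrame:
    with resources.files(_DATA_PACKAGE).joinpath(_COEFF_FILE).open() as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=None)
def load_attenuation_table(material: str) -> AttenuationTable:
    """Load the bundled coefficient table for ``material``."""
    df = _load_frame()
    sub = df[df["material"] == material].sort_values("energy_keV")
    if sub.empty:
        known = sorted(df["material"].unique())
        raise KeyError(f"unknown material {material!r}; available: {known}")
    return AttenuationTable(
        material=material,
        energies=sub["energy_keV"].to_numpy(float),
        mu_over_rho=sub["mu_over_rho"].to_numpy(float),
        mu_en_over_rho=sub["mu_en_over_rho"].to_numpy(float),
        density=float(sub["density_g_cm3"].iloc[0]),
    )


def available_materials() -> list[str]:
    return sorted(_load_frame()["material"].unique())
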