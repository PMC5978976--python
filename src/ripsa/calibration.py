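"""OSLD correction-factor algebra.

Optically stimulated luminescent dosimeters (OSLDs) are characterised
free-in-air against an ion chamber and on-phantom via Monte Carlo
energy-deposition tallies. Two kinds of correction factor connect the
domains:

* ``CF_measured = D_IC,air / D_OSL,air`` — the measured, energy-
  dependent cross-calibration converting an OSLD free-in-air dose to
  the ion-chamber (and hence dose-map) domain.
* ``CF_montecarlo = F6(geometry) / F6(air)`` — the simulated ratio of
  OSLD energy deposition in a complex geometry (on phantom, with the
  beam through table and/or pad) to free-in-air, which packs the
  backscatter, tissue-conversion and attenuation terms of the skin-
  dose product into a single factor.

From these, the predicted on-phantom OSLD response is
``D_OSL,air * CF_montecarlo``, and a ray-traced dose map is brought
into the OSLD domain by dividing by ``CF_measured``.

Tally values and free-in-air doses are *inputs* here (measured or
simulated elsewhere); this module owns only the algebra and its
bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import QualityError, SchemaError
from .engine import DoseMap

__all__ = [
    "TallyEntry",
    "MonteCarloTally",
    "OSLDReading",
    "CorrectionFactorSet",
    "cf_measured",
    "cf_montecarlo",
    "predict_osld",
    "ripsa_to_osld_domain",
    "dosemap_to_osld_domain",
    "fit_beta",
    "read_osld_readings",
    "write_osld_readings",
]

GEOMETRIES = ("phantom", "phantom+table", "phantom+table+pad")
_MAX_RELATIVE_ERROR = 0.05


@dataclass(frozen=True)
class TallyEntry:
    """One Monte Carlo energy-deposition tally (MeV/g per source photon)."""

    value: float
    relative_error: float = 0.0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise SchemaError("tally value must be > 0")
        if not (0 <= self.relative_error < 1):
            raise SchemaError("relative error must lie in [0, 1)")


@dataclass(frozen=True)
class MonteCarloTally:
    """Energy-deposition tallies keyed by irradiation geometry ('air', ...)."""

    f6_osl: Mapping[str, TallyEntry]

    def entry(self, geometry: str) -> TallyEntry:
        try:
            return self.f6_osl[geometry]
        except KeyError:
            raise KeyError(f"no tally for geometry {geometry!r}") from None


@dataclass(frozen=True)
class OSLDReading:
    """A single dosimeter reading at grid index (i, j), mGy."""

    i: int
    j: int
    dose_mGy: float
    beam_quality: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.dose_mGy < 0:
            raise SchemaError("OSLD dose must be >= 0")


def cf_measured(d_ic_air: float, d_osl_air: float) -> float:
    """Ion-chamber / OSLD free-in-air dose ratio for one beam quality."""
    if d_ic_air <= 0 or d_osl_air <= 0:
        raise ValueError("free-in-air doses must be > 0")
    return d_ic_air / d_osl_air


def cf_montecarlo(
    tally_geometry: TallyEntry,
    tally_air: TallyEntry,
    max_relative_error: float = _MAX_RELATIVE_ERROR,
) -> float:
    """Geometry-to-air tally ratio; rejects statistically poor tallies."""
    for label, entry in (("geometry", tally_geometry), ("air", tally_air)):
        if entry.relative_error >= max_relative_error:
            raise QualityError(
                f"{label} tally relative error {entry.relative_error:.3f} exceeds "
                f"{max_relative_error:.3f}"
            )
    return tally_geometry.value / tally_air.value


def predict_osld(d_osl_air: float, cf_mc: float) -> float:
    """Predicted on-phantom OSLD response from its free-in-air dose."""
    if d_osl_air <= 0 or cf_mc <= 0:
        raise ValueError("inputs must be > 0")
    return d_osl_air * cf_mc


def ripsa_to_osld_domain(d_ripsa: float, cf_measured_value: float) -> float:
    """Convert a ray-traced dose into the OSLD reading domain."""
    if cf_measured_value <= 0:
        raise ValueError("CF_measured must be > 0")
    return d_ripsa / cf_measured_value


@dataclass(frozen=True)
class CorrectionFactorSet:
    """Correction factors for a set of beam qualities.

    ``cf_measured_by_quality`` is keyed by (kVp, mm Cu);
    ``cf_montecarlo_by_key`` by (kVp, mm Cu, geometry, angle_deg) with
    geometry one of ``phantom``, ``phantom+table``,
    ``phantom+table+pad``. Angles other than the characterised ones are
    linearly interpolated between neighbours (clamped at the ends,
    since only those angles were characterised).
    """

    cf_measured_by_quality: Mapping[tuple[float, float], float]
    cf_montecarlo_by_key: Mapping[tuple[float, float, str, float], float]
    d_ic_air: Mapping[tuple[float, float], float] = field(default_factory=dict)
    d_osl_air: Mapping[tuple[float, float], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.cf_measured_by_quality.values()) or any(
            v <= 0 for v in self.cf_montecarlo_by_key.values()
        ):
            raise SchemaError("all correction factors must be > 0")

    def cf_meas(self, kvp: float, cu_mm: float) -> float:
        try:
            return self.cf_measured_by_quality[(float(kvp), float(cu_mm))]
        except KeyError:
            raise KeyError(f"no CF_measured for beam quality ({kvp}, {cu_mm})") from None

    def cf_mc(self, kvp: float, cu_mm: float, geometry: str, angle_deg: float = 0.0) -> float:
        if geometry not in GEOMETRIES:
            raise KeyError(f"unknown geometry {geometry!r}; expected one of {GEOMETRIES}")
        angles = sorted(
            a
            for (k, c, g, a) in self.cf_montecarlo_by_key
            if (k, c, g) == (float(kvp), float(cu_mm), geometry)
        )
        if not angles:
            raise KeyError(
                f"no CF_montecarlo for ({kvp}, {cu_mm}, {geometry!r}) at any angle"
            )
        values = [
            self.cf_montecarlo_by_key[(float(kvp), float(cu_mm), geometry, a)] for a in angles
        ]
        return float(np.interp(angle_deg, angles, values))

    def to_csv(self, path: str | Path) -> Path:
        rows = [
            {"kvp": k, "cu_mm": c, "geometry": "measured", "angle_deg": 0.0, "cf": v}
            for (k, c), v in sorted(self.cf_measured_by_quality.items())
        ] + [
            {"kvp": k, "cu_mm": c, "geometry": g, "angle_deg": a, "cf": v}
            for (k, c, g, a), v in sorted(self.cf_montecarlo_by_key.items())
        ]
        path = Path(path)
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrectionFactorSet":
        df = pd.read_csv(path)
        meas, mc = {}, {}
        for row in df.itertuples(index=False):
            if row.geometry == "measured":
                meas[(float(row.kvp), float(row.cu_mm))] = float(row.cf)
            else:
                mc[(float(row.kvp), float(row.cu_mm), str(row.geometry), float(row.angle_deg))] = (
                    float(row.cf)
                )
        return cls(cf_measured_by_quality=meas, cf_montecarlo_by_key=mc)


def dosemap_to_osld_domain(
    dosemap: DoseMap,
    cf_set: CorrectionFactorSet,
    quality_by_event: Mapping[str, tuple[float, float]],
) -> np.ndarray:
    """Per-point dose map in the OSLD domain.

    Each event's ledger contribution is divided by the CF_measured of
    that event's beam quality, then the converted contributions are
    summed; this honours logs that mix beam qualities.
    """
    out = np.zeros_like(dosemap.dose)
    for event_id, contrib in dosemap.ledger:
        kvp, cu = quality_by_event[event_id]
        out = out + contrib / cf_set.cf_meas(kvp, cu)
    return out


def fit_beta(model_doses_at_unit_beta: np.ndarray, measured_doses: np.ndarray) -> float:
    """Least-squares KAP-meter calibration factor.

    The dose model is linear in beta, so the fit is the closed-form
    projection sum(d_model * d_meas) / sum(d_model^2) over calibration
    exposures.
    """
    m = np.asarray(model_doses_at_unit_beta, float)
    y = np.asarray(measured_doses, float)
    if m.shape != y.shape or m.size == 0 or not np.any(m != 0):
        raise ValueError("need matching, non-degenerate calibration exposures")
    return float(np.dot(m, y) / np.dot(m, m))


def read_osld_readings(path: str | Path) -> list[OSLDReading]:
    """Read an OSLD grid CSV (columns i, j, dose_mGy)."""
    df = pd.read_csv(path)
    return [
        OSLDReading(i=int(r.i), j=int(r.j), dose_mGy=float(r.dose_mGy))
        for r in df.itertuples(index=False)
    ]


def write_osld_readings(readings: Sequence[OSLDReading], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"i": r.i, "j": r.j, "dose_mGy": r.dose_mGy} for r in readings]
    ).to_csv(path, index=False)
    return path
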