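"""Validation arithmetic: percent errors, summaries, map-vs-OSLD comparison.

Percent error is defined against the *measured* value,

    percent_error = 100 * (predicted - measured) / measured,

so a prediction below the measurement is negative. Report output
rounds half-away-from-zero to one decimal; summary statistics always
use the unrounded values.

The bundled reference table (``load_reference_tables``) carries the
published OSLD benchmark measurements — measured and predicted
on-phantom doses for nine beam qualities under three geometries
(phantom only, beam through table, beam through table and pad) and an
angular study — so the validation arithmetic can be exercised and
audited without access to the original instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import OSLDReading
from .errors import SchemaError

__all__ = [
    "ComparisonRow",
    "PercentErrorSummary",
    "percent_error",
    "round_report",
    "summarize",
    "compare_map_to_osld",
    "field_alignment_check",
    "load_reference_tables",
    "recompute_reference_errors",
]

_TABLE_FILE = "osld_validation_tables.csv"


def percent_error(measured: float, predicted: float) -> float:
    """Signed percent deviation of a prediction from its measurement."""
    if measured <= 0:
        raise ValueError("measured value must be > 0")
    return 100.0 * (predicted - measured) / measured


def round_report(value: float, decimals: int = 1) -> float:
    """Half-away-from-zero rounding used only at presentation time."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ComparisonRow:
    """One measured-vs-predicted pair and its percent error."""

    key: tuple
    measured: float
    predicted: float
    percent_error: float
    scatter_only: bool = False

    @property
    def percent_error_report(self) -> float:
        return round_report(self.percent_error)


@dataclass(frozen=True)
class PercentErrorSummary:
    minimum: float
    maximum: float
    mean: float
    mean_absolute: float
    n: int


def summarize(rows: Iterable[ComparisonRow | float]) -> PercentErrorSummary:
    """Summary statistics of unrounded percent errors.

    Accepts comparison rows (scatter-only rows are excluded — they
    carry no ray-traced dose to compare) or bare percent-error floats.
    """
    errors = [
        (r.percent_error if isinstance(r, ComparisonRow) else float(r))
        for r in rows
        if not (isinstance(r, ComparisonRow) and r.scatter_only)
    ]
    if not errors:
        raise ValueError("no comparable rows to summarize")
    arr = np.asarray(errors, float)
    return PercentErrorSummary(
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        mean=float(arr.mean()),
        mean_absolute=float(np.abs(arr).mean()),
        n=arr.size,
    )


def compare_map_to_osld(
    map_dose_by_index: Mapping[tuple[int, int], float] | Sequence[tuple[tuple[int, int], float]],
    readings: Sequence[OSLDReading],
) -> list[ComparisonRow]:
    """Compare a dose map (already in the OSLD domain) against readings.

    Points are matched by exact (i, j). A point where the map reports
    zero dose but the dosimeter read a nonzero value is flagged
    ``scatter_only`` — the ray tracer deliberately ignores scatter from
    adjacent fields, so such points are informative, not errors — and
    excluded from ratio statistics. Points where both are zero are
    skipped. Duplicate reading indices are rejected.
    """
    if not isinstance(map_dose_by_index, Mapping):
        map_dose_by_index = dict(map_dose_by_index)
    seen: set[tuple[int, int]] = set()
    rows: list[ComparisonRow] = []
    for r in readings:
        idx = (r.i, r.j)
        if idx in seen:
            raise SchemaError(f"duplicate OSLD reading at grid index {idx}")
        seen.add(idx)
        if idx not in map_dose_by_index:
            raise KeyError(f"OSLD reading at {idx} has no matching map point")
        ripsa = float(map_dose_by_index[idx])
        if ripsa == 0.0 and r.dose_mGy == 0.0:
            continue
        if ripsa == 0.0:
            rows.append(
                ComparisonRow(
                    key=idx,
                    measured=r.dose_mGy,
                    predicted=0.0,
                    percent_error=-100.0,
                    scatter_only=True,
                )
            )
            continue
        rows.append(
            ComparisonRow(
                key=idx,
                measured=r.dose_mGy,
                predicted=ripsa,
                percent_error=percent_error(r.dose_mGy, ripsa),
            )
        )
    return rows


def field_alignment_check(field_displacement_cm: float, grid_spacing_cm: float) -> float:
    """Remainder of the field displacement modulo the dosimeter spacing.

    A zero remainder means the displaced field's center lands exactly
    on dosimeter centers, so point-by-point agreement between the map
    and the dosimeter grid can be expected; a nonzero remainder means
    the comparison is inherently offset by a sub-pitch shift.
    """
    if grid_spacing_cm <= 0:
        raise ValueError("grid spacing must be > 0")
    return float(field_displacement_cm % grid_spacing_cm)


def load_reference_tables() -> pd.DataFrame:
    """Published OSLD benchmark: measured/predicted doses and printed errors."""
    with resources.files("ripsa.data").joinpath(_TABLE_FILE).open() as fh:
        return pd.read_csv(fh)


def recompute_reference_errors() -> pd.DataFrame:
    """Recompute every benchmark row's percent error from its printed doses.

    Adds ``percent_error_recomputed`` (unrounded) and
    ``percent_error_report`` (1-decimal, half-away-from-zero) columns
    next to the printed value.
    """
    df = load_reference_tables().copy()
    df["percent_error_recomputed"] = [
        percent_error(m, p) for m, p in zip(df["measured_mGy"], df["predicted_mGy"])
    ]
    df["percent_error_report"] = [round_report(e) for e in df["percent_error_recomputed"]]
    return df
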