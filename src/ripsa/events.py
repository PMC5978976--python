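"""Irradiation-event data model and event-log I/O.

Every dose-map run starts from a log of irradiation events — one
record per fluoroscopic exposure carrying the reference air kerma, the
beam quality, and the C-arm/table geometry, i.e. the per-event scalars
a radiation dose structured report (RDSR) exposes. Logs are flat JSON
arrays or CSV files with snake_case keys matching the
:class:`IrradiationEvent` fields exactly; units are fixed (mGy, cm,
kV, degrees, mm Cu) and never inferred.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ParseError, SchemaError

__all__ = ["IrradiationEvent", "CalibrationConfig", "read_event_log", "write_event_log"]

logger = logging.getLogger(__name__)

_MANDATORY = (
    "event_id",
    "k_ar",
    "kvp",
    "field_w_iso",
    "field_h_iso",
    "sod",
    "d_ref",
)


@dataclass(frozen=True)
class IrradiationEvent:
    """One fluoroscopic irradiation event.

    Attributes
    ----------
    event_id:
        Stable identifier, unique within a log.
    k_ar:
        Cumulative reference air kerma for the event, mGy.
    kvp:
        Peak tube potential, kV (40-150).
    added_filtration_mm_cu:
        Added copper filtration, mm (0 allowed).
    field_w_iso, field_h_iso:
        Collimated field side lengths at isocenter, cm.
    gantry_primary_deg, gantry_secondary_deg:
        C-arm rotation angles, degrees (conventions in
        :mod:`ripsa.geometry`).
    sod:
        Source-to-isocenter distance, cm.
    d_ref:
        Source-to-reference-point distance, cm (the point at which
        k_ar is stated).
    table_lateral_cm, table_longitudinal_cm, table_height_cm:
        Table offsets relative to the reference table position, cm.
    n_pulses, pulse_width_ms, tube_current_ma:
        Exposure protocol bookkeeping; not used by the dose model.
    """

    event_id: str
    k_ar: float
    kvp: float
    field_w_iso: float
    field_h_iso: float
    sod: float
    d_ref: float
    added_filtration_mm_cu: float = 0.0
    gantry_primary_deg: float = 0.0
    gantry_secondary_deg: float = 0.0
    table_lateral_cm: float = 0.0
    table_longitudinal_cm: float = 0.0
    table_height_cm: float = 0.0
    n_pulses: int = 1
    pulse_width_ms: float = 500.0
    tube_current_ma: float = 500.0

    def __post_init__(self) -> None:
        if not self.event_id:
            raise SchemaError("event_id must be a non-empty string")
        checks = [
            (self.k_ar >= 0, "k_ar must be >= 0"),
            (40.0 <= self.kvp <= 150.0, "kvp must lie in [40, 150]"),
            (self.field_w_iso > 0, "field_w_iso must be > 0"),
            (self.field_h_iso > 0, "field_h_iso must be > 0"),
            (self.sod > 0, "sod must be > 0"),
            (self.d_ref > 0, "d_ref must be > 0"),
            (self.added_filtration_mm_cu >= 0, "added_filtration_mm_cu must be >= 0"),
            (self.n_pulses >= 0, "n_pulses must be >= 0"),
            (self.pulse_width_ms >= 0, "pulse_width_ms must be >= 0"),
            (self.tube_current_ma >= 0, "tube_current_ma must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise SchemaError(f"event {self.event_id!r}: {msg}")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise SchemaError(f"event {self.event_id!r}: {f.name} must be finite")

    @property
    def beam_quality(self) -> tuple[float, float]:
        """(kVp, mm Cu) key identifying the beam quality."""
        return (self.kvp, self.added_filtration_mm_cu)


@dataclass(frozen=True)
class CalibrationConfig:
    """KAP-meter cross-calibration factor beta.

    ``beta`` is either a scalar applied to every event or a mapping
    keyed by ``(kvp, added_filtration_mm_cu)``; when a keyed lookup is
    missing the scalar fallback broadcasts. The system studied here
    never published its beta, so the default is 1.0.
    """

    beta: float | Mapping[tuple[float, float], float] = 1.0
    description: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.beta, Mapping):
            if not self.beta or any(v <= 0 for v in self.beta.values()):
                raise SchemaError("all beta values must be > 0")
        elif self.beta <= 0:
            raise SchemaError("beta must be > 0")

    def beta_for(self, kvp: float, added_filtration_mm_cu: float) -> float:
        if isinstance(self.beta, Mapping):
            key = (float(kvp), float(added_filtration_mm_cu))
            if key in self.beta:
                return float(self.beta[key])
            raise SchemaError(f"no beta entry for beam quality {key}")
        return float(self.beta)


_FIELD_TYPES = {f.name: f.type for f in fields(IrradiationEvent)}
_FLOAT_FIELDS = [f.name for f in fields(IrradiationEvent) if f.name not in ("event_id", "n_pulses")]


def _event_from_record(record: Mapping[str, object], index: int) -> IrradiationEvent:
    known = set(_FIELD_TYPES)
    unknown = set(record) - known
    if unknown:
        logger.warning("record %d: ignoring unknown fields %s", index, sorted(unknown))
    missing = [k for k in _MANDATORY if k not in record or record[k] in ("", None)]
    if missing:
        raise SchemaError(f"record {index}: missing mandatory field(s) {missing}")
    kwargs: dict[str, object] = {"event_id": str(record["event_id"])}
    for name in _FLOAT_FIELDS:
        if name in record and record[name] not in ("", None):
            try:
                kwargs[name] = float(record[name])  # type: ignore[arg-type]
            except (TypeError, ValueError) as exc:
                raise ParseError(f"record {index}: field {name!r} is not numeric") from exc
    if "n_pulses" in record and record["n_pulses"] not in ("", None):
        try:
            kwargs["n_pulses"] = int(float(record["n_pulses"]))  # type: ignore[arg-type]
        except (TypeError, ValueError) as exc:
            raise ParseError(f"record {index}: field 'n_pulses' is not numeric") from exc
    return IrradiationEvent(**kwargs)  # type: ignore[arg-type]


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("json", "csv"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return dialect
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv"):
        return suffix
    raise ValueError(f"cannot infer dialect from {path.name!r}; pass dialect=")


def read_event_log(path: str | Path, dialect: str | None = None) -> list[IrradiationEvent]:
    """Read an event log, validating every record.

    Events are returned in file order. Unknown fields are ignored with
    a logged warning; missing mandatory fields or non-numeric values
    raise :class:`SchemaError` / :class:`ParseError` naming the record.
    """
    path = Path(path)
    kind = _infer_dialect(path, dialect)
    if kind == "json":
        with path.open() as fh:
            payload = json.load(fh)
        if not isinstance(payload, list):
            raise SchemaError("JSON event log must be a top-level array")
        records: Iterable[Mapping[str, object]] = payload
    else:
        with path.open(newline="") as fh:
            records = list(csv.DictReader(fh))
    return [_event_from_record(rec, i) for i, rec in enumerate(records)]


def write_event_log(
    events: Sequence[IrradiationEvent], path: str | Path, dialect: str | None = None
) -> Path:
    """Write events so that :func:`read_event_log` round-trips them."""
    path = Path(path)
    kind = _infer_dialect(path, dialect)
    rows = [asdict(e) for e in events]
    if kind == "json":
        path.write_text(json.dumps(rows, indent=1) + "\n")
    else:
        names = [f.name for f in fields(IrradiationEvent)]
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=names)
            writer.writeheader()
            for row in rows:
                writer.writerow({k: repr(v) if isinstance(v, float) else v for k, v in row.items()})
    return path
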