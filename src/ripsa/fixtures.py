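"""Deterministic generators of benchmark-shaped scenarios.

Every other module is testable with no external data because this
module fabricates complete, self-consistent inputs that mirror the
physical validation campaign:

* nine beam qualities: {50, 80, 100} kVp x {0, 0.2, 0.6} mm added Cu;
* a 32-cm-diameter, 17.5-cm cylinder phantom with dosimeter centers on
  a uniform 1.5-cm grid;
* 15x15 and 5x5 cm^2 fields at isocenter; incidence angles 0/30/60
  degrees; beam-through-table and beam-through-table-and-pad variants;
* two two-field irradiation patterns: fields displaced by 6 cm
  (cranial-caudal and table-height) hitting the bare phantom, and by
  4 cm (cranial-caudal and left-right) through table and pad.

Synthetic OSLD readings are the ray-traced ground truth carried into
the OSLD domain, optionally inflated by a border scatter kernel and
multiplicative lognormal read noise. The scatter kernel is not
physics: its only job is to reproduce the systematic sign of real
comparisons — dosimeters read *higher* than a scatter-free ray tracer.
With ``noise_cv = 0`` and ``scatter_fraction = 0`` the readings equal
the ground truth exactly, closing the validation loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .calibration import CorrectionFactorSet, OSLDReading, dosemap_to_osld_domain
from .engine import (
    BeamQualityTables,
    DoseMap,
    EngineConfig,
    accumulate,
    beam_quality_spectrum,
)
from .events import CalibrationConfig, IrradiationEvent
from .geometry import PhantomGrid, SlabConfig, build_grid
from .spectrum import compute_hvl, slab_transmission_factor, spectrum_weighted_mu_en_ratio

__all__ = ["ScenarioSpec", "Scenario", "SCENARIO_NAMES", "nine_beam_qualities", "make_scenario"]

SCENARIO_NAMES = (
    "table2_grid",
    "table3_grid",
    "table4_grid",
    "table5_angles",
    "fig7_two_fields",
    "fig8_two_fields",
)

#: Source-to-isocenter distance, cm (typical interventional C-arm).
SOD_CM = 75.0
#: Source-to-reference-point distance, cm (patient entrance reference
#: point, 15 cm from isocenter toward the source).
D_REF_CM = 60.0

#: Per-beam-quality reference air kerma, mGy, sized to the magnitudes
#: of the benchmark on-phantom exposures (five 500-ms, 500-mA pulses).
K_AR_BY_QUALITY: Mapping[tuple[float, float], float] = {
    (50.0, 0.0): 65.6,
    (80.0, 0.0): 179.8,
    (100.0, 0.0): 276.5,
    (50.0, 0.2): 13.0,
    (80.0, 0.2): 61.9,
    (100.0, 0.2): 108.2,
    (50.0, 0.6): 1.7,
    (80.0, 0.6): 21.5,
    (100.0, 0.6): 43.8,
}

_CHARACTERIZED_ANGLES = (0.0, 30.0, 60.0)


def nine_beam_qualities() -> list[tuple[float, float]]:
    """The full (kVp, mm Cu) cross product {50, 80, 100} x {0, 0.2, 0.6}."""
    return [(kvp, cu) for kvp in (50.0, 80.0, 100.0) for cu in (0.0, 0.2, 0.6)]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic validation scenario."""

    name: str
    seed: int = 0
    noise_cv: float = 0.02
    scatter_fraction: float = 0.05
    beam_qualities: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}; known: {SCENARIO_NAMES}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not (0 <= self.scatter_fraction < 0.3):
            raise ValueError("scatter_fraction must lie in [0, 0.3)")


@dataclass(frozen=True)
class Scenario:
    """A fully materialised scenario: inputs, truth, and synthetic readings."""

    spec: ScenarioSpec
    events: tuple[IrradiationEvent, ...]
    config: EngineConfig
    grid: PhantomGrid
    cf_set: CorrectionFactorSet
    ground_truth: DoseMap
    readings: tuple[OSLDReading, ...]

    @property
    def quality_by_event(self) -> dict[str, tuple[float, float]]:
        return {e.event_id: e.beam_quality for e in self.events}


def _quality_label(kvp: float, cu: float) -> str:
    return f"{kvp:g}kVp_{cu:g}Cu"


def _grid_event(kvp: float, cu: float, prefix: str, field_side: float = 15.0, **kw) -> IrradiationEvent:
    return IrradiationEvent(
        event_id=f"{prefix}_{_quality_label(kvp, cu)}",
        k_ar=K_AR_BY_QUALITY[(kvp, cu)],
        kvp=kvp,
        added_filtration_mm_cu=cu,
        field_w_iso=field_side,
        field_h_iso=field_side,
        sod=SOD_CM,
        d_ref=D_REF_CM,
        n_pulses=5,
        **kw,
    )


def _synthetic_cf_measured(kvp: float, cu: float) -> float:
    # Deterministic, mildly energy-dependent cross-calibration near 1;
    # the real detector pair was never published, so this is a stand-in
    # shaped like a measured CF (harder beams read slightly higher).
    return 0.92 + 0.0006 * kvp + 0.03 * cu


_GEOMETRY_SLABS = {
    "phantom": SlabConfig.none(),
    "phantom+table": SlabConfig.table_only(),
    "phantom+table+pad": SlabConfig.table_and_pad(),
}


def _build_cf_set(
    qualities: Sequence[tuple[float, float]],
    tables: BeamQualityTables,
    field_side_cm: float,
) -> CorrectionFactorSet:
    """Correction factors consistent with the dose engine's own physics.

    CF_montecarlo packs BSF * (mu_en/rho ratio) * AF for each geometry
    and angle, exactly the bracketed term of the rearranged skin-dose
    product, so engine output and calibration algebra close on each
    other. CF_measured and the free-in-air doses behind it are
    synthetic (see :func:`_synthetic_cf_measured`).
    """
    meas, mc, d_ic, d_osl = {}, {}, {}, {}
    for kvp, cu in qualities:
        spec = beam_quality_spectrum(kvp, cu)
        hvl = compute_hvl(spec)
        ratio = spectrum_weighted_mu_en_ratio(spec, "soft_tissue", "air")
        bsf = float(tables.bsf(hvl, field_side_cm))
        cfm = _synthetic_cf_measured(kvp, cu)
        meas[(kvp, cu)] = cfm
        d_osl[(kvp, cu)] = 10.0
        d_ic[(kvp, cu)] = 10.0 * cfm
        for geometry, slabs in _GEOMETRY_SLABS.items():
            stack = [(s.material, s.thickness_mm) for s in slabs.slabs]
            for angle in _CHARACTERIZED_ANGLES:
                af = slab_transmission_factor(spec, stack, angle)
                mc[(kvp, cu, geometry, angle)] = bsf * ratio * af
    return CorrectionFactorSet(
        cf_measured_by_quality=meas,
        cf_montecarlo_by_key=mc,
        d_ic_air=d_ic,
        d_osl_air=d_osl,
    )


def _scenario_events(spec: ScenarioSpec) -> tuple[tuple[IrradiationEvent, ...], object, float]:
    """Events, slab configuration, and field size for a scenario name."""
    qualities = list(spec.beam_qualities or nine_beam_qualities())
    name = spec.name
    if name == "table2_grid":
        return (
            tuple(_grid_event(k, c, "table2") for k, c in qualities),
            SlabConfig.none(),
            15.0,
        )
    if name == "table3_grid":
        return (
            tuple(_grid_event(k, c, "table3") for k, c in qualities),
            SlabConfig.table_only(),
            15.0,
        )
    if name == "table4_grid":
        return (
            tuple(_grid_event(k, c, "table4") for k, c in qualities),
            SlabConfig.table_and_pad(),
            15.0,
        )
    if name == "table5_angles":
        events, slab_by_event = [], {}
        for pad in (False, True):
            for angle in _CHARACTERIZED_ANGLES:
                ev = IrradiationEvent(
                    event_id=f"table5_{'pad' if pad else 'nopad'}_{angle:g}deg",
                    k_ar=45.0,
                    kvp=80.0,
                    added_filtration_mm_cu=0.2,
                    field_w_iso=5.0,
                    field_h_iso=5.0,
                    gantry_secondary_deg=angle,
                    sod=SOD_CM,
                    d_ref=D_REF_CM,
                    n_pulses=5,
                )
                events.append(ev)
                slab_by_event[ev.event_id] = (
                    SlabConfig.table_and_pad() if pad else SlabConfig.table_only()
                )
        return tuple(events), slab_by_event, 5.0
    # two-field patterns: 5x5 cm^2 fields at 80 kVp / 0.2 mm Cu
    base = IrradiationEvent(
        event_id="fieldA",
        k_ar=45.0,
        kvp=80.0,
        added_filtration_mm_cu=0.2,
        field_w_iso=5.0,
        field_h_iso=5.0,
        sod=SOD_CM,
        d_ref=D_REF_CM,
        n_pulses=5,
    )
    if name == "fig7_two_fields":
        # 6-cm displacement in the cranial-caudal and table-height
        # directions; 6 is a multiple of the 1.5-cm grid pitch, so the
        # displaced field center lands exactly on dosimeter centers.
        other = replace(base, event_id="fieldB", table_longitudinal_cm=6.0, table_height_cm=6.0)
        return (base, other), SlabConfig.none(), 5.0
    # fig8_two_fields: 4-cm displacement (cranial-caudal and
    # left-right), beam through table and pad; 4 mod 1.5 != 0.
    other = replace(base, event_id="fieldC", table_longitudinal_cm=4.0, table_lateral_cm=4.0)
    return (base, other), SlabConfig.table_and_pad(), 5.0


def _border_indices(grid: PhantomGrid, in_field: np.ndarray) -> np.ndarray:
    """Out-of-field points within one grid step of an in-field point."""
    index_of = grid.index_map()
    infield_set = {tuple(ij) for ij in grid.indices[in_field]}
    border = np.zeros(grid.n_points, dtype=bool)
    for k, (i, j) in enumerate(grid.indices):
        if in_field[k]:
            continue
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if (di or dj) and (i + di, j + dj) in infield_set:
                    border[k] = True
                    break
            if border[k]:
                break
    return border


def make_scenario(spec: ScenarioSpec) -> Scenario:
    """Materialise a scenario: events, correction factors, truth, readings.

    Synthetic readings are built point-wise from the ground-truth map
    carried into the OSLD domain:

    * in-field points gain a multiplicative ``1 + scatter_fraction``
      excess (dosimeters see scatter the ray tracer ignores);
    * out-of-field points bordering the field receive
      ``scatter_fraction`` times their brightest in-field neighbour
      (scatter-only points);
    * every nonzero reading is then scaled by a lognormal factor with
      unit mean and coefficient of variation ``noise_cv``.

    The same seed always yields bit-identical output.
    """
    grid = build_grid()
    events, slab_config, field_side = _scenario_events(spec)
    tables = BeamQualityTables()
    config = EngineConfig(
        calibration=CalibrationConfig(beta=1.0),
        tables=tables,
        slab_config=slab_config,
    )
    ground_truth = accumulate(events, grid, config)
    qualities = sorted({e.beam_quality for e in events})
    cf_set = _build_cf_set(qualities, tables, field_side)

    quality_by_event = {e.event_id: e.beam_quality for e in events}
    osld_domain = dosemap_to_osld_domain(ground_truth, cf_set, quality_by_event)

    in_field = ground_truth.dose > 0
    readings_dose = osld_domain.copy()
    if spec.scatter_fraction > 0:
        readings_dose[in_field] *= 1.0 + spec.scatter_fraction
        border = _border_indices(grid, in_field)
        index_of = grid.index_map()
        for k in np.flatnonzero(border):
            i, j = grid.indices[k]
            neighbours = [
                osld_domain[index_of[(i + di, j + dj)]]
                for di in (-1, 0, 1)
                for dj in (-1, 0, 1)
                if (di or dj) and (i + di, j + dj) in index_of
            ]
            readings_dose[k] = spec.scatter_fraction * max(neighbours)
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=grid.n_points)
        readings_dose = readings_dose * factors

    unique_quality = qualities[0] if len(qualities) == 1 else None
    readings = tuple(
        OSLDReading(
            i=int(i), j=int(j), dose_mGy=float(readings_dose[k]), beam_quality=unique_quality
        )
        for k, (i, j) in enumerate(grid.indices)
        if readings_dose[k] > 0
    )
    return Scenario(
        spec=spec,
        events=events,
        config=config,
        grid=grid,
        cf_set=cf_set,
        ground_truth=ground_truth,
        readings=readings,
    )
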