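import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from ripsa import BeamQualityTables, IrradiationEvent, build_grid
from ripsa.geometry import PhantomGrid, TraceResult


@pytest.fixture(scope="session")
def default_grid():
    return build_grid()


@pytest.fixture(scope="session")
def default_tables():
    return BeamQualityTables()


@pytest.fixture()
def basic_event():
    return IrradiationEvent(
        event_id="e0",
        k_ar=100.0,
        kvp=80.0,
        added_filtration_mm_cu=0.2,
        field_w_iso=15.0,
        field_h_iso=15.0,
        sod=75.0,
        d_ref=60.0,
    )


def flat_bsf_tables(bsf_value: float, mu_en_ratio: float, af: float, quality):
    """Engine tables with every conversion factor pinned to a known constant."""
    rows = [
        {"hvl_mm_al": h, "field_side_cm": s, "bsf": bsf_value}
        for h in (0.1, 50.0)
        for s in (0.1, 1000.0)
    ]
    return BeamQualityTables(
        bsf_table=pd.DataFrame(rows),
        mu_en_ratio_lookup={quality: mu_en_ratio},
        af_mode="lookup",
        af_lookup={quality: af},
    )


def single_point_trace(d_skin: float, field_side_skin: float = 10.0) -> TraceResult:
    """A hand-built one-point trace for exercising the dose product."""
    grid = PhantomGrid(
        radius=16.0,
        length=17.5,
        spacing=1.5,
        positions=np.array([[0.0, 0.0, 0.0]]),
        normals=np.array([[0.0, -1.0, 0.0]]),
        indices=np.array([[0, 0]]),
    )
    return TraceResult(
        grid=grid,
        beam=None,
        slab_config=__import__("ripsa").SlabConfig.none(),
        in_field=np.array([True]),
        d_skin=np.array([d_skin]),
        incidence_angle_deg=np.array([0.0]),
        field_w_skin=np.array([field_side_skin]),
        field_h_skin=np.array([field_side_skin]),
        slab_paths={},
    )
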