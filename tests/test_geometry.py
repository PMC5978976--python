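"""Phantom grid construction, beam geometry, and ray tracing."""

import numpy as np
import pytest

from ripsa import (
    IrradiationEvent,
    Slab,
    SlabConfig,
    beam_from_event,
    build_grid,
    trace,
    two_field_overlap,
)
from ripsa.errors import GeometryError
from ripsa.geometry import PhantomGrid


def make_event(**overrides):
    base = dict(
        event_id="e", k_ar=100.0, kvp=80.0, field_w_iso=15.0, field_h_iso=15.0,
        sod=75.0, d_ref=60.0,
    )
    base.update(overrides)
    return IrradiationEvent(**base)


class TestBuildGrid:
    def test_neighbor_spacing_is_exactly_the_dosimeter_pitch(self, default_grid):
        index_of = default_grid.index_map()
        for k, (i, j) in enumerate(default_grid.indices):
            if (i + 1, j) in index_of:
                d = np.linalg.norm(
                    default_grid.positions[index_of[(i + 1, j)]] - default_grid.positions[k]
                )
                assert d == pytest.approx(1.5, abs=1e-12)

    def test_disc_filter_count_matches_combinatorial_oracle(self):
        radius, spacing = 16.0, 8.0
        grid = build_grid(radius=radius, spacing=spacing)
        n = int(np.floor(radius / spacing))
        expected = sum(
            1
            for i in range(-n, n + 1)
            for j in range(-n, n + 1)
            if (i * spacing) ** 2 + (j * spacing) ** 2 <= radius**2 + 1e-6
        )
        assert (2 * n + 1) ** 2 >= grid.n_points == expected

    def test_normals_unit_and_points_on_face(self, default_grid):
        assert np.allclose(np.linalg.norm(default_grid.normals, axis=1), 1.0, atol=1e-12)
        assert np.all(default_grid.positions[:, 1] == 0.0)
        radial = np.hypot(default_grid.positions[:, 0], default_grid.positions[:, 2])
        assert np.all(radial <= default_grid.radius + 1e-6)

    def test_row_major_ordering(self, default_grid):
        order = [tuple(ij) for ij in default_grid.indices]
        assert order == sorted(order)

    @pytest.mark.parametrize("kwargs", [dict(radius=-1), dict(spacing=0), dict(length=-2),
                                        dict(radius=1.0, spacing=1.5)])
    def test_bad_dimensions_rejected(self, kwargs):
        with pytest.raises(GeometryError):
            build_grid(**kwargs)


class TestBeamFromEvent:
    def test_half_angle_closed_form(self):
        beam = beam_from_event(make_event())
        assert beam.half_angle_w == pytest.approx(np.arctan(7.5 / 75.0), rel=1e-12)
        np.testing.assert_allclose(beam.source_position, [0, -75, 0], atol=1e-12)
        np.testing.assert_allclose(beam.central_axis, [0, 1, 0], atol=1e-12)

    def test_secondary_angle_tilts_axis_from_grid_normal(self, default_grid):
        beam = beam_from_event(make_event(gantry_secondary_deg=30.0))
        inward = -default_grid.normals[0]  # (0, 1, 0)
        angle = np.degrees(np.arccos(np.clip(beam.central_axis @ inward, -1, 1)))
        assert angle == pytest.approx(30.0, abs=1e-9)

    def test_table_offset_shifts_parallel_beam_by_6cm_on_skin_plane(self):
        a = beam_from_event(make_event())
        b = beam_from_event(make_event(table_longitudinal_cm=6.0))
        np.testing.assert_allclose(a.central_axis, b.central_axis, atol=1e-12)
        # central-axis intersections with the skin plane y = 0
        def face_hit(beam):
            t = -beam.source_position[1] / beam.central_axis[1]
            return beam.source_position + t * beam.central_axis
        assert np.linalg.norm(face_hit(a) - face_hit(b)) == pytest.approx(6.0, abs=1e-12)


class TestTrace:
    def test_axis_point_in_field_at_sod(self, default_grid):
        tr = trace(beam_from_event(make_event()), default_grid)
        k = default_grid.index_map()[(10, 10)]  # the face center
        assert tr.in_field[k]
        assert tr.d_skin[k] == pytest.approx(75.0, rel=1e-12)
        assert tr.incidence_angle_deg[k] == pytest.approx(0.0, abs=1e-9)

    def test_point_outside_small_field_not_in_field(self, default_grid):
        tr = trace(beam_from_event(make_event(field_w_iso=5, field_h_iso=5)), default_grid)
        idx = default_grid.index_map()
        # points strictly beyond the 2.5-cm half field must be out
        for (i, j), k in idx.items():
            x, _, z = default_grid.positions[k]
            if abs(x) > 2.6 or abs(z) > 2.6:
                assert not tr.in_field[k]

    def test_classification_agrees_with_plane_side_oracle(self):
        """Tan-based pyramid test vs an independent four-plane half-space
        oracle over 1e5 random point samples across 50 random beams."""
        rng = np.random.default_rng(42)
        eps = 1e-6
        checked = 0
        for _ in range(50):
            ev = make_event(
                field_w_iso=float(rng.uniform(3, 20)),
                field_h_iso=float(rng.uniform(3, 20)),
                sod=float(rng.uniform(55, 95)),
                gantry_primary_deg=float(rng.uniform(-25, 25)),
                gantry_secondary_deg=float(rng.uniform(-25, 25)),
                table_lateral_cm=float(rng.uniform(-4, 4)),
                table_longitudinal_cm=float(rng.uniform(-4, 4)),
            )
            beam = beam_from_event(ev)
            pts = np.column_stack(
                [
                    rng.uniform(-20, 20, 2000),
                    np.zeros(2000),
                    rng.uniform(-20, 20, 2000),
                ]
            )
            grid = PhantomGrid(
                radius=16.0, length=17.5, spacing=1.5,
                positions=pts,
                normals=np.tile([0.0, -1.0, 0.0], (len(pts), 1)),
                indices=np.column_stack([np.arange(len(pts)), np.zeros(len(pts), int)]),
            )
            tr = trace(beam, grid)
            # oracle: inward-facing normals of the four collimator planes
            s, axis = beam.source_position, beam.central_axis
            tw, th = np.tan(beam.half_angle_w), np.tan(beam.half_angle_h)
            corners = [
                axis + sw * tw * beam.u_width + sh * th * beam.u_height
                for sw, sh in [(-1, -1), (-1, 1), (1, 1), (1, -1)]
            ]
            planes = [np.cross(corners[m], corners[(m + 1) % 4]) for m in range(4)]
            planes = [p / np.linalg.norm(p) for p in planes]
            v = pts - s
            dots = np.column_stack([v @ p for p in planes])
            sign = 1.0 if np.all(np.column_stack([axis @ p for p in planes]) > 0) else -1.0
            inside_oracle = np.all(sign * dots >= 0, axis=1) & (v @ axis > 0)
            clear = np.all(np.abs(dots) > eps * np.linalg.norm(v, axis=1)[:, None], axis=1)
            assert np.array_equal(tr.in_field[clear], inside_oracle[clear])
            checked += int(clear.sum())
        assert checked > 90_000

    def test_slab_path_thickness_at_normal_and_60deg(self, default_grid):
        slabs = SlabConfig((Slab("table", "Al", 1.5, -10.0),))
        tr0 = trace(beam_from_event(make_event()), default_grid, slabs)
        k = default_grid.index_map()[(10, 10)]
        assert tr0.slab_paths["table"][k] == pytest.approx(1.5, rel=1e-12)
        tr60 = trace(beam_from_event(make_event(gantry_secondary_deg=60.0)), default_grid, slabs)
        assert tr60.slab_paths["table"][k] == pytest.approx(3.0, rel=1e-12)

    def test_frame_independence_under_translation(self, default_grid):
        ev = make_event(gantry_primary_deg=10, gantry_secondary_deg=20)
        beam = beam_from_event(ev)
        tr = trace(beam, default_grid)
        shift = np.array([3.0, -7.0, 11.0])
        moved_grid = PhantomGrid(
            radius=default_grid.radius, length=default_grid.length,
            spacing=default_grid.spacing,
            positions=default_grid.positions + shift,
            normals=default_grid.normals, indices=default_grid.indices,
        )
        from dataclasses import replace
        moved_beam = replace(beam, source_position=beam.source_position + shift)
        tr2 = trace(moved_beam, moved_grid)
        assert np.array_equal(tr.in_field, tr2.in_field)
        np.testing.assert_allclose(tr.d_skin, tr2.d_skin, rtol=1e-12)

    def test_d_skin_bounded_below_by_sod_minus_radius(self, default_grid):
        for angles in [(0, 0), (15, 30), (-20, 45)]:
            ev = make_event(gantry_primary_deg=angles[0], gantry_secondary_deg=angles[1])
            tr = trace(beam_from_event(ev), default_grid)
            assert np.all(tr.d_skin >= ev.sod - default_grid.radius - 1e-9)

    def test_source_inside_phantom_rejected(self, default_grid):
        with pytest.raises(GeometryError):
            trace(
                beam_from_event(
                    make_event(field_w_iso=0.1, field_h_iso=0.1, sod=0.5, table_height_cm=-5.0)
                ),
                default_grid,
            )


class TestTwoFieldOverlap:
    def test_identical_beams_overlap_everywhere_in_field(self, default_grid):
        tr = trace(beam_from_event(make_event()), default_grid)
        overlap = two_field_overlap(tr, tr)
        assert overlap == {tuple(ij) for ij in default_grid.indices[tr.in_field]}

    def test_disjoint_beams_30cm_apart_share_nothing(self, default_grid):
        a = trace(beam_from_event(make_event(field_w_iso=5, field_h_iso=5)), default_grid)
        b = trace(
            beam_from_event(
                make_event(field_w_iso=5, field_h_iso=5, table_longitudinal_cm=30.0)
            ),
            default_grid,
        )
        assert two_field_overlap(a, b) == set()

    def test_6cm_displaced_5cm_fields_are_spatially_separate(self, default_grid):
        """6-cm displacement exceeds the ~5.4-cm field side at the face, so
        the two fields do not intersect; both centers land on dosimeter
        centers because 6 is a multiple of the 1.5-cm pitch."""
        a = trace(beam_from_event(make_event(field_w_iso=5, field_h_iso=5)), default_grid)
        b = trace(
            beam_from_event(
                make_event(field_w_iso=5, field_h_iso=5,
                           table_longitudinal_cm=6.0, table_height_cm=6.0)
            ),
            default_grid,
        )
        assert two_field_overlap(a, b) == set()
        assert a.in_field.sum() > 0 and b.in_field.sum() > 0
        assert (6.0 % default_grid.spacing) == 0.0

    def test_4cm_displaced_fields_overlap(self, default_grid):
        """4-cm diagonal displacement leaves a corner intersection strip."""
        a = trace(beam_from_event(make_event(field_w_iso=5, field_h_iso=5)), default_grid)
        b = trace(
            beam_from_event(
                make_event(field_w_iso=5, field_h_iso=5,
                           table_longitudinal_cm=4.0, table_lateral_cm=4.0)
            ),
            default_grid,
        )
        assert len(two_field_overlap(a, b)) > 0

    def test_grid_mismatch_rejected(self, default_grid):
        other = build_grid(spacing=1.0)
        a = trace(beam_from_event(make_event()), default_grid)
        b = trace(beam_from_event(make_event()), other)
        with pytest.raises(GeometryError):
            two_field_overlap(a, b)
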