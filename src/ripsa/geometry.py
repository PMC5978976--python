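"""Phantom skin grid, C-arm beam construction, and ray tracing.

Coordinate convention (documented because vendors do not share one):
the patient/phantom frame is right-handed with +x patient-left,
+y anterior (up from the table), +z cranial. The phantom is a tissue
cylinder whose irradiated flat face lies in the y = 0 plane, centred
on the isocenter, with the body extending toward +y; the dosimeter
grid sits on that face with outward normals -y (facing the under-table
source). At gantry (0, 0) the source sits below the table at
(0, -sod, 0) pointing +y (posterior-anterior beam). The primary gantry
angle rotates the source about +z (axial plane), the secondary about
+x (sagittal plane), both right-handed.

Table offsets move the patient relative to the beam: an offset
``(lateral, height, longitudinal)`` in patient axes (x, y, z)
translates the source and its aim point by the negated offset in the
phantom frame.

The collimated field is a rectangular pyramid (four planes) with
half-angles set by the field size at isocenter; the "width" axis is
patient-lateral and the "height" axis cranial-caudal at gantry (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import GeometryError
from .events import IrradiationEvent

__all__ = [
    "PhantomGrid",
    "BeamGeometry",
    "Slab",
    "SlabConfig",
    "TraceResult",
    "build_grid",
    "beam_from_event",
    "trace",
    "two_field_overlap",
    "DEFAULT_TABLE_SLAB",
    "DEFAULT_PAD_SLAB",
]

_SURFACE_TOL = 1e-6


@dataclass(frozen=True)
class PhantomGrid:
    """Lattice of skin points on the irradiated face of the cylinder phantom.

    ``positions`` (N, 3) cm, ``normals`` (N, 3) unit outward vectors,
    ``indices`` (N, 2) 0-based (i, j) grid indices in row-major order.
    Defaults model a 32-cm-diameter, 17.5-cm-long tissue cylinder with
    dosimeter centers on a uniform 1.5-cm grid.
    """

    radius: float
    length: float
    spacing: float
    positions: np.ndarray
    normals: np.ndarray
    indices: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.positions)

    def index_map(self) -> dict[tuple[int, int], int]:
        """(i, j) -> row position, for exact index matching."""
        return {(int(i), int(j)): k for k, (i, j) in enumerate(self.indices)}

    def same_lattice(self, other: "PhantomGrid") -> bool:
        return (
            self.positions.shape == other.positions.shape
            and np.array_equal(self.indices, other.indices)
            and np.allclose(self.positions, other.positions)
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "i": self.indices[:, 0],
                "j": self.indices[:, 1],
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
            }
        )


def build_grid(radius: float = 16.0, length: float = 17.5, spacing: float = 1.5) -> PhantomGrid:
    """Lay skin points on the flat irradiated face of the cylinder.

    Candidate points at exact ``spacing`` on a square lattice centred
    on the cylinder axis are kept when they fall inside the face disc.
    Ordering is row-major by (i, j); indices are 0-based.
    """
    if radius <= 0 or length <= 0 or spacing <= 0:
        raise GeometryError("radius, length and spacing must all be positive")
    if spacing >= radius:
        raise GeometryError("grid spacing must be smaller than the phantom radius")
    n = int(np.floor(radius / spacing))
    positions, indices = [], []
    for i in range(-n, n + 1):  # x (patient-lateral)
        for j in range(-n, n + 1):  # z (cranial-caudal)
            x, z = i * spacing, j * spacing
            if x * x + z * z <= radius * radius + _SURFACE_TOL:
                positions.append((x, 0.0, z))
                indices.append((i + n, j + n))
    pos = np.asarray(positions, dtype=float)
    normals = np.tile(np.array([0.0, -1.0, 0.0]), (len(pos), 1))
    return PhantomGrid(
        radius=radius,
        length=length,
        spacing=spacing,
        positions=pos,
        normals=normals,
        indices=np.asarray(indices, dtype=int),
    )


@dataclass(frozen=True)
class BeamGeometry:
    """Source position and rectangular collimation pyramid for one event."""

    source_position: np.ndarray
    central_axis: np.ndarray  # unit, source -> isocenter
    u_width: np.ndarray  # unit, transverse "width" direction
    u_height: np.ndarray  # unit, transverse "height" direction
    half_angle_w: float  # radians
    half_angle_h: float
    sod: float
    d_ref: float

    def __post_init__(self) -> None:
        for name in ("central_axis", "u_width", "u_height"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise GeometryError(f"{name} must be a unit vector")
        if not (0 < self.half_angle_w < np.pi / 4 and 0 < self.half_angle_h < np.pi / 4):
            raise GeometryError("half-angles must lie in (0, pi/4)")


def _rot_x(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_z(alpha: float) -> np.ndarray:
    c, s = np.cos(alpha), np.sin(alpha)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def beam_from_event(
    event: IrradiationEvent, isocenter: Sequence[float] = (0.0, 0.0, 0.0)
) -> BeamGeometry:
    """Construct the beam geometry an event describes.

    The source sits at distance ``sod`` from the (table-shifted)
    isocenter along the gantry direction; collimation half-angles
    satisfy tan(half_angle) = (field_side / 2) / sod.
    """
    offset = np.array(
        [event.table_lateral_cm, event.table_height_cm, event.table_longitudinal_cm]
    )
    iso = np.asarray(isocenter, dtype=float) - offset
    alpha = np.radians(event.gantry_primary_deg)
    phi = np.radians(event.gantry_secondary_deg)
    rot = _rot_z(alpha) @ _rot_x(phi)
    source_dir = rot @ np.array([0.0, -1.0, 0.0])  # isocenter -> source
    source = iso + event.sod * source_dir
    axis = -source_dir
    u_w = rot @ np.array([1.0, 0.0, 0.0])
    u_h = rot @ np.array([0.0, 0.0, -1.0])
    return BeamGeometry(
        source_position=source,
        central_axis=axis,
        u_width=u_w,
        u_height=u_h,
        half_angle_w=float(np.arctan(0.5 * event.field_w_iso / event.sod)),
        half_angle_h=float(np.arctan(0.5 * event.field_h_iso / event.sod)),
        sod=float(event.sod),
        d_ref=float(event.d_ref),
    )


@dataclass(frozen=True)
class Slab:
    """A uniform attenuating slab crossed by the beam before the skin.

    The slab is a horizontal layer at ``y_plane_cm`` (patient frame)
    of ``thickness_mm``; ``half_extent_cm`` optionally bounds it
    laterally (in x and z).
    """

    name: str
    material: str
    thickness_mm: float
    y_plane_cm: float
    half_extent_cm: float | None = None

    def __post_init__(self) -> None:
        if self.thickness_mm < 0:
            raise GeometryError("slab thickness must be >= 0")


#: Tabletop modelled as its aluminium-equivalent thickness (1.5 mm Al),
#: 10 cm below the phantom face; swap in ``table_composite`` with a
#: physical thickness for an explicit carbon-fibre model.
DEFAULT_TABLE_SLAB = Slab("table", "Al", 1.5, -10.0)
#: 70-mm low-density foam mattress pad resting on the tabletop.
DEFAULT_PAD_SLAB = Slab("pad", "pad_foam", 70.0, -9.0)


@dataclass(frozen=True)
class SlabConfig:
    """The set of slabs present in a given irradiation geometry."""

    slabs: tuple[Slab, ...] = ()

    @classmethod
    def none(cls) -> "SlabConfig":
        return cls(())

    @classmethod
    def table_only(cls) -> "SlabConfig":
        return cls((DEFAULT_TABLE_SLAB,))

    @classmethod
    def table_and_pad(cls) -> "SlabConfig":
        return cls((DEFAULT_TABLE_SLAB, DEFAULT_PAD_SLAB))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SlabConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        slabs = []
        for name, cfg in payload.items():
            slabs.append(
                Slab(
                    name=name,
                    material=cfg["material"],
                    thickness_mm=float(cfg["thickness_mm"]),
                    y_plane_cm=float(cfg.get("y_plane_cm", -10.0)),
                    half_extent_cm=(
                        float(cfg["half_extent_cm"]) if "half_extent_cm" in cfg else None
                    ),
                )
            )
        return cls(tuple(slabs))

    def to_yaml(self, path: str | Path) -> Path:
        payload = {}
        for s in self.slabs:
            entry = {
                "material": s.material,
                "thickness_mm": s.thickness_mm,
                "y_plane_cm": s.y_plane_cm,
            }
            if s.half_extent_cm is not None:
                entry["half_extent_cm"] = s.half_extent_cm
            payload[s.name] = entry
        path = Path(path)
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path


@dataclass(frozen=True)
class TraceResult:
    """Per-skin-point outcome of tracing one beam onto a grid.

    Arrays are aligned with ``grid.positions``. ``slab_paths`` maps the
    slab name to the oblique path length (mm) through that slab for
    each point's ray (0 where the ray misses the slab or the point is
    out of field).
    """

    grid: PhantomGrid
    beam: BeamGeometry
    slab_config: SlabConfig
    in_field: np.ndarray
    d_skin: np.ndarray
    incidence_angle_deg: np.ndarray
    field_w_skin: np.ndarray
    field_h_skin: np.ndarray
    slab_paths: Mapping[str, np.ndarray]

    def slab_stack(self, point_index: int) -> list[tuple[str, float]]:
        """(material, oblique path mm) per slab crossed by this point's ray."""
        stack = []
        for slab in self.slab_config.slabs:
            p = float(self.slab_paths[slab.name][point_index])
            if p > 0:
                stack.append((slab.material, p))
        return stack


def _source_inside_phantom(source: np.ndarray, grid: PhantomGrid) -> bool:
    radial = float(np.hypot(source[0], source[2]))
    return radial < grid.radius and 0.0 < source[1] < grid.length


def trace(
    beam: BeamGeometry, grid: PhantomGrid, slab_config: SlabConfig | None = None
) -> TraceResult:
    """Ray-trace the collimated field onto every grid point.

    A point is in field iff its ray from the source lies inside the
    rectangular collimation pyramid and the point's outward normal
    faces the source (normal . ray < 0, grazing rays excluded).
    ``d_skin`` is the Euclidean source-to-point distance. Slab path
    lengths are thickness / cos(incidence on the slab) where the
    source-to-point segment crosses the slab plane, else 0.
    """
    slab_config = slab_config or SlabConfig.none()
    if _source_inside_phantom(beam.source_position, grid):
        raise GeometryError("x-ray source lies inside the phantom volume")

    v = grid.positions - beam.source_position  # (N, 3) source -> point
    d_skin = np.linalg.norm(v, axis=1)
    a = v @ beam.central_axis
    w = v @ beam.u_width
    h = v @ beam.u_height
    inside_pyramid = (
        (a > 0)
        & (np.abs(w) <= a * np.tan(beam.half_angle_w))
        & (np.abs(h) <= a * np.tan(beam.half_angle_h))
    )
    vhat = v / d_skin[:, None]
    facing = np.einsum("ij,ij->i", grid.normals, vhat) < 0.0
    in_field = inside_pyramid & facing

    cos_inc = np.clip(-np.einsum("ij,ij->i", grid.normals, vhat), -1.0, 1.0)
    incidence = np.degrees(np.arccos(cos_inc))

    field_w = 2.0 * np.clip(a, 0.0, None) * np.tan(beam.half_angle_w)
    field_h = 2.0 * np.clip(a, 0.0, None) * np.tan(beam.half_angle_h)

    sy = beam.source_position[1]
    slab_paths: dict[str, np.ndarray] = {}
    for slab in slab_config.slabs:
        paths = np.zeros(grid.n_points)
        dy = grid.positions[:, 1] - sy
        crossing = ((sy < slab.y_plane_cm) & (grid.positions[:, 1] > slab.y_plane_cm)) | (
            (sy > slab.y_plane_cm) & (grid.positions[:, 1] < slab.y_plane_cm)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(dy != 0, (slab.y_plane_cm - sy) / dy, np.nan)
        hit = crossing & np.isfinite(t)
        if slab.half_extent_cm is not None:
            cx = beam.source_position[0] + t * v[:, 0]
            cz = beam.source_position[2] + t * v[:, 2]
            hit &= (np.abs(cx) <= slab.half_extent_cm) & (np.abs(cz) <= slab.half_extent_cm)
        cos_slab = np.abs(vhat[:, 1])
        ok = hit & (cos_slab > 1e-12)
        paths[ok] = slab.thickness_mm / cos_slab[ok]
        slab_paths[slab.name] = paths

    return TraceResult(
        grid=grid,
        beam=beam,
        slab_config=slab_config,
        in_field=in_field,
        d_skin=d_skin,
        incidence_angle_deg=incidence,
        field_w_skin=field_w,
        field_h_skin=field_h,
        slab_paths=slab_paths,
    )


def two_field_overlap(trace_a: TraceResult, trace_b: TraceResult) -> set[tuple[int, int]]:
    """Grid indices in field for both traces (the spatial intersection)."""
    if not trace_a.grid.same_lattice(trace_b.grid):
        raise GeometryError("traces were computed on different grids")
    both = trace_a.in_field & trace_b.in_field
    return {(int(i), int(j)) for i, j in trace_a.grid.indices[both]}
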