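"""Core domain containers shared across the toolkit.

Geometry lives in the DICOM patient coordinate system: millimetres, with
``x`` increasing toward the patient's left, ``y`` toward posterior and ``z``
toward superior.  All arrays indexed per-voxel use axis order ``(x, y, z)``.

The containers here are deliberately thin: a :class:`RoiContour` is the
planar-polygon representation native to an RT Structure Set, while
:class:`BinaryMask` is its sampled counterpart on a :class:`VoxelGrid`.
Dose is a scalar field on the same kind of lattice (:class:`DoseGrid`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

__all__ = [
    "VoxelGrid",
    "BinaryMask",
    "RoiContour",
    "StructureSet",
    "DoseGrid",
]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular axis-aligned sampling lattice.

    Parameters
    ----------
    origin_mm
        Patient-space coordinate of the *center* of voxel ``(0, 0, 0)``.
    spacing_mm
        Voxel pitch along ``(x, y, z)``; strictly positive.
    dims
        Number of voxels along ``(x, y, z)``; at least 1 each.
    """

    origin_mm: tuple[float, float, float]
    spacing_mm: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))
        object.__setattr__(self, "spacing_mm", tuple(float(v) for v in self.spacing_mm))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))
        if len(self.origin_mm) != 3 or len(self.spacing_mm) != 3 or len(self.dims) != 3:
            raise GeometryError("VoxelGrid requires 3-vectors for origin, spacing and dims")
        if any(s <= 0 for s in self.spacing_mm):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if any(d < 1 for d in self.dims):
            raise GeometryError(f"dims must be >= 1 on each axis, got {self.dims}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (0=x, 1=y, 2=z)."""
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(self.dims[axis])

    @property
    def x_centers(self) -> np.ndarray:
        return self.axis_centers(0)

    @property
    def y_centers(self) -> np.ndarray:
        return self.axis_centers(1)

    @property
    def z_centers(self) -> np.ndarray:
        return self.axis_centers(2)

    def extent_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer bounding box (voxel faces, not centers) as (lo, hi) corners."""
        o = np.asarray(self.origin_mm)
        s = np.asarray(self.spacing_mm)
        d = np.asarray(self.dims)
        return o - s / 2.0, o + s * (d - 0.5)

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map (n, 3) patient coordinates to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)


@dataclass
class BinaryMask:
    """Boolean occupancy of a structure on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != self.grid.dims:
            raise GeometryError(
                f"occupancy shape {self.occupancy.shape} does not match grid dims {self.grid.dims}"
            )

    @property
    def count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()

    @property
    def volume_mm3(self) -> float:
        return self.count * self.grid.voxel_volume_mm3

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.grid, self.occupancy.copy())


@dataclass
class RoiContour:
    """A named structure as closed planar polygons stacked along z.

    ``slices`` is an ordered list of ``(z_mm, rings)`` pairs with strictly
    increasing z; each ring is an ``(n, 2)`` array of in-plane vertices in mm.
    Rings are implicitly closed (first vertex joins last).  Multiple rings on
    one slice combine by the even-odd rule, so holes are representable.
    """

    name: str
    slices: list[tuple[float, list[np.ndarray]]]
    frame_of_reference: str = ""

    def __post_init__(self) -> None:
        cleaned: list[tuple[float, list[np.ndarray]]] = []
        for z, rings in self.slices:
            cleaned.append(
                (float(z), [np.asarray(r, dtype=float).reshape(-1, 2) for r in rings])
            )
        cleaned.sort(key=lambda item: item[0])
        zs = [z for z, _ in cleaned]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise GeometryError(f"ROI '{self.name}': slice z values must be strictly increasing")
        self.slices = cleaned

    @property
    def n_polygons(self) -> int:
        return sum(len(rings) for _, rings in self.slices)

    @property
    def z_values(self) -> np.ndarray:
        return np.array([z for z, _ in self.slices], dtype=float)

    def all_vertices(self) -> np.ndarray:
        """All vertices as an (n, 3) array (x, y, z) — convenience for bounds."""
        chunks = []
        for z, rings in self.slices:
            for r in rings:
                chunks.append(np.column_stack([r, np.full(len(r), z)]))
        if not chunks:
            return np.empty((0, 3))
        return np.concatenate(chunks, axis=0)


@dataclass
class StructureSet:
    """A collection of uniquely named ROIs sharing one frame of reference."""

    rois: dict[str, RoiContour] = field(default_factory=dict)
    source_id: str = ""

    def __post_init__(self) -> None:
        frames = {r.frame_of_reference for r in self.rois.values() if r.frame_of_reference}
        if len(frames) > 1:
            raise GeometryError(
                f"structure set '{self.source_id}' mixes frames of reference: {sorted(frames)}"
            )

    @property
    def frame_of_reference(self) -> str:
        for roi in self.rois.values():
            if roi.frame_of_reference:
                return roi.frame_of_reference
        return ""

    def __contains__(self, name: str) -> bool:
        return name in self.rois

    def __getitem__(self, name: str) -> RoiContour:
        return self.rois[name]

    @property
    def names(self) -> list[str]:
        return list(self.rois)


@dataclass
class DoseGrid:
    """Scalar absorbed dose (Gy) sampled on a voxel lattice."""

    grid: VoxelGrid
    values: np.ndarray
    prescription_gy: float = 70.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise GeometryError(
                f"dose shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )
        if np.any(self.values < -1e-9):
            raise GeometryError("dose values must be non-negative")
        self.values = np.clip(self.values, 0.0, None)
        if not self.prescription_gy > 0:
            raise GeometryError(f"prescription must be positive, got {self.prescription_gy}")

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.grid, self.values * float(factor), self.prescription_gy)
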