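"""Voxelization, 3D mask booleans, and partial uninvolved OAR construction.

The central clinical operation is :func:`make_partial_uninvolved`: restrict an
organ-at-risk to the axial slices lying within a superior/inferior margin
(default 1 cm) of the planning target volume's z-extent, then remove every
voxel overlapping the PTV.  The margin is a z-band crop only — the in-plane
extent of the organ is untouched on retained slices — and overlap removal is
plain boolean subtraction with no additional margin.

Occupancy is decided at voxel centers (no partial-volume weighting), which
keeps every operation deterministic and checkable against per-voxel oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath
from skimage import measure

from .core import BinaryMask, RoiContour, StructureSet, VoxelGrid
from .errors import EmptyStructureError, GeometryError

__all__ = [
    "PartialContourParams",
    "rasterize",
    "mask_subtract",
    "mask_intersect",
    "mask_union",
    "z_extent",
    "make_partial_uninvolved",
    "resample_mask",
    "contours_from_mask",
    "bounding_grid",
]

log = logging.getLogger(__name__)

#: Tolerance (mm) for inclusive comparisons on voxel-center coordinates.
_COORD_EPS = 1e-9


@dataclass(frozen=True)
class PartialContourParams:
    """Parameters of the partial uninvolved contour construction.

    ``margin_sup_inf_mm`` is the superior/inferior distance from the PTV edge
    within which OAR slices are retained; the clinical default is 10 mm (1 cm).
    A voxel whose center sits exactly at the margin boundary is retained
    ("within" is read as inclusive).
    """

    margin_sup_inf_mm: float = 10.0

    def __post_init__(self) -> None:
        m = self.margin_sup_inf_mm
        if not (np.isfinite(m) and m >= 0):
            raise GeometryError(f"margin must be finite and non-negative, got {m}")


def _ring_path(ring: np.ndarray) -> MplPath:
    verts = np.vstack([ring, ring[:1]])
    codes = np.full(len(verts), MplPath.LINETO, dtype=np.uint8)
    codes[0] = MplPath.MOVETO
    codes[-1] = MplPath.CLOSEPOLY
    return MplPath(verts, codes)


def _ring_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def rasterize(roi: RoiContour, grid: VoxelGrid) -> BinaryMask:
    """Voxelize a planar-contour ROI onto a grid.

    A voxel is occupied iff its center lies inside the polygon set of the
    nearest contour slice (even-odd rule across rings), with nearest-slice
    assignment limited to half the contour slice spacing.  Degenerate rings
    (< 3 vertices or zero area) are skipped with a warning; contour slices
    outside the grid z-range are clipped with a warning.
    """
    occ = np.zeros(grid.dims, dtype=bool)
    if not roi.slices:
        return BinaryMask(grid, occ)

    zs = roi.z_values
    if len(zs) > 1:
        slice_spacing = float(np.median(np.diff(zs)))
    else:
        slice_spacing = grid.spacing_mm[2]

    zlo, zhi = grid.extent_mm()[0][2], grid.extent_mm()[1][2]
    n_clipped = sum(1 for z in zs if z < zlo - _COORD_EPS or z > zhi + _COORD_EPS)
    if n_clipped:
        log.warning("ROI '%s': %d contour slice(s) outside grid z-range, clipped", roi.name, n_clipped)

    xg, yg = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
    pts = np.column_stack([xg.ravel(), yg.ravel()])
    in_plane_shape = (grid.dims[0], grid.dims[1])

    # Pre-rasterize each contour slice once, then assign grid planes to slices.
    slice_masks: dict[int, np.ndarray] = {}

    def plane_mask(slice_idx: int) -> np.ndarray:
        if slice_idx not in slice_masks:
            inside = np.zeros(pts.shape[0], dtype=bool)
            for ring in roi.slices[slice_idx][1]:
                if len(ring) < 3 or _ring_area(ring) <= 0.0:
                    log.warning("ROI '%s': skipping degenerate ring (%d vertices)", roi.name, len(ring))
                    continue
                inside ^= _ring_path(ring).contains_points(pts)
            slice_masks[slice_idx] = inside.reshape(in_plane_shape)
        return slice_masks[slice_idx]

    half = slice_spacing / 2.0 + _COORD_EPS
    for k, zc in enumerate(grid.z_centers):
        nearest = int(np.argmin(np.abs(zs - zc)))
        if abs(zs[nearest] - zc) <= half:
            occ[:, :, k] = plane_mask(nearest)
    return BinaryMask(grid, occ)


def _require_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if a.grid != b.grid:
        raise GeometryError(
            "masks are on different grids; resample one with resample_mask() first"
        )


def mask_subtract(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise a AND NOT b."""
    _require_same_grid(a, b)
    return BinaryMask(a.grid, a.occupancy & ~b.occupancy)


def mask_intersect(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise a AND b."""
    _require_same_grid(a, b)
    return BinaryMask(a.grid, a.occupancy & b.occupancy)


def mask_union(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise a OR b."""
    _require_same_grid(a, b)
    return BinaryMask(a.grid, a.occupancy | b.occupancy)


def z_extent(mask: BinaryMask) -> tuple[float, float]:
    """Min and max z coordinate (mm) of occupied voxel centers."""
    if mask.is_empty:
        raise EmptyStructureError("z_extent of an empty mask is undefined")
    occupied_planes = np.flatnonzero(mask.occupancy.any(axis=(0, 1)))
    zc = mask.grid.z_centers
    return float(zc[occupied_planes[0]]), float(zc[occupied_planes[-1]])


def make_partial_uninvolved(
    oar: BinaryMask,
    ptv: BinaryMask,
    params: PartialContourParams = PartialContourParams(),
) -> BinaryMask:
    """Build the partial uninvolved OAR mask.

    Keeps OAR voxels whose center z lies in ``[ptv_zmin - m, ptv_zmax + m]``
    (m = ``params.margin_sup_inf_mm``, boundary inclusive) and removes all
    voxels overlapping the PTV.  The result is always a subset of the OAR and
    disjoint from the PTV.
    """
    _require_same_grid(oar, ptv)
    if ptv.is_empty:
        raise EmptyStructureError("PTV mask is empty; partial contour is undefined")
    zmin, zmax = z_extent(ptv)
    m = params.margin_sup_inf_mm
    zc = oar.grid.z_centers
    in_band = (zc >= zmin - m - _COORD_EPS) & (zc <= zmax + m + _COORD_EPS)
    occ = oar.occupancy & in_band[np.newaxis, np.newaxis, :] & ~ptv.occupancy
    return BinaryMask(oar.grid, occ)


def resample_mask(mask: BinaryMask, target: VoxelGrid) -> BinaryMask:
    """Nearest-neighbor resampling of occupancy onto a target grid.

    Resampling a mask onto its own grid is the exact identity.  Spatially
    disjoint grids yield an empty mask with a warning.
    """
    if target == mask.grid:
        return mask.copy()
    src = mask.grid
    tx, ty, tz = np.meshgrid(
        target.x_centers, target.y_centers, target.z_centers, indexing="ij"
    )
    idx = [
        np.rint((c - src.origin_mm[ax]) / src.spacing_mm[ax]).astype(int)
        for ax, c in enumerate([tx, ty, tz])
    ]
    inside = np.ones(target.dims, dtype=bool)
    for ax in range(3):
        inside &= (idx[ax] >= 0) & (idx[ax] < src.dims[ax])
    occ = np.zeros(target.dims, dtype=bool)
    if inside.any():
        occ[inside] = mask.occupancy[idx[0][inside], idx[1][inside], idx[2][inside]]
    else:
        log.warning("resample_mask: target grid does not overlap source grid; result is empty")
    return BinaryMask(target, occ)


def contours_from_mask(mask: BinaryMask, name: str, frame_of_reference: str = "") -> RoiContour:
    """Extract closed planar contours from a mask (marching squares at 0.5).

    The inverse of :func:`rasterize` up to half-voxel boundary placement:
    re-rasterizing the result on the same grid recovers the original
    occupancy, because the 0.5-level line passes midway between occupied and
    unoccupied voxel centers.
    """
    grid = mask.grid
    slices: list[tuple[float, list[np.ndarray]]] = []
    for k in range(grid.dims[2]):
        plane = mask.occupancy[:, :, k]
        if not plane.any():
            continue
        padded = np.pad(plane.astype(float), 1)
        rings = []
        for contour in measure.find_contours(padded, 0.5, fully_connected="low"):
            ij = contour - 1.0  # undo padding
            if len(ij) > 1 and np.allclose(ij[0], ij[-1]):
                ij = ij[:-1]
            if len(ij) < 3:
                continue
            ring = np.column_stack(
                [
                    grid.origin_mm[0] + ij[:, 0] * grid.spacing_mm[0],
                    grid.origin_mm[1] + ij[:, 1] * grid.spacing_mm[1],
                ]
            )
            rings.append(ring)
        if rings:
            slices.append((float(grid.z_centers[k]), rings))
    return RoiContour(name=name, slices=slices, frame_of_reference=frame_of_reference)


def bounding_grid(
    structure_sets: StructureSet | list[StructureSet],
    spacing_mm: float = 2.5,
    padding_mm: float = 5.0,
) -> VoxelGrid:
    """Isotropic grid bounding all contours of the given structure set(s).

    Used when no RTDOSE grid dictates the lattice; 2.5 mm matches typical
    pelvic CT slice spacing.
    """
    if isinstance(structure_sets, StructureSet):
        structure_sets = [structure_sets]
    verts = [roi.all_vertices() for ss in structure_sets for roi in ss.rois.values()]
    verts = [v for v in verts if len(v)]
    if not verts:
        raise EmptyStructureError("cannot build a bounding grid from empty structure sets")
    allv = np.concatenate(verts, axis=0)
    lo = allv.min(axis=0) - padding_mm
    hi = allv.max(axis=0) + padding_mm
    dims = tuple(int(np.ceil((hi[i] - lo[i]) / spacing_mm)) + 1 for i in range(3))
    return VoxelGrid(origin_mm=tuple(lo), spacing_mm=(spacing_mm,) * 3, dims=dims)
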