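"""Geometry module: rasterization, mask booleans, partial uninvolved construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon

import partialoar as po
from conftest import box_mask, mask_from, random_blob_mask

SQUARE_20MM = np.array([[0.0, 0.0], [20.0, 0.0], [20.0, 20.0], [0.0, 20.0]])


def shapely_even_odd_oracle(rings, grid, z_plane_idx):
    """Independent rasterization oracle: per-voxel-center point-in-polygon
    tests (shapely), combined across rings by the even-odd rule."""
    polys = [Polygon(r) for r in rings]
    occ = np.zeros(grid.dims[:2], dtype=bool)
    for i, x in enumerate(grid.x_centers):
        for j, y in enumerate(grid.y_centers):
            inside = False
            for p in polys:
                inside ^= p.contains(Point(x, y))
            occ[i, j] = inside
    return occ


class TestRasterize:
    def test_square_voxel_count_and_oracle(self):
        grid = po.VoxelGrid(origin_mm=(0.5, 0.5, 0.0), spacing_mm=(1, 1, 1), dims=(20, 20, 1))
        roi = po.RoiContour("sq", [(0.0, [SQUARE_20MM])])
        mask = po.rasterize(roi, grid)
        assert mask.count == 400
        oracle = shapely_even_odd_oracle([SQUARE_20MM], grid, 0)
        assert np.array_equal(mask.occupancy[:, :, 0], oracle)

    def test_donut_even_odd(self):
        inner = np.array([[8.0, 8.0], [12.0, 8.0], [12.0, 12.0], [8.0, 12.0]])
        grid = po.VoxelGrid(origin_mm=(0.5, 0.5, 0.0), spacing_mm=(1, 1, 1), dims=(20, 20, 1))
        roi = po.RoiContour("donut", [(0.0, [SQUARE_20MM, inner])])
        mask = po.rasterize(roi, grid)
        assert mask.count == 400 - 16
        oracle = shapely_even_odd_oracle([SQUARE_20MM, inner], grid, 0)
        assert np.array_equal(mask.occupancy[:, :, 0], oracle)

    def test_empty_roi_gives_empty_mask(self, unit_grid):
        mask = po.rasterize(po.RoiContour("none", []), unit_grid)
        assert mask.is_empty

    def test_degenerate_ring_skipped_with_warning(self, unit_grid, caplog):
        roi = po.RoiContour("bad", [(0.5, [np.array([[1.0, 1.0], [2.0, 2.0]])])])
        with caplog.at_level("WARNING"):
            mask = po.rasterize(roi, unit_grid)
        assert mask.is_empty
        assert "degenerate" in caplog.text

    def test_out_of_grid_slice_clipped_with_warning(self, unit_grid, caplog):
        roi = po.RoiContour("far", [(99.0, [SQUARE_20MM])])
        with caplog.at_level("WARNING"):
            mask = po.rasterize(roi, unit_grid)
        assert mask.is_empty
        assert "clipped" in caplog.text

    @pytest.mark.parametrize("spacing", [2.0, 1.0, 0.5])
    def test_area_convergence_bound(self, spacing):
        """Rasterized area converges to analytic area: |err| <= perimeter * spacing."""
        n = int(24 / spacing)
        grid = po.VoxelGrid(
            origin_mm=(spacing / 2 - 2.0, spacing / 2 - 2.0, 0.0),
            spacing_mm=(spacing, spacing, 1.0),
            dims=(n, n, 1),
        )
        mask = po.rasterize(po.RoiContour("sq", [(0.0, [SQUARE_20MM])]), grid)
        raster_area = mask.count * spacing**2
        assert abs(raster_area - 400.0) <= 80.0 * spacing


class TestBooleanOps:
    def test_subtract_self_is_empty(self, unit_grid):
        a = box_mask(unit_grid, (0, 0, 0), (4, 4, 4))
        assert po.mask_subtract(a, a).is_empty

    def test_subtract_empty_is_identity(self, unit_grid):
        a = box_mask(unit_grid, (0, 0, 0), (4, 4, 4))
        empty = mask_from(unit_grid, np.zeros(unit_grid.dims))
        assert np.array_equal(po.mask_subtract(a, empty).occupancy, a.occupancy)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_count_identity_on_random_masks(self, unit_grid, seed):
        """|a\\b| + |a∩b| = |a| — voxel-count oracle."""
        rng = np.random.default_rng(seed)
        a = random_blob_mask(unit_grid, rng)
        b = random_blob_mask(unit_grid, rng)
        assert po.mask_subtract(a, b).count + po.mask_intersect(a, b).count == a.count
        assert (
            po.mask_union(a, b).count
            == a.count + b.count - po.mask_intersect(a, b).count
        )

    def test_mismatched_grids_rejected(self, unit_grid):
        other = po.VoxelGrid(origin_mm=(0, 0, 0), spacing_mm=(2, 2, 2), dims=(10, 10, 10))
        a = box_mask(unit_grid, (0, 0, 0), (2, 2, 2))
        b = box_mask(other, (0, 0, 0), (2, 2, 2))
        with pytest.raises(po.GeometryError, match="resample"):
            po.mask_subtract(a, b)


class TestZExtent:
    def test_single_voxel(self):
        grid = po.VoxelGrid(origin_mm=(0, 0, 12.5), spacing_mm=(1, 1, 1), dims=(1, 1, 1))
        mask = mask_from(grid, np.ones((1, 1, 1)))
        assert po.z_extent(mask) == (12.5, 12.5)

    def test_slab(self):
        grid = po.VoxelGrid(origin_mm=(0, 0, 0), spacing_mm=(1, 1, 2.5), dims=(2, 2, 5))
        occ = np.zeros(grid.dims, dtype=bool)
        occ[:, :, 0:3] = True  # z centers 0, 2.5, 5.0
        assert po.z_extent(mask_from(grid, occ)) == (0.0, 5.0)

    def test_empty_raises(self, unit_grid):
        with pytest.raises(po.EmptyStructureError):
            po.z_extent(mask_from(unit_grid, np.zeros(unit_grid.dims)))

    def test_phantom_ptv_extent_matches_truth(self, compact_case, compact_masks):
        zmin, zmax = po.z_extent(compact_masks["PTV"])
        true_lo, true_hi = compact_case.truth["ptv_z_extent_mm"]
        dz = compact_case.grid.spacing_mm[2]
        assert true_lo - dz <= zmin <= true_lo + dz
        assert true_hi - dz <= zmax <= true_hi + dz


def brute_force_partial(oar, ptv, margin):
    """Per-voxel filter oracle: z-band membership + PTV-membership tests."""
    zmin, zmax = po.z_extent(ptv)
    grid = oar.grid
    expected = np.zeros(grid.dims, dtype=bool)
    zc = grid.z_centers
    for k in range(grid.dims[2]):
        in_band = (zc[k] >= zmin - margin - 1e-9) and (zc[k] <= zmax + margin + 1e-9)
        if in_band:
            expected[:, :, k] = oar.occupancy[:, :, k] & ~ptv.occupancy[:, :, k]
    return expected


class TestPartialUninvolved:
    def test_oar_entirely_beyond_band_gives_empty(self):
        grid = po.VoxelGrid(origin_mm=(0, 0, 0), spacing_mm=(1, 1, 1), dims=(4, 4, 40))
        ptv = box_mask(grid, (0, 0, 0), (3, 3, 4))       # z in [0, 4]
        oar = box_mask(grid, (0, 0, 30), (3, 3, 39))     # z in [30, 39] > 4 + 10
        result = po.make_partial_uninvolved(oar, ptv, po.PartialContourParams(10.0))
        assert result.is_empty

    def test_oar_inside_ptv_gives_empty(self, unit_grid):
        ptv = box_mask(unit_grid, (0, 0, 0), (9, 9, 9))
        oar = box_mask(unit_grid, (2, 2, 2), (5, 5, 5))
        assert po.make_partial_uninvolved(oar, ptv).is_empty

    def test_slab_band_crop(self):
        """PTV slab z in [10, 20], OAR slab z in [0, 40] disjoint in-plane,
        margin 10 -> OAR restricted to z in [0, 30]."""
        grid = po.VoxelGrid(origin_mm=(0, 0, 0), spacing_mm=(5, 5, 2.5), dims=(8, 8, 17))
        zc = grid.z_centers  # 0, 2.5, ..., 40
        ptv_occ = np.zeros(grid.dims, dtype=bool)
        ptv_occ[0:3, :, (zc >= 10) & (zc <= 20)] = True
        oar_occ = np.zeros(grid.dims, dtype=bool)
        oar_occ[5:8, :, :] = True
        ptv, oar = mask_from(grid, ptv_occ), mask_from(grid, oar_occ)
        result = po.make_partial_uninvolved(oar, ptv, po.PartialContourParams(10.0))
        expected = oar_occ & (zc <= 30.0)[np.newaxis, np.newaxis, :]
        assert np.array_equal(result.occupancy, expected)
        assert np.array_equal(result.occupancy, brute_force_partial(oar, ptv, 10.0))

    @pytest.mark.parametrize("seed", [0, 7])
    def test_exact_oracle_on_random_masks(self, seed):
        grid = po.VoxelGrid(origin_mm=(-10, -10, -10), spacing_mm=(2, 2, 2), dims=(12, 12, 12))
        rng = np.random.default_rng(seed)
        ptv = random_blob_mask(grid, rng, p=0.2)
        oar = random_blob_mask(grid, rng, p=0.3)
        for margin in (0.0, 4.0, 10.0):
            result = po.make_partial_uninvolved(oar, ptv, po.PartialContourParams(margin))
            assert np.array_equal(result.occupancy, brute_force_partial(oar, ptv, margin))

    def test_partiality_and_band_invariants(self, compact_masks):
        ptv = compact_masks["PTV"]
        for organ in ("Bladder", "Rectum"):
            oar = compact_masks[organ]
            margin = 10.0
            part = po.make_partial_uninvolved(oar, ptv, po.PartialContourParams(margin))
            # subset of the OAR, disjoint from the PTV
            assert not (part.occupancy & ~oar.occupancy).any()
            assert not (part.occupancy & ptv.occupancy).any()
            # every occupied voxel's z inside the band
            zmin, zmax = po.z_extent(ptv)
            zs = part.grid.z_centers[np.nonzero(part.occupancy)[2]]
            assert ((zs >= zmin - margin - 1e-9) & (zs <= zmax + margin + 1e-9)).all()

    def test_margin_monotonicity(self, compact_masks):
        ptv, oar = compact_masks["PTV"], compact_masks["Bladder"]
        counts = [
            po.make_partial_uninvolved(oar, ptv, po.PartialContourParams(m)).count
            for m in (0.0, 2.5, 5.0, 10.0, 20.0, 40.0)
        ]
        assert counts == sorted(counts)

    def test_empty_ptv_raises(self, unit_grid):
        oar = box_mask(unit_grid, (0, 0, 0), (3, 3, 3))
        empty = mask_from(unit_grid, np.zeros(unit_grid.dims))
        with pytest.raises(po.EmptyStructureError):
            po.make_partial_uninvolved(oar, empty)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), m1=st.floats(0, 15), m2=st.floats(0, 15))
    def test_margin_monotonicity_property(self, seed, m1, m2):
        grid = po.VoxelGrid(origin_mm=(0, 0, 0), spacing_mm=(2, 2, 2), dims=(8, 8, 16))
        rng = np.random.default_rng(seed)
        ptv = random_blob_mask(grid, rng, p=0.1)
        oar = random_blob_mask(grid, rng, p=0.3)
        if ptv.is_empty:
            return
        lo, hi = sorted([m1, m2])
        small = po.make_partial_uninvolved(oar, ptv, po.PartialContourParams(lo))
        big = po.make_partial_uninvolved(oar, ptv, po.PartialContourParams(hi))
        assert not (small.occupancy & ~big.occupancy).any()


class TestResample:
    def test_identity(self, compact_masks):
        bladder = compact_masks["Bladder"]
        again = po.resample_mask(bladder, bladder.grid)
        assert np.array_equal(again.occupancy, bladder.occupancy)

    def test_upsample_full_slab_stays_full(self):
        coarse = po.VoxelGrid(origin_mm=(0, 0, 0), spacing_mm=(2, 2, 2), dims=(8, 8, 8))
        fine = po.VoxelGrid(origin_mm=(0, 0, 0), spacing_mm=(1, 1, 1), dims=(15, 15, 15))
        full = mask_from(coarse, np.ones(coarse.dims))
        res = po.resample_mask(full, fine)
        assert res.count == 15**3

    def test_refinement_volume_change_bounded_by_surface_shell(self, compact_masks):
        bladder = compact_masks["Bladder"]
        g = bladder.grid
        fine = po.VoxelGrid(
            origin_mm=g.origin_mm,
            spacing_mm=tuple(s / 2 for s in g.spacing_mm),
            dims=tuple(2 * d - 1 for d in g.dims),
        )
        res = po.resample_mask(bladder, fine)
        # fine-grid volume differs from coarse volume by at most one
        # surface-voxel shell (6-connected face count x voxel volume)
        occ = bladder.occupancy
        faces = sum(
            np.count_nonzero(occ & ~np.roll(occ, shift, axis=ax))
            for ax in range(3)
            for shift in (1, -1)
        )
        shell_volume = faces * g.voxel_volume_mm3
        assert abs(res.volume_mm3 - bladder.volume_mm3) <= shell_volume

    def test_disjoint_grids_warn_and_empty(self, unit_grid, caplog):
        far = po.VoxelGrid(origin_mm=(1000, 1000, 1000), spacing_mm=(1, 1, 1), dims=(5, 5, 5))
        a = box_mask(unit_grid, (0, 0, 0), (3, 3, 3))
        with caplog.at_level("WARNING"):
            res = po.resample_mask(a, far)
        assert res.is_empty
        assert "overlap" in caplog.text


class TestContoursFromMask:
    @pytest.mark.parametrize("organ", ["PTV", "Bladder", "Rectum"])
    def test_rasterize_roundtrip_recovers_mask(self, compact_case, compact_masks, organ):
        mask = compact_masks[organ]
        roi = po.contours_from_mask(mask, organ)
        again = po.rasterize(roi, mask.grid)
        assert np.array_equal(again.occupancy, mask.occupancy)

    def test_partial_mask_roundtrip(self, compact_masks):
        part = po.make_partial_uninvolved(compact_masks["Bladder"], compact_masks["PTV"])
        roi = po.contours_from_mask(part, "Bladder_Part_Un")
        again = po.rasterize(roi, part.grid)
        assert np.array_equal(again.occupancy, part.occupancy)


class TestBoundingGrid:
    def test_contains_all_vertices(self, compact_case):
        grid = po.bounding_grid(compact_case.structures, spacing_mm=2.5)
        lo, hi = grid.extent_mm()
        for roi in compact_case.structures.rois.values():
            v = roi.all_vertices()
            assert (v >= lo - 1e-9).all() and (v <= hi + 1e-9).all()

    def test_empty_raises(self):
        with pytest.raises(po.EmptyStructureError):
            po.bounding_grid(po.StructureSet(rois={}, source_id="x"))
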