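import numpy as np
import pytest

import partialoar as po


def mask_from(grid: po.VoxelGrid, occupancy: np.ndarray) -> po.BinaryMask:
    return po.BinaryMask(grid, np.asarray(occupancy, dtype=bool))


def box_mask(grid: po.VoxelGrid, lo_idx, hi_idx) -> po.BinaryMask:
    """Axis-aligned box of voxels with inclusive index bounds."""
    occ = np.zeros(grid.dims, dtype=bool)
    occ[lo_idx[0]: hi_idx[0] + 1, lo_idx[1]: hi_idx[1] + 1, lo_idx[2]: hi_idx[2] + 1] = True
    return mask_from(grid, occ)


def random_blob_mask(grid: po.VoxelGrid, rng: np.random.Generator, p: float = 0.3) -> po.BinaryMask:
    return mask_from(grid, rng.random(grid.dims) < p)


@pytest.fixture
def unit_grid() -> po.VoxelGrid:
    """1 mm isotropic 10x10x10 grid with voxel centers at 0.5, 1.5, ..."""
    return po.VoxelGrid(origin_mm=(0.5, 0.5, 0.5), spacing_mm=(1, 1, 1), dims=(10, 10, 10))


@pytest.fixture(scope="session")
def compact_case() -> po.PhantomCase:
    """One deterministic reduced-extent pelvic case shared across tests."""
    return po.generate_case(po.PhantomSpec.compact())


@pytest.fixture(scope="session")
def compact_masks(compact_case):
    grid = compact_case.grid
    return {
        name: po.rasterize(compact_case.structures[name], grid)
        for name in compact_case.structures.names
    }
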