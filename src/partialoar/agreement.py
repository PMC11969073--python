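"""Geometric agreement scoring between contour variants (DSC and OI).

DSC (Dice similarity coefficient) is symmetric: ``2|A∩B| / (|A|+|B|)``.

OI (overlay index) is defined here as the overlap fraction of the *reference*
(manual) volume, ``|ref∩test| / |ref|`` — the common convention in the
contour-evaluation literature.  The reference role is an explicit argument
and is never inferred from call order; swapping arguments changes the value
whenever the two volumes differ.

When two variants are compared in *partial* mode, both are first reduced to
their partial uninvolved form against the SAME reference PTV, then scored.
A pair of empty masks yields an undefined score (reported as missing, never
silently as 0 or 1, which would bias cohort means).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .core import BinaryMask, StructureSet, VoxelGrid
from .errors import UndefinedScoreError
from .geometry import PartialContourParams, make_partial_uninvolved, mask_intersect, rasterize

__all__ = ["AgreementScores", "dice", "overlay_index", "compare_structures"]


@dataclass(frozen=True)
class AgreementScores:
    """DSC/OI plus the voxel counts they derive from."""

    dsc: float
    oi: float
    n_ref_voxels: int
    n_test_voxels: int
    n_overlap_voxels: int


def dice(ref: BinaryMask, test: BinaryMask) -> float:
    """Dice similarity coefficient, 2|ref∩test|/(|ref|+|test|)."""
    n_ref, n_test = ref.count, test.count
    if n_ref == 0 and n_test == 0:
        raise UndefinedScoreError("DSC of two empty masks is undefined")
    overlap = mask_intersect(ref, test).count
    return 2.0 * overlap / (n_ref + n_test)


def overlay_index(ref: BinaryMask, test: BinaryMask) -> float:
    """Overlay index |ref∩test|/|ref|; ``ref`` is the manual/reference mask."""
    n_ref = ref.count
    if n_ref == 0:
        raise UndefinedScoreError("OI with an empty reference mask is undefined")
    return mask_intersect(ref, test).count / n_ref


def score_pair(ref: BinaryMask, test: BinaryMask) -> AgreementScores:
    """Both metrics at once, with the underlying voxel counts."""
    return AgreementScores(
        dsc=dice(ref, test),
        oi=overlay_index(ref, test),
        n_ref_voxels=ref.count,
        n_test_voxels=test.count,
        n_overlap_voxels=mask_intersect(ref, test).count,
    )


def compare_structures(
    ref_ss: StructureSet,
    test_ss: StructureSet,
    organs: list[str],
    mode: Literal["full", "partial"],
    ptv_name: str,
    params: PartialContourParams = PartialContourParams(),
    grid: VoxelGrid | None = None,
) -> pd.DataFrame:
    """Score per-organ agreement between two structure sets.

    In partial mode both variants are transformed by the partial uninvolved
    construction against the reference PTV (taken from ``ref_ss``) before
    scoring.  Organs missing from either set are reported in the ``error``
    column; remaining organs are still scored.

    Returns a DataFrame with columns
    ``organ, mode, dsc, oi, n_ref, n_test, n_overlap, error``.
    """
    if mode not in ("full", "partial"):
        raise ValueError(f"mode must be 'full' or 'partial', got {mode!r}")
    if grid is None:
        from .geometry import bounding_grid

        grid = bounding_grid([ref_ss, test_ss])

    ptv_mask = None
    if mode == "partial":
        if ptv_name not in ref_ss:
            raise KeyError(f"PTV '{ptv_name}' not found in reference structure set")
        ptv_mask = rasterize(ref_ss[ptv_name], grid)

    rows = []
    for organ in organs:
        row: dict = {
            "organ": organ,
            "mode": mode,
            "dsc": float("nan"),
            "oi": float("nan"),
            "n_ref": pd.NA,
            "n_test": pd.NA,
            "n_overlap": pd.NA,
            "error": "",
        }
        missing = [
            label
            for label, ss in (("reference", ref_ss), ("test", test_ss))
            if organ not in ss
        ]
        if missing:
            row["error"] = f"missing from {' and '.join(missing)} set"
            rows.append(row)
            continue
        ref_mask = rasterize(ref_ss[organ], grid)
        test_mask = rasterize(test_ss[organ], grid)
        if mode == "partial":
            ref_mask = make_partial_uninvolved(ref_mask, ptv_mask, params)
            test_mask = make_partial_uninvolved(test_mask, ptv_mask, params)
        try:
            scores = score_pair(ref_mask, test_mask)
        except UndefinedScoreError as exc:
            row["error"] = str(exc)
            row["n_ref"] = ref_mask.count
            row["n_test"] = test_mask.count
            rows.append(row)
            continue
        row.update(
            dsc=scores.dsc,
            oi=scores.oi,
            n_ref=scores.n_ref_voxels,
            n_test=scores.n_test_voxels,
            n_overlap=scores.n_overlap_voxels,
        )
        rows.append(row)
    return pd.DataFrame(rows)
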