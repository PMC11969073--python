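"""Cumulative DVHs and plan dose indices (Dmax, Dmean, Vx Gy, D98 normalization).

Conventions (documented defaults; the clinical literature often leaves them
unstated):

* Dmax is the maximum voxel-sample dose over the full structure, with no
  small-volume surrogate.
* Vx is the percent of structure volume receiving at least x Gy; the DVH is
  binned at 0.1 Gy by default (0.14% of a 70 Gy prescription) and bin-edge
  ties count as "receiving" the dose.
* D_p (dose covering p% of the volume) uses linear interpolation on the
  sorted dose samples (inclusive percentile convention), so prescription
  normalization — scale the plan until the prescription covers 98% of the
  PTV — is deterministic, idempotent and scale-equivariant.
* Dose metrics are always evaluated on FULL organ masks.  Partial uninvolved
  contours are a planning-side construct; evaluating plans on full organs is
  the fairness rule of the comparison framework this toolkit implements.
* When dose and structure lattices differ, dose is sampled by trilinear
  interpolation at mask voxel centers (continuous field); masks themselves
  resample nearest-neighbor (categorical labels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask, DoseGrid, StructureSet
from .errors import EmptyStructureError, NormalizationError
from .geometry import rasterize

__all__ = [
    "DvhCurve",
    "structure_dose_samples",
    "compute_dvh",
    "d_max",
    "d_mean",
    "v_at_dose",
    "dose_at_volume",
    "normalize_prescription",
    "dose_metrics_report",
]

#: Bin-edge tie tolerance (Gy): a sample exactly at an edge counts as >= it.
_EDGE_EPS = 1e-9

DEFAULT_V_LEVELS_GY = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0]


@dataclass(frozen=True)
class DvhCurve:
    """Cumulative DVH: ``cum_volume_pct[i]`` = % of volume receiving >= ``bin_edges_gy[i]``."""

    bin_edges_gy: np.ndarray
    cum_volume_pct: np.ndarray


def structure_dose_samples(dose: DoseGrid, mask: BinaryMask) -> np.ndarray:
    """Dose (Gy) at each occupied voxel of ``mask``.

    Direct lookup when the mask shares the dose lattice; trilinear
    interpolation at mask voxel centers otherwise.
    """
    if mask.is_empty:
        raise EmptyStructureError("cannot sample dose over an empty structure")
    if mask.grid == dose.grid:
        return dose.values[mask.occupancy]
    ix, iy, iz = np.nonzero(mask.occupancy)
    centers = np.column_stack(
        [
            mask.grid.x_centers[ix],
            mask.grid.y_centers[iy],
            mask.grid.z_centers[iz],
        ]
    )
    frac_idx = dose.grid.world_to_index(centers)
    return ndimage.map_coordinates(dose.values, frac_idx.T, order=1, mode="nearest")


def compute_dvh(dose: DoseGrid, mask: BinaryMask, bin_width_gy: float = 0.1) -> DvhCurve:
    """Cumulative DVH over [0, max dose + one bin]; exactly 100% at 0 Gy."""
    if bin_width_gy <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width_gy}")
    samples = structure_dose_samples(dose, mask)
    return dvh_from_samples(samples, bin_width_gy)


def dvh_from_samples(samples: np.ndarray, bin_width_gy: float = 0.1) -> DvhCurve:
    """DVH from raw dose samples (used when samples are already in hand)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise EmptyStructureError("cannot build a DVH from zero dose samples")
    n_edges = int(np.floor(samples.max() / bin_width_gy)) + 2
    edges = np.arange(n_edges) * bin_width_gy
    sorted_s = np.sort(samples)
    # fraction of samples >= edge, with edge ties inclusive
    n_below = np.searchsorted(sorted_s, edges - _EDGE_EPS, side="left")
    pct = 100.0 * (samples.size - n_below) / samples.size
    return DvhCurve(bin_edges_gy=edges, cum_volume_pct=pct)


def d_max(samples: np.ndarray) -> float:
    """Maximum structure dose (Gy)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise EmptyStructureError("Dmax of an empty structure is undefined")
    return float(samples.max())


def d_mean(samples: np.ndarray) -> float:
    """Arithmetic mean structure dose (Gy)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise EmptyStructureError("Dmean of an empty structure is undefined")
    return float(samples.mean())


def v_at_dose(dvh: DvhCurve, level_gy: float) -> float:
    """Percent volume receiving >= ``level_gy``, linearly interpolated on the curve.

    Levels below the curve support return 100, above it 0.
    """
    edges, pct = dvh.bin_edges_gy, dvh.cum_volume_pct
    if level_gy <= edges[0]:
        return 100.0
    if level_gy >= edges[-1]:
        return 0.0
    return float(np.interp(level_gy, edges, pct))


def dose_at_volume(samples: np.ndarray, coverage_pct: float) -> float:
    """D_p: dose (Gy) received by at least ``coverage_pct``% of the structure.

    Linear-interpolated percentile of the sorted samples: D98 is the 2nd
    percentile of the dose distribution.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise EmptyStructureError("dose_at_volume of an empty structure is undefined")
    if not 0 < coverage_pct <= 100:
        raise ValueError(f"coverage must be in (0, 100], got {coverage_pct}")
    return float(np.percentile(samples, 100.0 - coverage_pct))


def normalize_prescription(
    dose: DoseGrid,
    ptv: BinaryMask,
    rx_gy: float | None = None,
    coverage_pct: float = 98.0,
) -> DoseGrid:
    """Scale the plan so the prescription dose covers ``coverage_pct``% of the PTV.

    The scale factor is ``rx / D_coverage(PTV)``.  After scaling,
    V_rx(PTV) = coverage within one DVH bin.  Idempotent: normalizing an
    already-normalized plan rescales by 1 (to floating-point precision), and
    normalizing ``c * dose`` equals normalizing ``dose`` for any c > 0.
    """
    rx = float(rx_gy) if rx_gy is not None else dose.prescription_gy
    samples = structure_dose_samples(dose, ptv)
    d_cov = dose_at_volume(samples, coverage_pct)
    if d_cov <= 0:
        raise NormalizationError(
            f"D{coverage_pct:g}(PTV) is {d_cov:.3f} Gy; cannot normalize to {rx:g} Gy"
        )
    return dose.scaled(rx / d_cov)


def dose_metrics_report(
    dose: DoseGrid,
    ss: StructureSet,
    organs: list[str],
    v_levels_gy: list[float] | None = None,
    bin_width_gy: float = 0.1,
) -> pd.DataFrame:
    """Dmax, Dmean and Vx table for the given organs, on the dose lattice.

    Organs are rasterized on the dose grid and evaluated as FULL structures.
    Missing or empty organs are flagged in the ``error`` column; the other
    rows are still computed.  Vx columns are named ``V{level:g}Gy`` and hold
    percent volume.
    """
    levels = list(v_levels_gy) if v_levels_gy is not None else list(DEFAULT_V_LEVELS_GY)
    rows = []
    for organ in organs:
        row: dict = {"organ": organ, "d_max_gy": np.nan, "d_mean_gy": np.nan, "error": ""}
        for lv in levels:
            row[f"V{lv:g}Gy"] = np.nan
        if organ not in ss:
            row["error"] = "missing from structure set"
            rows.append(row)
            continue
        mask = rasterize(ss[organ], dose.grid)
        if mask.is_empty:
            row["error"] = "empty after rasterization"
            rows.append(row)
            continue
        samples = structure_dose_samples(dose, mask)
        curve = dvh_from_samples(samples, bin_width_gy)
        row["d_max_gy"] = d_max(samples)
        row["d_mean_gy"] = d_mean(samples)
        for lv in levels:
            row[f"V{lv:g}Gy"] = v_at_dose(curve, lv)
        rows.append(row)
    cols = ["organ", "d_max_gy", "d_mean_gy"] + [f"V{lv:g}Gy" for lv in levels] + ["error"]
    return pd.DataFrame(rows, columns=cols)


def dvh_table(curve: DvhCurve) -> pd.DataFrame:
    """Two-column export form of a DVH curve."""
    return pd.DataFrame(
        {"dose_gy": curve.bin_edges_gy, "volume_pct": curve.cum_volume_pct}
    )
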