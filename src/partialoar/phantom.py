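"""Synthetic pelvic cases: structure sets, dose grids, and contour variants.

The phantom emulates the anatomy of a prostate radiotherapy case in patient
coordinates (mm; +x left, +y posterior, +z superior):

* **PTV** — an ellipsoid centered at the origin (prostate plus margin).
* **Bladder** — an ellipsoid superior-anterior to the PTV, placed so that it
  penetrates the PTV's superior surface by a controllable overlap depth.
* **Rectum** — a straight tube posterior to the PTV.  The gap between the
  PTV's posterior surface and the rectum's anterior surface is the single
  knob that emulates an injectable rectal spacer (SpaceOAR): spacer patients
  get a positive gap, non-spacer patients a negative one (overlap), since
  the spacer's role in the analysis is purely geometric displacement.
* **Femoral heads** — two lateral spheres.

Dose is an analytic field, not a treatment-planning surrogate: the
prescription inside the PTV (with a mild superior-inferior gradient so that
D98/Dmax are non-trivial) and exponential falloff with Euclidean distance
outside.  This gives closed-form oracles for DVH tests while preserving the
qualitative structure of a real plan (high dose on the target, distance-
driven sparing of OARs).

Contour variants emulating observer or auto-segmentation variability are
produced by perturbing masks: isotropic dilation/erosion, boundary-voxel
noise, or a rigid z-shift, optionally restricted to the PTV-overlap region
or to the region excluded by the partial-contour z-band.

Everything is a pure function of (spec, seed): fixed inputs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydicom.uid import generate_uid
from scipy import ndimage

from .core import BinaryMask, DoseGrid, RoiContour, StructureSet, VoxelGrid
from .errors import PhantomSpecError
from .geometry import PartialContourParams, make_partial_uninvolved, rasterize, z_extent

__all__ = [
    "PhantomSpec",
    "PerturbationSpec",
    "PhantomCase",
    "generate_case",
    "generate_cohort",
    "perturb_structure",
    "ai_variant",
    "contour_agreement_experiment",
    "write_case",
]

log = logging.getLogger(__name__)

_N_RING_VERTICES = 64


@dataclass(frozen=True)
class PhantomSpec:
    """Fully parameterized pelvic phantom (all lengths in mm, dose in Gy)."""

    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    dims: tuple[int, int, int] = (96, 96, 72)

    ptv_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ptv_semiaxes_mm: tuple[float, float, float] = (30.0, 28.0, 25.0)

    bladder_semiaxes_mm: tuple[float, float, float] = (35.0, 32.0, 30.0)
    bladder_anterior_offset_mm: float = 25.0
    #: how far the bladder's inferior tip reaches below the PTV's superior edge
    bladder_overlap_depth_mm: float = 15.0

    rectum_radius_mm: float = 12.0
    rectum_z_range_mm: tuple[float, float] = (-60.0, 40.0)
    #: PTV-posterior-surface to rectum-anterior-surface distance; negative =
    #: overlap.  Emulates a rectal spacer when positive.
    rectum_gap_mm: float = 10.0

    include_femoral_heads: bool = True
    femhead_radius_mm: float = 22.0
    femhead_center_x_mm: float = 68.0
    femhead_center_yz_mm: tuple[float, float] = (5.0, -5.0)

    prescription_gy: float = 70.0
    dose_falloff_mm: float = 8.0
    #: relative superior-inferior dose gradient inside the PTV
    dose_axial_gradient: float = 0.02

    seed: int = 0

    def grid(self) -> VoxelGrid:
        origin = tuple(
            -(d - 1) / 2.0 * s for d, s in zip(self.dims, self.spacing_mm)
        )
        return VoxelGrid(origin_mm=origin, spacing_mm=self.spacing_mm, dims=self.dims)

    @classmethod
    def compact(cls, **overrides) -> "PhantomSpec":
        """A reduced-extent configuration (smaller grid, smaller anatomy).

        Useful for exhaustive per-voxel oracle checks where the full-size
        lattice would be wasteful; the anatomy keeps the same topology
        (bladder overlapping the PTV superiorly, rectum posterior).
        """
        base = dict(
            spacing_mm=(2.5, 2.5, 2.5),
            dims=(40, 40, 40),
            ptv_semiaxes_mm=(16.0, 15.0, 14.0),
            bladder_semiaxes_mm=(16.0, 15.0, 13.0),
            bladder_anterior_offset_mm=12.0,
            bladder_overlap_depth_mm=8.0,
            rectum_radius_mm=7.0,
            rectum_z_range_mm=(-28.0, 20.0),
            rectum_gap_mm=0.0,
            include_femoral_heads=False,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class PerturbationSpec:
    """How to distort a contour into an 'observer/AI' variant."""

    mode: Literal["dilation", "erosion", "boundary-noise", "z-shift"] = "boundary-noise"
    magnitude_mm: float = 2.0
    region: Literal["everywhere", "overlap-only", "band-excluded-only"] = "everywhere"
    band_margin_mm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.magnitude_mm) and self.magnitude_mm >= 0):
            raise PhantomSpecError(f"perturbation magnitude must be >= 0, got {self.magnitude_mm}")


@dataclass
class PhantomCase:
    """One synthetic patient: contours, dose, and analytic ground truth.

    ``truth`` carries analytic values (volumes in mm³, extents, spec echo) so
    oracle tests never re-derive expectations from the masks under test.
    """

    structures: StructureSet
    dose: DoseGrid
    truth: dict = field(default_factory=dict)

    @property
    def grid(self) -> VoxelGrid:
        return self.dose.grid


# ---------------------------------------------------------------------------
# analytic shape helpers (public: used directly by oracle tests)

def ellipsoid_contours(
    center: tuple[float, float, float],
    semiaxes: tuple[float, float, float],
    z_planes: np.ndarray,
    name: str,
    frame: str = "",
    n_vertices: int = _N_RING_VERTICES,
) -> RoiContour:
    """Planar elliptical cross-sections of an axis-aligned ellipsoid."""
    cx, cy, cz = center
    a, b, c = semiaxes
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    slices = []
    for z in z_planes:
        t = (z - cz) / c
        if abs(t) >= 1.0:
            continue
        shrink = math.sqrt(1.0 - t * t)
        ring = np.column_stack(
            [cx + a * shrink * np.cos(theta), cy + b * shrink * np.sin(theta)]
        )
        slices.append((float(z), [ring]))
    return RoiContour(name=name, slices=slices, frame_of_reference=frame)


def tube_contours(
    center_xy: tuple[float, float],
    radius: float,
    z_range: tuple[float, float],
    z_planes: np.ndarray,
    name: str,
    frame: str = "",
    n_vertices: int = _N_RING_VERTICES,
) -> RoiContour:
    """Circular cross-sections of a straight z-aligned tube."""
    cx, cy = center_xy
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    ring = np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)])
    slices = [
        (float(z), [ring.copy()])
        for z in z_planes
        if z_range[0] - 1e-9 <= z <= z_range[1] + 1e-9
    ]
    return RoiContour(name=name, slices=slices, frame_of_reference=frame)


def _ellipsoid_volume(semiaxes) -> float:
    a, b, c = semiaxes
    return 4.0 / 3.0 * math.pi * a * b * c


def _structure_layout(spec: PhantomSpec) -> dict[str, dict]:
    """Analytic placement of every structure, plus its bounding box."""
    pcx, pcy, pcz = spec.ptv_center_mm
    pa, pb, pc = spec.ptv_semiaxes_mm
    ba, bb, bc = spec.bladder_semiaxes_mm

    bladder_center = (
        pcx,
        pcy - spec.bladder_anterior_offset_mm,
        pcz + pc + bc - spec.bladder_overlap_depth_mm,
    )
    rectum_center_xy = (
        pcx,
        pcy + pb + spec.rectum_radius_mm + spec.rectum_gap_mm,
    )

    layout = {
        "PTV": {
            "kind": "ellipsoid",
            "center": spec.ptv_center_mm,
            "semiaxes": spec.ptv_semiaxes_mm,
            "volume_mm3": _ellipsoid_volume(spec.ptv_semiaxes_mm),
            "bbox": _ellipsoid_bbox(spec.ptv_center_mm, spec.ptv_semiaxes_mm),
        },
        "Bladder": {
            "kind": "ellipsoid",
            "center": bladder_center,
            "semiaxes": spec.bladder_semiaxes_mm,
            "volume_mm3": _ellipsoid_volume(spec.bladder_semiaxes_mm),
            "bbox": _ellipsoid_bbox(bladder_center, spec.bladder_semiaxes_mm),
        },
        "Rectum": {
            "kind": "tube",
            "center_xy": rectum_center_xy,
            "radius": spec.rectum_radius_mm,
            "z_range": spec.rectum_z_range_mm,
            "volume_mm3": math.pi
            * spec.rectum_radius_mm**2
            * (spec.rectum_z_range_mm[1] - spec.rectum_z_range_mm[0]),
            "bbox": (
                (
                    rectum_center_xy[0] - spec.rectum_radius_mm,
                    rectum_center_xy[1] - spec.rectum_radius_mm,
                    spec.rectum_z_range_mm[0],
                ),
                (
                    rectum_center_xy[0] + spec.rectum_radius_mm,
                    rectum_center_xy[1] + spec.rectum_radius_mm,
                    spec.rectum_z_range_mm[1],
                ),
            ),
        },
    }
    if spec.include_femoral_heads:
        for side, sign in (("FemHead_L", +1), ("FemHead_R", -1)):
            center = (
                sign * spec.femhead_center_x_mm,
                spec.femhead_center_yz_mm[0],
                spec.femhead_center_yz_mm[1],
            )
            r = spec.femhead_radius_mm
            layout[side] = {
                "kind": "ellipsoid",
                "center": center,
                "semiaxes": (r, r, r),
                "volume_mm3": 4.0 / 3.0 * math.pi * r**3,
                "bbox": _ellipsoid_bbox(center, (r, r, r)),
            }
    return layout


def _ellipsoid_bbox(center, semiaxes):
    return (
        tuple(c - s for c, s in zip(center, semiaxes)),
        tuple(c + s for c, s in zip(center, semiaxes)),
    )


def generate_case(spec: PhantomSpec) -> PhantomCase:
    """Build one synthetic case: structure set, dose grid, ground truth.

    Deterministic for a fixed spec (including its seed).  A structure whose
    analytic bounding box exceeds the grid raises a spec error naming it.
    """
    grid = spec.grid()
    lo, hi = grid.extent_mm()
    layout = _structure_layout(spec)
    for name, info in layout.items():
        blo, bhi = info["bbox"]
        if any(b < g - 1e-9 for b, g in zip(blo, lo)) or any(
            b > g + 1e-9 for b, g in zip(bhi, hi)
        ):
            raise PhantomSpecError(
                f"structure '{name}' (bbox {blo}..{bhi}) exceeds the phantom grid {tuple(lo)}..{tuple(hi)}"
            )

    frame = generate_uid(entropy_srcs=[f"partialoar-phantom-frame-{spec.seed}"])
    zc = grid.z_centers
    rois: dict[str, RoiContour] = {}
    for name, info in layout.items():
        if info["kind"] == "ellipsoid":
            rois[name] = ellipsoid_contours(
                info["center"], info["semiaxes"], zc, name, frame
            )
        else:
            rois[name] = tube_contours(
                info["center_xy"], info["radius"], info["z_range"], zc, name, frame
            )
    ss = StructureSet(rois=rois, source_id=f"phantom-seed{spec.seed}")

    dose_values = _analytic_dose(spec, grid)
    dose = DoseGrid(grid=grid, values=dose_values, prescription_gy=spec.prescription_gy)

    truth = {
        "spec": _spec_to_jsonable(spec),
        "volumes_mm3": {name: info["volume_mm3"] for name, info in layout.items()},
        "ptv_z_extent_mm": [
            spec.ptv_center_mm[2] - spec.ptv_semiaxes_mm[2],
            spec.ptv_center_mm[2] + spec.ptv_semiaxes_mm[2],
        ],
        "rectum_gap_mm": spec.rectum_gap_mm,
        "prescription_gy": spec.prescription_gy,
    }
    return PhantomCase(structures=ss, dose=dose, truth=truth)


def _analytic_dose(spec: PhantomSpec, grid: VoxelGrid) -> np.ndarray:
    """Prescription with mild smooth 3D heterogeneity inside the analytic PTV
    ellipsoid, exponential distance falloff outside.

    The in-target modulation (superior-inferior gradient plus low-amplitude
    incommensurate in-plane ripples, all scaled by ``dose_axial_gradient``)
    emulates the few-percent hot/cold variation of a delivered plan and keeps
    the PTV dose distribution continuous, so coverage percentiles like D98
    are well defined rather than collapsing onto tied slice values.
    """
    x, y, z = np.meshgrid(grid.x_centers, grid.y_centers, grid.z_centers, indexing="ij")
    cx, cy, cz = spec.ptv_center_mm
    a, b, c = spec.ptv_semiaxes_mm
    inside = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
    dist_out = ndimage.distance_transform_edt(~inside, sampling=grid.spacing_mm)
    rx = spec.prescription_gy
    dose = rx * np.exp(-dist_out / spec.dose_falloff_mm)
    g = spec.dose_axial_gradient
    inhom = g * (
        (z - cz) / max(c, 1e-9)
        + 0.41 * np.sin((x - cx) / 7.1)
        + 0.29 * np.cos((y - cy) / 9.3)
    )
    dose = np.where(inside, rx * (1.0 + inhom), dose)
    return np.clip(dose, 0.0, None)


def _spec_to_jsonable(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


# ---------------------------------------------------------------------------
# cohorts

_JITTERABLE_SCALAR = {
    "bladder_overlap_depth_mm",
    "bladder_anterior_offset_mm",
    "rectum_radius_mm",
    "rectum_gap_mm",
    "femhead_radius_mm",
    "dose_falloff_mm",
}
_JITTERABLE_VECTOR = {"ptv_semiaxes_mm", "bladder_semiaxes_mm"}

#: per-parameter jitter SDs (mm) a pelvic cohort plausibly spans
DEFAULT_JITTER = {
    "ptv_semiaxes_mm": 2.0,
    "bladder_semiaxes_mm": 3.0,
    "rectum_radius_mm": 1.0,
    "rectum_gap_mm": 1.5,
    "bladder_overlap_depth_mm": 2.0,
}


def generate_cohort(
    n: int,
    template: PhantomSpec = PhantomSpec(),
    variability: dict[str, float] | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate ``n`` cases by jittering a template spec.

    ``variability`` maps spec field names to normal jitter SDs (mm); vector
    fields are jittered component-wise.  Draws are truncated at +/- 2 SD so
    jittered anatomy stays within the scan field of view.  Case i depends
    only on ``(seed, i)``, so cohorts are reproducible and extendable.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    jitter = DEFAULT_JITTER if variability is None else variability
    unknown = set(jitter) - _JITTERABLE_SCALAR - _JITTERABLE_VECTOR
    if unknown:
        raise PhantomSpecError(f"unknown jitter parameters: {sorted(unknown)}")

    cases = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, i)))
        overrides: dict = {"seed": int((seed * 100_003 + i) % 2**31)}
        def draw(rng, sd):
            return float(np.clip(rng.normal(0.0, sd), -2.0 * sd, 2.0 * sd))

        for name, sd in jitter.items():
            base = getattr(template, name)
            if name in _JITTERABLE_VECTOR:
                jittered = tuple(max(1.0, v + draw(rng, sd)) for v in base)
            else:
                jittered = base + draw(rng, sd)
                if name != "rectum_gap_mm":  # the gap may legitimately go negative
                    jittered = max(0.5, jittered)
            overrides[name] = jittered
        cases.append(generate_case(dataclasses.replace(template, **overrides)))
    return cases


# ---------------------------------------------------------------------------
# perturbations

def _surface_shell(occ: np.ndarray) -> np.ndarray:
    """One-voxel shell on both sides of the occupancy boundary."""
    dil = ndimage.binary_dilation(occ)
    ero = ndimage.binary_erosion(occ)
    return dil & ~ero


def perturb_structure(
    mask: BinaryMask,
    pert: PerturbationSpec,
    ptv: BinaryMask | None = None,
) -> BinaryMask:
    """Distort a mask per the perturbation spec, deterministically per seed.

    Dilation/erosion act by Euclidean distance (mm) on the lattice;
    boundary noise flips voxels in the one-voxel surface shell with
    probability ``min(1, magnitude / (2 * mean_spacing))``; z-shift
    translates by the nearest whole number of slices (superior for positive
    magnitude).  When a region restriction applies, voxels outside the
    region keep their original occupancy.
    """
    grid = mask.grid
    occ = mask.occupancy
    spacing = np.asarray(grid.spacing_mm)

    if pert.mode == "dilation":
        if mask.is_empty:
            new = occ.copy()
        else:
            dist = ndimage.distance_transform_edt(~occ, sampling=spacing)
            new = dist <= pert.magnitude_mm
    elif pert.mode == "erosion":
        dist_in = ndimage.distance_transform_edt(occ, sampling=spacing)
        new = dist_in > pert.magnitude_mm
    elif pert.mode == "boundary-noise":
        rng = np.random.default_rng(pert.seed)
        p = min(1.0, pert.magnitude_mm / (2.0 * float(spacing.mean())))
        flips = _surface_shell(occ) & (rng.random(occ.shape) < p)
        new = occ ^ flips
    elif pert.mode == "z-shift":
        shift = int(round(pert.magnitude_mm / grid.spacing_mm[2]))
        new = np.zeros_like(occ)
        if shift == 0:
            new = occ.copy()
        elif shift > 0:
            new[:, :, shift:] = occ[:, :, :-shift]
        else:
            new[:, :, :shift] = occ[:, :, -shift:]
    else:
        raise PhantomSpecError(f"unknown perturbation mode {pert.mode!r}")

    if pert.region != "everywhere":
        if ptv is None:
            raise PhantomSpecError(f"region '{pert.region}' requires a PTV mask")
        if ptv.grid != grid:
            raise PhantomSpecError("PTV mask must share the perturbed mask's grid")
        if pert.region == "overlap-only":
            region = ptv.occupancy
            if not (occ & region).any():
                raise PhantomSpecError(
                    "overlap-only perturbation requires a non-empty structure/PTV overlap"
                )
        else:  # band-excluded-only
            zmin, zmax = z_extent(ptv)
            m = pert.band_margin_mm
            zc = grid.z_centers
            outside_band = (zc < zmin - m - 1e-9) | (zc > zmax + m + 1e-9)
            region = np.broadcast_to(
                outside_band[np.newaxis, np.newaxis, :], grid.dims
            )
        new = np.where(region, new, occ)

    if occ.any() and not new.any():
        log.warning("perturbation (%s, %.1f mm) emptied the structure", pert.mode, pert.magnitude_mm)
    return BinaryMask(grid, new)


def ai_variant(
    case: PhantomCase,
    organs: list[str],
    pert: PerturbationSpec,
    ptv_name: str = "PTV",
) -> StructureSet:
    """Perturbed copy of a case's structure set, emulating an AI observer.

    Only the named organs are perturbed (each with a distinct sub-seed); all
    other ROIs, including the PTV, are carried over unchanged.
    """
    from .geometry import contours_from_mask

    grid = case.grid
    frame = case.structures.frame_of_reference
    ptv_mask = rasterize(case.structures[ptv_name], grid)
    rois: dict[str, RoiContour] = {}
    for name, roi in case.structures.rois.items():
        if name in organs:
            sub = dataclasses.replace(
                pert, seed=int((pert.seed * 1_000_003 + zlib.crc32(name.encode())) % 2**31)
            )
            perturbed = perturb_structure(rasterize(roi, grid), sub, ptv=ptv_mask)
            rois[name] = contours_from_mask(perturbed, name, frame)
        else:
            rois[name] = roi
    return StructureSet(rois=rois, source_id=case.structures.source_id + "-ai")


# ---------------------------------------------------------------------------
# the cohort agreement experiment

def contour_agreement_experiment(
    cases: list[PhantomCase],
    pert: PerturbationSpec,
    organs: tuple[str, ...] = ("Bladder", "Rectum"),
    ptv_name: str = "PTV",
    margin_mm: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Score manual-vs-perturbed agreement per case, full and partial modes.

    The manual contours are each case's own structure set; the test variant
    perturbs the named organs.  Partial-mode masks for both variants are
    built against the same (manual) PTV.  Returns a tidy DataFrame with
    columns ``case, organ, mode, dsc, oi``.
    """
    from .agreement import dice, overlay_index

    params = PartialContourParams(margin_sup_inf_mm=margin_mm)
    rows = []
    for i, case in enumerate(cases):
        grid = case.grid
        ptv_mask = rasterize(case.structures[ptv_name], grid)
        for organ in organs:
            manual = rasterize(case.structures[organ], grid)
            sub = dataclasses.replace(
                pert, seed=int((seed * 7_919 + i * 211 + zlib.crc32(organ.encode())) % 2**31)
            )
            test = perturb_structure(manual, sub, ptv=ptv_mask)
            for mode in ("full", "partial"):
                if mode == "partial":
                    ref_m = make_partial_uninvolved(manual, ptv_mask, params)
                    test_m = make_partial_uninvolved(test, ptv_mask, params)
                else:
                    ref_m, test_m = manual, test
                rows.append(
                    {
                        "case": i,
                        "organ": organ,
                        "mode": mode,
                        "dsc": dice(ref_m, test_m),
                        "oi": overlay_index(ref_m, test_m),
                    }
                )
    return pd.DataFrame(rows)


def write_case(case: PhantomCase, directory: str | Path) -> dict[str, Path]:
    """Write a case as rtstruct.dcm + rtdose.dcm + truth.json."""
    from .io_dicom_rt import write_rtdose, write_rtstruct

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "rtstruct": directory / "rtstruct.dcm",
        "rtdose": directory / "rtdose.dcm",
        "truth": directory / "truth.json",
    }
    write_rtstruct(case.structures, paths["rtstruct"])
    write_rtdose(case.dose, paths["rtdose"])
    paths["truth"].write_text(json.dumps(case.truth, indent=2, sort_keys=True))
    return paths
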