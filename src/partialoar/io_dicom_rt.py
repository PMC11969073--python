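"""Reading and writing DICOM-RT objects (RTSTRUCT, RTDOSE).

Only axial ``CLOSED_PLANAR`` contours are supported — the native
representation of CT-slice contours in clinical structure sets; any other
contour geometric type is rejected.  Coordinates are kept in the DICOM
patient coordinate system (mm) throughout.

Writing is deterministic: all UIDs are derived by hashing the object content,
so re-exporting the same structure set yields byte-identical files.  This
matters for reproducible pipelines and is exploited by the test suite.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import DoseGrid, RoiContour, StructureSet, VoxelGrid
from .errors import EmptyStructureError, FormatError

__all__ = ["read_rtstruct", "write_rtstruct", "read_rtdose", "write_rtdose"]

log = logging.getLogger(__name__)

RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"

# z values within this tolerance (mm) are treated as the same slice on read
_Z_TOL = 1e-4


def _det_uid(*entropy: str) -> str:
    """Deterministic UID from content strings (hash-based per PS3.5 B.2)."""
    return generate_uid(entropy_srcs=list(entropy))


def _content_hash(ss: StructureSet) -> str:
    h = hashlib.sha256()
    h.update(ss.source_id.encode())
    for name, roi in ss.rois.items():
        h.update(name.encode())
        for z, rings in roi.slices:
            h.update(np.float64(z).tobytes())
            for ring in rings:
                h.update(np.ascontiguousarray(ring, dtype=np.float64).tobytes())
    return h.hexdigest()


def _read_dicom(path: str | Path) -> pydicom.Dataset:
    try:
        return pydicom.dcmread(str(path))
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"cannot read DICOM file: {path}") from exc
    except Exception as exc:  # pydicom raises InvalidDicomError (subclass of ValueError)
        raise FormatError(f"not a readable DICOM file: {path} ({exc})") from exc


def read_rtstruct(path: str | Path) -> StructureSet:
    """Read an RT Structure Set into a :class:`StructureSet`.

    ROIs without geometric contour data are skipped with a warning; contour
    items on the same z plane are merged into one slice's ring list.
    """
    ds = _read_dicom(path)
    if getattr(ds, "Modality", None) != "RTSTRUCT" and getattr(ds, "SOPClassUID", "") != RTSTRUCT_SOP_CLASS:
        raise FormatError(f"{path}: not an RT Structure Set (Modality={getattr(ds, 'Modality', '?')})")

    roi_meta = {
        int(item.ROINumber): item for item in getattr(ds, "StructureSetROISequence", [])
    }
    rois: dict[str, RoiContour] = {}
    for rc in getattr(ds, "ROIContourSequence", []):
        number = int(rc.ReferencedROINumber)
        meta = roi_meta.get(number)
        name = str(meta.ROIName) if meta is not None else f"ROI_{number}"
        frame = str(getattr(meta, "ReferencedFrameOfReferenceUID", "")) if meta is not None else ""
        if not frame:
            frame = str(getattr(ds, "FrameOfReferenceUID", ""))
        contour_seq = getattr(rc, "ContourSequence", None)
        if not contour_seq:
            log.warning("RTSTRUCT %s: ROI '%s' has no contour data, skipped", path, name)
            continue
        by_z: dict[float, list[np.ndarray]] = {}
        for item in contour_seq:
            gtype = str(getattr(item, "ContourGeometricType", ""))
            if gtype != "CLOSED_PLANAR":
                raise FormatError(
                    f"{path}: ROI '{name}' has unsupported contour type '{gtype}' "
                    "(only axial CLOSED_PLANAR contours are supported)"
                )
            pts = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
            z = float(np.round(np.mean(pts[:, 2]) / _Z_TOL) * _Z_TOL)
            by_z.setdefault(z, []).append(pts[:, :2])
        slices = [(z, rings) for z, rings in sorted(by_z.items())]
        rois[name] = RoiContour(name=name, slices=slices, frame_of_reference=frame)
    source = str(getattr(ds, "StructureSetLabel", "")) or str(path)
    return StructureSet(rois=rois, source_id=source)


def write_rtstruct(ss: StructureSet, path: str | Path) -> None:
    """Write a standards-conformant RT Structure Set.

    Geometry survives a write→read round trip to within 1e-3 mm (vertices are
    serialized with 4 decimal places).  Raises on an empty structure set.
    """
    if not ss.rois:
        raise EmptyStructureError("refusing to write an empty structure set")
    path = Path(path)
    content = _content_hash(ss)
    frame_uid = ss.frame_of_reference or _det_uid(content, "frame")

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTSTRUCT_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = _det_uid(content, "sop")
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SpecificCharacterSet = "ISO_IR 100"
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.Manufacturer = "partialoar"
    ds.PatientName = ss.source_id or "PHANTOM"
    ds.PatientID = (ss.source_id or "PHANTOM")[:64]
    ds.PatientBirthDate = ""
    ds.PatientSex = ""
    ds.StudyDate = ""
    ds.StudyTime = ""
    ds.ReferringPhysicianName = ""
    ds.AccessionNumber = ""
    ds.StudyID = ""
    ds.SeriesNumber = 1
    ds.StudyInstanceUID = _det_uid(content, "study")
    ds.SeriesInstanceUID = _det_uid(content, "series")
    ds.FrameOfReferenceUID = frame_uid
    ds.StructureSetLabel = (ss.source_id or "STRUCTS")[:16]
    ds.StructureSetDate = ""
    ds.StructureSetTime = ""

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = frame_uid
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]

    struct_seq, contour_seq, obs_seq = [], [], []
    for number, (name, roi) in enumerate(ss.rois.items(), start=1):
        sroi = Dataset()
        sroi.ROINumber = number
        sroi.ReferencedFrameOfReferenceUID = frame_uid
        sroi.ROIName = name
        sroi.ROIGenerationAlgorithm = "AUTOMATIC"
        struct_seq.append(sroi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        items = []
        for z, rings in roi.slices:
            for ring in rings:
                if len(ring) < 3:
                    log.warning("ROI '%s': dropping degenerate ring on write", name)
                    continue
                item = Dataset()
                item.ContourGeometricType = "CLOSED_PLANAR"
                item.NumberOfContourPoints = len(ring)
                flat = np.column_stack([ring, np.full(len(ring), z)]).ravel()
                item.ContourData = [f"{v:.4f}" for v in flat]
                items.append(item)
        rc.ContourSequence = items
        contour_seq.append(rc)

        obs = Dataset()
        obs.ObservationNumber = number
        obs.ReferencedROINumber = number
        obs.ROIObservationLabel = name
        obs.RTROIInterpretedType = "ORGAN"
        obs.ROIInterpreter = ""
        obs_seq.append(obs)

    ds.StructureSetROISequence = struct_seq
    ds.ROIContourSequence = contour_seq
    ds.RTROIObservationsSequence = obs_seq
    ds.save_as(str(path), enforce_file_format=True)


def read_rtdose(path: str | Path, prescription_gy: float = 70.0) -> DoseGrid:
    """Read an RT Dose grid; values are returned in Gy (grid scaling applied).

    The prescription is not stored in RTDOSE, so it is supplied by the caller
    (default 70 Gy, the clinical prescription this toolkit targets).
    """
    ds = _read_dicom(path)
    if getattr(ds, "Modality", None) != "RTDOSE" and getattr(ds, "SOPClassUID", "") != RTDOSE_SOP_CLASS:
        raise FormatError(f"{path}: not an RT Dose object (Modality={getattr(ds, 'Modality', '?')})")
    if "DoseGridScaling" not in ds or "PixelData" not in ds:
        raise FormatError(f"{path}: RT Dose missing DoseGridScaling or PixelData")

    orient = np.asarray(getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), dtype=float)
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise FormatError(f"{path}: only axis-aligned axial dose grids are supported")

    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if len(offsets) > 1:
        dz = np.diff(offsets)
        if not np.allclose(dz, dz[0], atol=1e-6):
            raise FormatError(f"{path}: non-uniform dose frame spacing is not supported")
        z_spacing = float(dz[0])
    else:
        z_spacing = float(getattr(ds, "SliceThickness", 1.0) or 1.0)

    ipp = np.asarray(ds.ImagePositionPatient, dtype=float)
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)  # (dy, dx) per PS3.3
    arr = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    values = np.transpose(arr, (2, 1, 0))  # (frames, rows, cols) -> (x, y, z)
    grid = VoxelGrid(
        origin_mm=(ipp[0], ipp[1], ipp[2] + offsets[0]),
        spacing_mm=(col_sp, row_sp, z_spacing),
        dims=values.shape,
    )
    return DoseGrid(grid=grid, values=values, prescription_gy=prescription_gy)


def write_rtdose(dose: DoseGrid, path: str | Path) -> None:
    """Write an RT Dose object (32-bit integer pixels, GY units).

    The dose grid scaling quantum is max(dose)/(2**32 - 1), so the write→read
    round-trip error is below one quantum.
    """
    path = Path(path)
    nx, ny, nz = dose.grid.dims
    vmax = float(dose.values.max())
    scaling = vmax / (2**32 - 1) if vmax > 0 else 1.0
    pix = np.rint(dose.values / scaling).astype(np.uint32)
    frames = np.ascontiguousarray(np.transpose(pix, (2, 1, 0)))  # (z, y, x)

    h = hashlib.sha256(frames.tobytes()).hexdigest()
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTDOSE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = _det_uid(h, "sop")
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.Manufacturer = "partialoar"
    ds.PatientName = "PHANTOM"
    ds.PatientID = "PHANTOM"
    ds.PatientBirthDate = ""
    ds.PatientSex = ""
    ds.StudyDate = ""
    ds.StudyTime = ""
    ds.ReferringPhysicianName = ""
    ds.AccessionNumber = ""
    ds.StudyID = ""
    ds.SeriesNumber = 1
    ds.InstanceNumber = 1
    ds.StudyInstanceUID = _det_uid(h, "study")
    ds.SeriesInstanceUID = _det_uid(h, "series")
    ds.FrameOfReferenceUID = _det_uid(h, "frame")

    ds.ImagePositionPatient = [f"{v:.6f}" for v in dose.grid.origin_mm]
    ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
    ds.PixelSpacing = [f"{dose.grid.spacing_mm[1]:.6f}", f"{dose.grid.spacing_mm[0]:.6f}"]
    ds.SliceThickness = f"{dose.grid.spacing_mm[2]:.6f}"
    ds.GridFrameOffsetVector = [f"{k * dose.grid.spacing_mm[2]:.6f}" for k in range(nz)]
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = f"{scaling:.10e}"  # 16 chars max for VR DS
    ds.PixelData = frames.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
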