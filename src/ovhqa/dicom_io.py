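"""DICOM-RT ingestion: RTDOSE / RTSTRUCT reading, minimal writing.

Reading follows the DICOM contracts: dose pixels are scaled to Gy by
``DoseGridScaling``; contours are rasterized onto the dose grid (the dose
grid is the master grid); local ROI names are translated to canonical
labels (``ptv``, ``bowel_bag``, ``bladder``, ...) through a user-supplied
name map, and unmapped ROIs are ignored with a log line.  Patient axes are
LPS; only axial, coplanar contour planes are supported.

Writing produces minimal but valid RTDOSE/RTSTRUCT pairs from a
:class:`~ovhqa.grid.PatientCase`, used for end-to-end round-trip tests of
synthetic phantoms.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage import measure

from .grid import PatientCase, PlanMeta, StructureMask, VoxelGrid, rasterize_contours

logger = logging.getLogger("ovhqa")

__all__ = ["read_dicom_case", "write_case_dicom"]

RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"


def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def write_case_dicom(case: PatientCase, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a case as an RTSTRUCT/RTDOSE pair; returns the two file paths."""
    if not case.has_dose:
        raise ValueError("case has no dose grid to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame_uid = generate_uid()

    dose_path = out_dir / "rtdose.dcm"
    _write_rtdose(case, dose_path, frame_uid)
    struct_path = out_dir / "rtstruct.dcm"
    _write_rtstruct(case, struct_path, frame_uid)
    return struct_path, dose_path


def _write_rtdose(case: PatientCase, path: Path, frame_uid: str) -> None:
    grid = case.grid
    sop_instance = generate_uid()
    ds = FileDataset(
        str(path), {}, file_meta=_file_meta(RTDOSE_SOP_CLASS, sop_instance), preamble=b"\0" * 128
    )
    ds.SOPClassUID = RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = sop_instance
    ds.Modality = "RTDOSE"
    ds.PatientID = case.patient_id
    ds.PatientName = case.patient_id
    ds.FrameOfReferenceUID = frame_uid
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    # origin is (z, y, x); ImagePositionPatient is (x, y, z)
    ds.ImagePositionPatient = [grid.origin[2], grid.origin[1], grid.origin[0]]
    ds.PixelSpacing = [grid.spacing[1], grid.spacing[2]]  # [row, col] = [y, x]
    ds.SliceThickness = grid.spacing[0]
    ds.GridFrameOffsetVector = list(np.arange(grid.shape[0]) * grid.spacing[0])
    ds.NumberOfFrames = grid.shape[0]
    ds.Rows = grid.shape[1]
    ds.Columns = grid.shape[2]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    max_dose = float(case.dose.max())
    scaling = max_dose / (2**32 - 1) if max_dose > 0 else 1.0
    ds.DoseGridScaling = scaling
    ints = np.round(case.dose / scaling).astype("<u4")
    ds.PixelData = ints.tobytes()
    ds.save_as(path, enforce_file_format=True)


def _mask_contours(mask: StructureMask) -> list[tuple[float, np.ndarray]]:
    """Per-slice closed contours of a binary mask in world (x, y, z) mm."""
    grid = mask.grid
    out: list[tuple[float, np.ndarray]] = []
    for k in range(grid.shape[0]):
        sl = mask.voxels[k]
        if not sl.any():
            continue
        z = grid.origin[0] + k * grid.spacing[0]
        padded = np.pad(sl.astype(float), 1)
        for contour in measure.find_contours(padded, 0.5):
            ys = grid.origin[1] + (contour[:, 0] - 1) * grid.spacing[1]
            xs = grid.origin[2] + (contour[:, 1] - 1) * grid.spacing[2]
            verts = np.column_stack([xs, ys])
            if np.allclose(verts[0], verts[-1]):
                verts = verts[:-1]
            if len(verts) >= 3:
                out.append((z, verts))
    return out


def _write_rtstruct(case: PatientCase, path: Path, frame_uid: str) -> None:
    sop_instance = generate_uid()
    ds = FileDataset(
        str(path), {}, file_meta=_file_meta(RTSTRUCT_SOP_CLASS, sop_instance), preamble=b"\0" * 128
    )
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = sop_instance
    ds.Modality = "RTSTRUCT"
    ds.PatientID = case.patient_id
    ds.PatientName = case.patient_id
    ds.StructureSetLabel = "ovhqa"

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = frame_uid
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]

    structures = [case.ptv] + [case.oars[n] for n in sorted(case.oars)]
    roi_seq = []
    contour_seq = []
    for number, mask in enumerate(structures, start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIName = mask.name
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        items = []
        for z, verts in _mask_contours(mask):
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(verts)
            data = np.column_stack([verts, np.full(len(verts), z)])
            c.ContourData = [float(v) for v in data.ravel()]
            items.append(c)
        rc.ContourSequence = items
        contour_seq.append(rc)
    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.save_as(path, enforce_file_format=True)


def _read_rtdose(path: str | Path) -> tuple[VoxelGrid, np.ndarray, str]:
    ds = pydicom.dcmread(path)
    if ds.SOPClassUID != RTDOSE_SOP_CLASS:
        raise ValueError(f"{path} is not an RTDOSE object")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz, dz[0]):
        raise ValueError("non-uniform GridFrameOffsetVector is not supported")
    spacing_z = float(dz[0]) if offsets.size > 1 else float(ds.SliceThickness)
    ipp = [float(v) for v in ds.ImagePositionPatient]
    grid = VoxelGrid(
        origin=(ipp[2] + float(offsets[0]), ipp[1], ipp[0]),
        spacing=(spacing_z, float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])),
        shape=(int(ds.NumberOfFrames), int(ds.Rows), int(ds.Columns)),
    )
    dose = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    return grid, dose, str(ds.FrameOfReferenceUID)


def read_dicom_case(
    rtstruct_path: str | Path,
    rtdose_path: str | Path,
    structure_name_map: Mapping[str, str],
    patient_id: str | None = None,
    meta: PlanMeta | None = None,
) -> PatientCase:
    """Build a :class:`PatientCase` from an RTSTRUCT/RTDOSE pair.

    Parameters
    ----------
    structure_name_map
        Local ROI name -> canonical label (``ptv``, ``bowel_bag``,
        ``bladder``...).  ROIs absent from the map are ignored with a log
        line; a missing ``ptv`` after mapping is an error listing the
        available ROI names.
    """
    grid, dose, dose_frame = _read_rtdose(rtdose_path)
    struct = pydicom.dcmread(rtstruct_path)
    if struct.SOPClassUID != RTSTRUCT_SOP_CLASS:
        raise ValueError(f"{rtstruct_path} is not an RTSTRUCT object")
    struct_frame = str(
        struct.ReferencedFrameOfReferenceSequence[0].FrameOfReferenceUID
    )
    if struct_frame != dose_frame:
        raise ValueError(
            f"frame-of-reference mismatch: RTSTRUCT {struct_frame} vs RTDOSE {dose_frame}"
        )

    roi_names = {int(r.ROINumber): str(r.ROIName) for r in struct.StructureSetROISequence}
    masks: dict[str, StructureMask] = {}
    for rc in struct.ROIContourSequence:
        local = roi_names[int(rc.ReferencedROINumber)]
        if local not in structure_name_map:
            logger.info("ignoring unmapped ROI %r", local)
            continue
        canonical = structure_name_map[local]
        contours = []
        for item in getattr(rc, "ContourSequence", []):
            data = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
            contours.append((float(data[0, 2]), data[:, :2]))
        masks[canonical] = rasterize_contours(contours, grid, name=canonical)

    if "ptv" not in masks:
        raise ValueError(
            f"no ROI mapped to 'ptv'; available ROI names: {sorted(roi_names.values())}"
        )
    ptv = masks.pop("ptv")
    return PatientCase(
        patient_id=patient_id or str(getattr(struct, "PatientID", "unknown")),
        grid=grid,
        ptv=ptv,
        oars=masks,
        dose=dose,
        meta=meta or PlanMeta(),
    )
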