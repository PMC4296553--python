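"""File adapters: NIfTI/NRRD volumes, landmark CSVs, course YAML.

Scalar volumes round-trip through NIfTI-1 (via nibabel) or NRRD (via
SimpleITK), selected by file extension.  Arrays are stored index-order
``(x, y, z)`` with x fastest on disk, voxel-center origin and per-axis mm
spacing in the standard headers; only axis-aligned geometries are
supported.  Deformation fields are 4-D volumes with the displacement
component as the last axis.  Landmarks are plain CSV with columns
``name, x, y, z`` (mm).
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from .accumulation import FractionRecord, TreatmentCourse
from .errors import ConfigurationError, GeometryError
from .grids import GY_EQD2, GY_PHYSICAL, DoseGrid, GridGeometry, StructureMask
from .registration import DeformationField

__all__ = [
    "write_volume",
    "read_volume",
    "write_dose",
    "read_dose",
    "write_mask",
    "read_mask",
    "write_field",
    "read_field",
    "write_landmarks",
    "read_landmarks",
    "write_course_dir",
    "read_course",
]

_NIFTI_EXT = (".nii", ".nii.gz")
_NRRD_EXT = (".nrrd", ".nhdr")


def _is_nifti(path: str) -> bool:
    return str(path).endswith(_NIFTI_EXT)


def _is_nrrd(path: str) -> bool:
    return str(path).endswith(_NRRD_EXT)


def write_volume(path, values: np.ndarray, geometry: GridGeometry) -> None:
    """Write a scalar (or trailing-vector 4-D) volume with its geometry."""
    values = np.asarray(values)
    if _is_nifti(path):
        affine = np.eye(4)
        affine[:3, :3] = np.diag(geometry.spacing)
        affine[:3, 3] = geometry.origin
        nib.save(nib.Nifti1Image(values, affine), str(path))
    elif _is_nrrd(path):
        if values.ndim == 4:
            arr = np.moveaxis(values, (0, 1, 2, 3), (2, 1, 0, 3))
            img = sitk.GetImageFromArray(np.ascontiguousarray(arr),
                                         isVector=True)
        else:
            img = sitk.GetImageFromArray(
                np.ascontiguousarray(values.transpose(2, 1, 0))
            )
        img.SetSpacing(tuple(geometry.spacing))
        img.SetOrigin(tuple(geometry.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ConfigurationError(f"unsupported volume extension: {path}")


def read_volume(path, frame_id: str = "unknown"):
    """Read a volume; returns (values, GridGeometry)."""
    if _is_nifti(path):
        img = nib.load(str(path))
        affine = img.affine
        if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
            raise GeometryError("oblique NIfTI grids are not supported")
        spacing = np.diag(affine[:3, :3])
        if np.any(spacing <= 0):
            raise GeometryError("NIfTI affine must have positive diagonal spacing")
        values = np.asarray(img.dataobj)
        origin = affine[:3, 3]
    elif _is_nrrd(path):
        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # (z, y, x[, c])
        if arr.ndim == 4:
            values = np.moveaxis(arr, (0, 1, 2, 3), (2, 1, 0, 3))
        else:
            values = arr.transpose(2, 1, 0)
        spacing = np.asarray(img.GetSpacing())
        origin = np.asarray(img.GetOrigin())
    else:
        raise ConfigurationError(f"unsupported volume extension: {path}")
    geometry = GridGeometry(tuple(origin), tuple(spacing),
                            tuple(values.shape[:3]), frame_id)
    return np.ascontiguousarray(values), geometry


def write_dose(path, dose: DoseGrid) -> None:
    write_volume(path, dose.values.astype(np.float32), dose.geometry)


def read_dose(path, unit: str = GY_PHYSICAL, n_fractions: int = 1,
              frame_id: str = "unknown") -> DoseGrid:
    values, geometry = read_volume(path, frame_id)
    return DoseGrid(geometry, values.astype(float), unit, n_fractions)


def write_mask(path, mask: StructureMask) -> None:
    write_volume(path, mask.occupancy.astype(np.uint8), mask.geometry)


def read_mask(path, label: str = "other", frame_id: str = "unknown") -> StructureMask:
    values, geometry = read_volume(path, frame_id)
    return StructureMask(geometry, values > 0, label)


def write_field(path, fld: DeformationField) -> None:
    write_volume(path, fld.displacement.astype(np.float32), fld.geometry)


def read_field(path, frame_id: str = "unknown") -> DeformationField:
    values, geometry = read_volume(path, frame_id)
    if values.ndim != 4 or values.shape[3] != 3:
        raise GeometryError("deformation fields must be (nx, ny, nz, 3)")
    return DeformationField(geometry, values.astype(float))


def write_landmarks(path, points: np.ndarray, names=None) -> None:
    pts = np.atleast_2d(points)
    names = names or [f"p{i}" for i in range(len(pts))]
    pd.DataFrame(
        {"name": names, "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2]}
    ).to_csv(path, index=False)


def read_landmarks(path) -> np.ndarray:
    frame = pd.read_csv(path)
    return frame[["x", "y", "z"]].to_numpy(dtype=float)


def write_course_dir(course, out_dir) -> Path:
    """Write a phantom course as a consumable directory + course.yaml.

    Layout: one subdirectory per frame with ``ct.nii.gz``, ``dose.nii.gz``,
    per-structure masks and landmark CSVs, a ``truth_fields/`` directory
    with the known reference→frame displacement fields, and a course YAML
    tying everything together.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {"reference_frame": course.reference_frame, "records": []}
    for frame in course.frames:
        fdir = out / frame.frame_id
        fdir.mkdir(exist_ok=True)
        write_volume(fdir / "ct.nii.gz", frame.ct.astype(np.float32),
                     frame.geometry)
        write_dose(fdir / "dose.nii.gz", frame.dose)
        rec = {
            "frame_id": frame.frame_id,
            "modality": frame.modality,
            "n_fractions": frame.dose.n_fractions,
            "image": f"{frame.frame_id}/ct.nii.gz",
            "dose": f"{frame.frame_id}/dose.nii.gz",
            "landmarks": {},
            "structures": {},
        }
        if frame.session_index is not None:
            rec["session_index"] = frame.session_index
        for kind, pts in frame.landmarks.items():
            rel = f"{frame.frame_id}/landmarks_{kind}.csv"
            write_landmarks(out / rel, pts)
            rec["landmarks"][kind] = rel
        for label, mask in frame.organs.items():
            safe = label.replace("-", "").lower()
            rel = f"{frame.frame_id}/mask_{safe}.nii.gz"
            write_mask(out / rel, mask)
            rec["structures"][label] = rel
        doc["records"].append(rec)
    if course.truth_fields:
        tdir = out / "truth_fields"
        tdir.mkdir(exist_ok=True)
        doc["truth_fields"] = {}
        for frame_id, fld in course.truth_fields.items():
            rel = f"truth_fields/{frame_id}.nii.gz"
            write_field(out / rel, fld)
            doc["truth_fields"][frame_id] = rel
    with open(out / "course.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return out / "course.yaml"


def read_course(course_yaml):
    """Load a course directory; returns (TreatmentCourse, truth_fields dict)."""
    course_yaml = Path(course_yaml)
    base = course_yaml.parent
    with open(course_yaml) as fh:
        doc = yaml.safe_load(fh)
    records = []
    for rec in doc["records"]:
        frame_id = rec["frame_id"]
        dose = read_dose(base / rec["dose"], GY_PHYSICAL,
                         int(rec.get("n_fractions", 1)), frame_id)
        image = None
        if rec.get("image"):
            image, _ = read_volume(base / rec["image"], frame_id)
        landmarks = {
            kind: read_landmarks(base / rel)
            for kind, rel in rec.get("landmarks", {}).items()
        }
        structures = {
            label: read_mask(base / rel, label, frame_id)
            for label, rel in rec.get("structures", {}).items()
        }
        records.append(
            FractionRecord(
                dose=dose,
                modality=rec["modality"],
                frame_id=frame_id,
                landmarks=landmarks,
                session_index=rec.get("session_index"),
                image=image,
                structures=structures,
            )
        )
    reference_frame = doc["reference_frame"]
    ref_structures = next(
        r.structures for r in records if r.frame_id == reference_frame
    )
    course = TreatmentCourse(records, reference_frame, ref_structures)
    truth = {
        frame_id: read_field(base / rel, reference_frame)
        for frame_id, rel in doc.get("truth_fields", {}).items()
    }
    return course, truth
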