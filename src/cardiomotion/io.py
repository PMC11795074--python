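"""Readers and writers for volumes, displacement fields, point sets and landmarks.

Volumes travel as NIfTI (via nibabel) or MetaImage (via SimpleITK); structure
point sets and landmarks use a small documented JSON format with coordinates
in patient-space mm; DICOM-RT Structure Set ingestion is an optional adapter
(the native structure format remains JSON).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import Landmarks, StructurePointSet, VolumeFormatError, VolumeImage
from .registration import DisplacementField

__all__ = [
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
    "write_true_field",
    "read_point_sets",
    "write_point_sets",
    "read_landmarks",
    "write_landmarks",
    "ingest_rtss",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


def _has_suffix(path: Path, suffixes: tuple[str, ...]) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in suffixes)


def _check_affine(affine: np.ndarray, path: Path) -> tuple[tuple, tuple]:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > 1e-4:
        raise VolumeFormatError(
            f"{path}: oblique/rotated affines are not supported (axes must be grid-aligned)"
        )
    diag = np.diag(rot)
    if np.any(diag <= 0):
        raise VolumeFormatError(f"{path}: flipped axes are not supported")
    return tuple(float(d) for d in diag), tuple(float(t) for t in affine[:3, 3])


def read_volume(path: Path | str) -> VolumeImage:
    """Read a NIfTI or MetaImage volume with spacing/origin metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _has_suffix(path, _NIFTI_SUFFIXES):
        try:
            img = nib.load(path)
            data = np.asarray(img.dataobj, dtype=np.float64)
            affine = img.affine
        except Exception as exc:  # nibabel raises a zoo of parse errors
            raise VolumeFormatError(f"{path}: cannot parse NIfTI ({exc})") from exc
        if data.ndim != 3:
            raise VolumeFormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
        spacing, origin = _check_affine(affine, path)
        return VolumeImage(data, spacing, origin)
    if _has_suffix(path, _META_SUFFIXES):
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:
            raise VolumeFormatError(f"{path}: cannot parse MetaImage ({exc})") from exc
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
        return VolumeImage(data, img.GetSpacing(), img.GetOrigin())
    raise VolumeFormatError(f"{path}: unsupported volume format")


def _affine_of(volume: VolumeImage) -> np.ndarray:
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    return affine


def write_volume(volume: VolumeImage, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _has_suffix(path, _NIFTI_SUFFIXES):
        img = nib.Nifti1Image(np.asarray(volume.intensities), _affine_of(volume))
        img.header.set_zooms(volume.spacing)
        nib.save(img, path)
        return path
    if _has_suffix(path, _META_SUFFIXES):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(
            np.ascontiguousarray(np.asarray(volume.intensities).transpose(2, 1, 0))
        )
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        sitk.WriteImage(img, str(path))
        return path
    raise VolumeFormatError(f"{path}: unsupported volume format")


def write_field(field: DisplacementField, path: Path | str) -> Path:
    """Write a displacement field as a 4-component NIfTI (voxel units).

    A JSON sidecar (same stem, ``.json``) records the units and the
    direction contract.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(field.spacing) + [1.0])
    affine[:3, 3] = field.origin
    img = nib.Nifti1Image(field.vectors.astype(np.float32), affine)
    nib.save(img, path)
    sidecar = {
        "units": "voxels",
        "grid": "moving (end-diastolic) volume grid",
        "direction": "material point at ED voxel position q maps to ES position q + u(q)",
        "axes": ["x=RL", "y=AP", "z=SI"],
    }
    sidecar_path = path.with_name(path.name.split(".")[0] + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_field(path: Path | str) -> DisplacementField:
    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:
        raise VolumeFormatError(f"{path}: cannot parse field NIfTI ({exc})") from exc
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector convention (x,y,z,1,3)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[3] != 3:
        raise VolumeFormatError(f"{path}: expected a 3-component field, got {data.shape}")
    spacing, origin = _check_affine(img.affine, path)
    return DisplacementField(data, spacing, origin)


def write_true_field(ground_truth, path: Path | str) -> Path:
    """Write a phantom's analytic displacement field (converted to voxel units)."""
    spec = ground_truth.spec
    vectors_vox = ground_truth.field_mm() / np.asarray(spec.spacing)
    return write_field(DisplacementField(vectors_vox, spec.spacing), path)


# -- point sets and landmarks -------------------------------------------------


def write_point_sets(structures: list[StructurePointSet], path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "frame": "patient",
        "units": "mm",
        "structures": [
            {"name": s.name, "role": s.role, "points": np.asarray(s.points).tolist()}
            for s in structures
        ],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_point_sets(path: Path | str) -> list[StructurePointSet]:
    path = Path(path)
    payload = json.loads(path.read_text())
    if payload.get("frame") != "patient":
        raise VolumeFormatError(f"{path}: expected a patient-frame point-set file")
    return [
        StructurePointSet(s["name"], np.asarray(s["points"], dtype=float), role=s.get("role", "myocardium"))
        for s in payload["structures"]
    ]


def write_landmarks(landmarks: Landmarks, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "units": "mm",
        "apex": landmarks.apex.tolist(),
        "base_center": landmarks.base_center.tolist(),
        "rv_insertion": landmarks.rv_insertion.tolist(),
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_landmarks(path: Path | str) -> Landmarks:
    payload = json.loads(Path(path).read_text())
    return Landmarks(
        apex=np.asarray(payload["apex"], dtype=float),
        base_center=np.asarray(payload["base_center"], dtype=float),
        rv_insertion=np.asarray(payload["rv_insertion"], dtype=float),
    )


# -- DICOM-RT (optional adapter) ---------------------------------------------

_ROLE_KEYWORDS = (("ctv", "CTV"), ("tip", "ICD_tip"), ("icd", "ICD_tip"), ("myo", "myocardium"))


def _guess_role(name: str) -> str:
    lowered = name.lower()
    for key, role in _ROLE_KEYWORDS:
        if key in lowered:
            return role
    return "myocardium"


def ingest_rtss(
    path: Path | str, role_map: dict[str, str] | None = None
) -> list[StructurePointSet]:
    """Extract contour point clouds from a DICOM-RT Structure Set file.

    Contour points are concatenated over all contours of each structure, in
    patient mm.  Structures with no contour data are skipped with a warning.
    ``role_map`` optionally maps structure names to roles; otherwise a
    keyword heuristic is applied.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    if not hasattr(ds, "StructureSetROISequence"):
        raise VolumeFormatError(f"{path}: not a DICOM-RT Structure Set")
    names = {int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence}
    out: list[StructurePointSet] = []
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        number = int(roi_contour.ReferencedROINumber)
        name = names.get(number, f"ROI_{number}")
        contours = getattr(roi_contour, "ContourSequence", None)
        if not contours:
            warnings.warn(f"structure {name!r} has no contour data; skipped")
            continue
        points = np.concatenate(
            [np.asarray(c.ContourData, dtype=float).reshape(-1, 3) for c in contours]
        )
        role = (role_map or {}).get(name, _guess_role(name))
        out.append(StructurePointSet(name, points, role=role))
    return out
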