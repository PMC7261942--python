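"""NIfTI input/output and directory-layout conventions.

Layout: ``<root>/<patient_id>/<modality token>.nii.gz`` for sequences, with
mask files written wherever the caller points. Arrays are stored with axis
order (slice, row, col); the NIfTI pixdims record (slice_spacing,
in_plane_spacing, in_plane_spacing) in the same axis order, so a round trip
preserves both values and geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .types import (
    GeometryMismatchError,
    LesionClass,
    LesionMask,
    Modality,
    PatientStudy,
    SequenceVolume,
)

_EXTS = (".nii.gz", ".nii")


def _affine(in_plane: float, slice_sp: float) -> np.ndarray:
    return np.diag([slice_sp, in_plane, in_plane, 1.0])


def _find_file(patient_dir: Path, token: str) -> Path | None:
    for ext in _EXTS:
        p = patient_dir / f"{token}{ext}"
        if p.exists():
            return p
    return None


def _load(path: Path) -> tuple[np.ndarray, float, float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    slice_sp, in_plane = float(zooms[0]), float(zooms[1])
    return data, in_plane, slice_sp


def write_volume(volume: SequenceVolume, path: str | Path) -> Path:
    """Write one sequence volume as NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(
        volume.data.astype(np.float32),
        _affine(volume.in_plane_spacing, volume.slice_spacing),
    )
    img.header.set_zooms(
        (volume.slice_spacing, volume.in_plane_spacing, volume.in_plane_spacing)
    )
    nib.save(img, str(path))
    return path


def write_mask(mask: LesionMask, path: str | Path) -> Path:
    """Write a binary lesion mask as NIfTI; round-trips voxel-for-voxel."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(
        mask.values.astype(np.uint8),
        _affine(mask.in_plane_spacing, mask.slice_spacing),
    )
    img.header.set_zooms(
        (mask.slice_spacing, mask.in_plane_spacing, mask.in_plane_spacing)
    )
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, lesion_class: LesionClass) -> LesionMask:
    data, in_plane, slice_sp = _load(Path(path))
    return LesionMask(
        lesion_class=lesion_class,
        values=(data > 0.5).astype(np.uint8),
        in_plane_spacing=in_plane,
        slice_spacing=slice_sp,
    )


def read_study(root_path: str | Path, patient_id: str) -> PatientStudy:
    """Assemble a :class:`PatientStudy` from ``<root>/<patient_id>/``.

    Discovers every modality file present; raises ``FileNotFoundError`` if the
    directory is missing or holds no sequences, and
    :class:`GeometryMismatchError` if the discovered grids disagree.
    """
    patient_dir = Path(root_path) / patient_id
    if not patient_dir.is_dir():
        raise FileNotFoundError(f"no patient directory {patient_dir}")
    volumes: dict[Modality, SequenceVolume] = {}
    for modality in Modality:
        p = _find_file(patient_dir, modality.value)
        if p is None:
            continue
        data, in_plane, slice_sp = _load(p)
        volumes[modality] = SequenceVolume(
            modality=modality,
            data=data,
            in_plane_spacing=in_plane,
            slice_spacing=slice_sp,
        )
    if not volumes:
        raise FileNotFoundError(f"no sequence files under {patient_dir}")
    shapes = {v.shape for v in volumes.values()}
    if len(shapes) > 1:
        raise GeometryMismatchError(
            f"patient {patient_id!r}: sequence grids disagree: {sorted(shapes)}"
        )
    return PatientStudy(patient_id=patient_id, volumes=volumes)


def write_study(study: PatientStudy, root_path: str | Path) -> Path:
    patient_dir = Path(root_path) / study.patient_id
    for modality, vol in study.volumes.items():
        write_volume(vol, patient_dir / f"{modality.value}.nii.gz")
    return patient_dir


def list_patients(root_path: str | Path) -> list[str]:
    root = Path(root_path)
    if not root.is_dir():
        raise FileNotFoundError(f"no cohort directory {root}")
    return sorted(p.name for p in root.iterdir() if p.is_dir())


def save_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))
    return path


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
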