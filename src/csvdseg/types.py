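"""Core domain types shared across the package.

All voxel grids use 0-based indices in ``(slice, row, col)`` order. A patient's
sequences are assumed co-registered: every volume and mask of one study lives
on a single shared grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Modality(str, Enum):
    """MRI contrast. The value doubles as the on-disk file-name token."""

    T1 = "t1"
    T2FLAIR = "flair"
    DWI_B1000 = "dwi"
    T2STAR = "t2star"


class LesionClass(str, Enum):
    """The four small-vessel-disease lesion types segmented by the system."""

    LACUNE = "lacune"
    WMH = "wmh"
    INFARCT = "infarct"
    MICROBLEED = "microbleed"


class GeometryMismatchError(ValueError):
    """Raised when grids that must be co-registered differ in shape."""


class RoutingError(ValueError):
    """Raised when a study lacks a modality required by a segmentor."""


@dataclass
class SequenceVolume:
    """One MRI contrast for one patient.

    Parameters
    ----------
    modality
        Which contrast this volume holds.
    data
        Non-negative intensities, shape ``(slices, rows, cols)``.
    in_plane_spacing
        Millimetres per pixel along row and col (isotropic in-plane).
    slice_spacing
        Millimetres between consecutive slices.
    """

    modality: Modality
    data: np.ndarray
    in_plane_spacing: float
    slice_spacing: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got ndim={self.data.ndim}")
        if self.in_plane_spacing <= 0 or self.slice_spacing <= 0:
            raise ValueError("spacings must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass
class LesionMask:
    """Binary 3D mask for one lesion class, aligned to the study grid."""

    lesion_class: LesionClass
    values: np.ndarray
    in_plane_spacing: float
    slice_spacing: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D mask, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary (0/1)")
        self.values = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)

    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class PatientStudy:
    """A patient identifier plus the available co-registered sequences."""

    patient_id: str
    volumes: dict[Modality, SequenceVolume] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.volumes:
            raise ValueError("a study needs at least one sequence")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) > 1:
            raise GeometryMismatchError(
                f"sequences of patient {self.patient_id!r} disagree on grid "
                f"shape: {sorted(shapes)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.volumes.values())).shape

    def require(self, modalities) -> None:
        """Raise :class:`RoutingError` naming any missing modality."""
        missing = [m for m in modalities if m not in self.volumes]
        if missing:
            names = ", ".join(m.name for m in missing)
            raise RoutingError(f"study {self.patient_id!r} lacks modality: {names}")
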