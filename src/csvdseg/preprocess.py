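"""Slice standardization: square padding, resizing, white-matter normalization.

Every slice fed to a segmentor goes through the same three steps: zero-pad to
square, resize to the network's input edge, and (volume-wise, beforehand)
rescale intensities so the white-matter histogram peak sits at a fixed
reference value. The peak alignment is multiplicative only, which keeps the
zero background at zero and makes the map invariant under any global positive
rescaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from skimage.filters import threshold_otsu
from skimage.transform import resize as _sk_resize

from .types import Modality, SequenceVolume


class ResizeMode(str, Enum):
    INTENSITY = "intensity"  # bilinear
    MASK = "mask"  # nearest-neighbour, stays binary


class DegenerateVolumeError(ValueError):
    """Volume has no usable above-background content."""


@dataclass
class PreprocessSpec:
    """Parameters of the standardization pipeline.

    target_size
        Square edge (pixels) of the network input; must be divisible by
        2**depth of the paired network.
    wm_reference_value
        Intensity the white-matter peak is mapped to.
    histogram_bins
        Bin count for peak detection over the above-background range.
    background_threshold
        Voxels at or below this raw intensity are excluded from the histogram.
    """

    target_size: int = 256
    wm_reference_value: float = 1.0
    histogram_bins: int = 256
    background_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.target_size < 1:
            raise ValueError("target_size must be positive")
        if self.wm_reference_value <= 0:
            raise ValueError("wm_reference_value must be positive")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be at least 2")
        if self.background_threshold < 0:
            raise ValueError("background_threshold must be non-negative")


def pad_to_square(slice2d: np.ndarray) -> np.ndarray:
    """Zero-pad a 2D slice to a centred square of edge max(rows, cols)."""
    a = np.asarray(slice2d)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("expected a non-empty 2D slice")
    r, c = a.shape
    edge = max(r, c)
    out = np.zeros((edge, edge), dtype=a.dtype)
    r0 = (edge - r) // 2
    c0 = (edge - c) // 2
    out[r0 : r0 + r, c0 : c0 + c] = a
    return out


def crop_from_square(square: np.ndarray, orig_shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`pad_to_square` for the given original shape."""
    a = np.asarray(square)
    r, c = orig_shape
    edge = a.shape[0]
    r0 = (edge - r) // 2
    c0 = (edge - c) // 2
    return a[r0 : r0 + r, c0 : c0 + c]


def resize(slice2d: np.ndarray, target: int, mode: ResizeMode) -> np.ndarray:
    """Resize a square slice to ``target``×``target``.

    INTENSITY uses bilinear interpolation; MASK uses nearest-neighbour so the
    output stays binary. Resizing to the current size is the exact identity.
    """
    a = np.asarray(slice2d)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"resize expects a square slice, got {a.shape}")
    if a.shape[0] == target:
        return a.copy()
    if mode is ResizeMode.INTENSITY:
        return _sk_resize(
            a.astype(np.float64), (target, target), order=1,
            anti_aliasing=False, preserve_range=True,
        )
    out = _sk_resize(
        a.astype(np.float64), (target, target), order=0,
        anti_aliasing=False, preserve_range=True,
    )
    return (out > 0.5).astype(a.dtype)


def detect_wm_peak(
    data: np.ndarray,
    modality: Modality,
    spec: PreprocessSpec,
    tissue_hint: np.ndarray | None = None,
) -> float:
    """Locate the white-matter intensity peak of one volume.

    With a tissue hint the peak is the histogram mode inside the hinted
    voxels. Without one, the rule depends on contrast: on T1 and DWI white
    matter is bright, so the peak is the tallest bin in the upper half of the
    above-background range; on FLAIR and T2* the peak is the mode of the
    tissue lobe, separated from the dark background/CSF lobe by Otsu's
    threshold. Both rules are equivariant under global positive rescaling.
    """
    fg = data > spec.background_threshold
    if tissue_hint is not None:
        fg = fg & tissue_hint.astype(bool)
    vals = data[fg]
    if vals.size == 0:
        raise DegenerateVolumeError("no voxels above background threshold")
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= 0 or hi == lo:
        raise DegenerateVolumeError("degenerate intensity range")
    counts, edges = np.histogram(vals, bins=spec.histogram_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if tissue_hint is not None:
        sel = np.ones_like(centers, dtype=bool)
    elif modality in (Modality.T1, Modality.DWI_B1000):
        sel = centers >= (lo + hi) / 2
    else:
        cut = threshold_otsu(vals, nbins=spec.histogram_bins)
        sel = centers >= cut
        if not sel.any():
            sel = np.ones_like(centers, dtype=bool)
    idx = np.flatnonzero(sel)[np.argmax(counts[sel])]
    peak = float(centers[idx])
    # parabolic refinement over the argmax bin and its neighbours: stabilizes
    # the estimate against count jitter without leaving the winning bin
    if 0 < idx < len(counts) - 1:
        c0, c1, c2 = counts[idx - 1 : idx + 2].astype(np.float64)
        denom = c0 - 2 * c1 + c2
        if denom < 0:
            shift = 0.5 * (c0 - c2) / denom
            width = float(edges[1] - edges[0])
            peak += float(np.clip(shift, -0.5, 0.5)) * width
    if peak <= 0:
        raise DegenerateVolumeError("detected white-matter peak is non-positive")
    return peak


def normalize_wm(
    volume: SequenceVolume,
    spec: PreprocessSpec,
    tissue_hint: np.ndarray | None = None,
) -> SequenceVolume:
    """Rescale a volume so its white-matter peak equals the reference value.

    Purely multiplicative: ``out = in * (wm_reference_value / peak)``. The
    detected peak of the output equals the reference within one histogram
    bin, and the map is invariant under ``in -> c * in`` for any c > 0.
    """
    peak = detect_wm_peak(volume.data, volume.modality, spec, tissue_hint)
    scaled = volume.data * (spec.wm_reference_value / peak)
    return SequenceVolume(
        modality=volume.modality,
        data=scaled,
        in_plane_spacing=volume.in_plane_spacing,
        slice_spacing=volume.slice_spacing,
    )
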