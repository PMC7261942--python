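"""Mask combination: voxel-level mutual exclusivity of the final output.

WMH, lacune and subcortical infarct can look alike on T2-FLAIR, so the four
raw segmentor outputs are reconciled by subtraction in a fixed order before
anything is reported:

1. WMH := WMH minus infarct
2. WMH := WMH minus lacune (the *raw* lacune mask)
3. lacune := lacune minus infarct

Microbleeds are never touched. After combination WMH, lacune and infarct are
pairwise disjoint at the voxel level; at the image or patient level the
output remains multi-label (a patient can carry several diseases at once).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import GeometryMismatchError, LesionClass, LesionMask


@dataclass
class CombinedPrediction:
    """Post-combination masks plus per-class provenance (raw vs combined)."""

    masks: dict[LesionClass, LesionMask]
    provenance: dict[LesionClass, str]

    def present_classes(self) -> list[LesionClass]:
        """Classes with at least one positive voxel after combination."""
        return [cls for cls, m in self.masks.items() if m.count() > 0]


def _check_grids(masks: dict[LesionClass, LesionMask]) -> None:
    shapes = {m.shape for m in masks.values()}
    if len(shapes) > 1:
        raise GeometryMismatchError(f"mask grids disagree: {sorted(shapes)}")


def combine_masks(
    lacune: LesionMask,
    wmh: LesionMask,
    infarct: LesionMask,
    microbleed: LesionMask,
    subtract_raw_lacune: bool = True,
) -> CombinedPrediction:
    """Apply the exclusivity subtractions in their fixed order.

    ``subtract_raw_lacune`` controls which lacune mask is removed from WMH:
    the raw one (default, matching the stated order in which lacune is
    cleaned only after it has been used) or the infarct-cleaned one.
    """
    masks = {
        LesionClass.LACUNE: lacune,
        LesionClass.WMH: wmh,
        LesionClass.INFARCT: infarct,
        LesionClass.MICROBLEED: microbleed,
    }
    _check_grids(masks)
    inf = infarct.values.astype(bool)
    lac_raw = lacune.values.astype(bool)
    lac_clean = lac_raw & ~inf
    wmh_sub = lac_raw if subtract_raw_lacune else lac_clean
    wmh_new = wmh.values.astype(bool) & ~inf & ~wmh_sub

    def _mask(cls: LesionClass, values: np.ndarray, ref: LesionMask) -> LesionMask:
        return LesionMask(
            lesion_class=cls,
            values=values.astype(np.uint8),
            in_plane_spacing=ref.in_plane_spacing,
            slice_spacing=ref.slice_spacing,
        )

    return CombinedPrediction(
        masks={
            LesionClass.LACUNE: _mask(LesionClass.LACUNE, lac_clean, lacune),
            LesionClass.WMH: _mask(LesionClass.WMH, wmh_new, wmh),
            LesionClass.INFARCT: _mask(
                LesionClass.INFARCT, inf, infarct
            ),
            LesionClass.MICROBLEED: _mask(
                LesionClass.MICROBLEED,
                microbleed.values.astype(bool),
                microbleed,
            ),
        },
        provenance={
            LesionClass.LACUNE: "combined",
            LesionClass.WMH: "combined",
            LesionClass.INFARCT: "raw",
            LesionClass.MICROBLEED: "raw",
        },
    )


def finalize_patient(
    raw_masks: dict[LesionClass, LesionMask],
    subtract_raw_lacune: bool = True,
) -> tuple[CombinedPrediction, list[str]]:
    """Combine a patient's raw masks and summarize the patient-level labels.

    Returns the combined prediction plus the multi-label summary: the names
    of the classes with at least one positive voxel after combination.
    """
    missing = [cls for cls in LesionClass if cls not in raw_masks]
    if missing:
        raise ValueError(
            "masks required for all four classes (empty allowed); missing: "
            + ", ".join(cls.name for cls in missing)
        )
    combined = combine_masks(
        lacune=raw_masks[LesionClass.LACUNE],
        wmh=raw_masks[LesionClass.WMH],
        infarct=raw_masks[LesionClass.INFARCT],
        microbleed=raw_masks[LesionClass.MICROBLEED],
        subtract_raw_lacune=subtract_raw_lacune,
    )
    summary = [cls.name for cls in combined.present_classes()]
    return combined, summary
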