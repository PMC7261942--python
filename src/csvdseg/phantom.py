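"""Synthetic multi-sequence brain phantoms with ground-truth lesion masks.

The generator emulates the statistical structure of a multi-centre CSVD MRI
cohort rather than its anatomy: a three-compartment ellipsoidal brain (white
matter core, grey matter shell, CSF ventricles) rendered in four contrasts
(T1, T2-FLAIR, DWI b1000, T2*-GRE), with lesions of the four small-vessel
disease classes painted in at their characteristic contrast direction per
sequence and with their characteristic diameter range:

* lacune        — 3–15 mm, CSF-like hypointense on T1
* WMH           — variable extent, hyperintense on T2-FLAIR
* subcortical infarct — ≤20 mm, hyperintense on DWI and FLAIR, dark on T1
* microbleed    — 2–10 mm, hypointense on T2*-GRE

In-plane pixel spacing is drawn from 0.36–1.44 mm and slice spacing from
6–8 mm, matching thick-slice clinical acquisitions. Intensity units are
arbitrary; only ordering relations between compartments are contractual.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np

from .types import LesionClass, LesionMask, Modality, PatientStudy, SequenceVolume


class Tissue(IntEnum):
    BACKGROUND = 0
    WM = 1
    GM = 2
    CSF = 3


class ContrastDirection(str, Enum):
    DOWN = "down"
    NEUTRAL = "neutral"
    UP = "up"


class PlacementError(RuntimeError):
    """Lesion placement failed after bounded retries."""


class ConfigurationError(ValueError):
    """Invalid phantom configuration."""


#: Base compartment intensities per modality (arbitrary units). White matter
#: is the largest compartment, so its intensity is the dominant histogram
#: lobe in every contrast — the property the WM-peak normalizer relies on.
TISSUE_INTENSITY: dict[Modality, dict[Tissue, float]] = {
    Modality.T1: {Tissue.WM: 300.0, Tissue.GM: 220.0, Tissue.CSF: 60.0},
    Modality.T2FLAIR: {Tissue.WM: 200.0, Tissue.GM: 250.0, Tissue.CSF: 40.0},
    Modality.DWI_B1000: {Tissue.WM: 200.0, Tissue.GM: 170.0, Tissue.CSF: 60.0},
    Modality.T2STAR: {Tissue.WM: 200.0, Tissue.GM: 230.0, Tissue.CSF: 170.0},
}

_D, _N, _U = ContrastDirection.DOWN, ContrastDirection.NEUTRAL, ContrastDirection.UP

#: Default contrast direction of each lesion class on each sequence. Entries
#: that are ambiguous in clinical reading ("dark or isointense") are resolved
#: to one deterministic default; alternatives can be configured.
DEFAULT_CONTRAST: dict[tuple[LesionClass, Modality], ContrastDirection] = {
    (LesionClass.LACUNE, Modality.T1): _D,
    (LesionClass.LACUNE, Modality.T2FLAIR): _N,
    (LesionClass.LACUNE, Modality.DWI_B1000): _N,
    (LesionClass.LACUNE, Modality.T2STAR): _N,
    (LesionClass.WMH, Modality.T1): _N,
    (LesionClass.WMH, Modality.T2FLAIR): _U,
    (LesionClass.WMH, Modality.DWI_B1000): _N,
    (LesionClass.WMH, Modality.T2STAR): _N,
    (LesionClass.INFARCT, Modality.T1): _D,
    (LesionClass.INFARCT, Modality.T2FLAIR): _U,
    (LesionClass.INFARCT, Modality.DWI_B1000): _U,
    (LesionClass.INFARCT, Modality.T2STAR): _N,
    (LesionClass.MICROBLEED, Modality.T1): _N,
    (LesionClass.MICROBLEED, Modality.T2FLAIR): _N,
    (LesionClass.MICROBLEED, Modality.DWI_B1000): _N,
    (LesionClass.MICROBLEED, Modality.T2STAR): _D,
}

#: Lesion diameter ranges in millimetres (max in-plane extent). WMH extent is
#: "variable" and therefore unconstrained (None); the infarct range has an
#: effective 2 mm floor so every lesion is at least a visible blob.
DEFAULT_DIAMETERS_MM: dict[LesionClass, tuple[float, float] | None] = {
    LesionClass.LACUNE: (3.0, 15.0),
    LesionClass.INFARCT: (2.0, 20.0),
    LesionClass.MICROBLEED: (2.0, 10.0),
    LesionClass.WMH: None,
}

#: Positive-case fraction per class in the training cohort being emulated.
DEFAULT_POSITIVE_FRACTIONS: dict[LesionClass, float] = {
    LesionClass.LACUNE: 0.983,
    LesionClass.WMH: 0.983,
    LesionClass.INFARCT: 0.8515,
    LesionClass.MICROBLEED: 0.4178,
}

# Intensity of a lesion voxel relative to the white-matter base.
_DOWN_FACTOR = 0.45
_UP_FACTOR = 1.6

# Rendering order: confluent WMH first so that focal lesions overwrite it
# where masks overlap.
_RENDER_ORDER = (
    LesionClass.WMH,
    LesionClass.INFARCT,
    LesionClass.LACUNE,
    LesionClass.MICROBLEED,
)


def _default_counts() -> dict[LesionClass, tuple[int, int]]:
    return {cls: (1, 3) for cls in LesionClass}


@dataclass
class PhantomConfig:
    """Parameters of the synthetic cohort.

    ``lesion_counts`` maps each class to an inclusive ``(min, max)`` range for
    the number of lesions of that class per positive patient.
    """

    grid_shape: tuple[int, int, int] = (10, 96, 96)
    in_plane_spacing_range: tuple[float, float] = (0.7, 1.2)
    slice_spacing_range: tuple[float, float] = (6.0, 8.0)
    lesion_counts: dict[LesionClass, tuple[int, int]] = field(
        default_factory=_default_counts
    )
    diameter_ranges_mm: dict[LesionClass, tuple[float, float] | None] = field(
        default_factory=lambda: dict(DEFAULT_DIAMETERS_MM)
    )
    contrast_table: dict[tuple[LesionClass, Modality], ContrastDirection] = field(
        default_factory=lambda: dict(DEFAULT_CONTRAST)
    )
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.in_plane_spacing_range
        if not (0.36 <= lo <= hi <= 1.44):
            raise ConfigurationError(
                "in-plane spacing range must lie within [0.36, 1.44] mm"
            )
        lo, hi = self.slice_spacing_range
        if not (6.0 <= lo <= hi <= 8.0):
            raise ConfigurationError("slice spacing range must lie within [6, 8] mm")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")

    def replace(self, **kw) -> "PhantomConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Reference lesion masks plus the tissue label map they live in.

    ``tissue_map`` is None for truths reloaded from disk, where only the
    masks were persisted.
    """

    masks: dict[LesionClass, LesionMask]
    tissue_map: np.ndarray | None = None


def make_tissue_map(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Three-compartment ellipsoidal brain on the given grid.

    Outer ellipsoid is brain; its outer 12% radial shell is grey matter, the
    interior is white matter, and two small para-central ellipsoids are CSF
    ventricles. White matter is by far the largest compartment, which is what
    anchors histogram-peak normalization.
    """
    ns, nr, nc = grid_shape
    s, r, c = np.meshgrid(
        np.linspace(-1, 1, ns), np.linspace(-1, 1, nr), np.linspace(-1, 1, nc),
        indexing="ij",
    )
    # brain occupies ~90% of the grid in every direction
    rho2 = (s / 0.92) ** 2 + (r / 0.9) ** 2 + (c / 0.9) ** 2
    tissue = np.full(grid_shape, Tissue.BACKGROUND, dtype=np.uint8)
    tissue[rho2 <= 1.0] = Tissue.GM
    tissue[rho2 <= 0.88**2] = Tissue.WM
    for dc in (-0.2, 0.2):
        vent = (s / 0.4) ** 2 + (r / 0.25) ** 2 + ((c - dc) / 0.08) ** 2
        tissue[vent <= 1.0] = Tissue.CSF
    return tissue


def _pixel_span_bounds(
    lo: float, hi: float, spacing: float
) -> tuple[int, int]:
    """Integer pixel spans whose physical size (span × spacing) is in [lo, hi]."""
    n_min = max(1, int(np.ceil(lo / spacing - 1e-9)))
    n_max = int(np.floor(hi / spacing + 1e-9))
    if n_max < n_min:
        raise ConfigurationError(
            f"diameter range [{lo}, {hi}] mm unreachable at spacing {spacing} mm"
        )
    return n_min, n_max


def _ellipse_patch(span_major: int, span_minor: int) -> np.ndarray:
    """Boolean 2D patch: an ellipse spanning exactly ``span_major`` pixels
    along axis 0 and at most ``span_minor`` along axis 1."""
    ra = (span_major - 1) / 2 + 0.3
    rb = (span_minor - 1) / 2 + 0.3
    da = np.arange(span_major) - (span_major - 1) / 2
    db = np.arange(span_minor) - (span_minor - 1) / 2
    patch = (da[:, None] / ra) ** 2 + (db[None, :] / rb) ** 2 <= 1.0
    # force the spine so the major-axis span is exact even for thin patches
    patch[:, (span_minor - 1) // 2] = True
    if span_minor % 2 == 0:
        patch[:, span_minor // 2] = True
    return patch


def lesion_diameter_mm(footprint: np.ndarray, in_plane_spacing: float) -> float:
    """Diameter of a lesion: maximum in-plane bounding-box extent × spacing.

    ``footprint`` is an ``(n, 3)`` integer array of (slice, row, col) indices.
    """
    fp = np.asarray(footprint)
    if fp.size == 0:
        return 0.0
    rows = fp[:, 1].max() - fp[:, 1].min() + 1
    cols = fp[:, 2].max() - fp[:, 2].min() + 1
    return float(max(rows, cols) * in_plane_spacing)


def sample_lesion_geometry(
    lesion_class: LesionClass,
    rng: np.random.Generator,
    config: PhantomConfig,
    in_plane_spacing: float,
) -> np.ndarray:
    """Sample one lesion footprint centred at the origin.

    Returns an ``(n, 3)`` integer array of (slice, row, col) offsets. Focal
    classes (lacune, infarct, microbleed) are single ellipsoidal blobs whose
    max in-plane extent × spacing lies inside the configured diameter range;
    WMH is an irregular union of overlapping blobs with no diameter bound.
    """
    if lesion_class is LesionClass.WMH:
        return _sample_wmh_footprint(rng, config)
    drange = config.diameter_ranges_mm.get(lesion_class)
    if drange is None:
        raise ConfigurationError(f"{lesion_class} has no configured diameter range")
    lo, hi = drange
    if not (0 < lo <= hi):
        raise ConfigurationError(f"empty diameter range for {lesion_class}")
    n_min, n_max = _pixel_span_bounds(lo, hi, in_plane_spacing)
    target = rng.uniform(lo, hi)
    span = int(np.clip(round(target / in_plane_spacing), n_min, n_max))
    minor = int(rng.integers(max(1, int(np.ceil(0.6 * span))), span + 1))
    patch = _ellipse_patch(span, minor)
    if rng.random() < 0.5:
        patch = patch.T
    coords2d = np.argwhere(patch)
    coords2d -= (np.array(patch.shape) - 1) // 2
    # thick slices: lesions live on one slice; infarcts may reach a second
    slices = [0]
    if lesion_class is LesionClass.INFARCT and rng.random() < 0.3:
        slices.append(1 if rng.random() < 0.5 else -1)
    out = []
    for k, s in enumerate(slices):
        sub = coords2d if k == 0 else coords2d[:: 2]
        out.append(
            np.column_stack([np.full(len(sub), s), sub[:, 0], sub[:, 1]])
        )
    return np.vstack(out)


def _sample_wmh_footprint(
    rng: np.random.Generator, config: PhantomConfig
) -> np.ndarray:
    """Irregular confluent footprint: union of 2–4 overlapping ellipses."""
    _, nr, nc = config.grid_shape
    cap = max(4, min(nr, nc) // 4)
    n_blobs = int(rng.integers(2, 5))
    voxels: set[tuple[int, int, int]] = set()
    centre = np.zeros(2)
    for _ in range(n_blobs):
        span = int(rng.integers(3, cap + 1))
        minor = int(rng.integers(max(2, span // 2), span + 1))
        patch = _ellipse_patch(span, minor)
        if rng.random() < 0.5:
            patch = patch.T
        coords = np.argwhere(patch) - (np.array(patch.shape) - 1) // 2
        offset = centre + rng.integers(-2, 3, size=2)
        s = 0 if rng.random() < 0.7 else int(rng.integers(-1, 2))
        for dr, dc in coords:
            voxels.add((s, int(dr + offset[0]), int(dc + offset[1])))
        centre = offset
    return np.array(sorted(voxels), dtype=np.int64)


def _place_footprint(
    footprint: np.ndarray,
    tissue: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 60,
) -> np.ndarray:
    """Shift a centred footprint into the brain.

    Strictly-inside-white-matter placements are tried first; if none is
    found (small grids, large lesions) any all-brain placement centred on a
    white-matter voxel is accepted. Failing both is a placement error.
    """
    wm = np.argwhere(tissue == Tissue.WM)
    if len(wm) == 0:
        raise PlacementError("tissue map contains no white matter")
    shape = np.array(tissue.shape)
    for attempt in range(2 * max_tries):
        centre = wm[rng.integers(len(wm))]
        cand = footprint + centre
        if (cand < 0).any() or (cand >= shape).any():
            continue
        values = tissue[cand[:, 0], cand[:, 1], cand[:, 2]]
        if np.all(values == Tissue.WM):
            return cand
        if attempt >= max_tries and np.all(values != Tissue.BACKGROUND):
            return cand
    raise PlacementError(
        "could not place lesion inside the brain after bounded retries; "
        "brain too small for the requested diameter"
    )


def generate_study(
    config: PhantomConfig, patient_id: str = "phantom"
) -> tuple[PatientStudy, GroundTruth]:
    """Render one co-registered four-sequence study plus ground truth.

    Deterministic for a fixed ``config.seed``. Each lesion shows the
    configured contrast direction against surrounding white matter: DOWN
    strictly darker, UP strictly brighter, NEUTRAL within the noise.
    """
    rng = np.random.default_rng(config.seed)
    in_plane = float(rng.uniform(*config.in_plane_spacing_range))
    slice_sp = float(rng.uniform(*config.slice_spacing_range))
    tissue = make_tissue_map(config.grid_shape)

    masks: dict[LesionClass, np.ndarray] = {
        cls: np.zeros(config.grid_shape, dtype=np.uint8) for cls in LesionClass
    }
    for cls in _RENDER_ORDER:
        lo, hi = config.lesion_counts.get(cls, (0, 0))
        for _ in range(int(rng.integers(lo, hi + 1))):
            # a freshly sampled geometry (likely smaller) gets a few chances
            # before placement is declared impossible
            placed = None
            for _round in range(4):
                fp = sample_lesion_geometry(cls, rng, config, in_plane)
                try:
                    placed = _place_footprint(fp, tissue, rng)
                    break
                except PlacementError:
                    continue
            if placed is None:
                raise PlacementError(
                    f"could not place a {cls.value} lesion; brain too small "
                    "for the configured diameter range"
                )
            masks[cls][placed[:, 0], placed[:, 1], placed[:, 2]] = 1

    volumes: dict[Modality, SequenceVolume] = {}
    for modality in Modality:
        base = TISSUE_INTENSITY[modality]
        img = np.zeros(config.grid_shape, dtype=np.float64)
        for t in (Tissue.WM, Tissue.GM, Tissue.CSF):
            img[tissue == t] = base[t]
        wm_val = base[Tissue.WM]
        for cls in _RENDER_ORDER:
            sel = masks[cls].astype(bool)
            if not sel.any():
                continue
            direction = config.contrast_table[(cls, modality)]
            if direction is ContrastDirection.NEUTRAL:
                # isointense: the lesion leaves this sequence's signal as-is
                # (including any earlier-rendered lesion it overlaps)
                continue
            if direction is ContrastDirection.UP:
                val = wm_val * _UP_FACTOR
            elif cls is LesionClass.LACUNE and modality is Modality.T1:
                val = base[Tissue.CSF]  # CSF-like cavity
            else:
                val = wm_val * _DOWN_FACTOR
            img[sel] = val
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        np.clip(img, 0.0, None, out=img)
        volumes[modality] = SequenceVolume(
            modality=modality,
            data=img,
            in_plane_spacing=in_plane,
            slice_spacing=slice_sp,
        )

    truth = GroundTruth(
        masks={
            cls: LesionMask(
                lesion_class=cls,
                values=masks[cls],
                in_plane_spacing=in_plane,
                slice_spacing=slice_sp,
            )
            for cls in LesionClass
        },
        tissue_map=tissue,
    )
    return PatientStudy(patient_id=patient_id, volumes=volumes), truth


def generate_cohort(
    config: PhantomConfig,
    n_patients: int,
    positive_fractions: dict[LesionClass, float] | None = None,
) -> list[tuple[PatientStudy, GroundTruth]]:
    """Generate a cohort; each class is positive with its configured fraction.

    Negative patients for a class simply have that class's lesion count forced
    to zero, so their mask is empty. Realized positive fractions follow the
    binomial law around the requested ones.
    """
    if n_patients < 0:
        raise ConfigurationError("n_patients must be non-negative")
    if positive_fractions is None:
        positive_fractions = dict(DEFAULT_POSITIVE_FRACTIONS)
    for cls, f in positive_fractions.items():
        if not (0.0 <= f <= 1.0):
            raise ConfigurationError(f"positive fraction for {cls} outside [0, 1]")
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=max(n_patients, 1))
    cohort = []
    for i in range(n_patients):
        counts = dict(config.lesion_counts)
        for cls in LesionClass:
            frac = positive_fractions.get(cls, 1.0)
            if master.random() >= frac:
                counts[cls] = (0, 0)
        sub = config.replace(seed=int(seeds[i]), lesion_counts=counts)
        cohort.append(generate_study(sub, patient_id=f"p{i:03d}"))
    return cohort
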