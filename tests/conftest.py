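"""Shared fixtures: small phantom cohorts and session-scoped trained models."""

from __future__ import annotations

import numpy as np
import pytest

from csvdseg.phantom import PhantomConfig, generate_cohort
from csvdseg.preprocess import PreprocessSpec
from csvdseg.segmentor import Loss, SegmentorSpec, train_segmentor
from csvdseg.types import LesionClass

# Desk-scale study conditions for the segmentation-recovery experiment:
# 64×64 in-plane grids (so slices feed the nets without resampling), strong
# lesion contrast, low noise, 24 training + 6 held-out patients → ~192
# training slices per class.
RECOVERY_GRID = (8, 64, 64)
RECOVERY_NOISE_SD = 2.0
RECOVERY_TRAIN_N = 24
RECOVERY_HELD_N = 6
RECOVERY_COHORT_SEED = 11
RECOVERY_HELD_SEED = 99
RECOVERY_MODEL_SEED = 5

# Focal bright/dark blobs converge quickly; confluent irregular WMH and the
# scarcer microbleed positives need longer.
RECOVERY_EPOCHS = {
    LesionClass.LACUNE: 20,
    LesionClass.INFARCT: 14,
    LesionClass.WMH: 24,
    LesionClass.MICROBLEED: 22,
}


def recovery_phantom_config(seed: int = RECOVERY_COHORT_SEED) -> PhantomConfig:
    return PhantomConfig(
        grid_shape=RECOVERY_GRID, noise_sd=RECOVERY_NOISE_SD, seed=seed
    )


def recovery_segmentor_spec(cls: LesionClass) -> SegmentorSpec:
    return SegmentorSpec(
        lesion_class=cls,
        depth=2,
        base_channels=8,
        input_size=64,
        max_epochs=RECOVERY_EPOCHS[cls],
        batch_size=8,
        learning_rate=2e-3,
        loss=Loss.SUM,
        seed=RECOVERY_MODEL_SEED,
    )


@pytest.fixture(scope="session")
def recovery_run():
    """Train one tiny U-Net per class on a phantom cohort (shared session-wide).

    Used both by the segmentation-recovery check and as the checkpoint source
    for the end-to-end pipeline test, so training happens once.
    """
    cfg = recovery_phantom_config()
    # training phantoms are all-positive so every class has enough lesion
    # slices at this cohort size; the held-out cohort keeps the emulated
    # positive fractions (evaluation sets contain class-negative patients)
    cohort = generate_cohort(
        cfg, RECOVERY_TRAIN_N, positive_fractions={c: 1.0 for c in LesionClass}
    )
    held = generate_cohort(cfg.replace(seed=RECOVERY_HELD_SEED), RECOVERY_HELD_N)
    pspec = PreprocessSpec(target_size=64)
    models = {}
    for cls in LesionClass:
        spec = recovery_segmentor_spec(cls)
        model, state = train_segmentor(spec, cohort, preprocess_spec=pspec)
        models[cls] = {"model": model, "spec": spec, "state": state}
    return {
        "cohort": cohort,
        "held": held,
        "preprocess": pspec,
        "models": models,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
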