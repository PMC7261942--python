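"""Segmentor contracts: architecture, accuracy metric, stopping, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csvdseg.phantom import PhantomConfig, generate_cohort
from csvdseg.preprocess import PreprocessSpec
from csvdseg.segmentor import (
    DEFAULT_ROUTING,
    Loss,
    SegmentorSpec,
    TrainingDataError,
    TrainState,
    build_unet,
    load_checkpoint,
    predict_volume,
    save_checkpoint,
    should_stop,
    train_segmentor,
    training_accuracy,
)
from csvdseg.types import LesionClass, Modality, RoutingError

TINY = dict(depth=2, base_channels=4, input_size=32, max_epochs=2,
            batch_size=4, learning_rate=1e-3, loss=Loss.SUM)


def _tiny_cohort(n=4, seed=0):
    # coarse pixels so every diameter range fits the 32 px grid
    cfg = PhantomConfig(
        grid_shape=(4, 32, 32), in_plane_spacing_range=(1.3, 1.44),
        noise_sd=2.0, seed=seed,
    )
    return generate_cohort(cfg, n, positive_fractions={c: 1.0 for c in LesionClass})


class TestArchitecture:
    def test_default_routing_channel_counts(self):
        assert DEFAULT_ROUTING[LesionClass.INFARCT] == (Modality.DWI_B1000,)
        assert DEFAULT_ROUTING[LesionClass.WMH] == (Modality.T2FLAIR,)
        assert DEFAULT_ROUTING[LesionClass.LACUNE] == (
            Modality.T1, Modality.T2FLAIR,
        )
        assert DEFAULT_ROUTING[LesionClass.MICROBLEED] == (Modality.T2STAR,)
        spec = SegmentorSpec(lesion_class=LesionClass.LACUNE, **TINY)
        model = build_unet(spec)
        assert model.in_channels == 2

    def test_encoder_channel_sequence_doubles(self):
        spec = SegmentorSpec(
            lesion_class=LesionClass.WMH, depth=3, base_channels=8, input_size=64
        )
        assert build_unet(spec).encoder_channels == [8, 16, 32]

    def test_output_matches_input_size(self):
        spec = SegmentorSpec(
            lesion_class=LesionClass.WMH, depth=2, base_channels=4, input_size=64
        )
        out = build_unet(spec).forward(np.zeros((1, 1, 64, 64)))
        assert out.shape == (1, 1, 64, 64)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError):
            SegmentorSpec(
                lesion_class=LesionClass.WMH, depth=4, base_channels=4,
                input_size=60,
            )


class TestTrainingAccuracy:
    def test_perfect_and_disjoint(self):
        ref = np.zeros((2, 1, 4, 4))
        ref[:, :, 1, 1] = 1
        assert training_accuracy(ref.copy(), ref, 0.5) == 1.0
        assert training_accuracy(np.zeros_like(ref), ref, 0.5) == 0.0

    def test_batch_mean(self):
        ref = np.zeros((2, 1, 2, 2))
        ref[0, 0, 0, 0] = 1
        ref[1, 0, 0, 0] = 1
        pred = np.zeros((2, 1, 2, 2))
        pred[0, 0, 0, 0] = 1.0            # dice 1.0
        pred[1, 0, 0, :] = 1.0            # dice 2·1/(2+1) = 2/3
        assert training_accuracy(pred, ref, 0.5) == pytest.approx((1 + 2 / 3) / 2)

    def test_empty_pair_scores_one(self):
        z = np.zeros((1, 1, 4, 4))
        assert training_accuracy(z, z, 0.5) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            training_accuracy(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 2, 2)), 0.5)


class TestStoppingRule:
    @pytest.mark.parametrize(
        "train,val,expected",
        [
            (0.99, 0.80, True),   # both conditions met
            (0.99, 0.90, False),  # divergence 0.09 ≤ 0.15
            (0.97, 0.70, False),  # training accuracy ≤ 0.98
            (0.981, 0.83, True),
            (0.98, 0.80, False),  # strict inequality on the 98% bound
        ],
    )
    def test_printed_inequality(self, train, val, expected):
        state = TrainState(train_accuracy=train, val_accuracy=val)
        assert should_stop(state) is expected

    @given(
        train=st.floats(0, 1, allow_nan=False),
        val=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=300, deadline=None)
    def test_pure_function_of_the_two_accuracies(self, train, val):
        state = TrainState(train_accuracy=train, val_accuracy=val)
        assert should_stop(state) == (train > 0.98 and train - val > 0.15)


class TestTraining:
    def test_zero_epochs_returns_untrained_model(self):
        cohort = _tiny_cohort()
        spec = SegmentorSpec(
            lesion_class=LesionClass.WMH, **{**TINY, "max_epochs": 0}
        )
        model, state = train_segmentor(spec, cohort)
        assert state.epoch == 0 and not state.stopped and state.history == []
        fresh = build_unet(spec)
        for a, b in zip(model.params(), fresh.params()):
            np.testing.assert_array_equal(a.value, b.value)

    def test_same_seed_identical_history(self):
        cohort = _tiny_cohort()
        spec = SegmentorSpec(lesion_class=LesionClass.INFARCT, seed=3, **TINY)
        _, s1 = train_segmentor(spec, cohort)
        _, s2 = train_segmentor(spec, cohort)
        assert s1.history == s2.history

    def test_no_positive_slices_rejected(self):
        cfg = PhantomConfig(grid_shape=(4, 32, 32), seed=1)
        cohort = generate_cohort(
            cfg, 4, positive_fractions={c: 0.0 for c in LesionClass}
        )
        spec = SegmentorSpec(lesion_class=LesionClass.MICROBLEED, **TINY)
        with pytest.raises(TrainingDataError):
            train_segmentor(spec, cohort)

    def test_history_length_equals_epochs_run(self):
        cohort = _tiny_cohort()
        spec = SegmentorSpec(lesion_class=LesionClass.WMH, **TINY)
        _, state = train_segmentor(spec, cohort)
        assert len(state.history) == state.epoch
        for rec in state.history:
            assert 0.0 <= rec["train_accuracy"] <= 1.0
            assert 0.0 <= rec["val_accuracy"] <= 1.0


class TestPredict:
    def test_missing_routed_modality_raises_routing_error(self):
        cohort = _tiny_cohort(1)
        study, _ = cohort[0]
        del study.volumes[Modality.T2STAR]
        spec = SegmentorSpec(lesion_class=LesionClass.MICROBLEED, **TINY)
        model = build_unet(spec)
        with pytest.raises(RoutingError, match="T2STAR"):
            predict_volume(model, study, spec)

    def test_zero_probability_model_gives_empty_mask(self):
        cohort = _tiny_cohort(1)
        study, _ = cohort[0]
        spec = SegmentorSpec(lesion_class=LesionClass.WMH, **TINY)
        model = build_unet(spec)
        model.head.W.value[...] = 0.0
        model.head.b.value[...] = -50.0  # sigmoid ≈ 0 everywhere
        mask = predict_volume(model, study, spec)
        assert mask.count() == 0
        assert mask.shape == study.shape

    def test_output_grid_matches_study_grid(self):
        # non-square in-plane grid exercises the pad → resize → crop inverse;
        # only WMH lesions so every footprint fits the short axis
        counts = {c: (0, 0) for c in LesionClass}
        counts[LesionClass.WMH] = (1, 2)
        cfg = PhantomConfig(
            grid_shape=(3, 24, 32), lesion_counts=counts, noise_sd=2.0, seed=2
        )
        study, _ = generate_cohort(
            cfg, 1, positive_fractions={c: 1.0 for c in LesionClass}
        )[0]
        spec = SegmentorSpec(lesion_class=LesionClass.WMH, **TINY)
        mask = predict_volume(build_unet(spec), study, spec)
        assert mask.shape == (3, 24, 32)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        cohort = _tiny_cohort(2)
        spec = SegmentorSpec(lesion_class=LesionClass.INFARCT, **TINY)
        model, _ = train_segmentor(spec, cohort)
        path = save_checkpoint(model, spec, tmp_path / "infarct.npz")
        loaded, spec2 = load_checkpoint(path)
        assert spec2 == spec
        study, _ = cohort[0]
        np.testing.assert_array_equal(
            predict_volume(model, study, spec).values,
            predict_volume(loaded, study, spec2).values,
        )
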