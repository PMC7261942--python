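"""Metric unit tests against brute-force oracles and worked examples."""

import json

import numpy as np
import pytest

from csvdseg.metrics import (
    EvaluationReport,
    default_patch_edge,
    dice,
    evaluate_cohort,
    froc_curve,
    patch_dice,
    patch_discretize,
    region_components,
    region_f1,
)
from csvdseg.types import LesionClass, LesionMask

from oracles import dice_oracle, patch_discretize_oracle, region_f1_oracle


def _mask(cls, arr):
    return LesionMask(
        lesion_class=cls,
        values=np.asarray(arr, dtype=np.uint8),
        in_plane_spacing=1.0,
        slice_spacing=7.0,
    )


class TestDice:
    def test_identity_disjoint_and_counts(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, :2] = 1
        assert dice(a, a) == 1.0
        b = np.zeros((4, 4), dtype=int)
        b[3, :2] = 1
        assert dice(a, b) == 0.0
        # |P| = 4, |R| = 2, |P∩R| = 2 → 2·2 / 6
        p = np.zeros((4, 4), dtype=int)
        p[0] = 1
        r = np.zeros((4, 4), dtype=int)
        r[0, :2] = 1
        assert dice(p, r) == pytest.approx(2 * 2 / 6)

    def test_both_empty_scores_one(self):
        z = np.zeros((3, 3), dtype=int)
        assert dice(z, z) == 1.0

    def test_symmetry_and_oracle_agreement(self, rng):
        for _ in range(50):
            a = rng.random((6, 6)) > 0.6
            b = rng.random((6, 6)) > 0.6
            assert dice(a, b) == dice(b, a)
            assert dice(a, b) == pytest.approx(dice_oracle(a, b))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2)), np.zeros((3, 3)))


class TestPatchMetrics:
    def test_discretize_matches_blockwise_or(self, rng):
        for edge in (1, 2, 3, 5):
            m = rng.random((7, 9)) > 0.7
            np.testing.assert_array_equal(
                patch_discretize(m, edge), patch_discretize_oracle(m, edge)
            )

    def test_single_pixel_block_example(self):
        m = np.zeros((4, 4), dtype=int)
        m[0, 0] = 1
        out = patch_discretize(m, 2)
        expected = np.zeros((2, 2), dtype=int)
        expected[0, 0] = 1
        np.testing.assert_array_equal(out, expected)

    def test_patch_edge_one_is_identity(self, rng):
        m = (rng.random((5, 5)) > 0.5).astype(np.uint8)
        np.testing.assert_array_equal(patch_discretize(m, 1), m)

    def test_full_image_patch_collapses_to_presence(self):
        m = np.zeros((8, 8), dtype=int)
        m[5, 2] = 1
        assert patch_discretize(m, 8).shape == (1, 1)
        assert patch_discretize(m, 8)[0, 0] == 1

    def test_neighbouring_pixels_count_as_agreement(self):
        # pred and ref one pixel apart inside the same 2×2 patch
        pred = np.zeros((4, 4), dtype=int)
        ref = np.zeros((4, 4), dtype=int)
        pred[0, 0] = 1
        ref[1, 1] = 1
        assert dice(pred, ref) == 0.0
        assert patch_dice(pred, ref, 2) == 1.0

    def test_patch_dice_edge_one_equals_pixel_dice(self, rng):
        a = rng.random((6, 6)) > 0.5
        b = rng.random((6, 6)) > 0.5
        assert patch_dice(a, b, 1) == dice(a, b)

    def test_default_patch_edge_is_sqrt_of_edge(self):
        assert default_patch_edge((256, 256)) == 16
        assert default_patch_edge((10, 64, 64)) == 8

    def test_invalid_patch_edge(self):
        with pytest.raises(ValueError):
            patch_discretize(np.zeros((4, 4)), 0)


class TestRegionMetrics:
    def test_diagonal_pixels_are_one_component(self):
        m = np.zeros((4, 4), dtype=int)
        m[0, 0] = m[1, 1] = 1
        assert len(region_components(m)) == 1
        assert len(region_components(m, connectivity="face")) == 2

    def test_empty_and_isolated_blobs(self):
        assert region_components(np.zeros((4, 4), dtype=int)) == []
        m = np.zeros((9, 9), dtype=int)
        m[0, 0] = m[4, 4] = m[8, 8] = 1
        assert len(region_components(m)) == 3

    def test_two_hits_one_spurious(self):
        ref = np.zeros((12, 12), dtype=int)
        ref[0, 0:2] = 1    # lesion A — hit
        ref[5, 5:7] = 1    # lesion B — hit
        ref[10, 10] = 1    # lesion C — missed
        pred = np.zeros((12, 12), dtype=int)
        pred[0, 0] = 1
        pred[5, 6] = 1
        pred[10, 0] = 1    # spurious component
        out = region_f1(pred, ref)
        assert (out["tp"], out["fp"], out["fn"]) == (2, 1, 1)
        assert out["precision"] == pytest.approx(2 / 3)
        assert out["recall"] == pytest.approx(2 / 3)
        assert out["f1"] == pytest.approx(2 / 3)

    def test_one_pred_component_spanning_two_lesions(self):
        ref = np.zeros((5, 9), dtype=int)
        ref[2, 0:2] = 1
        ref[2, 6:8] = 1
        pred = np.zeros((5, 9), dtype=int)
        pred[2, :] = 1  # one blob across both
        out = region_f1(pred, ref)
        assert (out["tp"], out["fp"]) == (2, 0)
        greedy = region_f1(pred, ref, matching="greedy")
        assert (greedy["tp"], greedy["fp"], greedy["fn"]) == (1, 0, 1)

    def test_empty_cases(self):
        z = np.zeros((4, 4), dtype=int)
        nz = z.copy()
        nz[1, 1] = 1
        assert region_f1(z, z)["f1"] == 1.0
        assert region_f1(z, z)["empty_pair"]
        assert region_f1(z, nz)["f1"] == 0.0
        assert region_f1(nz, z)["f1"] == 0.0

    def test_oracle_agreement_on_random_masks(self, rng):
        for _ in range(100):
            a = rng.random((8, 8)) > 0.75
            b = rng.random((8, 8)) > 0.75
            got = region_f1(a, b)
            want = region_f1_oracle(a, b)
            for key in ("tp", "fp", "fn"):
                assert got[key] == want[key]
            assert got["f1"] == pytest.approx(want["f1"])


class TestFroc:
    def test_limits_and_monotone_sensitivity(self, rng):
        ref = np.zeros((10, 10), dtype=int)
        ref[2, 2:4] = 1
        ref[7, 7] = 1
        prob = rng.random((10, 10)) * 0.5
        prob[2, 2:4] = 0.9
        prob[7, 7] = 0.7
        ts = [0.0, 0.25, 0.5, 0.75, 0.95, 1.01]
        curve = froc_curve(prob, ref, ts)
        sens = [s for _, s in curve]
        assert sens == sorted(sens, reverse=True)
        assert curve[0][1] == 1.0       # threshold 0: everything detected
        assert curve[-1] == (0.0, 0.0)  # above 1: no positives at all

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            froc_curve(np.zeros((4, 4)), np.zeros((4, 4)), [0.5, 0.1])


class TestEvaluateCohort:
    def _cohort(self):
        shape = (2, 8, 8)
        truths, preds = {}, {}
        for i, pid in enumerate(["a", "b"]):
            truths[pid], preds[pid] = {}, {}
            for cls in LesionClass:
                t = np.zeros(shape, dtype=int)
                t[0, 2:4, 2:4] = 1
                p = t.copy()
                if pid == "b":
                    p[0, 2, 2] = 0  # slightly imperfect for patient b
                truths[pid][cls] = _mask(cls, t)
                preds[pid][cls] = _mask(cls, p)
        return preds, truths

    def test_aggregate_is_mean_of_per_patient(self):
        preds, truths = self._cohort()
        report = evaluate_cohort(preds, truths)
        for cls in LesionClass:
            vals = [report.per_patient[p][cls.name]["dice"] for p in ("a", "b")]
            assert report.aggregate["per_class"][cls.name]["dice"] == pytest.approx(
                np.mean(vals)
            )
        class_means = [
            report.aggregate["per_class"][c.name]["dice"] for c in LesionClass
        ]
        assert report.aggregate["overall"][
            "dice_mean_of_class_means"
        ] == pytest.approx(np.mean(class_means))

    def test_mean_example_values(self):
        # class dice 0.5 and 0.7 across two patients → class mean 0.6
        shape = (1, 4, 4)
        t = np.zeros(shape, dtype=int)
        t[0, 0, :2] = 1
        half = np.zeros(shape, dtype=int)
        half[0, 0, 0] = half[0, 1, 0] = 1  # dice 0.5 vs t
        truths = {"a": {}, "b": {}}
        preds = {"a": {}, "b": {}}
        for cls in LesionClass:
            truths["a"][cls] = _mask(cls, t)
            preds["a"][cls] = _mask(cls, half)
            truths["b"][cls] = _mask(cls, t)
            preds["b"][cls] = _mask(cls, t)
        report = evaluate_cohort(preds, truths)
        for cls in LesionClass:
            assert report.aggregate["per_class"][cls.name]["dice"] == pytest.approx(
                (0.5 + 1.0) / 2
            )

    def test_json_round_trip_lossless(self, tmp_path):
        preds, truths = self._cohort()
        report = evaluate_cohort(preds, truths)
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = EvaluationReport.load(path)
        assert loaded.per_patient == report.per_patient
        assert loaded.aggregate == report.aggregate
        assert loaded.patch_edge_used == report.patch_edge_used
        # and the text itself parses to the same structure
        assert json.loads(report.to_json()) == json.loads(loaded.to_json())

    def test_csv_export(self, tmp_path):
        preds, truths = self._cohort()
        report = evaluate_cohort(preds, truths)
        out = report.to_csv(tmp_path / "report.csv")
        text = out.read_text()
        assert "overall" in text and "WMH" in text

    def test_patient_mismatch_rejected(self):
        preds, truths = self._cohort()
        del preds["b"]
        with pytest.raises(ValueError, match="patient sets differ"):
            evaluate_cohort(preds, truths)
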