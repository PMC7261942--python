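"""Evaluation suite: dice, patch-discretized dice, region-wise F1, FROC.

Four complementary views of segmentation quality:

* **dice** — classic overlap 2|P∩R| / (|P|+|R|), computed per patient and
  aggregated by arithmetic mean.
* **patch dice** — a less demanding variant tolerant of few-pixel offsets:
  both masks are max-pooled onto a coarse square grid (patch edge about the
  square root of the image edge) before the dice is taken. At patch = image
  the metric collapses to presence/absence agreement, i.e. the patient-level
  multi-label classification problem.
* **region-wise F1** — every connected lesion counts once: a reference
  lesion touched by any predicted voxel is a true positive, an untouched one
  a false negative, and a predicted component touching no reference lesion a
  false positive.
* **FROC** — lesion sensitivity vs. false-positive components per case as
  the probability threshold sweeps, using the same counting rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import LesionClass, LesionMask


def _as_bool(a) -> np.ndarray:
    arr = a.values if isinstance(a, LesionMask) else np.asarray(a)
    return arr.astype(bool)


def dice(pred, ref) -> float:
    """Dice overlap; both-empty pairs score 1 by convention."""
    p, r = _as_bool(pred), _as_bool(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    np_, nr = int(p.sum()), int(r.sum())
    if np_ == 0 and nr == 0:
        return 1.0
    return 2.0 * int((p & r).sum()) / (np_ + nr)


def is_empty_pair(pred, ref) -> bool:
    return not _as_bool(pred).any() and not _as_bool(ref).any()


def default_patch_edge(shape) -> int:
    """Patch edge ≈ sqrt of the (larger) in-plane image edge."""
    return max(1, int(round(np.sqrt(max(shape[-2], shape[-1])))))


def patch_discretize(mask: np.ndarray, patch_edge: int) -> np.ndarray:
    """Max-pool a binary 2D mask onto a coarse patch grid.

    A patch is positive as soon as one of its pixels is positive. Boundary
    patches cover whatever pixels remain (zero padding does not create
    positives). ``patch_edge == 1`` is the identity.
    """
    if patch_edge < 1:
        raise ValueError("patch_edge must be >= 1")
    m = _as_bool(mask)
    if m.ndim != 2:
        raise ValueError("patch_discretize expects a 2D mask")
    r, c = m.shape
    pr = -(-r // patch_edge) * patch_edge
    pc = -(-c // patch_edge) * patch_edge
    padded = np.zeros((pr, pc), dtype=bool)
    padded[:r, :c] = m
    pooled = padded.reshape(
        pr // patch_edge, patch_edge, pc // patch_edge, patch_edge
    ).max(axis=(1, 3))
    return pooled.astype(np.uint8)


def patch_dice(pred, ref, patch_edge: int | None = None) -> float:
    """Dice of the patch-discretized masks (2D slice or 3D stack of slices).

    For 3D input the pooling is applied in-plane per slice and the dice is
    taken over the pooled stack; slices are never pooled together.
    """
    p, r = _as_bool(pred), _as_bool(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    if patch_edge is None:
        patch_edge = default_patch_edge(p.shape)
    if p.ndim == 2:
        return dice(patch_discretize(p, patch_edge), patch_discretize(r, patch_edge))
    if p.ndim == 3:
        pp = np.stack([patch_discretize(s, patch_edge) for s in p])
        rr = np.stack([patch_discretize(s, patch_edge) for s in r])
        return dice(pp, rr)
    raise ValueError("patch_dice expects a 2D or 3D mask")


def _structure(ndim: int) -> np.ndarray:
    # full connectivity: 8-connected in 2D, 26-connected in 3D
    return np.ones((3,) * ndim, dtype=bool)


def region_components(mask, connectivity: str = "full") -> list[np.ndarray]:
    """Connected components as coordinate arrays.

    ``connectivity`` is ``"full"`` (8-neighbour in 2D, 26-neighbour in 3D)
    or ``"face"`` (4- / 6-neighbour).
    """
    m = _as_bool(mask)
    if connectivity == "full":
        structure = _structure(m.ndim)
    elif connectivity == "face":
        structure = ndimage.generate_binary_structure(m.ndim, 1)
    else:
        raise ValueError("connectivity must be 'full' or 'face'")
    labels, n = ndimage.label(m, structure=structure)
    return [np.argwhere(labels == i + 1) for i in range(n)]


def region_f1(pred, ref, matching: str = "any_overlap") -> dict:
    """Lesion-level precision / recall / F1 with component counting.

    With the default ``any_overlap`` matching a single predicted blob that
    covers two reference lesions scores two true positives and no false
    positive; ``greedy`` instead enforces a one-to-one pairing by descending
    overlap. Both-empty pairs score 1 and are flagged.
    """
    p, r = _as_bool(pred), _as_bool(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    structure = _structure(p.ndim)
    ref_labels, n_ref = ndimage.label(r, structure=structure)
    pred_labels, n_pred = ndimage.label(p, structure=structure)
    empty_pair = n_ref == 0 and n_pred == 0
    if empty_pair:
        return {
            "precision": 1.0, "recall": 1.0, "f1": 1.0,
            "tp": 0, "fp": 0, "fn": 0, "empty_pair": True,
        }
    if matching == "any_overlap":
        hit_ref = np.unique(ref_labels[p & (ref_labels > 0)])
        tp = int(len(hit_ref))
        fn = n_ref - tp
        hit_pred = np.unique(pred_labels[r & (pred_labels > 0)])
        fp = n_pred - int(len(hit_pred))
    elif matching == "greedy":
        overlap = np.zeros((n_pred, n_ref), dtype=np.int64)
        both = p & r
        for pi, ri in zip(pred_labels[both], ref_labels[both]):
            overlap[pi - 1, ri - 1] += 1
        tp = 0
        used_p, used_r = set(), set()
        order = np.argsort(overlap, axis=None)[::-1]
        for flat in order:
            pi, ri = np.unravel_index(flat, overlap.shape)
            if overlap[pi, ri] == 0:
                break
            if pi in used_p or ri in used_r:
                continue
            used_p.add(int(pi))
            used_r.add(int(ri))
            tp += 1
        fn = n_ref - tp
        fp = n_pred - tp
    else:
        raise ValueError("matching must be 'any_overlap' or 'greedy'")
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {
        "precision": precision, "recall": recall, "f1": f1,
        "tp": tp, "fp": fp, "fn": fn, "empty_pair": False,
    }


def froc_curve(
    prob_map: np.ndarray, ref, thresholds
) -> list[tuple[float, float]]:
    """(false-positive components, lesion sensitivity) per threshold.

    Thresholds must be ascending in [0, 1]; a voxel is positive when its
    probability is ≥ the threshold. Sensitivity is monotone non-increasing
    as the threshold rises because the binarized masks are nested.
    """
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be ascending")
    prob = np.asarray(prob_map, dtype=np.float64)
    out = []
    for t in thresholds:
        scores = region_f1(prob >= t, ref)
        sens = scores["recall"] if not scores["empty_pair"] else 1.0
        out.append((float(scores["fp"]), float(sens)))
    return out


@dataclass
class EvaluationReport:
    """Per-patient and aggregated metric values for the four classes."""

    per_patient: dict[str, dict[str, dict]]  # patient -> class name -> metrics
    aggregate: dict
    patch_edge_used: int
    include_empty_pairs: bool = True

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "per_patient": self.per_patient,
            "aggregate": self.aggregate,
            "patch_edge_used": self.patch_edge_used,
            "include_empty_pairs": self.include_empty_pairs,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        payload = json.loads(text)
        return cls(
            per_patient=payload["per_patient"],
            aggregate=payload["aggregate"],
            patch_edge_used=payload["patch_edge_used"],
            include_empty_pairs=payload["include_empty_pairs"],
        )

    @classmethod
    def load(cls, path: str | Path) -> "EvaluationReport":
        return cls.from_json(Path(path).read_text())

    def to_csv(self, path: str | Path) -> Path:
        """Tabular export: one row per class plus the overall row."""
        rows = []
        for cls_name, vals in self.aggregate["per_class"].items():
            rows.append({"class": cls_name, **vals})
        rows.append(
            {
                "class": "overall",
                "dice": self.aggregate["overall"]["dice_mean_of_class_means"],
                "region_f1": self.aggregate["overall"][
                    "region_f1_mean_of_class_means"
                ],
            }
        )
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(path, index=False)
        return path


def evaluate_cohort(
    predictions: dict[str, dict[LesionClass, LesionMask]],
    ground_truths: dict[str, dict[LesionClass, LesionMask]],
    classes: list[LesionClass] | None = None,
    patch_edge: int | None = None,
    include_empty_pairs: bool = True,
    matching: str = "any_overlap",
) -> EvaluationReport:
    """Score a cohort of predictions against reference masks.

    Per patient and class: dice, patch dice, region precision/recall/F1 and
    lesion counts. Aggregates are unweighted arithmetic means over patients
    per class; the overall row is reported both as the mean of class means
    and as the pooled mean over all (patient, class) pairs, since either
    reading of "overall" is defensible. Patients whose prediction and
    reference are both empty for a class are flagged and, by default,
    included in the means.
    """
    if set(predictions) != set(ground_truths):
        only_p = sorted(set(predictions) - set(ground_truths))
        only_t = sorted(set(ground_truths) - set(predictions))
        raise ValueError(
            f"patient sets differ; prediction-only={only_p}, truth-only={only_t}"
        )
    if not predictions:
        raise ValueError("empty cohort")
    if classes is None:
        classes = list(LesionClass)
    first = next(iter(ground_truths.values()))
    shape = next(iter(first.values())).shape
    if patch_edge is None:
        patch_edge = default_patch_edge(shape)

    per_patient: dict[str, dict[str, dict]] = {}
    for pid in sorted(predictions):
        per_patient[pid] = {}
        for cls in classes:
            pred = predictions[pid][cls]
            ref = ground_truths[pid][cls]
            rf = region_f1(pred, ref, matching=matching)
            per_patient[pid][cls.name] = {
                "dice": dice(pred, ref),
                "patch_dice": patch_dice(pred, ref, patch_edge),
                "region_precision": rf["precision"],
                "region_recall": rf["recall"],
                "region_f1": rf["f1"],
                "tp": rf["tp"],
                "fp": rf["fp"],
                "fn": rf["fn"],
                "empty_pair": is_empty_pair(pred, ref),
            }

    per_class: dict[str, dict[str, float]] = {}
    pooled: dict[str, list[float]] = {"dice": [], "patch_dice": [], "region_f1": []}
    for cls in classes:
        vals: dict[str, list[float]] = {
            "dice": [], "patch_dice": [],
            "region_precision": [], "region_recall": [], "region_f1": [],
        }
        for pid in per_patient:
            rec = per_patient[pid][cls.name]
            if rec["empty_pair"] and not include_empty_pairs:
                continue
            for k in vals:
                vals[k].append(rec[k])
        per_class[cls.name] = {
            k: (float(np.mean(v)) if v else float("nan")) for k, v in vals.items()
        }
        pooled["dice"].extend(vals["dice"])
        pooled["patch_dice"].extend(vals["patch_dice"])
        pooled["region_f1"].extend(vals["region_f1"])

    overall = {
        "dice_mean_of_class_means": float(
            np.mean([per_class[c.name]["dice"] for c in classes])
        ),
        "patch_dice_mean_of_class_means": float(
            np.mean([per_class[c.name]["patch_dice"] for c in classes])
        ),
        "region_f1_mean_of_class_means": float(
            np.mean([per_class[c.name]["region_f1"] for c in classes])
        ),
        "dice_pooled": float(np.mean(pooled["dice"])) if pooled["dice"] else float("nan"),
        "patch_dice_pooled": float(np.mean(pooled["patch_dice"]))
        if pooled["patch_dice"] else float("nan"),
        "region_f1_pooled": float(np.mean(pooled["region_f1"]))
        if pooled["region_f1"] else float("nan"),
    }
    return EvaluationReport(
        per_patient=per_patient,
        aggregate={"per_class": per_class, "overall": overall},
        patch_edge_used=patch_edge,
        include_empty_pairs=include_empty_pairs,
    )
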