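"""Per-lesion-class U-Net segmentors: routing, training, stopping, inference.

One independent network is trained per lesion class, each reading only the
sequences on which that pathology is conspicuous:

* subcortical infarct  ← DWI b1000
* WMH                  ← T2-FLAIR
* lacune               ← T1 + T2-FLAIR (two input channels)
* microbleed           ← T2*-GRE

Training operates on 2D slices extracted from the routed volumes after
white-matter normalization, square padding and resizing. Training stops when
training accuracy exceeds 98% while diverging from validation accuracy by
more than 15 percentage points — i.e. when overfitting is detected — and the
best-validation checkpoint (not the final, overfit one) is kept. "Accuracy"
here is mean per-slice dice of the thresholded prediction, with empty-vs-
empty slices scoring 1; plain pixel accuracy would saturate near 1 under
lesion sparsity and make the 98% criterion meaningless.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

from .nn import Adam, UNet, soft_dice_loss
from .phantom import GroundTruth
from .preprocess import (
    PreprocessSpec,
    ResizeMode,
    crop_from_square,
    normalize_wm,
    pad_to_square,
    resize,
)
from .types import LesionClass, LesionMask, Modality, PatientStudy

#: Which sequences each class's segmentor consumes, in channel order.
DEFAULT_ROUTING: dict[LesionClass, tuple[Modality, ...]] = {
    LesionClass.INFARCT: (Modality.DWI_B1000,),
    LesionClass.WMH: (Modality.T2FLAIR,),
    LesionClass.LACUNE: (Modality.T1, Modality.T2FLAIR),
    LesionClass.MICROBLEED: (Modality.T2STAR,),
}


class Loss(str, Enum):
    SOFT_DICE = "soft_dice"
    BCE = "bce"
    SUM = "sum"  # soft dice + BCE


class TrainingDataError(ValueError):
    """Training set contains no positive slice for the class."""


@dataclass
class SegmentorSpec:
    """Architecture, routing and training configuration for one class."""

    lesion_class: LesionClass
    input_modalities: tuple[Modality, ...] | None = None
    depth: int = 4
    base_channels: int = 16
    channel_growth: int = 2
    input_size: int = 256
    threshold: float = 0.5
    loss: Loss = Loss.SOFT_DICE
    max_epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    scale_augment: bool = True
    balance_positive: bool = True

    def __post_init__(self) -> None:
        if self.input_modalities is None:
            self.input_modalities = DEFAULT_ROUTING[self.lesion_class]
        self.input_modalities = tuple(self.input_modalities)
        if self.input_size % 2**self.depth != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2**depth"
            )
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")


@dataclass
class TrainState:
    """Progress record of one training run."""

    epoch: int = 0
    train_accuracy: float = 0.0
    val_accuracy: float = 0.0
    best_val_accuracy: float = 0.0
    stopped: bool = False
    history: list[dict] = field(default_factory=list)


def build_unet(spec: SegmentorSpec) -> UNet:
    """Instantiate the network described by a spec (weights seeded)."""
    return UNet(
        in_channels=len(spec.input_modalities),
        depth=spec.depth,
        base_channels=spec.base_channels,
        growth=spec.channel_growth,
        seed=spec.seed,
    )


def _item_dice(pred: np.ndarray, ref: np.ndarray) -> float:
    p, r = int(pred.sum()), int(ref.sum())
    if p == 0 and r == 0:
        return 1.0
    inter = int(np.logical_and(pred, ref).sum())
    return 2.0 * inter / (p + r)


def training_accuracy(
    pred_probs: np.ndarray, ref: np.ndarray, threshold: float
) -> float:
    """Mean per-item dice of thresholded predictions (empty–empty pairs = 1)."""
    if pred_probs.shape != ref.shape:
        raise ValueError("prediction and reference batch shapes differ")
    if pred_probs.shape[0] == 0:
        raise ValueError("empty batch")
    binarized = pred_probs >= threshold
    refs = np.asarray(ref) > 0.5
    return float(
        np.mean([_item_dice(b, r) for b, r in zip(binarized, refs)])
    )


def should_stop(state: TrainState) -> bool:
    """Overfitting-detection stop: train acc > 0.98 AND train − val > 0.15."""
    return (
        state.train_accuracy > 0.98
        and (state.train_accuracy - state.val_accuracy) > 0.15
    )


def _soft_dice_logits(probs, target):
    loss, dprobs = soft_dice_loss(probs, target)
    return loss, dprobs * probs * (1.0 - probs)


def _bce_logits(probs: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    # gradient w.r.t. logits is (p - g)/N in closed form: it stays informative
    # even when the sigmoid saturates and p*(1-p) underflows
    eps = 1e-12
    p = np.clip(probs, eps, 1 - eps)
    g = np.asarray(target, dtype=np.float64)
    loss = float(np.mean(-(g * np.log(p) + (1 - g) * np.log(1 - p))))
    dlogits = (probs - g) / probs.size
    return loss, dlogits


def _loss_fn(loss: Loss):
    """Return a ``(probs, target) -> (loss, dlogits)`` function."""
    if loss is Loss.SOFT_DICE:
        return _soft_dice_logits
    if loss is Loss.BCE:
        return _bce_logits

    def _sum(probs, target):
        l1, d1 = _soft_dice_logits(probs, target)
        l2, d2 = _bce_logits(probs, target)
        return l1 + l2, d1 + d2

    return _sum


def extract_slices(
    cohort: list[tuple[PatientStudy, GroundTruth]],
    spec: SegmentorSpec,
    preprocess_spec: PreprocessSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Preprocessed training slices for one class.

    Returns ``(X, Y, patient_index)`` with X shaped
    ``(n_slices, n_modalities, size, size)`` and Y ``(n_slices, 1, size,
    size)``; ``patient_index`` maps each slice back to its cohort position so
    splits can be made patient-wise.
    """
    size = preprocess_spec.target_size
    xs, ys, pidx = [], [], []
    for pi, (study, truth) in enumerate(cohort):
        study.require(spec.input_modalities)
        normed = [
            normalize_wm(study.volumes[m], preprocess_spec)
            for m in spec.input_modalities
        ]
        mask = truth.masks[spec.lesion_class].values
        n_slices = study.shape[0]
        for s in range(n_slices):
            chans = [
                resize(pad_to_square(v.data[s]), size, ResizeMode.INTENSITY)
                for v in normed
            ]
            m = resize(pad_to_square(mask[s]), size, ResizeMode.MASK)
            xs.append(np.stack(chans))
            ys.append(m[None])
            pidx.append(pi)
    return (
        np.array(xs, dtype=np.float64),
        np.array(ys, dtype=np.float64),
        np.array(pidx, dtype=np.int64),
    )


def _augment_scale(
    xb: np.ndarray, yb: np.ndarray, factor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Zoom a batch by ``factor`` and crop/pad back to the original edge.

    Emulates the spread of in-plane resolutions across scanners so the
    network does not key on absolute lesion size in pixels.
    """
    size = xb.shape[-1]
    m = max(4, int(round(size * factor)))
    if m == size:
        return xb, yb
    xo = np.zeros_like(xb)
    yo = np.zeros_like(yb)
    for i in range(xb.shape[0]):
        for c in range(xb.shape[1]):
            z = resize(xb[i, c], m, ResizeMode.INTENSITY)
            xo[i, c] = _center_fit(z, size)
        z = resize(yb[i, 0], m, ResizeMode.MASK)
        yo[i, 0] = _center_fit(z, size)
    return xo, yo


def _center_fit(img: np.ndarray, size: int) -> np.ndarray:
    m = img.shape[0]
    if m >= size:
        o = (m - size) // 2
        return img[o : o + size, o : o + size]
    out = np.zeros((size, size), dtype=img.dtype)
    o = (size - m) // 2
    out[o : o + m, o : o + m] = img
    return out


def _batched_accuracy(
    model: UNet, x: np.ndarray, y: np.ndarray, threshold: float, batch: int
) -> float:
    dices = []
    for i in range(0, len(x), batch):
        probs = model.forward(x[i : i + batch])
        binar = probs >= threshold
        refs = y[i : i + batch] > 0.5
        dices.extend(_item_dice(b, r) for b, r in zip(binar, refs))
    return float(np.mean(dices))


def train_segmentor(
    spec: SegmentorSpec,
    cohort: list[tuple[PatientStudy, GroundTruth]],
    split: tuple[float, float] = (0.8, 0.2),
    preprocess_spec: PreprocessSpec | None = None,
) -> tuple[UNet, TrainState]:
    """Train one class's U-Net on a cohort; deterministic given ``spec.seed``.

    The cohort is split patient-wise into train/validation; training runs
    until :func:`should_stop` fires or ``max_epochs`` is reached, and the
    weights with the best validation accuracy are restored before returning.
    With ``max_epochs == 0`` the freshly initialized network is returned
    untouched.
    """
    if preprocess_spec is None:
        preprocess_spec = PreprocessSpec(target_size=spec.input_size)
    if preprocess_spec.target_size != spec.input_size:
        raise ValueError("preprocess target_size must equal spec.input_size")
    x, y, pidx = extract_slices(cohort, spec, preprocess_spec)
    rng = np.random.default_rng(spec.seed)
    patients = np.arange(len(cohort))
    rng.shuffle(patients)
    n_val = int(round(split[1] * len(cohort))) if len(cohort) > 1 else 0
    val_patients = set(patients[:n_val].tolist())
    # stratify: both splits need a lesion-positive patient where possible —
    # an all-negative validation set scores the empty predictor at dice 1
    # and would freeze it as the "best" checkpoint
    positives = {
        int(i)
        for i, (_, truth) in enumerate(cohort)
        if truth.masks[spec.lesion_class].count() > 0
    }
    if positives and n_val > 0:
        train_set = [int(p) for p in patients[n_val:]]
        if not (val_patients & positives) and (set(train_set) & positives):
            swap_in = next(p for p in train_set if p in positives)
            swap_out = next(p for p in patients[:n_val].tolist())
            val_patients = (val_patients - {swap_out}) | {swap_in}
        elif positives <= val_patients:
            # training would have no positive patient at all
            swap_out = sorted(positives & val_patients)[0]
            swap_in = next(p for p in train_set if p not in positives)
            val_patients = (val_patients - {swap_out}) | {swap_in}
    val_sel = np.isin(pidx, list(val_patients)) if val_patients else np.zeros(
        len(pidx), dtype=bool
    )
    xt, yt = x[~val_sel], y[~val_sel]
    xv, yv = x[val_sel], y[val_sel]

    model = build_unet(spec)
    state = TrainState()
    if spec.max_epochs == 0:
        return model, state
    if yt.sum() == 0:
        raise TrainingDataError(
            f"no positive {spec.lesion_class.name} slice in the training split"
        )

    loss_fn = _loss_fn(spec.loss)
    opt = Adam(model.params(), lr=spec.learning_rate)
    best_state = model.state_arrays()
    best_val = -1.0
    # lesion slices are a small minority; repeat them in the epoch stream so
    # batches regularly carry gradient signal (all negatives are kept too)
    order = np.arange(len(xt))
    if spec.balance_positive:
        pos_idx = np.flatnonzero(yt.sum(axis=(1, 2, 3)) > 0)
        n_neg = len(xt) - len(pos_idx)
        extra = min(4, max(0, round(n_neg / max(1, len(pos_idx))) - 1))
        if extra > 0:
            order = np.concatenate([order, np.tile(pos_idx, extra)])
    for epoch in range(1, spec.max_epochs + 1):
        rng.shuffle(order)
        epoch_loss = 0.0
        for i in range(0, len(order), spec.batch_size):
            sel = order[i : i + spec.batch_size]
            xb, yb = xt[sel], yt[sel]
            if spec.scale_augment and rng.random() < 0.5:
                xb, yb = _augment_scale(xb, yb, float(rng.uniform(0.75, 1.3)))
            probs = model.forward(xb)
            loss, dlogits = loss_fn(probs, yb)
            model.zero_grad()
            model.backward_logits(dlogits)
            opt.step()
            epoch_loss += loss * len(sel)
        train_acc = _batched_accuracy(model, xt, yt, spec.threshold, spec.batch_size)
        if len(xv):
            val_acc = _batched_accuracy(
                model, xv, yv, spec.threshold, spec.batch_size
            )
        else:
            val_acc = train_acc
        state.epoch = epoch
        state.train_accuracy = train_acc
        state.val_accuracy = val_acc
        if val_acc > best_val:
            best_val = val_acc
            best_state = model.state_arrays()
        state.best_val_accuracy = best_val
        state.history.append(
            {
                "epoch": epoch,
                "loss": epoch_loss / len(xt),
                "train_accuracy": train_acc,
                "val_accuracy": val_acc,
            }
        )
        if should_stop(state):
            state.stopped = True
            break
    model.load_state_arrays(best_state)
    return model, state


def predict_volume(
    model: UNet,
    study: PatientStudy,
    spec: SegmentorSpec,
    preprocess_spec: PreprocessSpec | None = None,
) -> LesionMask:
    """Segment one study slice-by-slice and reassemble the 3D mask.

    Each slice of the routed sequences is preprocessed exactly as in
    training, pushed through the network, thresholded, mapped back to the
    native slice geometry, and the per-slice masks are concatenated in order
    into a volume on the study grid.
    """
    if preprocess_spec is None:
        preprocess_spec = PreprocessSpec(target_size=spec.input_size)
    study.require(spec.input_modalities)
    normed = [
        normalize_wm(study.volumes[m], preprocess_spec)
        for m in spec.input_modalities
    ]
    ns, nr, nc = study.shape
    size = preprocess_spec.target_size
    out = np.zeros((ns, nr, nc), dtype=np.uint8)
    edge = max(nr, nc)
    for s in range(ns):
        chans = [
            resize(pad_to_square(v.data[s]), size, ResizeMode.INTENSITY)
            for v in normed
        ]
        probs = model.forward(np.stack(chans)[None])[0, 0]
        binar = (probs >= spec.threshold).astype(np.uint8)
        native = resize(binar, edge, ResizeMode.MASK)
        out[s] = crop_from_square(native, (nr, nc))
    ref = study.volumes[spec.input_modalities[0]]
    return LesionMask(
        lesion_class=spec.lesion_class,
        values=out,
        in_plane_spacing=ref.in_plane_spacing,
        slice_spacing=ref.slice_spacing,
    )


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(model: UNet, spec: SegmentorSpec, path: str | Path) -> Path:
    """Persist weights + spec as a single versioned .npz file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "lesion_class": spec.lesion_class.value,
        "input_modalities": [m.value for m in spec.input_modalities],
        "depth": spec.depth,
        "base_channels": spec.base_channels,
        "channel_growth": spec.channel_growth,
        "input_size": spec.input_size,
        "threshold": spec.threshold,
        "loss": spec.loss.value,
        "max_epochs": spec.max_epochs,
        "batch_size": spec.batch_size,
        "learning_rate": spec.learning_rate,
        "seed": spec.seed,
        "scale_augment": spec.scale_augment,
        "balance_positive": spec.balance_positive,
    }
    arrays = {f"param_{i:03d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)
    return path


def load_checkpoint(path: str | Path) -> tuple[UNet, SegmentorSpec]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = [
            data[k] for k in sorted(k for k in data.files if k.startswith("param_"))
        ]
    spec = SegmentorSpec(
        lesion_class=LesionClass(meta["lesion_class"]),
        input_modalities=tuple(Modality(m) for m in meta["input_modalities"]),
        depth=meta["depth"],
        base_channels=meta["base_channels"],
        channel_growth=meta["channel_growth"],
        input_size=meta["input_size"],
        threshold=meta["threshold"],
        loss=Loss(meta["loss"]),
        max_epochs=meta["max_epochs"],
        batch_size=meta["batch_size"],
        learning_rate=meta["learning_rate"],
        seed=meta["seed"],
        scale_augment=meta["scale_augment"],
        balance_positive=meta.get("balance_positive", True),
    )
    model = build_unet(spec)
    model.load_state_arrays(arrays)
    return model, spec
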