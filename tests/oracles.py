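"""Independent brute-force oracles for the evaluation metrics.

Deliberately naive: explicit set arithmetic, recursive flood fill and an
exhaustive overlap matrix. They share no code with the package
implementations they check.
"""

from __future__ import annotations

import numpy as np


def dice_oracle(pred: np.ndarray, ref: np.ndarray) -> float:
    p = {tuple(ix) for ix in np.argwhere(np.asarray(pred).astype(bool))}
    r = {tuple(ix) for ix in np.argwhere(np.asarray(ref).astype(bool))}
    if not p and not r:
        return 1.0
    return 2.0 * len(p & r) / (len(p) + len(r))


def patch_discretize_oracle(mask: np.ndarray, patch_edge: int) -> np.ndarray:
    m = np.asarray(mask).astype(bool)
    rows, cols = m.shape
    out_r = (rows + patch_edge - 1) // patch_edge
    out_c = (cols + patch_edge - 1) // patch_edge
    out = np.zeros((out_r, out_c), dtype=np.uint8)
    for i in range(out_r):
        for j in range(out_c):
            block = m[
                i * patch_edge : (i + 1) * patch_edge,
                j * patch_edge : (j + 1) * patch_edge,
            ]
            out[i, j] = 1 if block.any() else 0
    return out


def _neighbours(ix: tuple[int, ...]):
    """All touching offsets (8-connectivity in 2D, 26 in 3D)."""
    ndim = len(ix)
    offsets = np.indices((3,) * ndim).reshape(ndim, -1).T - 1
    for off in offsets:
        if not np.any(off):
            continue
        yield tuple(a + b for a, b in zip(ix, off))


def components_oracle(mask: np.ndarray) -> list[set[tuple[int, ...]]]:
    """Connected components by iterative flood fill under full connectivity."""
    m = np.asarray(mask).astype(bool)
    todo = {tuple(ix) for ix in np.argwhere(m)}
    comps = []
    while todo:
        stack = [todo.pop()]
        comp = set(stack)
        while stack:
            cur = stack.pop()
            for nb in _neighbours(cur):
                if nb in todo:
                    todo.discard(nb)
                    comp.add(nb)
                    stack.append(nb)
        comps.append(comp)
    return comps


def region_f1_oracle(pred: np.ndarray, ref: np.ndarray) -> dict:
    """Lesion counting via the exhaustive component overlap matrix."""
    pred_set = {tuple(ix) for ix in np.argwhere(np.asarray(pred).astype(bool))}
    ref_comps = components_oracle(ref)
    pred_comps = components_oracle(pred)
    if not ref_comps and not pred_comps:
        return {"precision": 1.0, "recall": 1.0, "f1": 1.0, "tp": 0, "fp": 0, "fn": 0}
    tp = sum(1 for rc in ref_comps if rc & pred_set)
    fn = len(ref_comps) - tp
    ref_set = {tuple(ix) for ix in np.argwhere(np.asarray(ref).astype(bool))}
    fp = sum(1 for pc in pred_comps if not (pc & ref_set))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn}
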