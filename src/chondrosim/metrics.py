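"""Instance-matching evaluation metrics.

Predicted and ground-truth instances are matched one-to-one by maximizing
total IoU (optimal assignment); pairs below the IoU threshold τ are
discarded.  accuracy(τ) = TP/(TP+FN+FP); precision, recall and F1 follow
the usual definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .types import EllipsoidSet, LabeledVolume

DEFAULT_TAU = 0.5


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    tau: float
    matched_pairs: list[tuple[int, int, float]] = field(default_factory=list)


def _overlap_table(pred: np.ndarray, gt: np.ndarray):
    """Sparse contingency of (pred label, gt label) voxel overlaps."""
    both = (pred > 0) | (gt > 0)
    p = pred[both].ravel()
    g = gt[both].ravel()
    pair = p.astype(np.int64) * (gt.max() + 1) + g
    uniq, counts = np.unique(pair, return_counts=True)
    pl = uniq // (gt.max() + 1)
    gl = uniq % (gt.max() + 1)
    return pl, gl, counts


def _border_labels(arr: np.ndarray) -> set[int]:
    out: set[int] = set()
    for ax in range(arr.ndim):
        for idx in (0, -1):
            face = np.take(arr, idx, axis=ax)
            out.update(int(l) for l in np.unique(face[face > 0]))
    return out


def match_instances(
    pred: LabeledVolume | np.ndarray,
    gt: LabeledVolume | np.ndarray,
    tau: float = DEFAULT_TAU,
    exclude_border: bool = False,
) -> MatchResult:
    """Optimal one-to-one IoU matching between instance label volumes.

    ``exclude_border`` drops instances touching the volume border from both
    images before matching (useful when a method is known to mishandle
    boundary-clipped cells).
    """
    p = pred.labels if isinstance(pred, LabeledVolume) else np.asarray(pred)
    g = gt.labels if isinstance(gt, LabeledVolume) else np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    if not 0 <= tau < 1:
        raise ValueError("tau must be in [0, 1)")
    if exclude_border:
        p = np.where(np.isin(p, list(_border_labels(p))), 0, p)
        g = np.where(np.isin(g, list(_border_labels(g))), 0, g)

    pred_labels = np.unique(p[p > 0])
    gt_labels = np.unique(g[g > 0])
    n_pred, n_gt = pred_labels.size, gt_labels.size
    if n_pred == 0 or n_gt == 0:
        return MatchResult(tp=0, fp=n_pred, fn=n_gt, tau=tau)

    pred_sizes = {int(l): int(np.count_nonzero(p == l)) for l in pred_labels}
    gt_sizes = {int(l): int(np.count_nonzero(g == l)) for l in gt_labels}

    pl, gl, counts = _overlap_table(p, g)
    keep = (pl > 0) & (gl > 0)
    pl, gl, counts = pl[keep], gl[keep], counts[keep]

    pidx = {int(l): i for i, l in enumerate(pred_labels)}
    gidx = {int(l): i for i, l in enumerate(gt_labels)}
    iou = np.zeros((n_pred, n_gt))
    for a, b, inter in zip(pl, gl, counts):
        union = pred_sizes[int(a)] + gt_sizes[int(b)] - int(inter)
        iou[pidx[int(a)], gidx[int(b)]] = inter / union

    rows, cols = linear_sum_assignment(-iou)
    matched = []
    for r, c in zip(rows, cols):
        # zero-overlap pairs are never matches; below-tau pairs are dropped
        if iou[r, c] > 0 and iou[r, c] >= tau:
            matched.append((int(pred_labels[r]), int(gt_labels[c]), float(iou[r, c])))
    tp = len(matched)
    return MatchResult(tp=tp, fp=n_pred - tp, fn=n_gt - tp, tau=tau, matched_pairs=matched)


def accuracy(m: MatchResult) -> float:
    """TP / (TP + FN + FP); defined as 1.0 when both images are empty."""
    denom = m.tp + m.fn + m.fp
    if denom == 0:
        return 1.0
    return m.tp / denom


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    precision = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else 0.0
    recall = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1


def population_summary(
    cells: EllipsoidSet, box: tuple[float, float, float] | None = None
) -> dict:
    """Count, mean/sd cell volume (µm³) and volume ratio vs the box, in %."""
    if box is None:
        box = cells.box
    if box is None:
        raise ValueError("a box is required for the volume ratio")
    box_volume = float(np.prod(np.asarray(box, dtype=float)))
    if box_volume <= 0:
        raise ValueError("box volume must be positive")
    vols = cells.volumes
    count = len(cells)
    return {
        "count": count,
        "volume_mean": float(vols.mean()) if count else 0.0,
        "volume_sd": float(vols.std(ddof=1)) if count > 1 else 0.0,
        "volume_ratio_percent": float(vols.sum() / box_volume * 100.0),
    }
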