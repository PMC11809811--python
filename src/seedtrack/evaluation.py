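"""Instance-segmentation and tracking metrics.

Detection metrics follow the IoU-threshold-sweep convention: predictions
and ground-truth objects are matched one-to-one (optimal assignment over
pairs with IoU above the threshold ``t``), giving TP/FP/FN and

    AP_t  = TP / (TP + FP + FN),
    avAP  = mean of AP_t over t = 0.50, 0.55, ..., 0.95.

SEG is the mean, over ground-truth objects in all frames, of the IoU with
the single prediction covering a strict majority of the object's pixels
(0 when none does).  Tracking quality is summarised by an identity-swap
count: the number of frames at which the established correspondence
between predicted and true cell identities changes.  This is a simplified
association-error count, not the Cell Tracking Challenge TRA/DET graph
scores, and is labelled non-CTC in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import LineageTree

IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))

__all__ = [
    "DetectionCounts", "EvalReport", "masks_from_labels", "mask_iou",
    "match_instances", "average_precision", "mean_average_precision",
    "seg_measure", "count_identity_swaps", "evaluate_stacks",
]


@dataclass
class DetectionCounts:
    """TP/FP/FN at one IoU threshold."""

    t: float
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.t < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        if other.t != self.t:
            raise ValueError("cannot add counts at different thresholds")
        return DetectionCounts(self.t, self.tp + other.tp,
                               self.fp + other.fp, self.fn + other.fn)


def masks_from_labels(label_image: np.ndarray) -> list[np.ndarray]:
    """Binary instance masks from a label image (sorted by label)."""
    return [label_image == v for v in np.unique(label_image) if v != 0]


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.astype(bool), b.astype(bool)
    union = int((a | b).sum())
    return (int((a & b).sum()) / union) if union else 0.0


def _iou_matrix(pred_masks, gt_masks) -> np.ndarray:
    m = np.zeros((len(pred_masks), len(gt_masks)))
    for i, p in enumerate(pred_masks):
        for j, g in enumerate(gt_masks):
            m[i, j] = mask_iou(p, g)
    return m


def match_instances(pred_masks, gt_masks, t: float):
    """One-to-one matching maximizing total IoU over pairs with IoU > t.

    Returns ``(counts, matching)`` where ``matching`` is a list of
    ``(pred_index, gt_index, iou)`` for the matched (TP) pairs.
    """
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    iou = _iou_matrix(pred_masks, gt_masks)
    eligible = iou > t
    cost = np.where(eligible, -iou, 0.0)
    matching = []
    if cost.size:
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if eligible[i, j]:
                matching.append((int(i), int(j), float(iou[i, j])))
    tp = len(matching)
    counts = DetectionCounts(t=t, tp=tp, fp=len(pred_masks) - tp,
                             fn=len(gt_masks) - tp)
    return counts, matching


def average_precision(counts: DetectionCounts) -> float:
    """AP_t = TP / (TP + FP + FN); 0 by convention when all are 0."""
    denom = counts.tp + counts.fp + counts.fn
    return counts.tp / denom if denom else 0.0


def mean_average_precision(per_threshold) -> float:
    """Mean AP over the 10 thresholds t = 0.50 ... 0.95.

    ``per_threshold``: mapping threshold -> :class:`DetectionCounts`; all
    10 grid thresholds must be present.
    """
    missing = [t for t in IOU_THRESHOLDS if t not in per_threshold]
    if missing:
        raise ValueError(f"missing counts for thresholds {missing}")
    return float(np.mean([average_precision(per_threshold[t])
                          for t in IOU_THRESHOLDS]))


def seg_measure(pred_mask_frames, gt_mask_frames) -> float:
    """SEG over per-frame lists of instance masks.

    For each ground-truth object, the prediction covering > 50% of its
    pixels contributes their IoU, else 0; SEG is the mean over all
    ground-truth objects and frames (1.0 when there are no ground-truth
    objects at all).  Disjoint predictions admit at most one majority
    coverer; should predictions overlap, the one covering most of the
    object is used.
    """
    scores = []
    for preds, gts in zip(pred_mask_frames, gt_mask_frames):
        for g in gts:
            g = g.astype(bool)
            g_area = int(g.sum())
            best, best_cover = 0.0, 0
            for p in preds:
                covered = int((p.astype(bool) & g).sum())
                if 2 * covered > g_area and covered > best_cover:
                    best, best_cover = mask_iou(p, g), covered
            scores.append(best)
    return float(np.mean(scores)) if scores else 1.0


# ---------------------------------------------------------------------------
# Identity swaps
# ---------------------------------------------------------------------------

def _frame_assignment(pred_pos: dict, gt_pos: dict):
    """Optimal pred<->gt correspondence by centroid proximity; returns
    ``(mapping, ambiguous)`` where ambiguity means two equally near
    predictions for one truth (or vice versa)."""
    pids = sorted(pred_pos)
    gids = sorted(gt_pos)
    if not pids or not gids:
        return {}, False
    d = np.zeros((len(pids), len(gids)))
    for i, p in enumerate(pids):
        for j, g in enumerate(gids):
            d[i, j] = np.hypot(pred_pos[p][0] - gt_pos[g][0],
                               pred_pos[p][1] - gt_pos[g][1])
    rows, cols = linear_sum_assignment(d)
    mapping = {pids[i]: gids[j] for i, j in zip(rows, cols)}
    # exact distance ties make the assignment ambiguous
    ambiguous = False
    for i, j in zip(rows, cols):
        ties = np.isclose(d[:, j], d[i, j]).sum()
        if ties > 1:
            ambiguous = True
    return mapping, ambiguous


def count_identity_swaps(pred: LineageTree, gt: LineageTree,
                         n_frames: int | None = None) -> int:
    """Count frames where the pred<->truth identity correspondence changes.

    The correspondence is established per frame by optimal centroid
    proximity; a swap is charged when a prediction that was matched to a
    truth id in the previous frame is matched to a *different, still
    coexisting* truth id in the current frame (so appearing/disappearing
    tracks around divisions do not count).  Ambiguous assignments
    (equidistant candidates) are counted as swaps.
    """
    frames = set()
    for tr in list(pred.tracks.values()) + list(gt.tracks.values()):
        frames.update(f for f, _, _ in tr.states)
    if n_frames is not None:
        frames = {f for f in frames if f < n_frames}
    swaps = 0
    prev_map: dict = {}
    for f in sorted(frames):
        mapping, ambiguous = _frame_assignment(pred.positions_at(f),
                                               gt.positions_at(f))
        changed = ambiguous
        for pid, gid in mapping.items():
            old = prev_map.get(pid)
            if old is not None and old != gid and old in gt.positions_at(f):
                changed = True
        if changed:
            swaps += 1
        prev_map = mapping
    return swaps


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Aggregate per-threshold detection counts plus SEG and swap count.

    Rates mirror the usual benchmarking table: TP/FP/FN as fractions of
    ground-truth objects, precision/recall/F1 and AP at 0.5, AP at 0.75,
    and avAP.  ``identity_swaps`` is the simplified (non-CTC) association
    error count.
    """

    counts: dict = field(default_factory=dict)  # threshold -> DetectionCounts
    seg: float = 0.0
    identity_swaps: int | None = None
    n_gt_objects: int = 0

    def precision(self, t: float = 0.5) -> float:
        c = self.counts[t]
        return c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0

    def recall(self, t: float = 0.5) -> float:
        c = self.counts[t]
        return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0

    def f1(self, t: float = 0.5) -> float:
        p, r = self.precision(t), self.recall(t)
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def ap(self, t: float = 0.5) -> float:
        return average_precision(self.counts[t])

    @property
    def av_ap(self) -> float:
        return mean_average_precision(self.counts)

    def to_dict(self) -> dict:
        c = self.counts[0.5]
        n = max(self.n_gt_objects, 1)
        return {
            "SEG": self.seg,
            "TP_0.5": c.tp / n, "FP_0.5": c.fp / n, "FN_0.5": c.fn / n,
            "Precision_0.5": self.precision(), "Recall_0.5": self.recall(),
            "F1_0.5": self.f1(),
            "AP_0.5": self.ap(0.5), "AP_0.75": self.ap(0.75),
            "avAP": self.av_ap,
            "identity_swaps_non_ctc": self.identity_swaps,
        }


def evaluate_stacks(pred_labels: np.ndarray, gt_labels: np.ndarray,
                    pred_tree: LineageTree | None = None,
                    gt_tree: LineageTree | None = None) -> EvalReport:
    """Evaluate predicted vs ground-truth label stacks ``(T, H, W)``."""
    if pred_labels.shape != gt_labels.shape:
        raise ValueError("stacks must share a shape")
    totals = {t: DetectionCounts(t) for t in IOU_THRESHOLDS}
    pred_frames, gt_frames = [], []
    n_gt = 0
    for pl, gl in zip(pred_labels, gt_labels):
        preds = masks_from_labels(pl)
        gts = masks_from_labels(gl)
        pred_frames.append(preds)
        gt_frames.append(gts)
        n_gt += len(gts)
        for t in IOU_THRESHOLDS:
            counts, _ = match_instances(preds, gts, t)
            totals[t] = totals[t] + counts
    report = EvalReport(counts=totals,
                        seg=seg_measure(pred_frames, gt_frames),
                        n_gt_objects=n_gt)
    if pred_tree is not None and gt_tree is not None:
        report.identity_swaps = count_identity_swaps(
            pred_tree, gt_tree, n_frames=pred_labels.shape[0])
    return report
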