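"""Detection and segmentation evaluation: IoU matching, AP and AR.

The protocol follows the de-facto detection-benchmark convention:
predictions are ranked by confidence; at each IoU threshold every
prediction greedily claims the highest-IoU still-unmatched ground truth
on its image (one-to-one); matched predictions are true positives,
unmatched ones false positives, unclaimed truths false negatives.  AP is
the mean of interpolated precision at 101 equally spaced recall points
(interpolated precision at recall r = max precision at recall >= r);
``interpolation="all_points"`` switches to the exact area under the
interpolated PR curve.  AR is TP / (TP + FN) at the full detection
budget.  Headline numbers average the 10 thresholds 0.5:0.05:0.95 and
are reported as percentages.

Boxes and masks are scored as separate tasks; box IoU uses rectangle
areas, mask IoU is pixelwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import InstanceMask, ValidationError

IOU_THRESHOLDS = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


def iou(a: InstanceMask, b: InstanceMask, mode: str = "mask") -> float:
    """Intersection over union of two instances, as boxes or masks.

    Symmetric; defined as 0 when both regions are empty.
    """
    if mode == "bbox":
        ax, ay, aw, ah = a.bbox
        bx, by, bw, bh = b.bbox
        ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
        iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
        inter = ix * iy
        union = aw * ah + bw * bh - inter
    elif mode == "mask":
        inter = float(np.logical_and(a.mask, b.mask).sum())
        union = float(np.logical_or(a.mask, b.mask).sum())
    else:
        raise ValueError(f"unknown IoU mode {mode!r}")
    return inter / union if union > 0 else 0.0


def _iou_matrix(preds, gts, mode: str) -> np.ndarray:
    return np.array([[iou(p, g, mode) for g in gts] for p in preds]).reshape(
        len(preds), len(gts)
    )


def _score_order(preds) -> list[int]:
    # descending score; ties broken by stable input order
    return sorted(range(len(preds)), key=lambda i: -preds[i].score)


def match_at_threshold(
    predictions: list[InstanceMask],
    ground_truth: list[InstanceMask],
    thr: float,
    mode: str = "mask",
    iou_matrix: np.ndarray | None = None,
):
    """Greedy one-to-one matching at one IoU threshold (single image).

    Returns ``(tp, fp, fn, assignment)`` where assignment maps prediction
    index -> ground-truth index for every true positive.
    """
    if iou_matrix is None:
        iou_matrix = _iou_matrix(predictions, ground_truth, mode)
    taken = np.zeros(len(ground_truth), dtype=bool)
    assignment: dict[int, int] = {}
    for pi in _score_order(predictions):
        candidates = [
            (iou_matrix[pi, gi], -gi)
            for gi in range(len(ground_truth))
            if not taken[gi] and iou_matrix[pi, gi] >= thr
        ]
        if candidates:
            _, neg_gi = max(candidates)  # highest IoU, ties to lowest gt index
            taken[-neg_gi] = True
            assignment[pi] = -neg_gi
    tp = len(assignment)
    fp = len(predictions) - tp
    fn = len(ground_truth) - tp
    return tp, fp, fn, assignment


def _match_scenes(predictions, ground_truth, thr, mode):
    """Per-image greedy matching; returns global (is_tp flags in input
    order, n_gt)."""
    images = sorted(
        {p.image_id for p in predictions} | {g.image_id for g in ground_truth}
    )
    is_tp = np.zeros(len(predictions), dtype=bool)
    n_gt = len(ground_truth)
    by_img_pred: dict[str, list[int]] = {im: [] for im in images}
    for i, p in enumerate(predictions):
        by_img_pred[p.image_id].append(i)
    by_img_gt: dict[str, list[InstanceMask]] = {im: [] for im in images}
    for g in ground_truth:
        by_img_gt[g.image_id].append(g)
    for im in images:
        pidx = by_img_pred[im]
        gts = by_img_gt[im]
        if not pidx or not gts:
            continue
        preds = [predictions[i] for i in pidx]
        _, _, _, assignment = match_at_threshold(preds, gts, thr, mode)
        for local_pi in assignment:
            is_tp[pidx[local_pi]] = True
    return is_tp, n_gt


def _precision_recall_curve(scores, is_tp, n_gt):
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    tp_cum = np.cumsum([is_tp[i] for i in order])
    fp_cum = np.cumsum([not is_tp[i] for i in order])
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    return recall, precision


def _ap_from_curve(recall, precision, interpolation: str) -> float:
    # interpolated precision: running max from the right
    mrec = np.concatenate(([0.0], recall, [recall[-1] if recall.size else 0.0]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    if interpolation == "101point":
        grid = np.linspace(0.0, 1.0, 101)
        interp = np.zeros_like(grid)
        for i, r in enumerate(grid):
            idx = np.searchsorted(mrec, r, side="left")
            interp[i] = mpre[idx] if idx < mpre.size else 0.0
        return float(interp.mean())
    if interpolation == "all_points":
        ap = 0.0
        for i in range(1, mrec.size):
            ap += (mrec[i] - mrec[i - 1]) * mpre[i]
        return float(ap)
    raise ValueError(f"unknown interpolation {interpolation!r}")


def average_precision(
    predictions,
    ground_truth,
    thr: float,
    mode: str = "mask",
    interpolation: str = "101point",
) -> float:
    """AP at one IoU threshold over one or more images, in [0, 1]."""
    if not ground_truth:
        raise ValidationError("AP undefined with zero ground-truth instances")
    if not predictions:
        return 0.0
    is_tp, n_gt = _match_scenes(predictions, ground_truth, thr, mode)
    scores = [p.score for p in predictions]
    recall, precision = _precision_recall_curve(scores, is_tp, n_gt)
    return _ap_from_curve(recall, precision, interpolation)


def average_recall(predictions, ground_truth, thr: float, mode: str = "mask") -> float:
    """Recall TP/(TP+FN) at the full detection budget, one threshold."""
    if not ground_truth:
        raise ValidationError("AR undefined with zero ground-truth instances")
    if not predictions:
        return 0.0
    is_tp, n_gt = _match_scenes(predictions, ground_truth, thr, mode)
    return float(is_tp.sum()) / n_gt


@dataclass
class EvalReport:
    """AP/AR summary per task, as percentages, plus per-threshold counts."""

    detection: dict
    segmentation: dict
    counts: dict = field(default_factory=dict)  # task -> thr -> (tp, fp, fn)

    METRIC_ORDER = ("AP_50_95", "AP_50", "AP_75", "AR_50_95")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"Metric": "Detection", **{m: self.detection[m] for m in self.METRIC_ORDER}},
            {"Metric": "Segmentation", **{m: self.segmentation[m] for m in self.METRIC_ORDER}},
        ]
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        doc = {
            "detection": self.detection,
            "segmentation": self.segmentation,
            "counts": {
                task: {str(t): list(v) for t, v in thrs.items()}
                for task, thrs in self.counts.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.1f")


def evaluate(
    predictions,
    ground_truth,
    interpolation: str = "101point",
) -> EvalReport:
    """Full protocol: AP@0.5, AP@0.75, AP and AR over 0.5:0.05:0.95,
    separately for boxes (detection) and masks (segmentation), as
    percentages."""
    if not predictions or not ground_truth:
        raise ValidationError("evaluate requires nonempty predictions and ground truth")
    report = {}
    counts = {}
    for task, mode in (("detection", "bbox"), ("segmentation", "mask")):
        aps = {}
        ars = {}
        task_counts = {}
        for thr in IOU_THRESHOLDS:
            aps[thr] = average_precision(predictions, ground_truth, thr, mode, interpolation)
            is_tp, n_gt = _match_scenes(predictions, ground_truth, thr, mode)
            tp = int(is_tp.sum())
            task_counts[thr] = (tp, len(predictions) - tp, n_gt - tp)
            ars[thr] = tp / n_gt
        report[task] = {
            "AP_50": 100.0 * aps[0.5],
            "AP_75": 100.0 * aps[0.75],
            "AP_50_95": 100.0 * float(np.mean(list(aps.values()))),
            "AR_50_95": 100.0 * float(np.mean(list(ars.values()))),
        }
        counts[task] = task_counts
    return EvalReport(
        detection=report["detection"], segmentation=report["segmentation"], counts=counts
    )
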