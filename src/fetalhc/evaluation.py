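"""Evaluation: HC error statistics, rotated-ellipse AP, Bland-Altman agreement.

``mae_me`` reports the mean absolute and mean signed error of predicted
head circumference (pred - gt, mm) with standard deviations; matching
for average precision uses the rasterized rotated-ellipse IOU (default
threshold 0.5) with greedy score-descending assignment and all-point
interpolation of the precision-recall curve; Bland-Altman analysis
reports the mean difference and the mean +- 1.96 sd limits of agreement
together with the (mean, difference) pairs for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Ellipse, ellipse_iou
from .inference import ScoredEllipse

__all__ = ["EvalReport", "mae_me", "average_precision", "bland_altman"]


@dataclass
class EvalReport:
    mae_mm: float
    mae_sd_mm: float
    me_mm: float
    me_sd_mm: float
    ap: float | None
    bland_altman: tuple[float, float, float] | None
    n: int
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "mae_mm": self.mae_mm, "mae_sd_mm": self.mae_sd_mm,
            "me_mm": self.me_mm, "me_sd_mm": self.me_sd_mm,
            "ap": self.ap, "bland_altman": self.bland_altman, "n": self.n,
            **self.meta,
        }


def _check_pair(pred, gt, min_n=1):
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape or pred.ndim != 1:
        raise ValueError("pred and gt must be equal-length 1-D sequences")
    if pred.size < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return pred, gt


def mae_me(pred_hc, gt_hc, ddof: int = 1):
    """Mean absolute error and mean (signed, pred - gt) error, each with sd.

    ``ddof=1`` gives the sample standard deviation (the default
    convention recorded in config); single-element inputs report sd 0.
    """
    pred, gt = _check_pair(pred_hc, gt_hc)
    diff = pred - gt
    sd = (lambda x: float(np.std(x, ddof=ddof)) if x.size > ddof else 0.0)
    return (float(np.mean(np.abs(diff))), sd(np.abs(diff)),
            float(np.mean(diff)), sd(diff))


def bland_altman(pred_hc, gt_hc, ddof: int = 1):
    """Mean difference and 1.96-sd limits of agreement.

    Returns ``(mean_diff, loa_low, loa_high, pairs)`` where ``pairs`` is
    the (mean, difference) scatter data for the agreement plot.
    """
    pred, gt = _check_pair(pred_hc, gt_hc, min_n=2)
    diff = pred - gt
    mean_diff = float(np.mean(diff))
    sd = float(np.std(diff, ddof=ddof))
    pairs = np.column_stack([(pred + gt) / 2.0, diff])
    return mean_diff, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd, pairs


def average_precision(preds: list[list[ScoredEllipse]], gts: list[list[Ellipse]],
                      iou_threshold: float = 0.5, iou_resolution: float = 2.0) -> float:
    """All-point interpolated AP with greedy rotated-IOU matching.

    ``preds[i]`` / ``gts[i]`` are the detections and ground truths of
    image i.  Detections are ranked by score across all images; each is
    a true positive iff its best rotated-ellipse IOU against a
    still-unmatched GT of its image reaches the threshold.
    """
    if len(preds) != len(gts):
        raise ValueError("preds and gts must cover the same images")
    n_gt = sum(len(g) for g in gts)
    if n_gt == 0:
        raise ValueError("AP undefined without ground-truth objects")
    flat = [(d.score, i, d) for i, dets in enumerate(preds) for d in dets]
    flat.sort(key=lambda t: -t[0])
    matched: list[set[int]] = [set() for _ in gts]
    tp = np.zeros(len(flat))
    for rank, (_, img, det) in enumerate(flat):
        best_iou, best_j = 0.0, None
        for j, gt in enumerate(gts[img]):
            if j in matched[img]:
                continue
            iou = ellipse_iou(det.ellipse, gt, resolution=iou_resolution)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j is not None and best_iou >= iou_threshold:
            tp[rank] = 1.0
            matched[img].add(best_j)
    if len(flat) == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, len(flat) + 1)
    recall = cum_tp / n_gt
    # all-point interpolation: running max of precision from the right
    precision = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for p, r in zip(precision, recall):
        ap += p * (r - prev_r)
        prev_r = r
    return float(ap)
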