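"""Segmentation evaluation metrics for single-instance binary masks.

Per-pair overlap metrics (IoU/Jaccard, Dice, precision, recall and the
complementary over-/under-segmentation rates) plus a COCO-style average
precision over IoU thresholds 0.50:0.05:0.95 restricted to the
one-instance-per-image setting, and unweighted aggregation to means.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean

import numpy as np

__all__ = [
    "SegPairEval",
    "SegAggregate",
    "IOU_THRESHOLDS",
    "pair_metrics",
    "average_precision",
    "aggregate",
]

IOU_THRESHOLDS = np.round(np.arange(0.50, 0.951, 0.05), 2)


@dataclass(frozen=True)
class SegPairEval:
    """Pixel-overlap metrics for one predicted/ground-truth mask pair.

    over_seg = 1 − precision is the fraction of predicted pixels outside
    the ground truth; under_seg = 1 − recall is the fraction of ground
    truth the prediction misses.
    """

    tp: int
    fp: int
    fn: int
    iou: float
    dsc: float
    precision: float
    recall: float
    over_seg: float
    under_seg: float


@dataclass(frozen=True)
class SegAggregate:
    """Unweighted means of per-pair metrics plus the dataset AP."""

    m_iou: float
    m_dsc: float
    m_ap: float
    mean_precision: float
    mean_recall: float
    mean_over_seg: float
    mean_under_seg: float
    n_pairs: int


def pair_metrics(pred: np.ndarray, gt: np.ndarray) -> SegPairEval:
    """Compute overlap metrics between a predicted and ground-truth mask.

    Precision is defined as 0 for an empty prediction so aggregation
    stays total; an empty ground truth is rejected (the metrics would
    be undefined).
    """
    pred = np.asarray(pred) > 0
    gt = np.asarray(gt) > 0
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if not gt.any():
        raise ValueError("ground-truth mask has no foreground pixels")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    iou = tp / (tp + fp + fn)
    dsc = 2 * tp / (2 * tp + fp + fn)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn)
    return SegPairEval(
        tp=tp,
        fp=fp,
        fn=fn,
        iou=iou,
        dsc=dsc,
        precision=precision,
        recall=recall,
        over_seg=1.0 - precision,
        under_seg=1.0 - recall,
    )


def average_precision(
    pairs: list[tuple[np.ndarray, float, np.ndarray]],
    iou_thresholds: np.ndarray = IOU_THRESHOLDS,
) -> float:
    """COCO-style AP averaged over IoU thresholds, one instance per image.

    ``pairs`` holds (predicted mask, confidence score, ground-truth
    mask) per image. At each threshold detections are ranked by score;
    a detection is a true positive iff its IoU with its image's ground
    truth meets the threshold (each ground truth matchable once — here
    automatic, one detection per image). AP at a threshold is the area
    under the precision–recall curve with the usual all-point (envelope)
    interpolation; the returned value is the mean over thresholds. For
    a single image this reduces to (#thresholds passed) / #thresholds.
    """
    if not pairs:
        raise ValueError("need at least one (pred, score, gt) pair")
    ious = np.array([pair_metrics(pred, gt).iou for pred, _, gt in pairs])
    scores = np.array([s for _, s, _ in pairs], dtype=float)
    order = np.argsort(-scores, kind="stable")
    ious = ious[order]
    n_gt = len(pairs)

    aps = []
    for t in iou_thresholds:
        tp = (ious >= t).astype(float)
        cum_tp = np.cumsum(tp)
        ranks = np.arange(1, n_gt + 1)
        precision = cum_tp / ranks
        recall = cum_tp / n_gt
        # precision envelope, then sum precision at recall steps
        prec_env = np.maximum.accumulate(precision[::-1])[::-1]
        recall_prev = np.concatenate([[0.0], recall[:-1]])
        aps.append(float(np.sum((recall - recall_prev) * prec_env)))
    return float(np.mean(aps))


def aggregate(evals: list[SegPairEval], ap: float) -> SegAggregate:
    """Unweighted arithmetic means of per-pair metrics; AP passes through."""
    if not evals:
        raise ValueError("need at least one pair evaluation")
    return SegAggregate(
        m_iou=fmean(e.iou for e in evals),
        m_dsc=fmean(e.dsc for e in evals),
        m_ap=ap,
        mean_precision=fmean(e.precision for e in evals),
        mean_recall=fmean(e.recall for e in evals),
        mean_over_seg=fmean(e.over_seg for e in evals),
        mean_under_seg=fmean(e.under_seg for e in evals),
        n_pairs=len(evals),
    )
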