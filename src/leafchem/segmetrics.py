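"""Instance-segmentation evaluation: mask IoU, AP, mAP50, mAP50-95, mIoU.

Single-category ("leaf") evaluation.  Matching is greedy in descending
prediction score: each ground-truth mask may be claimed by at most one
prediction, a prediction is a true positive when its best free ground truth
overlaps at IoU >= threshold.  AP is the area under the all-point
interpolated precision-recall curve.  mAP50-95 averages AP over the ten IoU
thresholds 0.50, 0.55, ..., 0.95.  mIoU is the mean, over ground-truth
leaves, of the IoU achieved by the leaf's greedily matched prediction
(unmatched leaves contribute 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

IOU_THRESHOLDS = np.arange(0.50, 0.96, 0.05).round(2)


@dataclass
class Prediction:
    mask: np.ndarray
    score: float
    image_id: str = "0"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class SegEvalReport:
    mAP50: float
    mAP50_95: float
    mIoU: float
    detail: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {"mAP50": self.mAP50, "mAP50_95": self.mAP50_95, "mIoU": self.mIoU}


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks of equal shape."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("IoU undefined: both masks empty")
    return np.count_nonzero(a & b) / union


def _greedy_match(predictions: list[Prediction], gts: list[np.ndarray],
                  iou_threshold: float) -> tuple[list[bool], dict[int, tuple[int, float]]]:
    """Greedy score-descending matching within one image.

    Returns per-prediction TP flags (in score order) and a map
    ``gt index -> (prediction rank, IoU)`` for the matched ground truths.
    """
    order = np.argsort([-p.score for p in predictions], kind="stable")
    taken: set[int] = set()
    tp_flags: list[bool] = []
    matches: dict[int, tuple[int, float]] = {}
    for rank, pi in enumerate(order):
        pred = predictions[pi]
        best_iou, best_gt = 0.0, -1
        for gi, gt in enumerate(gts):
            if gi in taken:
                continue
            iou = mask_iou(pred.mask, gt) if (pred.mask.any() or gt.any()) else 0.0
            if iou > best_iou:
                best_iou, best_gt = iou, gi
        if best_gt >= 0 and best_iou >= iou_threshold:
            taken.add(best_gt)
            matches[best_gt] = (rank, best_iou)
            tp_flags.append(True)
        else:
            tp_flags.append(False)
    return tp_flags, matches


def average_precision(tp_flags: np.ndarray, scores: np.ndarray, n_gt: int) -> float:
    """AP from per-prediction TP flags: all-point interpolated PR area."""
    if n_gt == 0:
        raise ValueError("AP undefined with no ground truths")
    if len(tp_flags) == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = np.asarray(tp_flags, dtype=float)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope + sum over recall increments
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.where(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def match_and_ap(predictions: list[Prediction], gts: list[np.ndarray],
                 iou_threshold: float, image_ids: list[str] | None = None) -> float:
    """AP at one IoU threshold over one or more images.

    ``predictions`` carry an ``image_id``; ``image_ids`` gives the id of each
    ground-truth mask (defaults to a single shared image).
    """
    if image_ids is None:
        image_ids = ["0"] * len(gts)
    all_flags, all_scores = [], []
    for img in sorted({*image_ids, *(p.image_id for p in predictions)}):
        img_preds = [p for p in predictions if p.image_id == img]
        img_gts = [g for g, i in zip(gts, image_ids) if i == img]
        flags, _ = _greedy_match(img_preds, img_gts, iou_threshold)
        order = np.argsort([-p.score for p in img_preds], kind="stable")
        all_flags.extend(flags)
        all_scores.extend(img_preds[i].score for i in order)
    return average_precision(np.array(all_flags), np.array(all_scores), n_gt=len(gts))


def evaluate(predictions: list[Prediction], gts: list[np.ndarray],
             image_ids: list[str] | None = None) -> SegEvalReport:
    """Full report: mAP50, mAP50-95 (10 thresholds), mIoU, per-image detail."""
    if len(gts) == 0:
        raise ValueError("evaluation needs at least one ground-truth mask")
    if image_ids is None:
        image_ids = ["0"] * len(gts)
    aps = {t: match_and_ap(predictions, gts, t, image_ids) for t in IOU_THRESHOLDS}
    # mIoU: greedy best-match at threshold 0 (any positive overlap counts)
    rows = []
    ious = []
    for img in sorted(set(image_ids)):
        img_preds = [p for p in predictions if p.image_id == img]
        img_gts = [g for g, i in zip(gts, image_ids) if i == img]
        _, matches = _greedy_match(img_preds, img_gts, iou_threshold=1e-12)
        for gi in range(len(img_gts)):
            iou = matches.get(gi, (None, 0.0))[1]
            ious.append(iou)
            rows.append({"image_id": img, "gt_index": gi, "best_iou": iou,
                         "matched": gi in matches})
    return SegEvalReport(
        mAP50=aps[0.50],
        mAP50_95=float(np.mean([aps[t] for t in IOU_THRESHOLDS])),
        mIoU=float(np.mean(ious)),
        detail=pd.DataFrame(rows),
    )


def masks_from_label(label: np.ndarray) -> list[np.ndarray]:
    """Split a label image (0 = background) into per-instance boolean masks."""
    return [label == k for k in np.unique(label) if k != 0]
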