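"""Detection metrics: IoU, greedy matching, AP/mAP, F1, and k-fold splits.

AP uses the continuous all-point interpolation (area under the precision
envelope over recall).  An IoU threshold of exactly 0 switches matching to
any-overlap mode — a detection counts as correct if it touches a same-class
ground-truth box at all, which treats detection as a classification task.
mAP averages only classes with at least one ground-truth instance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .voc import BoundingBox


def iou(a: BoundingBox | np.ndarray, b: BoundingBox | np.ndarray) -> float:
    """Intersection-over-union of two xyxy boxes; 0 when disjoint."""
    a = a.as_xyxy() if isinstance(a, BoundingBox) else np.asarray(a, dtype=np.float64)
    b = b.as_xyxy() if isinstance(b, BoundingBox) else np.asarray(b, dtype=np.float64)
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0:
        return 0.0
    union = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return float(inter / union)


def match_detections(
    det_boxes: np.ndarray,
    det_scores: np.ndarray,
    gt_boxes: np.ndarray,
    iou_threshold: float = 0.5,
) -> np.ndarray:
    """Greedy TP/FP flags for same-class detections against one image's GT.

    Detections are visited in confidence order; each claims the unmatched GT
    box with the highest IoU, provided IoU >= threshold (strictly > 0 in
    any-overlap mode when threshold == 0).  Each GT matches at most once.
    """
    det_boxes = np.asarray(det_boxes, dtype=np.float64).reshape(-1, 4)
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    order = np.argsort(-np.asarray(det_scores), kind="stable")
    flags = np.zeros(len(det_boxes), dtype=bool)
    used = np.zeros(len(gt_boxes), dtype=bool)
    for i in order:
        best_j, best_iou = -1, 0.0
        for j in range(len(gt_boxes)):
            if used[j]:
                continue
            v = iou(det_boxes[i], gt_boxes[j])
            if v > best_iou:
                best_iou, best_j = v, j
        ok = best_iou > 0.0 if iou_threshold == 0 else best_iou >= iou_threshold
        if best_j >= 0 and ok:
            flags[i] = True
            used[best_j] = True
    return flags


def average_precision(flags: np.ndarray, scores: np.ndarray, n_gt: int) -> float:
    """All-point interpolated AP from per-detection TP flags and confidences.

    Returns NaN when the class has no ground truth and no detections
    (undefined; excluded from mAP by the caller).
    """
    flags = np.asarray(flags, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    if n_gt == 0:
        return np.nan if len(flags) == 0 else 0.0
    if len(flags) == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(flags[order])
    fp = np.cumsum(~flags[order])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope, integrated over recall
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    ap: float
    f1: float
    tp: int
    fp: int
    fn: int


@dataclass
class EvalResult:
    iou_threshold: float
    per_class: dict[str, ClassMetrics]
    mAP: float


def evaluate(
    detections_per_image: list[list],
    gts_per_image: list[list[BoundingBox]],
    class_names: list[str],
    iou_thresholds: tuple[float, ...] = (0.5,),
    conf_threshold: float = 0.25,
) -> list[EvalResult]:
    """Aggregate P/R/AP/F1 per class and mAP at each IoU threshold.

    ``detections_per_image`` holds per-image lists of objects with ``box``
    (BoundingBox), ``class_id`` or a class-labeled box, and ``confidence``.
    P/R/F1 are computed at ``conf_threshold``; AP over all confidences.
    """
    known = set(class_names)
    for dets in detections_per_image:
        for d in dets:
            label = _det_label(d, class_names)
            if label not in known:
                raise ValueError(f"detection class {label!r} not in class list")
    results = []
    for thr in iou_thresholds:
        per_class: dict[str, ClassMetrics] = {}
        aps = []
        for label in class_names:
            flags_all, scores_all = [], []
            n_gt = 0
            tp_at = fp_at = 0
            for dets, gts in zip(detections_per_image, gts_per_image):
                gt_sel = np.array(
                    [g.as_xyxy() for g in gts if g.class_label == label]
                ).reshape(-1, 4)
                n_gt += len(gt_sel)
                d_sel = [d for d in dets if _det_label(d, class_names) == label]
                boxes = np.array([d.box.as_xyxy() for d in d_sel]).reshape(-1, 4)
                scores = np.array([d.confidence for d in d_sel])
                flags = match_detections(boxes, scores, gt_sel, thr)
                flags_all.append(flags)
                scores_all.append(scores)
                conf_mask = scores >= conf_threshold
                # recompute matching among confident detections only for P/R
                flags_conf = match_detections(boxes[conf_mask], scores[conf_mask], gt_sel, thr)
                tp_at += int(flags_conf.sum())
                fp_at += int((~flags_conf).sum())
            flags_cat = np.concatenate(flags_all) if flags_all else np.zeros(0, bool)
            scores_cat = np.concatenate(scores_all) if scores_all else np.zeros(0)
            ap = average_precision(flags_cat, scores_cat, n_gt)
            fn = n_gt - tp_at
            prec = tp_at / (tp_at + fp_at) if (tp_at + fp_at) else 0.0
            rec = tp_at / n_gt if n_gt else 0.0
            f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
            per_class[label] = ClassMetrics(prec, rec, ap, f1, tp_at, fp_at, fn)
            if n_gt > 0:
                aps.append(ap)
        results.append(
            EvalResult(
                iou_threshold=thr,
                per_class=per_class,
                mAP=float(np.mean(aps)) if aps else 0.0,
            )
        )
    return results


def _det_label(d, class_names: list[str]) -> str:
    if hasattr(d, "class_id") and d.class_id is not None and d.class_id < len(class_names):
        return class_names[d.class_id]
    return d.box.class_label


def kfold_splits(
    records: list[dict], k: int = 5, seed: int = 0
) -> list[tuple[list[dict], list[dict]]]:
    """Class-stratified k-fold (train, test) manifest pairs."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_class.setdefault(rec.get("class", ""), []).append(i)
    fold_of = np.zeros(len(records), dtype=int)
    for label in sorted(by_class):
        idxs = np.array(by_class[label])
        if len(idxs) < k:
            import warnings

            warnings.warn(f"class {label!r} has fewer than {k} items")
        perm = rng.permutation(len(idxs))
        offset = int(rng.integers(k))  # rotate remainders so folds stay balanced
        for pos, j in enumerate(perm):
            fold_of[idxs[j]] = (pos + offset) % k
    out = []
    for f in range(k):
        test = [rec for i, rec in enumerate(records) if fold_of[i] == f]
        train = [rec for i, rec in enumerate(records) if fold_of[i] != f]
        out.append((train, test))
    return out
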