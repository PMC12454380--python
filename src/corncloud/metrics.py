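"""Semantic and instance evaluation metrics, reported as percentages.

Semantic: overall accuracy, precision/recall of the seedling (positive)
class, per-class IoU and their mean (mIoU). Instance: micro-averaged
precision/recall/F1 over Hungarian-matched clusters and iIoU, the mean IoU
over ground-truth instances (unmatched truth instances contribute 0).
Degenerate denominators yield 0 with an ``undefined`` flag rather than NaN.
"""

from __future__ import annotations

import numpy as np

__all__ = ["confusion_counts", "semantic_metrics", "instance_metrics"]


def _ratio(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return 100.0 * num / den


def confusion_counts(pred: np.ndarray, truth: np.ndarray, positive: int = 1) -> dict:
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("label sequences differ in length")
    tp = int(((pred == positive) & (truth == positive)).sum())
    fp = int(((pred == positive) & (truth != positive)).sum())
    fn = int(((pred != positive) & (truth == positive)).sum())
    tn = int(((pred != positive) & (truth != positive)).sum())
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def semantic_metrics(pred_labels: np.ndarray, true_labels: np.ndarray) -> dict:
    """Acc, Pre, Rec (seedling class) and mIoU over both classes, in percent.

    Acc = (TP+TN)/total, Pre = TP/(TP+FP), Rec = TP/(TP+FN),
    IoU_c = TP_c/(TP_c+FP_c+FN_c), mIoU = mean over the two classes.
    """
    pred = np.asarray(pred_labels).ravel()
    truth = np.asarray(true_labels).ravel()
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != truth.shape:
        raise ValueError("label sequences differ in length")
    flags: list[str] = []
    cc = confusion_counts(pred, truth, positive=1)
    total = cc["tp"] + cc["fp"] + cc["fn"] + cc["tn"]
    acc = 100.0 * (cc["tp"] + cc["tn"]) / total
    pre = _ratio(cc["tp"], cc["tp"] + cc["fp"], flags, "pre")
    rec = _ratio(cc["tp"], cc["tp"] + cc["fn"], flags, "rec")
    per_class_iou = []
    for c in (0, 1):
        c_ = confusion_counts(pred, truth, positive=c)
        per_class_iou.append(
            _ratio(c_["tp"], c_["tp"] + c_["fp"] + c_["fn"], flags, f"iou_{c}"))
    return {
        "acc": acc, "pre": pre, "rec": rec,
        "miou": float(np.mean(per_class_iou)),
        "per_class_iou": per_class_iou,
        "undefined": flags,
        "counts": cc,
    }


def instance_metrics(pred_labels: np.ndarray, true_labels: np.ndarray,
                     matching: dict[int, int]) -> dict:
    """Micro-averaged instance Pre/Rec/F1 and iIoU, in percent.

    ``pred_labels`` uses −1 for noise and 0..K−1 for clusters;
    ``true_labels`` uses 0 for background and 1..M for plants. ``matching``
    maps predicted cluster id → truth instance id (from
    :func:`corncloud.instseg.match_instances`). Per matched pair TP is the
    shared point count, FP predicted-only, FN truth-only; noise points count
    toward FN of their truth instance and never as FP. iIoU averages IoU over
    all M truth instances, 0 for unmatched ones.
    """
    pred = np.asarray(pred_labels).ravel()
    truth = np.asarray(true_labels).ravel()
    if pred.shape != truth.shape:
        raise ValueError("label sequences differ in length")
    truth_ids = [int(t) for t in np.unique(truth) if t > 0]
    matched_truth = {t: p for p, t in matching.items()}
    flags: list[str] = []
    tp_sum = fp_sum = fn_sum = 0
    per_instance_iou = []
    for t in truth_ids:
        t_mask = truth == t
        p = matched_truth.get(t)
        if p is None:
            per_instance_iou.append(0.0)
            fn_sum += int(t_mask.sum())
            continue
        p_mask = pred == p
        tp = int((t_mask & p_mask).sum())
        fp = int((p_mask & ~t_mask).sum())
        fn = int((t_mask & ~p_mask).sum())
        tp_sum += tp
        fp_sum += fp
        fn_sum += fn
        per_instance_iou.append(
            100.0 * tp / (tp + fp + fn) if (tp + fp + fn) else 0.0)
    # predicted clusters with no matched truth instance are pure false positives
    for p in (int(c) for c in np.unique(pred) if c >= 0):
        if p not in matching:
            fp_sum += int((pred == p).sum())
    pre = _ratio(tp_sum, tp_sum + fp_sum, flags, "pre")
    rec = _ratio(tp_sum, tp_sum + fn_sum, flags, "rec")
    f1 = 2 * pre * rec / (pre + rec) if (pre + rec) > 0 else 0.0
    iiou = float(np.mean(per_instance_iou)) if per_instance_iou else 0.0
    return {
        "pre": pre, "rec": rec, "f1": f1, "iiou": iiou,
        "per_instance_iou": per_instance_iou,
        "undefined": flags,
    }
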