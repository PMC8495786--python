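"""Classifier performance metrics.

Per-class one-vs-rest precision, recall and F-beta, reported as
macro-averages so rare classes carry equal weight, plus the area under the
precision-recall curve (step-wise rule, no interpolation) and the
true-positive / false-positive score-density summary used to judge how
well the detection threshold separates correct from incorrect detections.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

log = logging.getLogger(__name__)


def confusion_matrix(true_labels: Sequence, predicted_labels: Sequence,
                     classes: Sequence) -> np.ndarray:
    """Confusion matrix with rows = true labels, columns = predicted.

    Raises on labels outside ``classes``.
    """
    classes = list(classes)
    seen = set(true_labels) | set(predicted_labels)
    unknown = seen - set(classes)
    if unknown:
        raise ValueError(f"labels outside class set: {sorted(map(str, unknown))}")
    return _sk_confusion(true_labels, predicted_labels, labels=classes)


def macro_metrics(cm: np.ndarray, beta: float = 1.0) -> dict:
    """Per-class and macro precision/recall/F-beta from a confusion matrix.

    Precision = diagonal / column sum; recall = diagonal / row sum (rows
    are true labels).  A class with zero predicted (or zero true)
    instances contributes 0 to the affected metric, with a warning.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.size == 0 or cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(cm)
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    if np.any(col == 0) or np.any(row == 0):
        log.warning("degenerate class with zero predicted or true instances; metric set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
        b2 = beta * beta
        denom = b2 * precision + recall
        f = np.where(denom > 0, (1 + b2) * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return {
        "precision": precision,
        "recall": recall,
        "f": f,
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f.mean()),
    }


def pr_curve(true_binary: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision-recall pairs at every distinct score threshold.

    Returns (precision, recall, thresholds) sweeping the threshold from
    high to low; recall is non-decreasing along the output.
    """
    true_binary = np.asarray(true_binary).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if true_binary.sum() == 0:
        raise ValueError("pr_curve needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    yt = true_binary[order]
    ss = scores[order]
    tp = np.cumsum(yt)
    fp = np.cumsum(~yt)
    # evaluate only at the last index of each tied score block
    last = np.flatnonzero(np.r_[np.diff(ss) != 0, True])
    precision = tp[last] / (tp[last] + fp[last])
    recall = tp[last] / true_binary.sum()
    return precision, recall, ss[last]


def pr_curve_auc(true_binary: np.ndarray, scores: np.ndarray) -> float:
    """Area under the PR curve by the step-wise (interpolation-free) rule:
    ``sum (R_i - R_{i-1}) * P_i`` over thresholds from high to low."""
    precision, recall, _ = pr_curve(true_binary, scores)
    prev_r = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_r) * precision))


def macro_pr_auc(true_labels: Sequence, score_matrix: np.ndarray, classes: Sequence) -> float:
    """One-vs-rest prAUC per class, macro-averaged.

    Classes with no positive instances are reported as missing (skipped
    with a warning) rather than contributing a defined value.
    """
    true_labels = np.asarray(true_labels)
    aucs = []
    for j, cls in enumerate(classes):
        yb = true_labels == cls
        if yb.sum() == 0:
            log.warning("class %r has no positives; prAUC undefined, skipped", cls)
            continue
        aucs.append(pr_curve_auc(yb, score_matrix[:, j]))
    if not aucs:
        raise ValueError("no class has positive instances")
    return float(np.mean(aucs))


def metrics_report(true_labels: Sequence, predicted_labels: Sequence,
                   score_matrix: np.ndarray | None, classes: Sequence,
                   beta: float = 1.0) -> pd.DataFrame:
    """Per-class metric table (+ macro row)."""
    cm = confusion_matrix(true_labels, predicted_labels, classes)
    mm = macro_metrics(cm, beta)
    rows = []
    for i, cls in enumerate(classes):
        row = {"class": str(cls), "precision": mm["precision"][i],
               "recall": mm["recall"][i], "f1": mm["f"][i]}
        if score_matrix is not None:
            yb = np.asarray(true_labels) == cls
            row["prauc"] = pr_curve_auc(yb, score_matrix[:, i]) if yb.sum() else np.nan
        rows.append(row)
    macro = {"class": "macro", "precision": mm["macro_precision"],
             "recall": mm["macro_recall"], "f1": mm["macro_f1"]}
    if score_matrix is not None:
        macro["prauc"] = macro_pr_auc(true_labels, score_matrix, classes)
    rows.append(macro)
    return pd.DataFrame(rows)


def score_density_summary(scores: np.ndarray, is_true_positive: np.ndarray,
                          bins: int = 20) -> dict:
    """Normalized TP vs FP histograms of detection scores + overlap.

    The overlap statistic is the summed bin-wise minimum of the two
    normalized densities (1 = identical, 0 = disjoint).
    """
    scores = np.asarray(scores, dtype=float)
    is_tp = np.asarray(is_true_positive).astype(bool)
    edges = np.linspace(0.0, 1.0, bins + 1)
    tp_hist, _ = np.histogram(scores[is_tp], bins=edges)
    fp_hist, _ = np.histogram(scores[~is_tp], bins=edges)
    tp_d = tp_hist / tp_hist.sum() if tp_hist.sum() else tp_hist.astype(float)
    fp_d = fp_hist / fp_hist.sum() if fp_hist.sum() else fp_hist.astype(float)
    return {
        "edges": edges,
        "tp_density": tp_d,
        "fp_density": fp_d,
        "overlap": float(np.minimum(tp_d, fp_d).sum()),
    }
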