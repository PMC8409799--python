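"""Evaluation battery: accuracy, macro-average accuracy, ROC / micro-AUC.

Predictions are pooled over all (individual, target) pairs.  Accuracy is the
plain fraction of correct genotype calls; macro-average accuracy averages the
per-target-SNP accuracies (unweighted over variants).  ROC analysis treats
each genotype class one-vs-rest; the micro-averaged AUC pools every
(prediction, class) pair into one binary problem, which is insensitive to
monotone transforms of the scores — so raw integer scores and normalized
probabilities give the same value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["EvalReport", "accuracy", "macro_accuracy", "micro_auc", "evaluate"]


class MetricsError(ValueError):
    """Shape mismatch or empty input."""


def _check_aligned(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise MetricsError(f"shape mismatch: predictions {pred.shape} vs truth {truth.shape}")
    if pred.size == 0:
        raise MetricsError("empty prediction table")
    return pred, truth


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Correct predictions / total predictions over all (individual, target) pairs."""
    pred, truth = _check_aligned(pred, truth)
    return float(np.mean(pred == truth))


def macro_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Unweighted mean over target SNPs of the per-variant accuracy.

    Inputs are (individuals x targets); a 1-D input is treated as a single
    variant.
    """
    pred, truth = _check_aligned(pred, truth)
    if pred.ndim == 1:
        pred = pred[:, None]
        truth = truth[:, None]
    per_variant = np.mean(pred == truth, axis=0)
    return float(np.mean(per_variant))


def micro_auc(scores: np.ndarray, truth: np.ndarray) -> tuple[list[float], float, dict]:
    """One-vs-rest per-class AUC and the micro-averaged AUC.

    ``scores``: (M, 3) class scores (raw or normalized) for M pooled
    (individual, target) predictions; ``truth``: M genotypes in {0,1,2} or an
    (M, 3) one-hot matrix aligned with the score columns.  Score column ``j``
    votes for genotype ``2 - j`` (the one-hot convention).

    A class absent from the truth yields ``nan`` for that per-class AUC; the
    micro average, which pools all (prediction, class) pairs into a single
    binary ROC, is always defined.  Ties are handled by the midpoint
    (Mann-Whitney) convention.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth)
    if scores.ndim != 2 or scores.shape[1] != 3:
        raise MetricsError("scores must be an (M, 3) array")
    if truth.ndim == 1:
        onehot = np.zeros_like(scores)
        onehot[np.arange(len(truth)), 2 - truth.astype(int)] = 1.0
    else:
        onehot = truth.astype(np.float64)
    if onehot.shape != scores.shape:
        raise MetricsError("truth does not align with scores")
    if scores.size == 0:
        raise MetricsError("empty input")

    per_class: list[float] = []
    roc_points: dict = {}
    for j in range(3):
        genotype = 2 - j
        y = onehot[:, j]
        if y.min() == y.max():  # class absent (or universal): AUC undefined
            per_class.append(float("nan"))
            continue
        per_class.append(float(roc_auc_score(y, scores[:, j])))
        fpr, tpr, _ = roc_curve(y, scores[:, j])
        roc_points[f"class_{genotype}"] = (fpr.tolist(), tpr.tolist())

    y_micro = onehot.ravel()
    s_micro = scores.ravel()
    fpr, tpr, _ = roc_curve(y_micro, s_micro)
    roc_points["micro"] = (fpr.tolist(), tpr.tolist())
    return per_class, float(_sk_auc(fpr, tpr)), roc_points


@dataclass
class EvalReport:
    """Summary of one evaluation run; every metric lies in [0, 1]."""

    accuracy: float
    macro_accuracy: float
    per_class_auc: list[float]
    micro_auc: float
    per_target_accuracy: dict[str, float] = field(default_factory=dict)
    roc_points: dict = field(default_factory=dict)

    def to_json(self, path: Optional[str | Path] = None, include_roc: bool = False) -> str:
        doc = {
            "accuracy": self.accuracy,
            "macro_accuracy": self.macro_accuracy,
            "per_class_auc": [None if np.isnan(a) else a for a in self.per_class_auc],
            "micro_auc": self.micro_auc,
            "per_target_accuracy": self.per_target_accuracy,
        }
        if include_roc:
            doc["roc_points"] = self.roc_points
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def write_roc_tsv(self, path: str | Path) -> None:
        lines = ["curve\tfpr\ttpr"]
        for name, (fpr, tpr) in self.roc_points.items():
            for f, t in zip(fpr, tpr):
                lines.append(f"{name}\t{f:.10g}\t{t:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")


def evaluate(pred_genotypes: np.ndarray, scores: np.ndarray, truth: np.ndarray,
             target_ids: Optional[list[str]] = None) -> EvalReport:
    """Full report from an (n x t) prediction table against the true genotypes.

    ``scores`` is (n, t, 3); normalized per-sample probabilities are computed
    from the raw scores for the ROC analysis (AUC itself is invariant to the
    normalization).
    """
    pred, truth = _check_aligned(pred_genotypes, truth)
    if pred.ndim == 1:
        pred = pred[:, None]
        truth = truth[:, None]
        scores = np.asarray(scores).reshape(pred.shape[0], 1, 3)
    n, t = pred.shape
    flat_scores = np.asarray(scores, dtype=np.float64).reshape(n * t, 3)
    totals = flat_scores.sum(axis=1, keepdims=True)
    probs = np.full_like(flat_scores, 1.0 / 3.0)
    nz = totals[:, 0] > 0
    probs[nz] = flat_scores[nz] / totals[nz]
    per_class, mauc, roc_points = micro_auc(probs, truth.reshape(-1))
    per_target = {}
    ids = target_ids or [f"target{j}" for j in range(t)]
    for j, tid in enumerate(ids):
        per_target[tid] = float(np.mean(pred[:, j] == truth[:, j]))
    return EvalReport(
        accuracy=accuracy(pred, truth),
        macro_accuracy=macro_accuracy(pred, truth),
        per_class_auc=per_class,
        micro_auc=mauc,
        per_target_accuracy=per_target,
        roc_points=roc_points,
    )
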