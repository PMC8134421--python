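"""Classifier evaluation: AUROC, confusion matrices, threshold metrics.

AUROC is computed as the Mann-Whitney rank statistic — the probability
that a randomly chosen positive outranks a randomly chosen negative,
with ties counted one half — which is exactly the area under the ROC
curve.  Threshold metrics (PPV, NPV, sensitivity, specificity) use the
``p >= threshold`` classification rule; rates whose denominator is zero
are reported as undefined (NaN with a flag), never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int
    threshold: float = 0.5

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricReport:
    """Threshold metrics plus (optional) fold-wise AUROC summary."""

    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    confusion: ConfusionMatrix
    auroc_mean: float | None = None
    auroc_sd: float | None = None
    fold_aurocs: list | None = None
    undefined: tuple = ()

    def rounded(self, ndigits: int = 2) -> dict:
        """Display rounding, half-up, as rates are conventionally printed."""
        def r(x):
            if x is None or not np.isfinite(x):
                return None
            q = 10 ** ndigits
            return float(np.floor(x * q + 0.5) / q)
        out = {"ppv": r(self.ppv), "npv": r(self.npv),
               "sensitivity": r(self.sensitivity), "specificity": r(self.specificity)}
        if self.auroc_mean is not None:
            out["auroc_mean"] = r(self.auroc_mean)
        return out

    def to_dict(self) -> dict:
        cm = self.confusion
        return {
            "counts": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn,
                       "threshold": cm.threshold},
            "rates": {"ppv": self.ppv, "npv": self.npv,
                      "sensitivity": self.sensitivity, "specificity": self.specificity},
            "rates_2dp": self.rounded(2),
            "auroc_mean": self.auroc_mean,
            "auroc_sd": self.auroc_sd,
            "fold_aurocs": self.fold_aurocs,
            "undefined": list(self.undefined),
        }


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return y


def confusion_at_threshold(probs, labels, threshold: float = 0.5) -> ConfusionMatrix:
    """Count the four outcomes of the ``p >= threshold`` rule."""
    p = np.asarray(probs, dtype=float)
    y = _check_binary(labels)
    if p.size == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    if p.shape != y.shape:
        raise ValueError("probs and labels are not aligned")
    pred = p >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & (y == 1))), fn=int(np.sum(~pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))), tn=int(np.sum(~pred & (y == 0))),
        threshold=float(threshold))


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricReport:
    """PPV, NPV, sensitivity and specificity from the four counts."""
    undefined = []

    def rate(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    report = MetricReport(
        ppv=rate(cm.tp, cm.tp + cm.fp, "ppv"),
        npv=rate(cm.tn, cm.tn + cm.fn, "npv"),
        sensitivity=rate(cm.tp, cm.tp + cm.fn, "sensitivity"),
        specificity=rate(cm.tn, cm.tn + cm.fp, "specificity"),
        confusion=cm)
    report.undefined = tuple(undefined)
    return report


def roc_auc(probs, labels) -> float:
    """AUROC via the rank (Mann-Whitney) statistic with half-counted ties."""
    p = np.asarray(probs, dtype=float)
    y = _check_binary(labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(p)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_ensemble(ensemble, matrix, labels, threshold: float = 0.5) -> MetricReport:
    """Full report for a trained ensemble on a feature matrix.

    AUROC is computed per outer-fold model (mean and standard deviation
    reported); the threshold metrics use the ensemble-mean probability.
    The matrix may come from a different cohort than the training one as
    long as columns match (cross-cohort evaluation).
    """
    y = _check_binary(labels)
    per_fold = ensemble.predict_proba_per_fold(matrix)
    fold_aurocs = [roc_auc(per_fold[:, j], y) for j in range(per_fold.shape[1])]
    mean_probs = per_fold.mean(axis=1)
    cm = confusion_at_threshold(mean_probs, y, threshold)
    report = metrics_from_confusion(cm)
    report.auroc_mean = float(np.mean(fold_aurocs))
    report.auroc_sd = float(np.std(fold_aurocs))
    report.fold_aurocs = [float(a) for a in fold_aurocs]
    return report
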