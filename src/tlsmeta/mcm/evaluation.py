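"""Accuracy, chance accuracy, chi-squared, ROC and precision-recall curves."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from ..errors import ValidationError

__all__ = [
    "ClassificationReport",
    "CurveResult",
    "accuracy_report",
    "chance_accuracy",
    "chi_squared_gof",
    "roc_with_ci",
    "pr_with_ci",
    "best_threshold_accuracy",
]


@dataclass
class CurveResult:
    """ROC or precision-recall curve with AUC and bootstrap 95% CI.

    ROC points are (false positive rate, true positive rate); PR points are
    (recall, precision).  The CI is a seeded stratified percentile
    bootstrap over observations.
    """

    kind: str
    points: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    n_resamples: int

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "auc": float(self.auc),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "n_resamples": int(self.n_resamples),
            "points": [[float(a), float(b)] for a, b in self.points],
        }


@dataclass
class ClassificationReport:
    """Confusion breakdown and accuracy metrics for one evaluation set.

    ``confusion`` maps each class to ``{"correct": c, "total": n,
    "misassigned": m, "other_total": n_other}`` — c of the n members of the
    class were predicted correctly, and m of the other class's n_other
    members were misassigned to this class (the layout of the
    per-class True/False count tables).
    """

    set_name: str
    n: int
    confusion: dict
    accuracy_pct: float
    sensitivity: float
    specificity: float
    false_positive_rate: float
    false_negative_rate: float
    chance_accuracy_pct: float = math.nan
    chi_squared: Optional[dict] = None
    roc: Optional[CurveResult] = None
    pr: Optional[CurveResult] = None

    def to_dict(self) -> dict:
        d = {
            "set_name": self.set_name,
            "n": int(self.n),
            "confusion": self.confusion,
            "accuracy_pct": float(self.accuracy_pct),
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "false_positive_rate": float(self.false_positive_rate),
            "false_negative_rate": float(self.false_negative_rate),
            "chance_accuracy_pct": float(self.chance_accuracy_pct),
            "chi_squared": self.chi_squared,
            "roc": self.roc.to_dict() if self.roc else None,
            "pr": self.pr.to_dict() if self.pr else None,
        }
        return d


def _binary_arrays(true_labels, predicted):
    t = np.asarray(true_labels)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ValidationError("true and predicted labels must have equal length")
    if t.size == 0:
        raise ValidationError("empty label vectors")
    return t, p


def accuracy_report(true_labels, predicted, set_name: str = "testing",
                    positive_label=1) -> ClassificationReport:
    """Confusion counts and accuracy metrics for one set of predictions.

    Sensitivity is the true positive rate for ``positive_label``;
    specificity the true negative rate; overall accuracy is reported in
    percent of the set size.
    """
    t, p = _binary_arrays(true_labels, predicted)
    classes = sorted(set(np.unique(t)) | set(np.unique(p)))
    if len(classes) > 2:
        raise ValidationError(f"binary labels expected, got classes {classes}")
    confusion = {}
    correct_total = 0
    for c in classes:
        in_c = t == c
        n_c = int(in_c.sum())
        correct = int((in_c & (p == c)).sum())
        misassigned = int((~in_c & (p == c)).sum())
        key = int(c) if isinstance(c, (np.integer, np.bool_)) else c
        confusion[key] = {
            "correct": correct,
            "total": n_c,
            "misassigned": misassigned,
            "other_total": int((~in_c).sum()),
        }
        correct_total += correct
    n = t.size
    accuracy_pct = 100.0 * correct_total / n

    pos = t == positive_label
    neg = ~pos
    tp = float((pos & (p == positive_label)).sum())
    fn = float((pos & (p != positive_label)).sum())
    tn = float((neg & (p != positive_label)).sum())
    fp = float((neg & (p == positive_label)).sum())
    sens = tp / (tp + fn) if (tp + fn) else math.nan
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    fpr = fp / (fp + tn) if (fp + tn) else math.nan
    fnr = fn / (fn + tp) if (fn + tp) else math.nan
    return ClassificationReport(
        set_name=set_name, n=n, confusion=confusion,
        accuracy_pct=accuracy_pct, sensitivity=sens, specificity=spec,
        false_positive_rate=fpr, false_negative_rate=fnr,
    )


def chance_accuracy(group_counts) -> float:
    """Expected accuracy (%) of proportional random assignment: 100·Σ(nᵢ/N)²."""
    counts = np.asarray(group_counts, dtype=float)
    if np.any(counts < 0):
        raise ValidationError("group counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValidationError("at least one group must be non-empty")
    props = counts / total
    return float(100.0 * np.sum(props ** 2))


def chi_squared_gof(observed, expected) -> dict:
    """Goodness-of-fit χ² = Σ(obs−exp)²/exp with df = classes − 1."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.size < 2:
        raise ValidationError("observed and expected need equal length ≥ 2")
    if np.any(exp <= 0):
        raise ValidationError("expected counts must be strictly positive")
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return {"statistic": stat, "df": int(obs.size - 1)}


def _bootstrap_ci(labels, scores, auc_fn, n_resamples, seed):
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    aucs = np.empty(n_resamples)
    for b in range(n_resamples):
        take = np.concatenate([
            rng.choice(idx0, size=idx0.size, replace=True),
            rng.choice(idx1, size=idx1.size, replace=True),
        ])
        aucs[b] = auc_fn(labels[take], scores[take])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def roc_with_ci(labels, probabilities, n_resamples: int = 2000,
                seed: int = 0) -> CurveResult:
    """ROC curve over all score thresholds with trapezoidal AUC and 95% CI.

    The AUC equals the tie-aware Mann-Whitney concordant-pair fraction; the
    CI is a seeded stratified percentile bootstrap.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(probabilities, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("labels and scores must have equal length")
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    lo, hi = _bootstrap_ci(y, s, roc_auc_score, n_resamples, seed)
    return CurveResult(kind="roc", points=np.column_stack([fpr, tpr]),
                       auc=auc, ci_low=lo, ci_high=hi, n_resamples=n_resamples)


def pr_with_ci(labels, probabilities, n_resamples: int = 2000,
               seed: int = 0) -> CurveResult:
    """Precision-recall curve with average-precision AUC and bootstrap 95% CI."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(probabilities, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("labels and scores must have equal length")
    if not np.any(y == 1):
        raise ValidationError("precision-recall requires positive examples")
    precision, recall, _ = precision_recall_curve(y, s)
    auc = float(average_precision_score(y, s))
    if len(np.unique(y)) < 2:
        lo = hi = auc
    else:
        lo, hi = _bootstrap_ci(y, s, average_precision_score, n_resamples, seed)
    return CurveResult(kind="pr", points=np.column_stack([recall, precision]),
                       auc=auc, ci_low=lo, ci_high=hi, n_resamples=n_resamples)


def best_threshold_accuracy(values, labels) -> dict:
    """Best single-threshold classifier on one metric (both orientations).

    Scans every midpoint between consecutive distinct values and returns
    the maximal accuracy (%), the threshold and the orientation
    (``"ge"`` = predict class 1 when value ≥ threshold).  A completely
    separating metric yields 100%.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape or v.size == 0:
        raise ValidationError("values and labels must be equal-length, non-empty")
    finite = np.isfinite(v)
    # the infinite first:second sentinel is still orderable; map it to a
    # value beyond the finite maximum so thresholds can use it
    vv = v.copy()
    if (~finite).any():
        top = np.nanmax(vv[finite]) if finite.any() else 0.0
        vv[np.isposinf(v)] = top + 1.0
        vv[np.isneginf(v)] = (np.nanmin(vv[finite]) if finite.any() else 0.0) - 1.0
    uniq = np.unique(vv)
    cuts = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0,
                           [uniq[-1] + 1.0]])
    best = {"accuracy_pct": -1.0, "threshold": math.nan, "orientation": "ge"}
    n = y.size
    for c in cuts:
        for orient, pred in (("ge", vv >= c), ("lt", vv < c)):
            acc = 100.0 * float((pred.astype(int) == y).sum()) / n
            if acc > best["accuracy_pct"]:
                best = {"accuracy_pct": acc, "threshold": float(c),
                        "orientation": orient}
    return best
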