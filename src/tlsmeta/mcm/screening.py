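"""Pre-model stages: variable assessment, transforms, power analysis, split."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..errors import NotComputableError, ValidationError

__all__ = [
    "LogitAssessment",
    "PowerAnalysisSpec",
    "detect_complete_separation",
    "logit_assessment",
    "apply_transforms",
    "power_analysis",
    "stratified_split",
]


def _clean_pairs(values, labels):
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if v.shape != y.shape:
        raise ValidationError("values and labels must have equal length")
    keep = np.isfinite(v)
    v, y = v[keep], y[keep]
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError("labels must be binary 0/1")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValidationError("both classes must be present with finite values")
    return v, y


def detect_complete_separation(values, labels) -> bool:
    """True iff the two classes' value ranges do not overlap.

    Complete separation makes the standard logistic MLE diverge; a
    separating variable must either be dropped or fitted with Firth's
    penalized likelihood.  Non-finite (flagged) values are excluded first.
    """
    v, y = _clean_pairs(values, labels)
    v0, v1 = v[y == 0], v[y == 1]
    return bool(v0.max() < v1.min() or v1.max() < v0.min())


@dataclass
class LogitAssessment:
    """Graphical assessment of one metaproperty against the binary response.

    ``curve`` holds (value, fitted probability) points from a univariate
    logistic fit; ``linearity`` is |Pearson r| between binned empirical
    logits and the bin-mean metric value (1 = perfectly logit-linear);
    ``separation`` flags complete separation; ``slope_p`` is the Wald
    p-value of the univariate slope (NaN when only a penalized fit exists
    or the variable is degenerate).
    """

    variable: str
    separation: bool
    linearity: float = math.nan
    slope_p: float = math.nan
    degenerate: bool = False
    curve: Optional[np.ndarray] = None


def _empirical_logit_linearity(v, y, n_bins=8):
    """|corr| between bin-mean value and empirical logit of bin proportions."""
    qs = np.quantile(v, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    if len(edges) < 3:
        return math.nan
    which = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, len(edges) - 2)
    xs, ls = [], []
    for b in range(len(edges) - 1):
        m = which == b
        n = int(m.sum())
        if n == 0:
            continue
        k = float(y[m].sum())
        ls.append(math.log((k + 0.5) / (n - k + 0.5)))
        xs.append(float(v[m].mean()))
    if len(xs) < 3 or np.std(xs) == 0 or np.std(ls) == 0:
        return math.nan
    return float(abs(np.corrcoef(xs, ls)[0, 1]))


def logit_assessment(values, labels, variable: str = "x",
                     n_curve_points: int = 100) -> LogitAssessment:
    """Assess one metaproperty: fitted logit curve, linearity, separation.

    Fits a univariate logistic model of the label on the metric (penalized,
    so a curve exists even under complete separation) and evaluates the
    fitted probability over the value range.
    """
    v, y = _clean_pairs(values, labels)
    if np.count_nonzero(y == 0) < 2 or np.count_nonzero(y == 1) < 2:
        raise ValidationError("need at least 2 scans per class with finite values")
    if np.ptp(v) == 0:
        return LogitAssessment(variable=variable, separation=False, degenerate=True)

    sep = detect_complete_separation(v, y)
    X = np.column_stack([np.ones_like(v), v])
    from .regression import fit_firth, fit_logistic
    slope_p = math.nan
    if sep:
        fit = fit_firth(v.reshape(-1, 1), y, variable_names=[variable])
    else:
        fit = fit_logistic(v.reshape(-1, 1), y, variable_names=[variable])
        slope_p = float(fit.wald_p[1])
    grid = np.linspace(v.min(), v.max(), n_curve_points)
    eta = fit.beta[0] + fit.beta[1] * grid
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    return LogitAssessment(
        variable=variable,
        separation=sep,
        linearity=_empirical_logit_linearity(v, y),
        slope_p=slope_p,
        curve=np.column_stack([grid, prob]),
    )


def apply_transforms(table: pd.DataFrame, log_transform_vars: Sequence[str]) -> pd.DataFrame:
    """Replace named columns by their natural logs, renamed ``log_<name>``.

    Values must be strictly positive and finite; a flagged-infinite
    first:second ratio is rejected rather than silently transformed.
    """
    out = table.copy()
    for name in log_transform_vars:
        if name not in out.columns:
            raise ValidationError(f"transform variable {name!r} not in table")
        col = out[name].to_numpy(dtype=float)
        present = ~np.isnan(col)
        bad = present & ~(np.isfinite(col) & (col > 0))
        if bad.any():
            ids = out.loc[bad, "scan_id"].tolist() if "scan_id" in out else \
                np.flatnonzero(bad).tolist()
            raise ValidationError(
                f"cannot log-transform {name!r}: non-positive or non-finite "
                f"values for scans {ids[:5]}")
        new = np.full_like(col, np.nan)
        new[present] = np.log(col[present])
        out[name] = new
        out = out.rename(columns={name: f"log_{name}"})
    return out


@dataclass(frozen=True)
class PowerAnalysisSpec:
    """Testing-set size from the finite-population margin-of-error formula.

    x = Z²·r·(100−r) with r the group proportion in percent, and
    n = ceil(N·x / ((N−1)·E² + x)) with E the margin of error in percent.
    With Z = 1.96, E = 5 and r = 50, n → 385 as N → ∞.
    """

    N: int
    r: float
    Z: float
    E: float
    x: float
    n: int


def power_analysis(N: int, r: float, Z: float = 1.96, E: float = 5.0) -> PowerAnalysisSpec:
    """Required testing-set size for the given confidence and margin of error."""
    if N < 2:
        raise ValidationError("population must contain at least 2 scans")
    if not 0 < r < 100:
        raise ValidationError(f"group proportion r={r}% is degenerate")
    x = Z * Z * r * (100.0 - r)
    n = math.ceil(N * x / ((N - 1) * E * E + x))
    return PowerAnalysisSpec(N=N, r=r, Z=Z, E=E, x=x, n=min(n, N))


def stratified_split(table: pd.DataFrame, test_n: int, seed: int,
                     label_col: str = "label"):
    """Split rows into (train, test) with class-proportional test allocation.

    Per-class testing counts are the largest-remainder rounding of
    ``test_n × class proportion`` (so they always sum to ``test_n``); rows
    are drawn without replacement with a seeded generator, making the
    split reproducible.
    """
    if test_n >= len(table):
        raise ValidationError("test_n must be smaller than the population")
    labels = table[label_col]
    classes, counts = np.unique(labels.to_numpy(), return_counts=True)
    if len(classes) < 2:
        raise ValidationError("both classes must be present")
    exact = test_n * counts / counts.sum()
    alloc = np.floor(exact).astype(int)
    remainder = exact - alloc
    for i in np.argsort(-remainder)[: test_n - alloc.sum()]:
        alloc[i] += 1
    if np.any(alloc >= counts):
        raise ValidationError("test allocation would leave a class empty in training")
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls, k in zip(classes, alloc):
        pool = table.index[labels == cls].to_numpy()
        test_idx.extend(rng.choice(pool, size=k, replace=False))
    test_idx = pd.Index(sorted(test_idx))
    train = table.loc[~table.index.isin(test_idx)]
    test = table.loc[test_idx]
    return train, test
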