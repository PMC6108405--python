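"""The full classification workflow as a statsmodels-style model object.

:class:`MetapropertyClassifier` is built from a per-scan metaproperty table
(one row per scan: ``scan_id, label`` and the six metric columns) and a
:class:`MCMConfig`; :meth:`MetapropertyClassifier.fit` executes the ten
workflow stages in order and returns a :class:`MCMResults` carrying every
intermediate product — per-variable assessments, the power analysis, the
split, the coefficient table with standard errors and Wald p-values,
influence diagnostics, and train/test reports with chance accuracy,
chi-squared, ROC and precision-recall curves.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from ..errors import StageError, TlsMetaError, ValidationError
from ..metaproperties import METRIC_NAMES
from .evaluation import (
    ClassificationReport,
    accuracy_report,
    chance_accuracy,
    chi_squared_gof,
    pr_with_ci,
    roc_with_ci,
)
from .regression import (
    ModelFit,
    diagnose_influence,
    fit_firth,
    fit_logistic,
    predict_classes,
    reduce_model,
)
from .screening import (
    apply_transforms,
    detect_complete_separation,
    logit_assessment,
    power_analysis,
    stratified_split,
)

__all__ = ["MCMConfig", "MCMResults", "MetapropertyClassifier", "run_mcm"]


@dataclass(frozen=True)
class MCMConfig:
    """Workflow configuration.

    ``method`` selects the regression: ``"auto"`` uses Firth's penalized
    fit when any retained predictor completely separates the classes and
    the standard fit otherwise.  ``drop_separating_vars`` removes
    separating variables from the predictor set instead (never dropping
    the last one).  ``full_population_mode`` trains and evaluates on the
    complete population, skipping the split.  ``predictors`` restricts the
    model to the named metric columns (post-transform names accepted).
    """

    alpha: float = 0.05
    residual_threshold: float = 3.0
    cooks_threshold: float = 1.5
    classification_threshold: float = 0.5
    log_transform_vars: tuple = ()
    predictors: Optional[tuple] = None
    method: str = "auto"
    drop_separating_vars: bool = False
    full_population_mode: bool = False
    run_diagnostics: bool = True
    reduce_if_needed: bool = True
    compute_pr: bool = True
    power_Z: float = 1.96
    power_E: float = 5.0
    seed: int = 0
    bootstrap_resamples: int = 2000

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        for name in ("residual_threshold", "cooks_threshold",
                     "classification_threshold", "power_Z", "power_E"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.method not in ("auto", "standard", "firth"):
            raise ValidationError("method must be auto, standard or firth")
        object.__setattr__(self, "log_transform_vars", tuple(self.log_transform_vars))
        if self.predictors is not None:
            object.__setattr__(self, "predictors", tuple(self.predictors))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["log_transform_vars"] = list(self.log_transform_vars)
        d["predictors"] = list(self.predictors) if self.predictors else None
        return d


@dataclass
class MCMResults:
    """Everything the fitted workflow produced; see :meth:`summary`."""

    config: MCMConfig
    assessments: dict
    separating_vars: List[str]
    predictors: List[str]
    power: object
    train_ids: List
    test_ids: List
    fit: ModelFit
    diagnostics: Optional[dict]
    train_report: ClassificationReport
    test_report: ClassificationReport
    n_dropped_rows: int = 0

    def summary(self) -> str:
        lines = []
        add = lines.append
        add("Metaproperty Classification Model")
        add("=" * 60)
        add(f"regression method : {self.fit.method}"
            + ("  (penalized: complete separation present)"
               if self.fit.method == "firth" else ""))
        add(f"predictors        : {', '.join(self.predictors)}")
        if self.separating_vars:
            add(f"separating vars   : {', '.join(self.separating_vars)}")
        if self.n_dropped_rows:
            add(f"rows dropped      : {self.n_dropped_rows} (missing metrics)")
        add(f"power analysis    : N={self.power.N}, r={self.power.r:.2f}%, "
            f"n_test={self.power.n}")
        add(f"split             : {len(self.train_ids)} train / "
            f"{len(self.test_ids)} test"
            + ("  (full-population mode)" if self.config.full_population_mode else ""))
        add("")
        add(f"{'variable':<24}{'beta':>12}{'SE':>12}{'Wald p':>10}")
        for name, b, s, p in zip(self.fit.variable_names, self.fit.beta,
                                 self.fit.se, self.fit.wald_p):
            add(f"{name:<24}{b:>12.4g}{s:>12.4g}{p:>10.3g}")
        add(f"model p (LR test) : {self.fit.model_p:.4g}   "
            f"converged: {self.fit.converged}")
        if self.diagnostics is not None:
            add(f"outliers (|r|>{self.config.residual_threshold:g})      : "
                f"{self.diagnostics['outlier_ids']}")
            add(f"influential (D>{self.config.cooks_threshold:g})   : "
                f"{self.diagnostics['influential_ids']}")
        add("")
        for rep in (self.train_report, self.test_report):
            add(f"{rep.set_name} set (n={rep.n}): accuracy {rep.accuracy_pct:.2f}%"
                f"  (chance {rep.chance_accuracy_pct:.2f}%)")
            add(f"  sensitivity {rep.sensitivity:.4f}  specificity "
                f"{rep.specificity:.4f}")
            chi = rep.chi_squared
            add(f"  chi-squared {chi['statistic']:.4f} ({chi['df']} df)")
            add(f"  ROC AUC {rep.roc.auc:.4f} "
                f"(95% CI: {rep.roc.ci_low:.3f}-{rep.roc.ci_high:.3f})")
            if rep.pr is not None:
                add(f"  PR AUC {rep.pr.auc:.4f} "
                    f"(95% CI: {rep.pr.ci_low:.3f}-{rep.pr.ci_high:.3f})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "config": self.config.to_dict(),
            "assessments": {
                name: {
                    "separation": bool(a.separation),
                    "linearity": None if math.isnan(a.linearity) else float(a.linearity),
                    "slope_p": None if math.isnan(a.slope_p) else float(a.slope_p),
                    "degenerate": bool(a.degenerate),
                }
                for name, a in self.assessments.items()
            },
            "separating_vars": list(self.separating_vars),
            "predictors": list(self.predictors),
            "n_dropped_rows": int(self.n_dropped_rows),
            "power": dataclasses.asdict(self.power),
            "train_ids": [str(i) for i in self.train_ids],
            "test_ids": [str(i) for i in self.test_ids],
            "fit": {
                "method": self.fit.method,
                "variable_names": list(self.fit.variable_names),
                "beta": [float(b) for b in self.fit.beta],
                "se": [float(s) for s in self.fit.se],
                "wald_p": [float(p) for p in self.fit.wald_p],
                "model_p": float(self.fit.model_p),
                "converged": bool(self.fit.converged),
                "n_iterations": int(self.fit.n_iterations),
                "log_likelihood": float(self.fit.log_likelihood),
                "reduction_trace": self.fit.reduction_trace,
            },
            "diagnostics": None if self.diagnostics is None else {
                "outlier_ids": [str(i) for i in self.diagnostics["outlier_ids"]],
                "influential_ids": [str(i) for i in self.diagnostics["influential_ids"]],
            },
            "train_report": self.train_report.to_dict(),
            "test_report": self.test_report.to_dict(),
        }

    def to_json(self, path=None, indent=2) -> str:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON serializable: {type(o)}")

        text = json.dumps(self.to_dict(), indent=indent, default=_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _stage(name):
    """Wrap stage failures with the stage name for actionable errors."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, TlsMetaError) \
                    and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False
    return _Ctx()


def run_mcm(table: pd.DataFrame, config: MCMConfig = MCMConfig()) -> MCMResults:
    """Execute the full workflow on a metaproperty table.

    The table needs a binary ``label`` column, a ``scan_id`` column and the
    metric columns.  Rows with missing values in the selected predictors
    are dropped (listwise deletion, counted in the result).
    """
    if "label" not in table.columns:
        raise ValidationError("metaproperty table needs a 'label' column")
    work = table.copy()
    if "scan_id" not in work.columns:
        work.insert(0, "scan_id", [f"row{i}" for i in range(len(work))])
    work["label"] = pd.to_numeric(work["label"])
    if set(work["label"].unique()) != {0, 1}:
        raise ValidationError("labels must be binary 0/1 with both classes present")
    if (work["label"] == 1).sum() < 2 or (work["label"] == 0).sum() < 2:
        raise ValidationError("need at least 2 scans per class")

    with _stage("transform"):
        work = apply_transforms(work, config.log_transform_vars)

    # resolve predictor names against post-transform columns
    metric_cols = [c for c in work.columns if c not in ("scan_id", "label")]
    if config.predictors is None:
        predictors = list(metric_cols)
    else:
        predictors = []
        for name in config.predictors:
            if name in work.columns:
                predictors.append(name)
            elif f"log_{name}" in work.columns:
                predictors.append(f"log_{name}")
            else:
                raise ValidationError(f"predictor {name!r} not in table")

    # listwise deletion over the selected predictors (NaN or the infinite
    # first:second sentinel both make a row unusable for regression)
    usable = np.isfinite(work[predictors].to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~usable).sum())
    work = work.loc[usable].reset_index(drop=True)

    y_all = work["label"].to_numpy(dtype=int)
    with _stage("assessment"):
        assessments = {
            name: logit_assessment(work[name].to_numpy(dtype=float), y_all,
                                   variable=name)
            for name in predictors
        }
    separating = [n for n, a in assessments.items() if a.separation]

    used = list(predictors)
    if config.drop_separating_vars and separating:
        kept = [n for n in used if n not in separating]
        if kept:
            used = kept
        # dropping every predictor would leave nothing to fit; keep them and
        # rely on the penalized regression instead
    sep_in_used = [n for n in used if assessments[n].separation]
    if config.method == "auto":
        method = "firth" if sep_in_used else "standard"
    else:
        method = config.method

    with _stage("power_analysis"):
        r = 100.0 * float((y_all == 1).mean())
        power = power_analysis(len(work), r, Z=config.power_Z, E=config.power_E)

    with _stage("split"):
        if config.full_population_mode:
            train = test = work
        else:
            train, test = stratified_split(work, power.n, seed=config.seed)

    y_train = train["label"].to_numpy(dtype=int)
    y_test = test["label"].to_numpy(dtype=int)

    with _stage("regression"):
        fit_fn = fit_firth if method == "firth" else fit_logistic
        fit = fit_fn(train[used], y_train)
        if not (fit.converged and fit.model_p < config.alpha) \
                and config.reduce_if_needed and len(used) > 1:
            fit = reduce_model(train[used], y_train, alpha=config.alpha,
                               method=method)

    diagnostics = None
    if config.run_diagnostics and fit.converged:
        with _stage("influence_diagnostics"):
            diagnostics = diagnose_influence(
                fit, train[fit.predictors], y_train,
                residual_threshold=config.residual_threshold,
                cooks_threshold=config.cooks_threshold,
                ids=train["scan_id"].to_numpy())

    with _stage("prediction"):
        pred_train = predict_classes(fit, train[fit.predictors],
                                     config.classification_threshold)
        pred_test = predict_classes(fit, test[fit.predictors],
                                    config.classification_threshold)

    chance = chance_accuracy(np.bincount(y_all, minlength=2))
    reports = []
    for name, y_set, pred, seed_off in (
            ("training", y_train, pred_train, 1),
            ("testing", y_test, pred_test, 2)):
        with _stage(f"{name}_report"):
            rep = accuracy_report(y_set, pred["classes"], set_name=name)
            rep.chance_accuracy_pct = chance
            observed = np.bincount(pred["classes"], minlength=2)
            expected = np.bincount(y_set, minlength=2)
            rep.chi_squared = chi_squared_gof(observed, expected)
            rep.roc = roc_with_ci(y_set, pred["probabilities"],
                                  n_resamples=config.bootstrap_resamples,
                                  seed=config.seed * 1000 + seed_off)
            if config.compute_pr:
                rep.pr = pr_with_ci(y_set, pred["probabilities"],
                                    n_resamples=config.bootstrap_resamples,
                                    seed=config.seed * 1000 + 10 + seed_off)
            reports.append(rep)

    return MCMResults(
        config=config,
        assessments=assessments,
        separating_vars=separating,
        predictors=used,
        power=power,
        train_ids=train["scan_id"].tolist(),
        test_ids=test["scan_id"].tolist(),
        fit=fit,
        diagnostics=diagnostics,
        train_report=reports[0],
        test_report=reports[1],
        n_dropped_rows=n_dropped,
    )


class MetapropertyClassifier:
    """Model object over a metaproperty table; ``fit()`` runs the workflow.

    Examples
    --------
    >>> model = MetapropertyClassifier(table, MCMConfig(seed=7))
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(self, table: pd.DataFrame, config: MCMConfig = MCMConfig()):
        self.table = table
        self.config = config

    @classmethod
    def from_csv(cls, path, config: MCMConfig = MCMConfig()) -> "MetapropertyClassifier":
        return cls(pd.read_csv(path), config)

    def fit(self) -> MCMResults:
        return run_mcm(self.table, self.config)
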