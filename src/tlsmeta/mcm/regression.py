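"""Binomial logistic regression: standard MLE, Firth penalization, diagnostics.

The standard fit is maximum likelihood via statsmodels' iteratively
reweighted Newton solver.  Under complete separation that likelihood has no
finite maximizer, so the fit is flagged ``converged=False``; Firth's
bias-reduced logistic regression — which maximizes the Jeffreys-prior
penalized log-likelihood

    l*(β) = l(β) + ½ log det I(β),      I(β) = XᵀWX,  W = diag(p(1-p))

— always has a finite maximizer and is the recommended replacement when any
explanatory variable completely separates the classes.  The Firth solver
here is a damped Newton iteration on the modified score

    U*(β) = Xᵀ(y − p + h ∘ (½ − p))

with h the leverages of the weighted hat matrix (Firth 1993; the same
scheme as the logistf reference implementation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import (
    CollinearityError,
    ConvergenceError,
    ValidationError,
)

__all__ = [
    "ModelFit",
    "fit_logistic",
    "fit_firth",
    "diagnose_influence",
    "reduce_model",
    "predict_classes",
]

_DIVERGENCE_GUARD = 1e3  # |beta| beyond this is treated as a diverging MLE


@dataclass
class ModelFit:
    """Coefficients and inference of one (penalized) binomial logistic fit.

    ``variable_names`` starts with ``"intercept"``; ``beta``, ``se`` and
    ``wald_p`` are aligned with it.  ``model_p`` is the p-value of the
    likelihood-ratio test of the fitted model against intercept-only (the
    model-level significance used to judge convergence of the workflow).
    """

    method: str
    variable_names: List[str]
    beta: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    model_p: float
    converged: bool
    n_iterations: int
    log_likelihood: float
    reduction_trace: list = field(default_factory=list)

    def __post_init__(self):
        k = len(self.variable_names)
        if not (len(self.beta) == len(self.se) == len(self.wald_p) == k):
            raise ValidationError("beta/se/wald_p lengths must match variable names")

    @property
    def predictors(self) -> List[str]:
        return self.variable_names[1:]

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se, "wald_p": self.wald_p},
            index=self.variable_names,
        )


def _as_design(X, variable_names):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa.reshape(-1, 1)
        names = list(variable_names) if variable_names is not None else \
            [f"x{i + 1}" for i in range(Xa.shape[1])]
    if variable_names is not None:
        names = list(variable_names)
    if len(names) != Xa.shape[1]:
        raise ValidationError("variable_names length must match predictor count")
    if Xa.shape[1] == 0:
        raise ValidationError("at least one predictor is required")
    if np.isnan(Xa).any():
        raise ValidationError("predictor matrix contains missing values")
    return Xa, names


def _validate_response(y):
    ya = np.asarray(y, dtype=float)
    if not set(np.unique(ya)) <= {0.0, 1.0}:
        raise ValidationError("response must be binary 0/1")
    if not (np.any(ya == 0) and np.any(ya == 1)):
        raise ValidationError("both response classes must be present")
    return ya


def _check_rank(design, names):
    r = np.linalg.matrix_rank(design)
    if r < design.shape[1]:
        # identify aliased columns greedily: a column is aliased if adding it
        # to the preceding columns does not increase the rank
        aliased = []
        rank_so_far = 0
        for j in range(design.shape[1]):
            rj = np.linalg.matrix_rank(design[:, : j + 1])
            if rj == rank_so_far:
                aliased.append(names[j] if j < len(names) else f"col{j}")
            rank_so_far = rj
        raise CollinearityError(aliased or names)


def _expit(eta):
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def _loglik(y, p):
    eps = 1e-300
    return float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def fit_logistic(X, y, variable_names: Optional[Sequence[str]] = None,
                 maxiter: int = 100) -> ModelFit:
    """Maximum-likelihood binomial logistic regression (IRLS/Newton).

    ``converged`` is False when the iteration cap is hit, the solver reports
    failure, or coefficients run past a divergence guard — the signature of
    complete separation, where the MLE does not exist.
    """
    import statsmodels.api as sm

    Xa, names = _as_design(X, variable_names)
    ya = _validate_response(y)
    if len(ya) != Xa.shape[0]:
        raise ValidationError("response and predictors must have equal length")
    design = np.column_stack([np.ones(len(ya)), Xa])
    all_names = ["intercept"] + names
    _check_rank(design, all_names)

    model = sm.Logit(ya, design)
    model.raise_on_perfect_prediction = False  # flag, don't abort
    k = design.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", maxiter=maxiter, disp=0,
                            warn_convergence=False)
        beta = np.asarray(res.params, dtype=float)
        converged = bool(res.mle_retvals.get("converged", False))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            se = np.asarray(res.bse, dtype=float)
            wald_p = np.asarray(res.pvalues, dtype=float)
            model_p = float(res.llr_pvalue)
        llf = float(res.llf)
        n_iter = int(res.mle_retvals.get("iterations", maxiter))
    except (np.linalg.LinAlgError, Exception) as exc:
        if not isinstance(exc, np.linalg.LinAlgError) \
                and type(exc).__name__ != "PerfectSeparationError":
            raise
        # Hessian became singular along a diverging path (separation):
        # report a non-converged fit rather than aborting the workflow
        beta = np.full(k, np.nan)
        se = np.full(k, np.nan)
        wald_p = np.full(k, np.nan)
        model_p = math.nan
        llf = math.nan
        n_iter = maxiter
        converged = False
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta), initial=0) > _DIVERGENCE_GUARD:
        converged = False
    wald_p = np.where(np.isfinite(wald_p), wald_p, np.nan)
    return ModelFit(
        method="standard",
        variable_names=all_names,
        beta=beta,
        se=se,
        wald_p=wald_p,
        model_p=model_p,
        converged=converged,
        n_iterations=n_iter,
        log_likelihood=llf,
    )


def _firth_penalized_ll(design, y, beta):
    p = _expit(design @ beta)
    w = np.clip(p * (1 - p), 1e-12, None)
    info = design.T @ (design * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return _loglik(y, p) + 0.5 * logdet


def _firth_newton(design, y, maxiter=100, tol=1e-8):
    n, k = design.shape
    beta = np.zeros(k)
    pll = _firth_penalized_ll(design, y, beta)
    it = 0
    for it in range(1, maxiter + 1):
        p = _expit(design @ beta)
        w = np.clip(p * (1 - p), 1e-12, None)
        info = design.T @ (design * w[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        h = np.einsum("ij,jk,ik->i", design, info_inv, design) * w
        score = design.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        if np.max(np.abs(step)) < tol:
            return beta, info_inv, pll, it, True
        # step-halving on the penalized log-likelihood
        scale = 1.0
        for _ in range(25):
            cand = beta + scale * step
            cand_pll = _firth_penalized_ll(design, y, cand)
            if cand_pll >= pll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        new_pll = _firth_penalized_ll(design, y, beta)
        if abs(new_pll - pll) < 1e-12 and np.max(np.abs(scale * step)) < 1e-6:
            return beta, info_inv, new_pll, it, True
        pll = new_pll
    return beta, info_inv, pll, it, False


def fit_firth(X, y, variable_names: Optional[Sequence[str]] = None,
              maxiter: int = 100) -> ModelFit:
    """Firth bias-reduced logistic regression (Jeffreys-prior penalty).

    Produces finite estimates even under complete separation.  Standard
    errors come from the inverse Fisher information at the penalized
    optimum; ``model_p`` is the penalized likelihood-ratio test against the
    intercept-only Firth fit.
    """
    Xa, names = _as_design(X, variable_names)
    ya = _validate_response(y)
    if len(ya) != Xa.shape[0]:
        raise ValidationError("response and predictors must have equal length")
    design = np.column_stack([np.ones(len(ya)), Xa])
    all_names = ["intercept"] + names
    _check_rank(design, all_names)

    beta, info_inv, pll, n_iter, ok = _firth_newton(design, ya, maxiter=maxiter)
    se = np.sqrt(np.clip(np.diag(info_inv), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    wald_p = 2 * stats.norm.sf(np.abs(z))

    null_design = np.ones((len(ya), 1))
    _, _, pll0, _, _ = _firth_newton(null_design, ya, maxiter=maxiter)
    lr = max(0.0, 2.0 * (pll - pll0))
    model_p = float(stats.chi2.sf(lr, df=Xa.shape[1]))
    return ModelFit(
        method="firth",
        variable_names=all_names,
        beta=beta,
        se=se,
        wald_p=wald_p,
        model_p=model_p,
        converged=bool(ok and np.all(np.isfinite(beta))),
        n_iterations=n_iter,
        log_likelihood=pll,
    )


def diagnose_influence(fit: ModelFit, X, y, residual_threshold: float = 3.0,
                       cooks_threshold: float = 1.5, ids=None) -> dict:
    """Standardized Pearson residuals and Cook's distances per observation.

    Returns ``{"outlier_ids": [...], "influential_ids": [...],
    "std_residuals": array, "cooks_distance": array}``.  Observations can
    appear in both lists.
    """
    if not fit.converged:
        raise ConvergenceError("influence diagnostics require a converged fit")
    Xa, _ = _as_design(X, fit.predictors)
    ya = _validate_response(y)
    if ids is None:
        ids = X.index.to_numpy() if isinstance(X, pd.DataFrame) else np.arange(len(ya))
    ids = np.asarray(ids)
    design = np.column_stack([np.ones(len(ya)), Xa])
    p = _expit(design @ fit.beta)
    w = np.clip(p * (1 - p), 1e-12, None)
    info_inv = np.linalg.inv(design.T @ (design * w[:, None]))
    h = np.clip(np.einsum("ij,jk,ik->i", design, info_inv, design) * w, 0, 1 - 1e-12)
    pearson = (ya - p) / np.sqrt(w)
    std_resid = pearson / np.sqrt(1 - h)
    k = design.shape[1]
    cooks = (std_resid ** 2) * h / (k * (1 - h))
    return {
        "outlier_ids": ids[np.abs(std_resid) > residual_threshold].tolist(),
        "influential_ids": ids[cooks > cooks_threshold].tolist(),
        "std_residuals": std_resid,
        "cooks_distance": cooks,
    }


def reduce_model(X, y, alpha: float = 0.05, method: str = "standard",
                 variable_names: Optional[Sequence[str]] = None) -> ModelFit:
    """Backward reduction: keep the full model if it converges, else prune.

    If the full model is significant at ``alpha`` (likelihood-ratio test
    against intercept-only) it is returned unchanged, even when individual
    coefficients are non-significant — a guard against overfitting.
    Otherwise the predictor with the highest Wald p-value is removed and
    the model refitted on the same data, until the reduced model is
    significant; exhausting all predictors is an error.  The removal
    sequence is recorded in ``reduction_trace``.
    """
    fit_fn = fit_firth if method == "firth" else fit_logistic
    if isinstance(X, pd.DataFrame):
        frame = X.copy()
    else:
        Xa, names = _as_design(X, variable_names)
        frame = pd.DataFrame(Xa, columns=names)
    trace = []
    while True:
        fit = fit_fn(frame, y)
        if fit.converged and fit.model_p < alpha:
            fit.reduction_trace = trace
            return fit
        if frame.shape[1] == 1:
            raise ConvergenceError(
                "model reduction exhausted all predictors without convergence")
        wald = pd.Series(fit.wald_p[1:], index=fit.predictors).fillna(2.0)
        worst = wald.idxmax()
        if not fit.converged:
            # a diverging fit flattens every Wald p to ~1, so the ordering
            # is uninformative; remove the highest-p variable among those
            # that completely separate the classes (the cause of the
            # divergence) before touching overlapping ones
            from .screening import detect_complete_separation
            seps = [n for n in wald.index
                    if detect_complete_separation(frame[n].to_numpy(), y)]
            if seps:
                worst = wald[seps].idxmax()
        trace.append({"dropped": worst,
                      "wald_p": float(wald[worst]) if np.isfinite(wald[worst]) else None,
                      "model_p": fit.model_p})
        frame = frame.drop(columns=[worst])


def predict_classes(fit: ModelFit, X, classification_threshold: float = 0.5) -> dict:
    """Predicted probabilities and classes for new metaproperty rows.

    ``X`` may be a DataFrame (columns matched to the fit's predictors by
    name) or an array with the same column order.  The linear predictor is
    clipped before the inverse logit, so extreme fits cannot overflow.
    """
    if isinstance(X, pd.DataFrame):
        missing = [c for c in fit.predictors if c not in X.columns]
        if missing:
            raise ValidationError(f"prediction input lacks columns {missing}")
        Xa = X[fit.predictors].to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa.reshape(-1, 1)
        if Xa.shape[1] != len(fit.predictors):
            raise ValidationError(
                f"prediction input has {Xa.shape[1]} columns; fit expects "
                f"{len(fit.predictors)}")
    eta = fit.beta[0] + Xa @ fit.beta[1:]
    prob = _expit(eta)
    return {"probabilities": prob,
            "classes": (prob >= classification_threshold).astype(int)}
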