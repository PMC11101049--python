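"""Binomial presence/absence GLMs with BIC forward selection.

Species occupancy across lakes is modelled with a logit-link binomial
GLM. Model quality is summarised by the deviance-based D² and its
adjusted form (the GLM analogue of adjusted R²),

    D² = (nulldev − resdev)/nulldev,
    adj-D² = 1 − ((n − 1)/(n − p)) (1 − D²),

and candidate predictors are admitted one at a time by a forward
procedure with three conditions: (i) the model BIC must drop,
(ii) the added variable must be significant (chi-square test on the
deviance difference), and (iii) the fit must converge without fitted
probabilities numerically indistinguishable from 0 or 1 (a symptom of
separation/overfitting). A candidate failing (iii) is substituted by
the next candidate on the BIC ranking, provided that one still
satisfies (i) and (ii).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["GlmFit", "SelectedModel", "fit_binomial", "deviance_chisq", "adjusted_d2", "forward_select"]


@dataclass
class GlmFit:
    """A fitted binomial GLM with the diagnostics selection needs."""

    names: list[str]  # predictor names, excluding intercept
    coefficients: np.ndarray  # intercept first
    fitted: np.ndarray
    resdev: float
    nulldev: float
    n: int
    p: int  # number of estimated coefficients incl. intercept
    converged: bool
    boundary_fit: bool

    @property
    def bic(self) -> float:
        # For 0/1 responses the saturated log-likelihood is 0, so the
        # residual deviance is −2ℓ and this is the usual −2ℓ + p log n.
        return self.resdev + self.p * math.log(self.n)

    @property
    def d2(self) -> float:
        return (self.nulldev - self.resdev) / self.nulldev if self.nulldev > 0 else 0.0

    @property
    def adj_d2(self) -> float:
        return adjusted_d2(self)


@dataclass
class StepRecord:
    """Audit entry for one candidate evaluated during forward selection."""

    step: int
    candidate: str
    bic_before: float
    bic_after: float | None
    chisq_p: float | None
    accepted: bool
    reason: str  # "accepted" | "bic" | "significance" | "boundary_fit" | "not_converged" | "fit_error"


@dataclass
class SelectedModel:
    """Result of forward selection for one species × predictor subset."""

    species: str
    subset_name: str
    selected: list[str]
    fit: GlmFit
    audit: list[StepRecord] = field(default_factory=list)

    def coefficient_signs(self) -> dict[str, int]:
        return {name: int(np.sign(self.fit.coefficients[self.fit.names.index(name) + 1]))
                for name in self.selected}


def fit_binomial(y: np.ndarray, X: pd.DataFrame | None, eps: float = 1e-10,
                 maxiter: int = 100, tol: float = 1e-8) -> GlmFit:
    """Fit a logit-link binomial GLM by IRLS (intercept always included).

    ``X`` may be None/empty for the intercept-only model. Raises on a
    rank-deficient design, naming a collinear column. ``boundary_fit``
    flags any fitted probability within ``eps`` of 0 or 1.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be 0/1")
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        names: list[str] = []
        design = np.ones((n, 1))
    else:
        names = list(X.columns)
        design = np.column_stack([np.ones(n), np.asarray(X, dtype=float)])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            for j in range(1, design.shape[1]):
                if np.linalg.matrix_rank(design[:, : j + 1]) < j + 1:
                    raise np.linalg.LinAlgError(f"design is rank deficient: column {names[j - 1]!r} "
                                                "is collinear with earlier columns")
            raise np.linalg.LinAlgError("design is rank deficient")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=maxiter, tol=tol, tol_criterion="deviance")
            converged = bool(getattr(res, "converged", True))
            mu = np.asarray(res.mu)
            coefficients = np.asarray(res.params)
            resdev = float(res.deviance)
            nulldev = float(res.null_deviance)
        except Exception:  # separation / numerical failure
            converged = False
            coefficients = np.full(design.shape[1], np.nan)
            mu = np.full(n, np.nan)
            resdev = np.nan
            pbar = y.mean()
            nulldev = -2 * (y.sum() * np.log(pbar) + (n - y.sum()) * np.log(1 - pbar)) if 0 < pbar < 1 else 0.0
    if not np.isfinite(mu).all():
        boundary = True
        converged = False
    else:
        boundary = bool((mu < eps).any() or (mu > 1 - eps).any())
    return GlmFit(names=names, coefficients=coefficients, fitted=mu, resdev=resdev,
                  nulldev=nulldev, n=n, p=design.shape[1], converged=converged,
                  boundary_fit=boundary)


def deviance_chisq(fit_small: GlmFit, fit_big: GlmFit) -> float:
    """Chi-square p-value comparing nested GLMs via the deviance drop."""
    if fit_small.n != fit_big.n:
        raise ValueError("fits use different numbers of observations")
    if not set(fit_small.names) <= set(fit_big.names):
        raise ValueError("models are not nested")
    df = fit_big.p - fit_small.p
    if df == 0:
        return 1.0
    stat = max(fit_small.resdev - fit_big.resdev, 0.0)
    return float(stats.chi2.sf(stat, df))


def adjusted_d2(fit: GlmFit) -> float:
    """Adjusted D²; penalises parameter count, may be negative."""
    if fit.n <= fit.p:
        raise ValueError("adjusted D² undefined for n <= p")
    return 1.0 - ((fit.n - 1) / (fit.n - fit.p)) * (1.0 - fit.d2)


def forward_select(y: np.ndarray, candidates: pd.DataFrame, species: str = "",
                   subset_name: str = "", alpha: float = 0.05, eps: float = 1e-10) -> SelectedModel:
    """Three-condition forward selection over named candidate columns.

    Each step re-ranks the remaining candidates by the BIC of the model
    including them, then walks the ranking: the first candidate passing
    all three conditions is accepted; one failing convergence or
    boundary-probability checks (condition iii) is skipped in favour of
    the next, but the walk stops as soon as a candidate fails the BIC
    drop or the significance test, since lower-ranked candidates cannot
    do better on BIC. An empty selection is a legal outcome. Fit errors
    count as condition-(iii) failures.
    """
    if candidates.columns.duplicated().any():
        raise ValueError("candidate names must be unique")
    y = np.asarray(y, dtype=float)
    selected: list[str] = []
    audit: list[StepRecord] = []
    current = fit_binomial(y, None, eps=eps)
    step = 0
    while True:
        step += 1
        remaining = [c for c in candidates.columns if c not in selected]
        if not remaining:
            break
        trials = []
        for name in remaining:
            try:
                trial = fit_binomial(y, candidates[selected + [name]], eps=eps)
                trials.append((name, trial, None))
            except Exception as err:
                trials.append((name, None, str(err)))
        ranked = sorted(trials, key=lambda it: it[1].bic if it[1] is not None and np.isfinite(it[1].bic)
                        else np.inf)
        accepted = None
        for name, trial, err in ranked:
            if trial is None or not np.isfinite(trial.resdev):
                audit.append(StepRecord(step, name, current.bic, None, None, False,
                                        "fit_error" if err else "not_converged"))
                continue
            if trial.bic >= current.bic:
                audit.append(StepRecord(step, name, current.bic, trial.bic, None, False, "bic"))
                break  # ranked by BIC: nothing later can pass (i)
            pval = deviance_chisq(current, trial)
            if pval >= alpha:
                audit.append(StepRecord(step, name, current.bic, trial.bic, pval, False, "significance"))
                break  # substitution rule requires (i) and (ii) to hold
            if not trial.converged:
                audit.append(StepRecord(step, name, current.bic, trial.bic, pval, False, "not_converged"))
                continue  # condition (iii): substitute next on the BIC list
            if trial.boundary_fit:
                audit.append(StepRecord(step, name, current.bic, trial.bic, pval, False, "boundary_fit"))
                continue
            audit.append(StepRecord(step, name, current.bic, trial.bic, pval, True, "accepted"))
            accepted = (name, trial)
            break
        if accepted is None:
            break
        selected.append(accepted[0])
        current = accepted[1]
    return SelectedModel(species=species, subset_name=subset_name, selected=selected,
                         fit=current, audit=audit)
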