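"""Logistic model fitting, G² nested-model tests, and bootstrap c-statistics.

Each evaluated model is a plain maximum-likelihood logistic regression of a
binary mortality outcome on the four baseline covariates (age in years,
male, aborigine, surgery), optionally plus one comorbidity measure's binary
category columns. Comorbidity columns with 0% or 100% prevalence in the
analytic cohort are dropped before fitting.

Model comparison uses G² = 2·(ℓ_full − ℓ_base), chi-squared with df equal
to the parameter-count difference; because published tables sometimes print
the total non-intercept parameter count instead, both df conventions are
reported. Discrimination is the c-statistic (area under the ROC curve; ties
counted one-half), with a percentile bootstrap confidence interval obtained
by resampling patients with replacement and refitting inside every
replicate. Paired comparisons refit two models on the same resampled rows
and report the fraction of replicates in which one wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                             PerfectSeparationWarning)

from .errors import (ContractError, DegenerateOutcomeError,
                     UndefinedStatisticError)

__all__ = [
    "BASELINE_COLUMNS",
    "FitResult",
    "ModelEvalResult",
    "BootstrapCResult",
    "PairedCompareResult",
    "drop_degenerate_columns",
    "fit_logistic",
    "g2_statistic",
    "c_statistic",
    "bootstrap_c_ci",
    "paired_bootstrap_compare",
    "assemble_design",
    "evaluate_model",
]

BASELINE_COLUMNS = ["age_years", "male", "aborigine", "surgery"]

G2_TOLERANCE = 1e-6


@dataclass
class FitResult:
    """A fitted logistic model.

    ``n_parameters`` excludes the intercept. ``separation`` flags complete
    or quasi-complete separation (the fit is still returned; scores remain
    usable for ranking).
    """

    params: pd.Series
    bse: pd.Series
    loglik: float
    columns: list[str]
    nobs: int
    converged: bool
    separation: bool
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return len(self.columns)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.params["const"] + X[self.columns].to_numpy(float) @ \
            self.params[self.columns].to_numpy(float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class BootstrapCResult:
    point: float
    ci_low: float
    ci_high: float
    replicates: np.ndarray
    n_redraws: int


@dataclass
class PairedCompareResult:
    win_fraction_a: float
    tie_fraction: float
    diffs: np.ndarray
    n_redraws: int


@dataclass
class ModelEvalResult:
    """One model's full evaluation: fit, G² vs baseline, bootstrap c."""

    fit: FitResult
    g2: Optional[float]
    g2_df_diff: Optional[int]
    g2_df_total: int
    g2_p: Optional[float]
    c_statistic: float
    c_ci: tuple[float, float]
    n_bootstrap: int
    dropped_columns: list[str]


def drop_degenerate_columns(design: pd.DataFrame,
                            ) -> tuple[pd.DataFrame, list[str]]:
    """Remove binary columns with 0% or 100% prevalence over the rows."""
    dropped = [c for c in design.columns
               if design[c].mean() in (0.0, 1.0)]
    return design.drop(columns=dropped), dropped


def fit_logistic(design: pd.DataFrame, outcome: Sequence[int],
                 ) -> FitResult:
    """Maximum-likelihood logistic fit with separation detection.

    Newton-Raphson first; if the Hessian is singular (collinear columns) or
    separation aborts it, a quasi-Newton (BFGS) fit supplies the
    coefficients and log-likelihood and the result is flagged.
    """
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(design):
        raise ContractError("design and outcome lengths differ")
    if y.sum() == 0 or y.sum() == len(y):
        raise DegenerateOutcomeError(
            "outcome has no events or no non-events; the model is degenerate")
    X = design.reset_index(drop=True).astype(float)
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(disp=0, method="newton", maxiter=200, tol=1e-8)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
            res = model.fit(disp=0, method="bfgs", maxiter=1000)
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        separation = True
    converged = bool(res.mle_retvals.get("converged", False))
    bse = res.bse
    if np.any(~np.isfinite(bse)):
        separation = True
    return FitResult(
        params=pd.Series(res.params, index=Xc.columns),
        bse=pd.Series(np.asarray(bse), index=Xc.columns),
        loglik=float(res.llf),
        columns=list(design.columns),
        nobs=len(y),
        converged=converged,
        separation=separation,
    )


def g2_statistic(full: FitResult, base: FitResult,
                 ) -> tuple[float, int, int, float]:
    """Nested-model likelihood-ratio statistic.

    Returns ``(g2, df_diff, df_total, p)`` where g2 = 2(ℓ_full − ℓ_base),
    df_diff is the parameter-count difference (the df the chi-squared
    p-value uses), and df_total is the full model's non-intercept parameter
    count (the convention some published tables print).
    """
    if not set(base.columns) <= set(full.columns):
        raise ContractError(
            "models are not nested: baseline columns are not a subset of the "
            "full model's columns")
    if base.nobs != full.nobs:
        raise ContractError("models were fitted on different numbers of rows")
    g2 = 2.0 * (full.loglik - base.loglik)
    if g2 < -G2_TOLERANCE:
        raise ContractError(
            f"negative G² ({g2:.3g}): the 'full' model fits worse than its "
            f"nested baseline, which indicates a fitting failure")
    g2 = max(g2, 0.0)
    df_diff = full.n_parameters - base.n_parameters
    df_total = full.n_parameters
    p = float(stats.chi2.sf(g2, df_diff)) if df_diff > 0 else 1.0
    return g2, df_diff, df_total, p


def c_statistic(scores: Sequence[float], outcomes: Sequence[int]) -> float:
    """Concordance probability (ROC area), ties counted one-half.

    c = (concordant + 0.5·tied) / (n_events · n_nonevents), computed via
    midranks so it is exact and O(n log n).
    """
    y = np.asarray(outcomes, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ContractError("scores and outcomes lengths differ")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedStatisticError(
            "c-statistic undefined: outcome has a single class")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _resample_indices(rng: np.random.Generator, y: np.ndarray,
                      max_redraws: int = 1000) -> tuple[np.ndarray, int]:
    """One bootstrap index vector with both outcome classes present."""
    n = len(y)
    for redraws in range(max_redraws + 1):
        idx = rng.integers(0, n, size=n)
        s = y[idx].sum()
        if 0 < s < n:
            return idx, redraws
    raise DegenerateOutcomeError(
        "could not draw a bootstrap replicate containing both outcome classes")


def bootstrap_c_ci(design: pd.DataFrame, outcome: Sequence[int],
                   n_reps: int = 1000, seed: Optional[int] = None,
                   refit: bool = True) -> BootstrapCResult:
    """Percentile bootstrap CI for the c-statistic.

    Patients are resampled with replacement to the original n; by default
    the model is refitted inside every replicate and the replicate's c is
    computed on the replicate's own rows. Replicates with a single-class
    outcome are redrawn (counted; a warning is issued past 10%). The CI is
    the 2.5th/97.5th percentile of the replicate vector.
    """
    y = np.asarray(outcome, dtype=int)
    X = design.reset_index(drop=True)
    full_fit = fit_logistic(X, y)
    point = c_statistic(full_fit.predict(X), y)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    total_redraws = 0
    for r in range(n_reps):
        idx, redraws = _resample_indices(rng, y)
        total_redraws += redraws
        Xb = X.iloc[idx].reset_index(drop=True)
        yb = y[idx]
        fit = fit_logistic(Xb, yb) if refit else full_fit
        reps[r] = c_statistic(fit.predict(Xb), yb)
    if total_redraws > 0.10 * n_reps:
        warnings.warn(
            f"{total_redraws} bootstrap redraws over {n_reps} replicates "
            f"(>10%): the outcome is very rare in this cohort")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BootstrapCResult(point=point, ci_low=float(lo), ci_high=float(hi),
                            replicates=reps, n_redraws=total_redraws)


def paired_bootstrap_compare(design_a: pd.DataFrame, design_b: pd.DataFrame,
                             outcome: Sequence[int], n_reps: int = 1000,
                             seed: Optional[int] = None,
                             ) -> PairedCompareResult:
    """Refit two models on the same resampled rows; report A's win fraction.

    Ties (|c_A − c_B| below numerical tolerance) are reported separately,
    not counted as wins.
    """
    y = np.asarray(outcome, dtype=int)
    if len(design_a) != len(design_b) or len(design_a) != len(y):
        raise ContractError("paired comparison requires identical rows")
    Xa = design_a.reset_index(drop=True)
    Xb = design_b.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_reps)
    total_redraws = 0
    for r in range(n_reps):
        idx, redraws = _resample_indices(rng, y)
        total_redraws += redraws
        yb = y[idx]
        ca = c_statistic(fit_logistic(Xa.iloc[idx].reset_index(drop=True), yb)
                         .predict(Xa.iloc[idx].reset_index(drop=True)), yb)
        cb = c_statistic(fit_logistic(Xb.iloc[idx].reset_index(drop=True), yb)
                         .predict(Xb.iloc[idx].reset_index(drop=True)), yb)
        diffs[r] = ca - cb
    tol = 1e-12
    wins = float(np.mean(diffs > tol))
    ties = float(np.mean(np.abs(diffs) <= tol))
    if total_redraws > 0.10 * n_reps:
        warnings.warn(f"{total_redraws} bootstrap redraws over {n_reps} "
                      f"replicates (>10%)")
    return PairedCompareResult(win_fraction_a=wins, tie_fraction=ties,
                               diffs=diffs, n_redraws=total_redraws)


def assemble_design(cohort_df: pd.DataFrame,
                    comorbidity_matrix: Optional[pd.DataFrame] = None,
                    ) -> pd.DataFrame:
    """Baseline covariates (+ optionally a comorbidity block) as one table.

    Degenerate (0%/100% prevalence) comorbidity columns are retained here;
    :func:`evaluate_model` drops them and records the names.
    """
    X = cohort_df.set_index("patient_id")[BASELINE_COLUMNS].astype(float)
    if comorbidity_matrix is not None:
        cm = comorbidity_matrix.loc[X.index]
        X = pd.concat([X, cm.astype(float)], axis=1)
    return X


def evaluate_model(cohort_df: pd.DataFrame, outcome_col: str,
                   comorbidity_matrix: Optional[pd.DataFrame] = None,
                   n_bootstrap: int = 1000, seed: Optional[int] = None,
                   ) -> ModelEvalResult:
    """Fit baseline (+ comorbidity) models and assemble the full evaluation.

    For a baseline-only evaluation (``comorbidity_matrix=None``) the G²
    fields are None, mirroring the N/A entries of a published baseline row.
    """
    y = cohort_df[outcome_col].to_numpy(int)
    base_X = assemble_design(cohort_df)
    base_fit = fit_logistic(base_X, y)
    if comorbidity_matrix is None:
        boot = bootstrap_c_ci(base_X, y, n_reps=n_bootstrap, seed=seed)
        return ModelEvalResult(
            fit=base_fit, g2=None, g2_df_diff=None,
            g2_df_total=base_fit.n_parameters, g2_p=None,
            c_statistic=boot.point, c_ci=(boot.ci_low, boot.ci_high),
            n_bootstrap=n_bootstrap, dropped_columns=[])
    reduced, dropped = drop_degenerate_columns(
        comorbidity_matrix.loc[base_X.index])
    full_X = assemble_design(cohort_df, reduced)
    full_fit = fit_logistic(full_X, y)
    full_fit.dropped_columns = dropped
    g2, df_diff, df_total, p = g2_statistic(full_fit, base_fit)
    boot = bootstrap_c_ci(full_X, y, n_reps=n_bootstrap, seed=seed)
    return ModelEvalResult(
        fit=full_fit, g2=g2, g2_df_diff=df_diff, g2_df_total=df_total,
        g2_p=p, c_statistic=boot.point, c_ci=(boot.ci_low, boot.ci_high),
        n_bootstrap=n_bootstrap, dropped_columns=dropped)
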