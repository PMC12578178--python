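"""Sensitivity analysis: risk factors for DIMD among complete-case reports.

The outcome is y = 1 for DIMD case reports and y = 0 for all other reports
in the same deduplicated, complete-case universe (reports with non-missing
sex and age).  Candidate covariates are binary: male sex, age < 33 years
(strict), one prime-suspect exposure indicator per screened drug, and seven
comorbidity flags derived from indication PTs.

Drugs enter the candidate set through the univariate screen — ROR lower 95%
bound > 1, case count a > 100 and Bonferroni-adjusted Fisher p < 0.01 (all
strict) — then an L1-penalized (LASSO) logistic path with stratified 10-fold
cross-validation picks λ.min; covariates with non-zero coefficients at λ.min
go into an unpenalized multivariable logistic fit whose Wald CIs and
Bonferroni-corrected p-values are reported together with the ROC AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cohort import Cohort
from .disproportionality import bonferroni

__all__ = [
    "SeparationError",
    "DesignMatrix",
    "LassoResult",
    "LogisticFit",
    "complete_cases",
    "univariate_screen",
    "build_design",
    "lasso_select",
    "fit_logistic",
    "roc_auc",
    "run_risk_model",
]

AGE_SPLIT_YEARS = 33.0  # age < 33 (strict) -> young-age indicator


class SeparationError(RuntimeError):
    """Complete (quasi-)separation in the logistic fit."""


@dataclass
class DesignMatrix:
    """Binary design for the sensitivity analysis (no missing values)."""

    X: pd.DataFrame  # one column per covariate, values in {0, 1}
    y: np.ndarray  # outcome per row
    primaryid: pd.Series

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("design matrix contains missing values")
        if not self.X.columns.is_unique:
            raise ValueError("design matrix column names must be unique")


@dataclass
class LassoResult:
    lambdas: np.ndarray
    cv_error: np.ndarray  # mean CV loss per lambda
    cv_se: np.ndarray
    lambda_min: float
    selected: tuple[str, ...]  # covariates with non-zero coefficient
    coef_at_min: pd.Series  # standardized-scale coefficients
    n_folds: int
    seed: int
    metric: str
    n_unconverged: int = 0


@dataclass
class LogisticFit:
    table: pd.DataFrame  # covariate, coef, or, or_lo, or_hi, p, p_adjust
    intercept: float
    converged: bool
    llf: float
    fitted: np.ndarray  # in-sample probabilities
    model: object = field(repr=False, default=None)


def complete_cases(cohort: Cohort) -> pd.DataFrame:
    """Reports with non-missing sex and age (the complete-data rule)."""
    reports = cohort.reports
    keep = reports["sex"].isin(["F", "M"]) & reports["age_years"].notna()
    subset = reports.loc[keep]
    if subset.empty:
        raise ValueError("no complete-case reports (sex and age both present)")
    return subset.reset_index(drop=True)


def univariate_screen(
    signals: pd.DataFrame,
    *,
    min_count: int = 100,
    max_p_adjust: float = 0.01,
) -> pd.DataFrame:
    """Drugs with ROR lower 95% bound > 1, a > min_count and Bonferroni p <
    max_p_adjust — all strict inequalities."""
    keep = (
        (signals["ror_lo"] > 1.0)
        & (signals["a"] > min_count)
        & (signals["p_adjust"] < max_p_adjust)
    )
    return signals.loc[keep].reset_index(drop=True)


def build_design(
    reports: pd.DataFrame,
    exposures: pd.DataFrame,
    screened_drugs: Sequence[str],
    comorbidity_flags: Sequence[str] = (),
) -> DesignMatrix:
    """Assemble the binary design matrix over complete-case reports.

    Columns: ``male``, ``age_lt_33`` (strict; age exactly 33 -> 0), one
    ``drug:NAME`` indicator per screened drug (prime-suspect exposure) and
    the comorbidity flags.  Constant columns are retained (the LASSO handles
    them) but reported with a warning.
    """
    X = pd.DataFrame(index=reports.index)
    X["male"] = (reports["sex"] == "M").astype(np.int8)
    X["age_lt_33"] = (reports["age_years"] < AGE_SPLIT_YEARS).astype(np.int8)

    ids = reports["primaryid"]
    id_index = pd.Index(ids)
    for drug in screened_drugs:
        exposed = set(exposures.loc[exposures["drug"] == drug, "primaryid"])
        X[f"drug:{drug}"] = id_index.isin(exposed).astype(np.int8)
    for flag in comorbidity_flags:
        X[flag] = reports[flag].astype(np.int8)

    constant = [c for c in X.columns if X[c].nunique() == 1]
    if constant:
        warnings.warn(
            f"constant design columns retained: {constant}", stacklevel=2
        )
    y = reports["is_dimd_case"].to_numpy(dtype=np.int8)
    return DesignMatrix(X=X, y=y, primaryid=ids.reset_index(drop=True))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def _lambda_path(
    Xs: np.ndarray, y: np.ndarray, n_lambdas: int, lambda_min_ratio: float
) -> np.ndarray:
    n = Xs.shape[0]
    resid = y - y.mean()
    lam_max = np.abs(Xs.T @ resid).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)


def _l1_fit(
    Xs: np.ndarray, y: np.ndarray, lam: float, tol: float, max_iter: int
) -> tuple[np.ndarray, float, bool]:
    """One L1-penalized logistic fit at penalty lam (glmnet scale: mean
    log-loss + lam * ||w||_1).  Returns (coef, intercept, converged)."""
    n = Xs.shape[0]
    clf = LogisticRegression(
        penalty="l1",
        C=1.0 / (n * lam),
        solver="liblinear",
        tol=tol,
        max_iter=max_iter,
        intercept_scaling=100.0,  # keep the intercept effectively unpenalized
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xs, y)
    converged = int(np.asarray(clf.n_iter_).max()) < max_iter
    return clf.coef_.ravel(), float(clf.intercept_[0]), converged


def lasso_select(
    design: DesignMatrix,
    *,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 16,
    lambda_min_ratio: float = 0.01,
    lambdas: Sequence[float] | None = None,
    metric: str = "deviance",
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> LassoResult:
    """LASSO path with stratified K-fold CV; selection at λ.min.

    Covariates are standardized (population SD) within each training fold
    and for the final whole-data fit.  ``metric`` is the CV loss: binomial
    ``"deviance"`` (default) or ``"mse"`` (squared error on probabilities).
    Deterministic given the seed.  Fits that hit the iteration cap are
    counted, not fatal.
    """
    X = design.X.to_numpy(dtype=float)
    y = np.asarray(design.y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes required for the LASSO")
    if metric not in ("deviance", "mse"):
        raise ValueError(f"unknown CV metric {metric!r}")

    Xs_full, _, sd_full = _standardize(X)
    lams = (
        np.asarray(sorted(lambdas, reverse=True), dtype=float)
        if lambdas is not None
        else _lambda_path(Xs_full, y, n_lambdas, lambda_min_ratio)
    )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    losses = np.zeros((folds, lams.size))
    n_unconverged = 0
    for k, (tr, te) in enumerate(skf.split(X, y)):
        Xs_tr, mean_tr, sd_tr = _standardize(X[tr])
        Xs_te = (X[te] - mean_tr) / sd_tr
        for j, lam in enumerate(lams):
            coef, icpt, ok = _l1_fit(Xs_tr, y[tr], lam, tol, max_iter)
            n_unconverged += not ok
            eta = Xs_te @ coef + icpt
            p = 1.0 / (1.0 + np.exp(-eta))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            if metric == "deviance":
                losses[k, j] = 2.0 * log_loss(y[te], p, labels=[0, 1])
            else:
                losses[k, j] = float(np.mean((y[te] - p) ** 2))

    cv_mean = losses.mean(axis=0)
    cv_se = losses.std(axis=0, ddof=1) / np.sqrt(folds)
    j_min = int(np.argmin(cv_mean))
    lam_min = float(lams[j_min])

    coef, _, ok = _l1_fit(Xs_full, y, lam_min, tol, max_iter)
    n_unconverged += not ok
    coef_series = pd.Series(coef, index=design.X.columns)
    selected = tuple(coef_series.index[np.abs(coef_series.to_numpy()) > 1e-10])
    return LassoResult(
        lambdas=lams,
        cv_error=cv_mean,
        cv_se=cv_se,
        lambda_min=lam_min,
        selected=selected,
        coef_at_min=coef_series,
        n_folds=folds,
        seed=seed,
        metric=metric,
        n_unconverged=n_unconverged,
    )


def fit_logistic(
    design: DesignMatrix, covariates: Sequence[str] | None = None
) -> LogisticFit:
    """Unpenalized maximum-likelihood logistic fit with Wald 95% CIs and
    Bonferroni correction over the tested covariates.

    Raises :class:`SeparationError` naming the offending covariate when a
    binary covariate perfectly predicts the outcome among its exposed
    reports (zero cell — the MLE diverges).
    """
    cols = list(covariates) if covariates is not None else list(design.X.columns)
    if not cols:
        raise ValueError("no covariates to fit")
    X = design.X.loc[:, cols]
    y = np.asarray(design.y, dtype=int)

    separating = []
    for c in cols:
        x = X[c].to_numpy()
        n_exp = int((x == 1).sum())
        if n_exp == 0:
            continue
        n_case = int(y[x == 1].sum())
        if n_case in (0, n_exp):
            separating.append(c)
    if separating:
        raise SeparationError(
            "complete separation for covariate(s): " + ", ".join(separating)
        )

    model = sm.Logit(y, sm.add_constant(X.astype(float), has_constant="add"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=200)
    params = res.params.drop("const")
    ci = res.conf_int().drop(index="const")
    pvals = res.pvalues.drop("const")
    table = pd.DataFrame(
        {
            "covariate": params.index,
            "coef": params.to_numpy(),
            "or": np.exp(params.to_numpy()),
            "or_lo": np.exp(ci[0].to_numpy()),
            "or_hi": np.exp(ci[1].to_numpy()),
            "p": pvals.to_numpy(),
            "p_adjust": bonferroni(pvals.to_numpy(), m=len(cols)),
        }
    ).reset_index(drop=True)
    return LogisticFit(
        table=table,
        intercept=float(res.params["const"]),
        converged=bool(res.mle_retvals.get("converged", True)),
        llf=float(res.llf),
        fitted=np.asarray(res.predict()),
        model=res,
    )


def roc_auc(y: Sequence[int], scores: Sequence[float]) -> float:
    """AUC by the rank (Mann–Whitney) formulation with tie correction."""
    y_arr = np.asarray(y, dtype=int)
    if len(np.unique(y_arr)) < 2:
        raise ValueError("AUC requires both outcome classes")
    return float(roc_auc_score(y_arr, np.asarray(scores, dtype=float)))


def run_risk_model(
    cohort: Cohort,
    signals: pd.DataFrame,
    *,
    seed: int = 0,
    folds: int = 10,
    use_lasso_selection: bool = True,
    n_lambdas: int = 16,
) -> dict:
    """End-to-end sensitivity analysis.

    complete cases -> univariate screen -> design matrix -> LASSO (λ.min)
    -> multivariable logistic with Bonferroni -> ROC AUC.  With
    ``use_lasso_selection=False`` the logistic model takes every screened
    covariate (the LASSO path is still computed and reported).
    """
    cases = complete_cases(cohort)
    screened = univariate_screen(signals)
    design = build_design(
        cases,
        cohort.exposures,
        screened["drug"].tolist(),
        cohort.comorbidity_flags,
    )
    lasso = lasso_select(design, folds=folds, seed=seed, n_lambdas=n_lambdas)
    covariates = list(lasso.selected) if use_lasso_selection else list(design.X.columns)
    if not covariates:
        raise ValueError("LASSO selected no covariates; nothing to fit")
    fit = fit_logistic(design, covariates)
    auc = roc_auc(design.y, fit.fitted)
    return {
        "n_complete": len(cases),
        "n_candidates": design.X.shape[1],
        "screened": screened,
        "design": design,
        "lasso": lasso,
        "fit": fit,
        "auc": auc,
    }
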