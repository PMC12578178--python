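"""Sensitivity analysis: complete cases, screening thresholds, LASSO
selection, logistic inference and AUC."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_tables
from faers_dimd.cohort import build_cohort_from_tables
from faers_dimd.risk_model import (
    DesignMatrix,
    SeparationError,
    build_design,
    complete_cases,
    fit_logistic,
    lasso_select,
    roc_auc,
    univariate_screen,
)


def _design_from(X: pd.DataFrame, y: np.ndarray) -> DesignMatrix:
    return DesignMatrix(
        X=X, y=y, primaryid=pd.Series(np.arange(len(y)).astype(str))
    )


def _simulate(seed, n, betas, expose_p=0.2, intercept=-2.5):
    """Binary design + logistic outcome with known log-odds coefficients."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {f"x{j}": (rng.random(n) < expose_p).astype(np.int8)
         for j in range(len(betas))}
    )
    eta = intercept + X.to_numpy() @ np.asarray(betas)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(np.int8)
    return _design_from(X, y)


# ------------------------------------------------------------ complete cases
def test_complete_cases_counting():
    demo = []
    for i in range(1, 11):
        row = {"primaryid": str(i), "caseid": str(i), "fda_dt": "20240101",
               "sex": "F", "age": "50", "age_cod": "YR"}
        if i in (1, 2):
            row["age"] = ""  # missing age -> dropped
        if i == 3:
            row["sex"] = ""  # missing sex -> dropped
        demo.append(row)
    cohort = build_cohort_from_tables(make_tables(demo, reac_rows=[
        {"primaryid": str(i), "caseid": str(i), "pt": "Rash"} for i in range(1, 11)
    ]))
    kept = complete_cases(cohort)
    assert len(kept) == 7
    assert set(kept["primaryid"]) == {str(i) for i in range(4, 11)}


# ------------------------------------------------------------------- screen
@pytest.mark.parametrize(
    "a, ror_lo, p_adj, retained",
    [
        (150, 1.2, 0.001, True),
        (101, 1.2, 0.001, True),
        (100, 1.2, 0.001, False),  # strict a > 100
        (150, 0.99, 0.001, False),
        (150, 1.0, 0.001, False),  # strict ror_lo > 1
        (150, 1.2, 0.01, False),  # strict p < 0.01
    ],
)
def test_univariate_screen_thresholds(a, ror_lo, p_adj, retained):
    signals = pd.DataFrame(
        [{"drug": "X", "a": a, "ror_lo": ror_lo, "p_adjust": p_adj}]
    )
    out = univariate_screen(signals)
    assert (len(out) == 1) is retained


# ------------------------------------------------------------------- design
def _reports(rows):
    df = pd.DataFrame(rows)
    df["is_dimd_case"] = df.get("is_dimd_case", False)
    return df


def test_build_design_indicators_and_age_boundary():
    reports = _reports(
        [
            {"primaryid": "1", "sex": "M", "age_years": 30.0, "flagA": True},
            {"primaryid": "2", "sex": "F", "age_years": 33.0, "flagA": False},
            {"primaryid": "3", "sex": "F", "age_years": 35.0, "flagA": False},
        ]
    )
    exposures = pd.DataFrame({"primaryid": ["1"], "drug": ["X"]})
    d = build_design(reports, exposures, ["X"], ["flagA"])
    assert list(d.X.columns) == ["male", "age_lt_33", "drug:X", "flagA"]
    assert d.X.loc[0].tolist() == [1, 1, 1, 1]
    assert d.X.loc[1, "age_lt_33"] == 0  # age exactly 33 is not "< 33"
    assert d.X.loc[2, "drug:X"] == 0


def test_build_design_warns_on_constant_column():
    reports = _reports(
        [{"primaryid": "1", "sex": "F", "age_years": 50.0},
         {"primaryid": "2", "sex": "F", "age_years": 60.0}]
    )
    exposures = pd.DataFrame({"primaryid": [], "drug": []})
    with pytest.warns(UserWarning, match="constant"):
        d = build_design(reports, exposures, ["X"], [])
    assert "drug:X" in d.X.columns  # retained, not dropped


# -------------------------------------------------------------------- LASSO
def test_lasso_full_shrinkage_at_huge_lambda():
    d = _simulate(0, 2000, [1.5, 0.0])
    res = lasso_select(d, folds=3, seed=0, lambdas=[10.0, 5.0])
    assert res.selected == ()


def test_lasso_near_zero_lambda_matches_unpenalized_fit():
    d = _simulate(1, 4000, [1.0, -0.5, 0.0])
    res = lasso_select(d, folds=3, seed=0, lambdas=[1e-7, 5e-8])
    Xs = (d.X - d.X.mean()) / d.X.std(ddof=0)
    ref = sm.Logit(d.y, sm.add_constant(Xs)).fit(disp=0)
    for col in d.X.columns:
        assert res.coef_at_min[col] == pytest.approx(ref.params[col], abs=1e-3)


def test_lasso_selects_strong_covariate_across_seeds():
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        d = _simulate(100 + seed, 20_000, [np.log(8.0)] + [0.0] * 20,
                      expose_p=0.05, intercept=-3.0)
        res = lasso_select(d, folds=10, seed=seed, n_lambdas=8)
        hits += "x0" in res.selected
    assert hits >= int(0.95 * n_seeds)


def test_lasso_same_seed_is_reproducible():
    d = _simulate(2, 5000, [1.0, 0.0, 0.0])
    r1 = lasso_select(d, folds=5, seed=3)
    r2 = lasso_select(d, folds=5, seed=3)
    assert r1.lambda_min == r2.lambda_min
    assert r1.selected == r2.selected
    np.testing.assert_array_equal(r1.cv_error, r2.cv_error)


def test_lasso_requires_two_classes():
    d = _design_from(pd.DataFrame({"x": [0, 1, 0, 1]}), np.zeros(4, dtype=int))
    with pytest.raises(ValueError):
        lasso_select(d, folds=2, seed=0)


# ----------------------------------------------------------------- logistic
def test_logistic_recovers_designed_or():
    d = _simulate(11, 50_000, [np.log(4.0), 0.0], expose_p=0.1)
    fit = fit_logistic(d)
    row = fit.table.set_index("covariate").loc["x0"]
    assert row["or_lo"] < 4.0 < row["or_hi"]
    null = fit.table.set_index("covariate").loc["x1"]
    assert null["p_adjust"] > 0.1


def test_logistic_or_recovery_median_bias_small():
    designed = [1.0, 2.0, 4.0, 8.0]
    biases = {m: [] for m in designed}
    for seed in range(20):
        d = _simulate(
            300 + seed, 50_000, [np.log(m) for m in designed],
            expose_p=0.08, intercept=-3.0,
        )
        fit = fit_logistic(d)
        ors = fit.table.set_index("covariate")["or"]
        for j, m in enumerate(designed):
            biases[m].append(abs(ors[f"x{j}"] - m) / m)
    for m in designed:
        assert np.median(biases[m]) < 0.05, m


def test_saturated_single_covariate_equals_cross_product_ratio():
    # counts (a, b, c, d) = (30, 20, 10, 40): OR = ad/bc = 6
    x = np.repeat([1, 1, 0, 0], [30, 20, 10, 40])
    y = np.repeat([1, 0, 1, 0], [30, 20, 10, 40])
    d = _design_from(pd.DataFrame({"x": x}), y)
    fit = fit_logistic(d)
    assert fit.table.loc[0, "or"] == pytest.approx(6.0, rel=1e-6)


def test_complete_separation_raises_naming_covariate():
    x = np.repeat([1, 0], [20, 80])
    y = np.repeat([1, 0], [20, 80])  # x = 1 exactly when y = 1
    d = _design_from(pd.DataFrame({"sep_col": x}), y)
    with pytest.raises(SeparationError, match="sep_col"):
        fit_logistic(d)


def test_bonferroni_family_is_number_of_covariates():
    d = _simulate(5, 5000, [1.0, 0.0, 0.0])
    fit = fit_logistic(d)
    expected = np.minimum(1.0, fit.table["p"] * 3)
    np.testing.assert_allclose(fit.table["p_adjust"], expected)


# ---------------------------------------------------------------------- AUC
def test_auc_worked_examples():
    assert roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2]) == 1.0
    assert roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5
    assert roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.7, 0.85]) == 0.75


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


@given(
    st.lists(st.floats(0.01, 0.99), min_size=6, max_size=30),
    st.sampled_from(["logit", "cube", "affine"]),
)
def test_auc_invariant_under_monotone_transforms(scores, transform):
    y = [i % 2 for i in range(len(scores))]
    s = np.asarray(scores)
    transformed = {
        "logit": np.log(s / (1 - s)),
        "cube": s**3,
        "affine": 5 * s + 2,
    }[transform]
    assert roc_auc(y, s) == pytest.approx(roc_auc(y, transformed), abs=1e-12)
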