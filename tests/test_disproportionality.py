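"""Disproportionality statistics against independent oracles, plus the
combined signal-classification logic."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special

from conftest import make_tables
from faers_dimd.cohort import build_cohort_from_tables
from faers_dimd.disproportionality import (
    ContingencyTable,
    EBGMHyperparams,
    bcpnn_ic,
    bonferroni,
    classify_signals,
    contingency,
    ebgm_fit,
    ebgm_score,
    fisher_exact,
    prr,
    ror,
    volcano_table,
)
from oracles import (
    bcpnn_moments_by_quadrature,
    chi2_oracle,
    fisher_two_sided_exact,
    gamma_posterior_log_mean_by_quadrature,
    prr_oracle,
    ror_oracle,
)

Z = 1.959963984540054


# ----------------------------------------------------------------- 2x2 tables
def _fixture_cohort():
    """10 hand-countable reports: X is PS on 4 (3 cases), others on 6 (2 cases)."""
    demo, drug, reac = [], [], []
    memberships = [
        ("1", "X", "Chorea"), ("2", "X", "Chorea"), ("3", "X", "Tic"),
        ("4", "X", "Nausea"),
        ("5", "Y", "Chorea"), ("6", "Y", "Rash"), ("7", "Y", "Rash"),
        ("8", "Z", "Chorea"), ("9", "Z", "Rash"), ("10", "Z", "Rash"),
    ]
    for pid, d, pt in memberships:
        demo.append({"primaryid": pid, "caseid": pid, "fda_dt": "20240101"})
        drug.append({"primaryid": pid, "caseid": pid, "role_cod": "PS", "drugname": d})
        reac.append({"primaryid": pid, "caseid": pid, "pt": pt})
    return build_cohort_from_tables(make_tables(demo, drug, reac))


def test_contingency_hand_counted():
    cohort = _fixture_cohort()
    t = contingency(cohort, "X")
    assert (t.a, t.b, t.c, t.d) == (3, 1, 2, 4)


def test_contingency_degenerate_margins():
    cohort = _fixture_cohort()
    absent = contingency(cohort, "NOT_THERE")
    assert (absent.a, absent.b) == (0, 0)
    # a drug on every report -> c = d = 0
    demo = [{"primaryid": p, "caseid": p, "fda_dt": "20240101"} for p in "12"]
    drug = [{"primaryid": p, "caseid": p, "role_cod": "PS", "drugname": "X"} for p in "12"]
    reac = [{"primaryid": "1", "caseid": "1", "pt": "Chorea"},
            {"primaryid": "2", "caseid": "2", "pt": "Rash"}]
    everywhere = contingency(
        build_cohort_from_tables(make_tables(demo, drug, reac)), "X"
    )
    assert (everywhere.c, everywhere.d) == (0, 0)


FIXED_TABLES = [
    (10, 10, 10, 10), (20, 10, 10, 20), (10, 90, 10, 890), (3, 7, 11, 79),
    (25, 75, 100, 800), (1, 9, 10, 80), (50, 450, 100, 9400), (7, 3, 2, 8),
    (12, 34, 56, 78), (100, 900, 200, 8800), (5, 5, 50, 500), (40, 60, 30, 70),
    (2, 18, 20, 160), (15, 5, 10, 30), (9, 81, 27, 883), (33, 67, 66, 134),
    (4, 16, 8, 72), (11, 1, 3, 9), (60, 140, 120, 680), (8, 2, 5, 25),
    (21, 19, 17, 23),
]


@pytest.mark.parametrize("cells", FIXED_TABLES)
def test_ror_prr_chi2_match_hand_arithmetic(cells):
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    est, lo, hi, corrected = ror(t)
    o_est, o_lo, o_hi = ror_oracle(a, b, c, d)
    assert not corrected
    assert est == pytest.approx(o_est, abs=1e-10 * max(1, o_est))
    assert lo == pytest.approx(o_lo, rel=1e-10)
    assert hi == pytest.approx(o_hi, rel=1e-10)
    p_est, chi2, _ = prr(t)
    assert p_est == pytest.approx(prr_oracle(a, b, c, d), rel=1e-12)
    assert chi2 == pytest.approx(chi2_oracle(a, b, c, d), rel=1e-10)


def test_ror_worked_example():
    est, lo, hi, _ = ror(ContingencyTable(20, 10, 10, 20))
    assert est == 4.0
    assert lo == pytest.approx(1.3673, abs=5e-4)
    assert hi == pytest.approx(11.7017, abs=5e-3)
    _, chi2, _ = prr(ContingencyTable(20, 10, 10, 20))
    assert chi2 == pytest.approx(20 / 3, rel=1e-12)


def test_prr_worked_examples():
    est, _, _ = prr(ContingencyTable(10, 90, 10, 890))
    assert est == pytest.approx(9.0, rel=1e-12)
    # equal row proportions -> PRR 1
    est, _, _ = prr(ContingencyTable(10, 90, 20, 180))
    assert est == pytest.approx(1.0, rel=1e-12)


def test_zero_cell_triggers_flagged_haldane():
    est, lo, hi, corrected = ror(ContingencyTable(0, 10, 10, 10))
    assert corrected
    assert est == pytest.approx((0.5 * 10.5) / (10.5 * 10.5), rel=1e-12)
    est_nan, *_ = ror(ContingencyTable(0, 10, 10, 10), continuity="nan")
    assert math.isnan(est_nan)


def test_ror_prr_monotone_in_a():
    rors, prrs = [], []
    for a in range(1, 21):
        t = ContingencyTable(a, 50, 40, 900)
        rors.append(ror(t)[0])
        prrs.append(prr(t)[0])
    assert all(x < y for x, y in zip(rors, rors[1:]))
    assert all(x < y for x, y in zip(prrs, prrs[1:]))


def test_ror_close_to_prr_for_rare_events():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = int(rng.integers(1, 20))
        b = int(rng.integers(500, 5000))
        c = int(rng.integers(10, 100))
        d = int(rng.integers(20_000, 100_000))
        t = ContingencyTable(a, b, c, d)
        r, p = ror(t)[0], prr(t)[0]
        assert abs(r - p) / p < 0.05


# --------------------------------------------------------------------- BCPNN
def test_bcpnn_independence_limit():
    ic, ic025 = bcpnn_ic(ContingencyTable(1000, 1000, 1000, 1000))
    assert abs(ic) < 0.01
    assert ic025 < ic


def test_bcpnn_shrinks_toward_zero():
    # raw IC = log2(2) = 1; shrunk estimate must land in (0.8, 1.0)
    ic, _ = bcpnn_ic(ContingencyTable(25, 75, 100, 800))
    assert 0.8 < ic < 1.0


@pytest.mark.parametrize("cells", [(25, 75, 100, 800), (3, 7, 11, 79),
                                   (0, 10, 20, 170), (100, 900, 200, 8800)])
def test_bcpnn_moments_match_quadrature(cells):
    t = ContingencyTable(*cells)
    ic, ic025 = bcpnn_ic(t)
    e_q, v_q = bcpnn_moments_by_quadrature(*cells)
    assert ic == pytest.approx(e_q, abs=1e-6)
    assert ic025 == pytest.approx(e_q - Z * math.sqrt(v_q), abs=1e-6)


def test_ic025_below_ic_on_grid():
    for cells in FIXED_TABLES:
        ic, ic025 = bcpnn_ic(ContingencyTable(*cells))
        assert ic025 < ic


# ---------------------------------------------------------------------- EBGM
DEGENERATE = EBGMHyperparams(1.0, 1.0, 1.0, 1.0, 1.0)


def test_ebgm_degenerate_prior_closed_form():
    ebgm, eb05 = ebgm_score((0, 1.0), DEGENERATE)
    assert ebgm == pytest.approx(math.exp(special.digamma(1.0)) / 2.0, abs=1e-8)
    assert eb05 <= ebgm


def test_ebgm_large_count_asymptotics_and_quadrature():
    ebgm, _ = ebgm_score((1000, 100.0), DEGENERATE)
    assert ebgm == pytest.approx(10.0, rel=0.01)
    # numeric integration of E[ln lambda] under the Gamma(1001, 101) posterior
    oracle = math.exp(gamma_posterior_log_mean_by_quadrature(1001.0, 101.0))
    assert ebgm == pytest.approx(oracle, rel=1e-6)


def test_eb05_below_ebgm_on_grid():
    h = EBGMHyperparams(2.0, 2.0, 1.0, 0.5, 0.7)
    for a, e in [(0, 1.0), (3, 1.0), (10, 2.5), (100, 40.0), (7, 70.0)]:
        ebgm, eb05 = ebgm_score((a, e), h)
        assert eb05 < ebgm


def test_ebgm_shrinks_toward_prior_mean():
    h = EBGMHyperparams(2.0, 2.0, 2.0, 2.0, 0.5)  # prior mean 1
    for a, e in [(30, 10.0), (8, 2.0), (2, 20.0), (1, 9.0)]:
        ebgm, _ = ebgm_score((a, e), h)
        ratio = a / e
        if ratio > 1:
            assert ebgm < ratio
        else:
            assert ebgm > ratio


def test_ebgm_fit_recovers_single_gamma():
    rng = np.random.default_rng(42)
    n = 5000
    e = rng.uniform(0.5, 50.0, n)
    lam = rng.gamma(2.0, 1 / 2.0, n)
    a = rng.poisson(lam * e)
    h = ebgm_fit(a, e)
    # dominant mixture component should recover (shape 2, rate 2)
    if h.mix_p >= 0.5:
        shape, rate = h.alpha1, h.beta1
    else:
        shape, rate = h.alpha2, h.beta2
    assert shape == pytest.approx(2.0, rel=0.15)
    assert rate == pytest.approx(2.0, rel=0.15)


def test_ebgm_fit_null_data_prior_mean_near_one():
    rng = np.random.default_rng(7)
    e = rng.uniform(50.0, 200.0, 3000)
    a = rng.poisson(e)  # lambda = 1 everywhere
    h = ebgm_fit(a, e)
    assert h.prior_mean == pytest.approx(1.0, rel=0.05)


def test_ebgm_fit_single_table_is_error():
    with pytest.raises(ValueError):
        ebgm_fit([3], [1.0])


# -------------------------------------------------------- Fisher / Bonferroni
@pytest.mark.parametrize(
    "cells, expected",
    [
        ((3, 1, 1, 3), 34 / 70),
        ((1, 1, 1, 1), 1.0),
        ((10, 0, 0, 10), 2 / 184756),
    ],
)
def test_fisher_exact_worked_examples(cells, expected):
    assert fisher_exact(ContingencyTable(*cells)) == pytest.approx(expected, rel=1e-12)


def test_fisher_matches_rational_enumeration_on_random_tables():
    rng = np.random.default_rng(3)
    for _ in range(100):
        cells = rng.integers(0, 11, size=4)
        if cells.sum() == 0 or cells.sum() > 40:
            continue
        t = ContingencyTable(*map(int, cells))
        assert fisher_exact(t) == pytest.approx(
            float(fisher_two_sided_exact(*map(int, cells))), abs=1e-12
        )


def test_bonferroni_caps_and_scales():
    out = bonferroni([0.01, 0.5, 0.0], m=10)
    assert out == pytest.approx([0.1, 1.0, 0.0])
    raw = np.array([0.001, 0.2, 0.9])
    adj = bonferroni(raw)
    assert (adj >= raw).all() and (adj <= 1.0).all()


# ------------------------------------------------------- combined signal rule
def _stats_row(**overrides):
    row = {
        "drug": "X", "a": 5, "ror_lo": 1.5, "prr": 3.0, "chi2": 10.0,
        "ic025": 0.5, "ebgm": 3.0,
    }
    row.update(overrides)
    return pd.DataFrame([row])


@pytest.mark.parametrize(
    "overrides, expected",
    [
        ({}, True),  # all four criteria met, a = 5
        ({"a": 2}, False),  # report count below 3 can never signal
        ({"ror_lo": 0.99}, False),  # conjunction: one failing flag suffices
        ({"prr": 1.9}, False),
        ({"ic025": 0.0}, False),
        ({"ebgm": 2.0}, False),
    ],
)
def test_classify_signals_combined_rule(overrides, expected):
    out = classify_signals(_stats_row(**overrides))
    assert bool(out["is_signal"].iloc[0]) is expected


# -------------------------------------------------------------------- volcano
def test_volcano_coordinates():
    signals = pd.DataFrame(
        {"drug": ["A", "B", "C", "D"], "a": [100, 10, 5, 3],
         "ror": [10.0, 1.0, 2.0, 5.0], "p_adjust": [0.001, 0.5, 1.0, 0.0]}
    )
    v = volcano_table(signals)
    assert v.loc[0, "log_ror"] == pytest.approx(1.0)
    assert v.loc[0, "neg_log10_p_adjust"] == pytest.approx(3.0)
    assert v.loc[0, "log10_case_count"] == pytest.approx(2.0)
    assert v.loc[1, "log_ror"] == 0.0
    assert v.loc[2, "neg_log10_p_adjust"] == 0.0
    assert bool(v.loc[3, "p_floor_applied"])
    assert np.isfinite(v.loc[3, "neg_log10_p_adjust"])
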