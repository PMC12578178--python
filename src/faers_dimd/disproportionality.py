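"""Disproportionality statistics for drug × DIMD 2×2 tables.

For each drug the 2×2 table against the DIMD event class is

    a: reports with the drug (PS) and a DIMD reaction
    b: reports with the drug (PS), no DIMD reaction
    c: reports without the drug, with a DIMD reaction
    d: reports without the drug, no DIMD reaction        N = a+b+c+d

Four classical signal-detection statistics are computed:

ROR  — reporting odds ratio ad/bc with Wald 95% CI
       exp(ln ROR ± 1.96·sqrt(1/a+1/b+1/c+1/d)); signal if lower bound > 1
       and a ≥ 3.
PRR  — proportional reporting ratio [a/(a+b)] / [c/(c+d)] with Pearson χ²
       (no Yates correction by default); signal if PRR ≥ 2, χ² ≥ 4, a ≥ 3.
BCPNN IC — information component log2 P(drug,event)/(P(drug)P(event)) with
       Bayesian shrinkage; the closed-form posterior mean and variance under
       the standard priors (marginal Beta(1,1) for drug and event, joint
       pseudocount γ11 = 1 with γ calibrated so the prior IC expectation is
       zero) give E(IC) = log2 of the ratio of posterior Beta means and
       V(IC) as the delta-method sum of Var/E² terms; signal if
       IC025 = E(IC) − 1.96·sqrt(V(IC)) > 0.
EBGM — empirical Bayes geometric mean of the relative reporting rate
       λ = a/E, E = (a+b)(a+c)/N, under a two-component gamma mixture prior
       fitted by maximum marginal likelihood across all drug tables
       (gamma-Poisson shrinker); signal if EBGM > 2 by default (EB05, the
       posterior 5th percentile, is also reported).

A drug is a combined signal only when all four criteria hold and its case
count a is at least 3.  Fisher's exact two-sided p with Bonferroni
correction over the drugs tested supplies the volcano-plot significance
axis.  Any 2×2 statistic facing a zero cell falls back to the
Haldane–Anscombe +0.5 correction and is flagged as corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import Cohort

__all__ = [
    "ContingencyTable",
    "EBGMHyperparams",
    "ConvergenceError",
    "contingency",
    "contingency_tables",
    "ror",
    "prr",
    "bcpnn_ic",
    "ebgm_fit",
    "ebgm_score",
    "fisher_exact",
    "bonferroni",
    "classify_signals",
    "compute_signals",
    "volcano_table",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class ConvergenceError(RuntimeError):
    """Raised when the EBGM hyperparameter fit fails; carries the iterate
    trace in ``.trace``."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of one drug × event-class 2×2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """E = (a+b)(a+c)/N, the expected count under independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def haldane(self) -> tuple[float, float, float, float]:
        """Cells with the +0.5 Haldane–Anscombe correction."""
        return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5


def contingency(cohort: Cohort, drug: str) -> ContingencyTable:
    """2×2 table of one drug against the DIMD event class.

    Exposure means the normalized drug name appears among the report's
    role-filtered (by default prime-suspect) drugs.  A drug absent from the
    cohort yields a=b=0, not an error.
    """
    reports = cohort.reports
    exposed_ids = set(
        cohort.exposures.loc[cohort.exposures["drug"] == drug, "primaryid"]
    )
    exposed = reports["primaryid"].isin(exposed_ids)
    case = reports["is_dimd_case"].to_numpy(dtype=bool)
    a = int((exposed & case).sum())
    b = int((exposed & ~case).sum())
    c = int((~exposed & case).sum())
    d = int((~exposed & ~case).sum())
    return ContingencyTable(a, b, c, d)


def contingency_tables(cohort: Cohort) -> pd.DataFrame:
    """All per-drug 2×2 tables at once (one row per exposed drug name)."""
    reports = cohort.reports.loc[:, ["primaryid", "is_dimd_case"]]
    merged = cohort.exposures.merge(reports, on="primaryid", how="inner")
    grouped = merged.groupby("drug")["is_dimd_case"]
    a = grouped.sum().astype(int)
    exposed_n = grouped.size().astype(int)
    total = len(reports)
    total_cases = int(reports["is_dimd_case"].sum())
    out = pd.DataFrame({"drug": a.index, "a": a.to_numpy()})
    out["b"] = (exposed_n - a).to_numpy()
    out["c"] = total_cases - out["a"]
    out["d"] = total - total_cases - out["b"]
    return out.reset_index(drop=True)


def ror(
    t: ContingencyTable, *, continuity: str = "haldane"
) -> tuple[float, float, float, bool]:
    """Reporting odds ratio with Wald 95% CI.

    Returns (ror, lower, upper, corrected).  Zero cells trigger the
    configured continuity policy: ``"haldane"`` (+0.5 to every cell, result
    flagged corrected) or ``"nan"``.
    """
    corrected = min(t.a, t.b, t.c, t.d) == 0
    if corrected:
        if continuity == "nan":
            return float("nan"), float("nan"), float("nan"), True
        if continuity != "haldane":
            raise ValueError(f"unknown continuity policy {continuity!r}")
        a, b, c, d = t.haldane()
    else:
        a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    est = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = est * np.exp(-Z95 * se), est * np.exp(Z95 * se)
    return float(est), float(lo), float(hi), corrected


def prr(
    t: ContingencyTable, *, yates: bool = False, continuity: str = "haldane"
) -> tuple[float, float, bool]:
    """Proportional reporting ratio and Pearson χ².

    χ² is computed on the uncorrected table (optionally Yates-corrected);
    the PRR falls back to Haldane cells when its denominator would vanish
    (c = 0) or the drug margin is empty.  Returns (prr, chi2, corrected).
    """
    corrected = t.c == 0 or (t.a + t.b) == 0
    if corrected:
        if continuity == "nan":
            est = float("nan")
        else:
            a, b, c, d = t.haldane()
            est = (a / (a + b)) / (c / (c + d))
    else:
        est = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))

    n = t.n
    r1, r0 = t.a + t.b, t.c + t.d
    c1, c0 = t.a + t.c, t.b + t.d
    if min(r1, r0, c1, c0) == 0:
        chi2 = float("nan")
    else:
        diff = abs(t.a * t.d - t.b * t.c)
        if yates:
            diff = max(diff - n / 2.0, 0.0)
        chi2 = n * diff**2 / (r1 * r0 * c1 * c0)
    return float(est), float(chi2), corrected


# BCPNN prior pseudocounts: marginal Beta(1,1) priors for the drug and the
# event (alpha1 = beta1 = 1, alpha = beta = 2), joint pseudocount gamma11 = 1
# with gamma calibrated so the prior expectation of IC is zero.
_BC_A1, _BC_A = 1.0, 2.0
_BC_B1, _BC_B = 1.0, 2.0
_BC_G11 = 1.0


def bcpnn_ic(t: ContingencyTable) -> tuple[float, float]:
    """Shrunk information component and its 2.5th percentile (IC025).

    Closed-form posterior moments: E(IC) is the log2 ratio of the posterior
    Beta means of P(drug,event), P(drug) and P(event); V(IC) the
    delta-method sum of their Var/E² terms.  Defined for a = 0.
    """
    a, n = float(t.a), float(t.n)
    m1 = float(t.a + t.b)  # drug margin
    m2 = float(t.a + t.c)  # event margin
    gamma = _BC_G11 * (n + _BC_A) * (n + _BC_B) / ((m1 + _BC_A1) * (m2 + _BC_B1))
    e_ic = np.log2(
        (a + _BC_G11)
        * (n + _BC_A)
        * (n + _BC_B)
        / ((n + gamma) * (m1 + _BC_A1) * (m2 + _BC_B1))
    )
    v_ic = (
        (n - a + gamma - _BC_G11) / ((a + _BC_G11) * (1 + n + gamma))
        + (n - m1 + _BC_A - _BC_A1) / ((m1 + _BC_A1) * (1 + n + _BC_A))
        + (n - m2 + _BC_B - _BC_B1) / ((m2 + _BC_B1) * (1 + n + _BC_B))
    ) / np.log(2) ** 2
    ic = float(e_ic)
    return ic, float(ic - Z95 * np.sqrt(v_ic))


@dataclass(frozen=True)
class EBGMHyperparams:
    """Two-component gamma mixture prior on the relative reporting rate λ.

    Component i is Gamma(shape=alpha_i, rate=beta_i); mix_p is the weight of
    the first component.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    mix_p: float

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes and rates must be positive")
        if not 0.0 <= self.mix_p <= 1.0:
            raise ValueError("mix_p must lie in [0, 1]")

    @property
    def prior_mean(self) -> float:
        return (
            self.mix_p * self.alpha1 / self.beta1
            + (1 - self.mix_p) * self.alpha2 / self.beta2
        )


def _nb_logpmf(a: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """log P(a | E) when λ ~ Gamma(alpha, beta) and a | λ ~ Poisson(λE):
    a negative-binomial with size alpha and probability beta/(beta+E)."""
    return (
        special.gammaln(alpha + a)
        - special.gammaln(alpha)
        - special.gammaln(a + 1.0)
        + alpha * np.log(beta / (beta + e))
        + a * np.log(e / (beta + e))
    )


# DuMouchel's canonical starting point for the gamma-mixture fit.
EBGM_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)
EBGM_BOUNDS = (1e-6, 1e6)


def ebgm_fit(
    a: Sequence[int],
    e: Sequence[float],
    *,
    start: tuple[float, float, float, float, float] = EBGM_START,
    maxiter: int = 500,
) -> EBGMHyperparams:
    """Fit the mixture hyperparameters by maximum marginal likelihood.

    Deterministic: bounded quasi-Newton (L-BFGS-B) in log (shapes, rates)
    and logit (mixture weight) space from a fixed start.  Requires at least
    two drug tables; raises :class:`ConvergenceError` with the iterate trace
    on failure.
    """
    a_arr = np.asarray(a, dtype=float)
    e_arr = np.asarray(e, dtype=float)
    if a_arr.shape != e_arr.shape:
        raise ValueError("a and e must have the same length")
    if a_arr.size < 2:
        raise ValueError("EBGM hyperparameter fit requires at least two tables")
    if (e_arr <= 0).any():
        raise ValueError("expected counts must be positive")

    lo, hi = np.log(EBGM_BOUNDS[0]), np.log(EBGM_BOUNDS[1])

    def unpack(theta: np.ndarray) -> tuple[float, float, float, float, float]:
        a1, b1, a2, b2 = np.exp(theta[:4])
        p = 1.0 / (1.0 + np.exp(-theta[4]))
        return a1, b1, a2, b2, p

    def nll(theta: np.ndarray) -> float:
        a1, b1, a2, b2, p = unpack(theta)
        l1 = np.log(p + 1e-300) + _nb_logpmf(a_arr, e_arr, a1, b1)
        l2 = np.log(1 - p + 1e-300) + _nb_logpmf(a_arr, e_arr, a2, b2)
        return -float(special.logsumexp(np.stack([l1, l2]), axis=0).sum())

    theta0 = np.array(
        [np.log(start[0]), np.log(start[1]), np.log(start[2]), np.log(start[3]),
         np.log(start[4] / (1 - start[4]))]
    )
    trace: list[tuple[np.ndarray, float]] = []

    def record(theta: np.ndarray) -> None:
        trace.append((theta.copy(), nll(theta)))

    res = optimize.minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * 4 + [(-15.0, 15.0)],
        callback=record,
        options={"maxiter": maxiter},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter reached
        raise ConvergenceError(
            f"EBGM hyperparameter fit failed: {res.message}", trace
        )
    a1, b1, a2, b2, p = unpack(res.x)
    return EBGMHyperparams(a1, b1, a2, b2, p)


def ebgm_score(
    t: ContingencyTable | tuple[int, float], h: EBGMHyperparams
) -> tuple[float, float]:
    """Posterior EBGM = 2^{E[log2 λ | a]} and EB05 (posterior 5th pct).

    The posterior over λ is the gamma mixture updated by (a, E): component i
    becomes Gamma(alpha_i + a, beta_i + E) with weight proportional to the
    prior weight times the marginal NB likelihood.  E = 0 yields NaNs.
    """
    if isinstance(t, ContingencyTable):
        a, e = t.a, t.expected_a
    else:
        a, e = t
    if e <= 0:
        return float("nan"), float("nan")
    a = float(a)

    log_w1 = np.log(h.mix_p + 1e-300) + _nb_logpmf(
        np.array(a), np.array(e), h.alpha1, h.beta1
    )
    log_w2 = np.log(1 - h.mix_p + 1e-300) + _nb_logpmf(
        np.array(a), np.array(e), h.alpha2, h.beta2
    )
    norm = np.logaddexp(log_w1, log_w2)
    q1 = float(np.exp(log_w1 - norm))

    s1, r1 = h.alpha1 + a, h.beta1 + e
    s2, r2 = h.alpha2 + a, h.beta2 + e
    mean_log = q1 * (special.digamma(s1) - np.log(r1)) + (1 - q1) * (
        special.digamma(s2) - np.log(r2)
    )
    ebgm = float(np.exp(mean_log))

    def cdf(x: float) -> float:
        return q1 * stats.gamma.cdf(x, s1, scale=1 / r1) + (1 - q1) * stats.gamma.cdf(
            x, s2, scale=1 / r2
        )

    lo = min(stats.gamma.ppf(0.0005, s1, scale=1 / r1),
             stats.gamma.ppf(0.0005, s2, scale=1 / r2))
    hi = max(stats.gamma.ppf(0.9995, s1, scale=1 / r1),
             stats.gamma.ppf(0.9995, s2, scale=1 / r2))
    lo = max(lo, 1e-12)
    eb05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-12))
    return ebgm, eb05


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities no
    larger than that of the observed table."""
    return float(
        stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1]
    )


def bonferroni(pvals: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment p_adj = min(1, p·m); m defaults to len(pvals)."""
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be at least 1")
    return np.minimum(1.0, p * m)


def classify_signals(
    results: pd.DataFrame,
    *,
    min_count: int = 3,
    prr_threshold: float = 2.0,
    chi2_threshold: float = 4.0,
    ebgm_threshold: float = 2.0,
) -> pd.DataFrame:
    """Apply the four per-algorithm criteria and the combined rule.

    flag_ror: ROR lower CI > 1 and a ≥ min_count; flag_prr: PRR ≥ 2, χ² ≥ 4
    and a ≥ min_count; flag_bcpnn: IC025 > 0; flag_ebgm: EBGM > threshold.
    is_signal: all four flags and a ≥ min_count.
    """
    out = results.copy()
    n_ok = out["a"] >= min_count
    out["flag_ror"] = (out["ror_lo"] > 1.0) & n_ok
    out["flag_prr"] = (
        (out["prr"] >= prr_threshold) & (out["chi2"] >= chi2_threshold) & n_ok
    )
    out["flag_bcpnn"] = out["ic025"] > 0.0
    out["flag_ebgm"] = out["ebgm"] > ebgm_threshold
    out["is_signal"] = (
        out["flag_ror"] & out["flag_prr"] & out["flag_bcpnn"] & out["flag_ebgm"] & n_ok
    )
    return out


def compute_signals(
    cohort: Cohort,
    *,
    min_count: int = 3,
    yates: bool = False,
    ebgm_threshold: float = 2.0,
) -> pd.DataFrame:
    """Full disproportionality screen: one row per exposed drug with all
    four statistics, Fisher/Bonferroni p-values, per-algorithm flags and the
    combined signal call.

    The EBGM prior is fitted across all drug tables; the Bonferroni family
    size is the number of drugs with a ≥ 1 against the event class.
    """
    tables = contingency_tables(cohort)
    if tables.empty:
        raise ValueError("no exposed drugs in cohort")

    rows = []
    cts = [
        ContingencyTable(int(r.a), int(r.b), int(r.c), int(r.d))
        for r in tables.itertuples()
    ]
    hyper = (
        ebgm_fit([t.a for t in cts], [max(t.expected_a, 1e-9) for t in cts])
        if len(cts) >= 2
        else None
    )
    for drug, t in zip(tables["drug"], cts):
        r, r_lo, r_hi, r_corr = ror(t)
        p_est, chi2, _ = prr(t, yates=yates)
        ic, ic025 = bcpnn_ic(t)
        if hyper is not None and t.expected_a > 0:
            ebgm, eb05 = ebgm_score(t, hyper)
        else:
            ebgm, eb05 = float("nan"), float("nan")
        rows.append(
            {
                "drug": drug,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "ror": r,
                "ror_lo": r_lo,
                "ror_hi": r_hi,
                "ror_corrected": r_corr,
                "prr": p_est,
                "chi2": chi2,
                "ic": ic,
                "ic025": ic025,
                "ebgm": ebgm,
                "eb05": eb05,
                "fisher_p": fisher_exact(t),
            }
        )
    signals = pd.DataFrame(rows)
    family = int((signals["a"] >= 1).sum())
    signals["p_adjust"] = bonferroni(signals["fisher_p"], m=max(family, 1))
    signals = classify_signals(
        signals, min_count=min_count, ebgm_threshold=ebgm_threshold
    )
    return signals.sort_values("drug", kind="stable").reset_index(drop=True)


def volcano_table(signals: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready volcano coordinates: log10 ROR, −log10 Bonferroni p and
    log10 case count per drug.  Zero adjusted p-values are floored at the
    smallest positive float and flagged."""
    tiny = np.nextafter(0.0, 1.0)
    p = signals["p_adjust"].to_numpy(dtype=float)
    floored = p <= 0.0
    p = np.where(floored, tiny, p)
    with np.errstate(divide="ignore"):
        log_count = np.where(
            signals["a"] > 0, np.log10(signals["a"].to_numpy(dtype=float)), np.nan
        )
    return pd.DataFrame(
        {
            "drug": signals["drug"],
            "log_ror": np.log10(signals["ror"].to_numpy(dtype=float)),
            "neg_log10_p_adjust": -np.log10(p),
            "log10_case_count": log_count,
            "p_floor_applied": floored,
        }
    )
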