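"""Independent oracles used by the statistics tests.

Everything here is deliberately computed by a different route from the
package implementation: exact rational arithmetic for the 2×2 statistics and
the Fisher enumeration, numeric quadrature for the Bayesian posterior
moments.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy import integrate, stats


def ror_oracle(a, b, c, d):
    """Point estimate, Wald CI and SE by plain arithmetic."""
    est = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = 1.959963984540054
    return est, est * np.exp(-z * se), est * np.exp(z * se)


def prr_oracle(a, b, c, d):
    return (a / (a + b)) / (c / (c + d))


def chi2_oracle(a, b, c, d):
    """Pearson χ² via the O−E definition (no continuity correction)."""
    n = a + b + c + d
    rows, cols = (a + b, c + d), (a + c, b + d)
    total = 0.0
    for i, (o1, o2) in enumerate(((a, b), (c, d))):
        for j, o in enumerate((o1, o2)):
            e = rows[i] * cols[j] / n
            total += (o - e) ** 2 / e
    return total


def fisher_two_sided_exact(a, b, c, d) -> Fraction:
    """Two-sided Fisher p by exhaustive rational enumeration of the
    hypergeometric support: sum of P(table) over tables (with the same
    margins) whose probability does not exceed the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_x = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if p_x <= p_obs:
            total += p_x
    return total


def bcpnn_moments_by_quadrature(a, b, c, d):
    """IC posterior mean and variance assembled from Beta posterior moments
    obtained by numeric integration (quadrature over the Beta densities).

    Priors: Beta(1, 1) marginals for the drug and the event, joint
    pseudocount 1 with total gamma calibrated so the prior IC expectation is
    zero; moments combine as E(IC) = log2 of the ratio of means and
    V(IC) = delta-method sum of Var/mean² terms.
    """
    n = a + b + c + d
    m1, m2 = a + b, a + c
    gamma = (n + 2.0) * (n + 2.0) / ((m1 + 1.0) * (m2 + 1.0))

    def beta_moments(p, q):
        dist = stats.beta(p, q)
        mean = integrate.quad(lambda x: x * dist.pdf(x), 0, 1, limit=200)[0]
        second = integrate.quad(lambda x: x * x * dist.pdf(x), 0, 1, limit=200)[0]
        return mean, second - mean**2

    m11, v11 = beta_moments(a + 1.0, n - a + gamma - 1.0)
    mm1, vv1 = beta_moments(m1 + 1.0, n - m1 + 1.0)
    mm2, vv2 = beta_moments(m2 + 1.0, n - m2 + 1.0)
    e_ic = np.log2(m11 / (mm1 * mm2))
    v_ic = (v11 / m11**2 + vv1 / mm1**2 + vv2 / mm2**2) / np.log(2) ** 2
    return e_ic, v_ic


def gamma_posterior_log_mean_by_quadrature(shape, rate):
    """E[ln λ] for λ ~ Gamma(shape, rate) by numeric integration."""
    dist = stats.gamma(shape, scale=1.0 / rate)
    lo, hi = dist.ppf(1e-12), dist.ppf(1 - 1e-12)
    val, _ = integrate.quad(lambda x: np.log(x) * dist.pdf(x), lo, hi, limit=400)
    return val
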