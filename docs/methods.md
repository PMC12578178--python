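# Methods

This note documents the models, assumptions, numerical choices and known
limitations of the `faers_dimd` pipeline.

## Synthetic reporting world

The generator (`faers_dimd.synthetic`) emulates the public FAERS quarterly
ASCII extracts closely enough to exercise every downstream stage, with a
known ground truth.

**Outcome model.** Each underlying report draws prime-suspect (PS) drug
exposures independently; the DIMD outcome is Bernoulli with

    odds(DIMD) = odds0 · Π_j m_j^{PS_j},

where `odds0` derives from `baseline_dimd_prob` and `m_j` is drug *j*'s
configured odds multiplier. Because the link is exactly logistic in the PS
indicators, the *conditional* odds ratio of DIMD for PS exposure to drug
*j* is `m_j` by construction, which makes recovery tests sharp: a correct
logistic fit on the complete-case universe estimates `m_j` consistently,
and because the outcome is rare (1% baseline by default) the marginal 2×2
odds ratio is numerically indistinguishable from the conditional one at the
studied scales.

**Study conditions (defaults).** Four study drugs with multipliers 8, 4, 2
and 1 plus twelve null background drugs; baseline DIMD probability 0.01
(spontaneous-report databases are dominated by non-study events; a ~1%
event class is typical for a broad preferred-term family); 10% of caseids
duplicated; demographic mix matched to the DIMD reporting cohort: sex
F/M/missing = 54.45/35.95/9.60%, age median 53 (IQR 33–67) years with
43.24% missing, weight median 70.0 (IQR 57.2–85.0) kg with 73.70% missing.
Age and weight are drawn from the distribution whose quantile function
linearly interpolates those quartiles (tails pinned at 1–100 y and
30–160 kg). Exposure probabilities (0.03–0.08) are set so that at the
validation scale of 200,000 reports every non-null drug's expected case
count sits well clear of the univariate screen's a > 100 boundary — the
recovery study is meant to measure estimator behaviour, not Poisson noise
at a screening threshold. Roles are drawn per exposure (PS 55%, SS 15%,
C 25%, I 5%); the multiplier applies only when the drawn role is PS, so
role filtering is exercised with real consequences.

**Duplicates.** A configurable fraction of caseids is emitted in 2–3
versions. Later versions always carry a larger primaryid; with probability
0.5 they also carry a strictly later fda_dt (otherwise the same fda_dt), so
both the recency rule and the larger-id tie rule of deduplication are
exercised. The canonical member of each cluster — max (fda_dt, primaryid)
— is recorded in the ground truth.

**Field noise.** Ages are emitted under mixed unit codes (90% years, 5%
months, 5% decades); weights under KG or LBS; reaction and indication PTs
in display form ("Tardive dyskinesia") so that PT normalization matters;
0.1% of reports carry implausible demographics (age ≥ 120 y or weight
≥ 400 kg) to exercise outlier exclusion.

**What it does not emulate** (hence what passing tests do not show):
reporting-lag dynamics, country-specific reporting propensities, drug
co-prescription structure, misspelled or free-text drug names beyond
case/whitespace noise, partially divergent duplicate versions (duplicate
versions are exact copies apart from primaryid/fda_dt), and MedDRA hierarchy
effects. Real-FAERS analyses face all of these; the synthetic results
validate the statistical machinery, not robustness to real-world coding
noise.

## Ingestion and deduplication

Files are "$"-delimited with a header line; rows whose field count differs
from the header are counted as malformed and skipped (never silently), and
child rows whose primaryid is absent from DEMO are counted as orphans and
dropped. Row conservation (parsed + malformed = physical lines − 1) is
asserted in tests. Pre-2012 legacy column names (ISR, CASE, GNDR_COD) are
resolved through an extensible alias table.

Deduplication is two-stage: per caseid keep the row with the latest fda_dt,
breaking ties by the larger primaryid (read as the report-version key);
any primaryid still appearing in more than one row is resolved by keeping
the largest (fda_dt, caseid), mirroring the primary rule. The operation is
idempotent and, on synthetic data, recovers exactly one canonical
representative per duplicate cluster.

Age unit conversion: YR×1, MON÷12, WK×7/365.25, DY÷365.25, HR÷8766,
DEC×10. Unknown or missing unit codes and negative values map to missing
rather than being assumed years — conservative against unit corruption.
Weight: KG×1, LBS×0.45359237, GMS÷1000. Drug names are uppercased, trimmed
and whitespace-collapsed before an optional user synonym map applies.

## Cohort

A report is a DIMD case iff at least one reaction PT, normalized (uppercase,
internal spaces removed), is in the 28-term DIMD PT set. Exposure uses PS
entries only by default (configurable). Outlier exclusion (age ≥ 120 y or
weight ≥ 400 kg) applies to the whole analysis set by default, switchable to
descriptives-only via `exclude_outliers=False` at cohort build time.
Quartiles use linear interpolation (type 7), the common default. The seven
comorbidity flags (Parkinson's disease, schizophrenia, affective disorders,
epilepsy, gastro-oesophageal reflux, nausea/vomiting, other CNS disorders)
are derived from indication PTs through an editable YAML map; the
`other_cns_disorders` list in particular is a small illustrative default
that users should replace with their own MedDRA query. Age-band tallies
default to {<33, 33–53, 53–67, >67}, anchored at the cohort quartiles, and
are configurable.

## Disproportionality statistics

All four statistics operate on a, b, c, d with N = a+b+c+d and
E = (a+b)(a+c)/N.

**ROR** = ad/bc with Wald 95% CI `exp(ln ROR ± z·SE)`,
SE = √(1/a+1/b+1/c+1/d), z = 1.959963984540054. **PRR** =
[a/(a+b)]/[c/(c+d)]; Pearson χ² is computed without Yates correction by
default (Yates available by flag). Zero cells trigger the Haldane–Anscombe
+0.5 correction on all four cells, and the result is flagged `corrected`;
χ² is always computed on the uncorrected table.

**BCPNN IC.** The information component is log2 p11/(p1·p2) with
independent Beta posteriors for p11, p1, p2. Priors: Beta(1,1) marginals
for drug and event (α1 = β1 = 1, α = β = 2), joint pseudocount γ11 = 1 with
total γ = γ11(N+α)(N+β)/((a+b+α1)(a+c+β1)), which makes the prior IC
expectation zero. The posterior mean is the log2 ratio of the posterior
Beta means and the variance is the delta-method sum of Var/E² terms — the
standard closed form; both are validated against numeric quadrature of the
Beta moments. IC025 = E(IC) − 1.96·√V(IC); defined for a = 0.

**EBGM.** The relative reporting rate λ = a/E receives a two-component
gamma mixture prior, P(λ) = p·Γ(α₁,β₁) + (1−p)·Γ(α₂,β₂) (shape/rate).
Hyperparameters maximize the marginal likelihood — a two-component
negative-binomial mixture over all drug tables — via L-BFGS-B in
log-parameter / logit-weight space with box constraints [1e−6, 1e6], from
the fixed canonical start (0.2, 0.1, 2.0, 4.0, 1/3). A symmetric start
(both components identical) was rejected deliberately: the mixture
likelihood is symmetric under component exchange, so a gradient method
started on that ridge can never separate the components. The fit is
deterministic given data; failures raise with the iterate trace. Scoring:
the posterior is the conjugate mixture of Γ(αᵢ+a, βᵢ+E) with
likelihood-updated weights; EBGM = exp(E[ln λ]) via digamma, EB05 solves
the mixture CDF at 0.05 by bracketed root-finding. Signal rule EBGM > 2
(EB05 > 2 is a stricter common alternative, configurable by threshold).

**Fisher/Bonferroni.** Two-sided Fisher exact p sums hypergeometric
probabilities ≤ the observed table's (delegated to scipy; validated against
exact rational enumeration). Bonferroni family size is the number of drugs
with a ≥ 1 against the event class. In the volcano table a zero adjusted p
is floored at the smallest positive double and flagged; both axis
orientations of the volcano appear in practice, so the table emits named
columns (log_ror, neg_log10_p_adjust) and leaves orientation to the
plotting layer.

**Combined rule.** is_signal ⇔ ROR025 > 1 ∧ (PRR ≥ 2 ∧ χ² ≥ 4) ∧ IC025 > 0
∧ EBGM > 2 ∧ a ≥ 3.

## Risk-factor model

The control universe is all non-case reports in the same deduplicated,
complete-case (sex and age present) set — the only control definition
consistent with drug-exposure odds ratios far above 1 in this design.
Covariates are binary: male sex; age < 33 years (strict — exactly 33 maps
to 0); one PS-exposure indicator per screened drug (ROR025 > 1, a > 100,
Bonferroni p < 0.01, all strict); and the seven comorbidity flags. Constant
columns are retained with a warning (the LASSO handles them; dropping them
silently would hide a data problem).

The LASSO path uses glmnet-style scaling: covariates standardized by
population SD, penalty λ on the mean log-loss, path of 16 λ values
geometrically spaced from the data-derived λ_max down to λ_max/100 (a
desk-scale resolution; finer paths change λ.min slightly but not the
selected set in our validation worlds). Each fold of the stratified 10-fold
CV standardizes on its own training data. Per-λ fits use coordinate-descent
L1 logistic regression (liblinear, tol 1e−6, iteration cap 100,000,
intercept effectively unpenalized via intercept scaling). The CV loss is
binomial deviance by default; a squared-error option is provided because
"minimum mean-squared prediction error" is sometimes reported for logistic
LASSOs. λ.min minimizes mean CV loss; selection is the non-zero coefficient
set of the whole-data fit at λ.min. Everything is deterministic given the
fold seed.

The final inference is an unpenalized maximum-likelihood logistic fit on
the selected covariates (a flag allows fitting all screened covariates
instead), with Wald 95% CIs and Bonferroni correction over the covariates
in the final model. No post-selection inference correction is applied
beyond Bonferroni; with the strong, near-deterministically selected effects
this pipeline targets, selection noise is negligible, but the p-values
should still be read as conditional on selection. Complete separation
(a binary covariate with a zero cell against the outcome) is detected
before fitting and raised as an explicit error naming the covariate. The
AUC is the rank-based (Mann–Whitney) estimate with tie correction, computed
on in-sample fitted probabilities.

## Validation scales

The test suite validates statistics against independent oracles (exact
rational arithmetic, exhaustive hypergeometric enumeration for all tables
with N ≤ 16 plus random tables to N = 40, numeric quadrature for posterior
moments) and runs recovery studies at the package's chosen validation
sizes: 20 worlds of 200,000 reports for CI coverage of the designed odds
ratios, 50,000 reports at a 20% duplicate rate for deduplication, 30,000
reports for byte-level reproducibility of the file-based pipeline, and
20,000-report simulations for LASSO selection stability. These sizes give
the coverage assertions comfortable binomial margins while keeping the
suite fast.

## Known limitations

- PT matching is literal (normalized string equality); no MedDRA hierarchy
  traversal, so the case definition is exactly the configured PT list.
- The EBGM prior in small synthetic worlds is fitted across few drug
  tables; with fewer than ~20 tables the mixture is weakly identified and
  shrinkage is strong. On real FAERS-scale data (thousands of drugs) this
  is not a concern.
- Time-stratified, sex-stratified or otherwise covariate-adjusted
  disproportionality is out of scope, as are drug–drug interaction
  analyses.
- The logistic model's AUC on synthetic defaults is modest (~0.6): rare
  exposures explain few cases. This is a property of the designed world,
  not a defect of the fit.
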