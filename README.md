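# faers-dimd

Signal detection and risk-factor modelling for **drug-induced movement
disorders (DIMDs)** in spontaneous adverse-event reporting data shaped like
the public FAERS quarterly extracts.

DIMDs — tardive dyskinesia, extrapyramidal disorders, chorea, oculogyric
crisis and related presentations — are reported for a wide range of drugs
(antipsychotics, antiparkinsonian agents, gastroprokinetics, some
antibiotics), but spontaneous-report counts cannot be compared across drugs
without an expected-frequency baseline. This package implements the standard
pharmacovigilance answer to that problem end to end, for epidemiologists and
pharmacovigilance analysts:

1. **Ingestion** of "$"-delimited quarterly DEMO/DRUG/REAC/OUTC/RPSR/THER/
   INDI tables, with legacy column aliases, malformed-row accounting and the
   FDA-recommended two-stage deduplication (per caseid keep the latest
   fda_dt, ties to the larger primaryid; residual primaryid duplicates
   resolved the same way).
2. **Case definition**: a report is a DIMD case if any reaction preferred
   term (PT), normalized to uppercase with spaces removed, falls in a
   28-term DIMD PT set; exposure is restricted to prime-suspect (PS) drugs;
   implausible demographics (age ≥ 120 y, weight ≥ 400 kg) are excluded.
3. **Disproportionality analysis** on each drug's 2×2 table
   (a, b, c, d; N = a+b+c+d; E = (a+b)(a+c)/N):

   | statistic | estimate | signal criterion |
   |---|---|---|
   | ROR | ad/bc, Wald CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` | lower 95% bound > 1, a ≥ 3 |
   | PRR | `[a/(a+b)] / [c/(c+d)]` with Pearson χ² | PRR ≥ 2, χ² ≥ 4, a ≥ 3 |
   | BCPNN IC | shrunk `log2 P(drug,event)/(P(drug)P(event))` (closed-form posterior moments) | IC025 > 0 |
   | EBGM | gamma-Poisson shrinkage of a/E under a fitted two-component gamma mixture prior | EBGM > 2 |

   A drug is a combined signal only when **all four** criteria hold and
   a ≥ 3. Fisher's exact test with Bonferroni correction supplies volcano
   coordinates (log ROR vs −log10 adjusted p).
4. **Sensitivity analysis**: complete cases (sex and age present) →
   univariate screen (ROR025 > 1, a > 100, adjusted p < 0.01) → 10-fold
   cross-validated LASSO logistic regression (λ.min) → multivariable
   logistic model with Bonferroni-corrected Wald inference → ROC AUC.
5. A **synthetic FAERS generator** whose outcome model is logistic in the
   PS-drug indicators, so each drug's conditional odds ratio of DIMD is a
   configurable constant. Every downstream stage is validated against this
   known ground truth — no FAERS download is needed to test the pipeline.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
world of 200,000 reports with designed odds multipliers 8 (METOCLOPRAMIDE),
4 (ARIPIPRAZOLE), 2 (RISPERIDONE) and 1 (QUETIAPINE plus twelve background
drugs):

```sh
python analysis/01_simulate.py    # writes quarterly files under scratch/
python analysis/02_ingest.py      # parses + deduplicates, checks vs truth
python analysis/03_cohort.py      # case cohort + Table-1 style summary
python analysis/04_signals.py     # four-algorithm disproportionality
python analysis/05_risk_model.py  # screen -> LASSO -> logistic -> AUC
```

Output of the last three steps (seed 20240101):

```
199807 retained reports, 2442 DIMD cases; case age median 53.0 (Q1 34.0, Q3 70.0)

16 drugs screened, 2 combined signals:
          drug   a   ror  ror_lo   prr     chi2    ic  ebgm
  ARIPIPRAZOLE 185 3.790   3.252 3.672  336.530 1.775 3.469
METOCLOPRAMIDE 273 8.193   7.188 7.591 1404.771 2.745 6.782

102710 complete cases, 3 screened drugs, 12 candidate covariates,
3 selected at lambda.min = 0.000476
          covariate   coef     or  or_lo   or_hi   p  p_adjust
  drug:ARIPIPRAZOLE 1.2585 3.5201 2.8287  4.3805 0.0       0.0
drug:METOCLOPRAMIDE 2.2071 9.0892 7.6133 10.8512 0.0       0.0
   drug:RISPERIDONE 0.5584 1.7479 1.4116  2.1642 0.0       0.0
AUC = 0.586
```

Reading the output: the designed multipliers 8, 4 and 2 are recovered by
both the ROR (8.19, 3.79; RISPERIDONE's ROR CI covers 2 but its PRR sits at
the ≥2 threshold, so it is not always a combined signal at this scale) and
the logistic odds ratios (9.09, 3.52, 1.75, each CI covering the designed
value); the null drugs produce no signals. The AUC is modest by design —
drug exposure is rare, so most case reports carry no risk factor.

## Layout

```
src/faers_dimd/     synthetic.py  ingest.py  cohort.py
                    disproportionality.py  risk_model.py  pipeline.py
analysis/           numbered study drivers (simulate -> ... -> risk model)
scripts/            acceptance.py
tests/              pytest suite with independent statistical oracles
docs/methods.md     models, assumptions, numerical choices, limitations
```
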