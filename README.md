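# recallval

Agreement statistics and regression dilution ratios for validation studies
of self-reported exposure data.

Epidemiological cohorts routinely rely on self-reported exposures — body
size throughout life, reproductive history, and similar quantities recalled
years after the fact. Reporting error in such data has two components:
random noise, which attenuates estimated disease–exposure associations
toward the null, and systematic (differential) error, such as heavier
individuals under-reporting their weight more, which can either add to or
oppose that attenuation. `recallval` is for analysts running a validation
substudy: a set of participants with both a self-reported value and a
reference value (measured, or collected close to the relevant age) for each
variable of interest. It quantifies both error components and, crucially,
their *consequence* for association estimates.

## The statistics

For a paired sample (self-report *S*, reference *R*) per participant:

- **Agreement** — Pearson *r* with SE √((1−r²)/(n−2)); paired *t*-test of
  the mean difference S−R; Bland–Altman 95% limits of agreement
  (mean ± 1.96 SD of the differences), both raw and divided by the
  reference SD; the one-way random-effects intraclass correlation
  ICC(1,1) = (MS_B − MS_W)/(MS_B + MS_W), which unlike Pearson's *r* is
  lowered by systematic shifts; mean/SD of the error within reference
  quintiles with a one-way ANOVA for differential error.
- **Regression dilution ratio (RDR)** — participants are grouped by
  pre-specified categories of the self-report, and

      RDR = range of per-category reference means
            ─────────────────────────────────────
            range of per-category self-report means

  a non-parametric estimate of the factor by which a linear log relative
  risk estimated from self-reported data is attenuated relative to the true
  exposure. Confidence intervals come from a percentile bootstrap
  resampling whole participants. A naive RR corrects to
  `exp(ln(RR)/RDR)`; the squared correlation r² gives the effective sample
  size as a fraction of the actual one (a power loss no correction
  restores).
- **Categorical variables** — percent agreement and Cohen's κ with the
  conventional verbal bands, Spearman/linear-trend analysis of ordinal
  body-size categories against a quantitative reference, and Fisher-exact
  subgroup comparisons (with a Monte-Carlo exact-conditional extension for
  tables larger than 2×2).
- **Synthetic cohorts** — a generator with the explicit error model
  S = a + b·T + ε, R = T + u (linear systematic error, random reporting
  error, optional "alloyed gold standard" reference error, correlated
  errors between the components of a ratio, thresholded ordinal and
  misclassified binary variables), with the analytic attenuation
  λ = b·σ_T²/(b²σ_T² + σ_ε²) attached as ground truth.

## Worked example

```python
import numpy as np
from recallval import (ErrorModelSpec, simulate_quantitative, summarize_agreement,
                       rdr_bootstrap_ci, correct_relative_risk,
                       effective_sample_fraction, classify_rdr)

# weight-like variable: under-reporting that grows with true weight (b < 1)
spec = ErrorModelSpec(mu_T=70.0, sigma_T=12.0, a=2.0, b=0.93, sigma_eps=3.0,
                      n=5000, seed=42, name="weight", units="kg")
sample = simulate_quantitative(spec)
summ = summarize_agreement(sample)
res = rdr_bootstrap_ci(sample, n_boot=2000, seed=7)
```

prints (via the fields of `summ` and `res`):

```
n = 5000
mean self-report = 66.88 kg, mean reference = 69.76 kg
mean difference  = -2.89 kg (t-test p = 0)
95% limits of agreement = -9.12 to 3.35 kg
scaled (reference-SD units) = -0.76 to 0.28
ICC(1,1) = 0.934 (SE 0.002), Pearson r = 0.964
RDR = 1.010 (95% CI 1.002-1.019) -> little-or-no attenuation
analytic attenuation = 1.003
naive RR 1.30 per kg corrects to 1.30
effective sample fraction = 0.93 (7% reduction)
```

Reading it: weight is under-reported by 2.9 kg on average and the limits of
agreement are asymmetric about zero (systematic error), and the ICC sits
below Pearson's *r* for the same reason. Yet the RDR is ≈ 1: the
differential under-reporting (b < 1) inflates association estimates by just
enough to cancel the attenuation from random error, so a relative risk
estimated from the self-reports needs essentially no correction — though
the error still costs 7% of the effective sample size.

A full multi-variable run goes through the CLI:

```sh
recallval simulate --spec generator.yaml --out cohort.csv --seed 3
recallval run --config analysis.yaml --input cohort.csv --out report/ --seed 17 --n-boot 2000
recallval correct-rr --rr 1.5 --rdr 0.5     # -> corrected RR = 2.25
```

`run` writes `agreement.csv`, `quintile_errors.csv`, `ordinal.csv`,
`categorical.csv`, `rdr.json`, per-variable figure-data CSVs, and a
`manifest.json` that fully determines reproduction.

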