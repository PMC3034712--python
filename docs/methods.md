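# Methods

## Setting and data model

The package analyses paired validation data: for each participant and each
variable, a self-reported value *S* (recalled, typically in middle age) and
a reference value *R* (measured, or collected close to the relevant age).
Input is a long-format table (one row per participant × variable) so that
variables with different amounts of missing data coexist cleanly; a
wide-to-long reshaper is provided. Missingness is handled per variable
pair (complete case) — never listwise across variables — and the excluded
count per variable is retained so that missingness itself can be compared
across subgroups. "Don't know" and blank responses are both treated as
missing; the package does not attempt to distinguish them.

Data preparation follows the conventions of validation studies of
anthropometry: imperial measurements convert with the international
factors (1 in = 2.54 cm, 1 lb = 0.45359237 kg); durations in months divide
by 12 without rounding; and ages recorded in whole years receive a
+0.5-year mid-year adjustment (the mean age of "12-year-olds" is 12 years
6 months), applied only to variables explicitly flagged `integer_years` in
the config, never automatically.

## Agreement statistics

For a quantitative variable the per-variable record contains:

- Pearson *r* with the large-sample SE √((1−r²)/(n−2)). Pearson's *r*
  responds to random but not systematic error.
- Paired *t*-test of mean(S−R)=0, two-sided. Degenerate inputs are
  handled by convention and flagged: a constant nonzero difference vector
  has p reported as its analytic limit 0; identically zero differences give
  p = 1.
- Bland–Altman 95% limits of agreement, mean ± 1.96·SD of the differences.
  The multiplier is fixed at 1.96 (no small-sample *t* correction),
  matching the originating method. Because the limits are centred on the
  mean difference, systematic error makes them asymmetric about 0. Scaled
  limits divide each bound by the SD of the *reference* values: under a
  simple error model, the ratio of error SD to truth SD governs
  attenuation, so reference-SD units are the scale on which the limits
  speak to epidemiological impact. The scaled bounds are invariant to
  rescaling both vectors by a common positive factor.
- ICC(1,1), the one-way random-effects intraclass correlation for single
  ratings, computed from the one-way ANOVA decomposition over participants
  with k = 2 ratings: ICC = (MS_B − MS_W)/(MS_B + (k−1)MS_W). The one-way
  model charges systematic shifts to the within-participant mean square,
  so adding a constant to the self-report strictly lowers the ICC while
  leaving Pearson's *r* unchanged — the gap between the two flags
  systematic error. The SE uses the classical Fisher large-sample
  variance for the one-way intraclass correlation,
  var = 2(1−ρ)²(1+(k−1)ρ)²/(k(k−1)(n−1)), which at k = 2 reduces to
  (1−ρ²)/√(n−1); F-based interval methods exist but an SE is what the
  summary record carries.
- Error profile by reference quintile: reference values are cut at their
  empirical 20/40/60/80 percentiles with ties assigned to the lower
  stratum (tied data therefore produce visibly unequal stratum sizes —
  expected behaviour, not an error), and a one-way ANOVA tests equality of
  the stratum mean errors. Strata with n < 2 are excluded from the ANOVA
  and flagged; a constant error vector makes the ANOVA degenerate (p
  reported as NaN, flagged).

All p-values in the package are two-sided.

## Regression dilution ratio

Participants are grouped by pre-specified categories of the self-report
(half-open intervals [e_i, e_{i+1}) between consecutive configured
boundaries, the last closed; when no boundaries are configured, empirical
self-report quintiles are used). The RDR is the range of the per-category
reference means divided by the range of the per-category self-report
means, taken over non-empty categories — never over individuals. It is a
non-parametric estimate of the slope of E[R | S]: under the linear error
model below that slope is λ = b·σ_T²/(b²σ_T²+σ_ε²) irrespective of the
additive offset *a* and of reference-side error σ_u, and the range-of-means
estimator is consistent for it whenever the conditional mean is linear.
RDR < 1 means attenuation of linear log-relative-risk coefficients; RDR > 1
means inflation, which arises when a systematic scale error (b < 1)
opposes random error. A slope-based OLS estimator is included as a
diagnostic cross-check only; the headline statistic is the range-of-means
form, which is robust to mild non-linearity at the extremes of the
category scale.

Confidence intervals use the percentile bootstrap (2.5th/97.5th
percentiles), resampling whole participants so the within-pair error
structure is preserved; resampling within categories was the rejected
alternative, since it would condition on the observed category counts.
Category boundaries stay fixed across replicates. Replicates in which any
originally occupied category empties, or the self-report mean range
collapses, are discarded and counted (empty categories are routine in
sparse data, so exclusion-with-accounting was chosen over failure); more
than 50% discarded aborts with a diagnostic. The default replicate count
is 2000. The implementation vectorises the resampling — category
membership is fixed by the edges, so each replicate's category sums reduce
to bincounts over replicate×category codes — making even the coverage
study (200 cohorts × 500 replicates) a matter of seconds. With fixed
(edges, n_boot, seed) the result is bit-reproducible.

Downstream arithmetic: a naive relative risk RR corrects to
exp(ln(RR)/RDR) (exact inverse of attenuation on the log scale; identity
at RDR = 1); attenuation percent is 100·(1−RDR), negative for inflation;
and r² is the effective sample fraction, with the percent reduction
rounded to the nearest integer for display. RDR-based correction restores
the coefficient, not the power: the effective-sample-size loss stands.
Verbal RDR bands (substantial < 0.66 ≤ slight-to-moderate ≤ 0.86 <
little-or-no attenuation) are descriptive labels with overridable
boundaries, not inferential claims. RDRs are not suitable for correcting
non-linear dose–response shapes; for those, the per-category reference
means are the interpretable scale.

## Categorical and ordinal variables

Cohen's κ = (p_o − p_e)/(1 − p_e) with chance agreement from the marginal
products, alongside raw percent agreement (κ is undefined when both raters
are constant on the same label; percent agreement is still reported). The
test of κ = 0 is the large-sample z-test with the Fleiss null variance,
two-sided. Verbal bands follow the common convention: ≤0.2 poor, ≤0.4
fair, ≤0.6 moderate, ≤0.8 substantial, above that excellent ("almost
perfect" in some conventions); the lowest band absorbs chance-level and
negative values.

Ordinal self-reports are scored by integer level rank (1 = lowest) and
related to the quantitative reference by the Spearman correlation
(midranks for ties) and a trend p-value from the least-squares regression
of the reference on the scores — equivalent to the one-degree-of-freedom
linear contrast in a one-way ANOVA. Both are invariant to strictly
monotone relabelling of the levels. Dichotomisation recodes (e.g. a
breastfeeding duration collapsed to ever/never) are config-driven maps.

Subgroup comparisons of categorical outcomes use Fisher's exact test for
2×2 tables. Larger tables use an exact-conditional p approximated by
Monte-Carlo sampling of tables with the observed margins (Patefield's
algorithm via scipy), scoring sampled tables whose conditional probability
does not exceed the observed table's (a relative fp guard of 1e-9 on the
log scale prevents ties being missed), reported with its Monte-Carlo SE.
All-zero rows/columns are dropped with a warning.

## Synthetic cohorts

The generator defines the conditions every simulation-based test runs
under:

    T ~ Normal(μ_T, σ_T²)        truth
    R = T + u,  u ~ N(0, σ_u²)   reference ("alloyed gold standard" if σ_u>0)
    S = a + b·T + ε, ε ~ N(0, σ_ε²)   self-report

Truths are Normal by default — the variables this emulates (heights,
weights, ages at reproductive events) are roughly symmetric — with a
log-normal option for skewed quantities. Systematic error is linear in
the truth, consistent with the monotone error-by-quintile patterns and
approximately linear category-mean plots such data show; σ_u defaults to 0
(gold-standard reference) with an alloyed preset. Ratio variables
(waist/hip-style) draw the two components' reporting errors from a
bivariate normal with correlation ρ_ε — substantial in practice for waist
and hip (≈0.55) — and non-positive denominators are resampled with a
count. Ordinal variables threshold the error-prone report; binary
variables flip a Bernoulli reference through sensitivity/specificity, with
the closed-form expected κ attached. Optional integer rounding of the
report is available for heaping-prone quantities, but no digit-preference
model is asserted. Every generator is a pure function of (spec, seed).

What the generator does *not* emulate: within-person drift of the true
exposure over follow-up, digit preference/heaping beyond plain rounding,
non-linear (threshold) reporting error, and truth distributions beyond
normal/log-normal. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated error model, not robustness of RDR
estimates to every failure mode of real questionnaire data.

## Verification strategy and problem sizes

Closed-form claims are tested where they are exact (λ metadata, corrected
RR, expected κ); sampling-based claims use sizes at which Monte-Carlo
error is comfortably inside the asserted tolerance: n = 50 000 for
attenuation recovery (|RDR − λ| < 0.05 across λ ∈ {0.5, 0.8, 1.0, 1.25}),
n = 20 000 for the ratio error-correlation check (±0.03), and a coverage
study of 200 cohorts of n = 500 with 500 bootstrap replicates each
(nominal 95% interval required to cover λ in 90–99% of cohorts). ICC is
verified against brute-force sum-of-squares arithmetic on 100 random small
instances and against pingouin; κ against direct evaluation of Cohen's
formula and scikit-learn; Fisher 2×2 against full hypergeometric
enumeration for every table with total n ≤ 20; the r×c Monte-Carlo p
against full enumeration on a small table within 3 Monte-Carlo SEs.

## Known limitations

- The range-of-means RDR assumes an (approximately) linear relation
  between reference and self-report; with a flat upper range (as ratio
  variables can show) the category means, not the single RDR, are the
  interpretable output.
- The percentile bootstrap can undercover slightly at small n with sparse
  categories; discarded-replicate counts are reported so such runs are
  visible.
- ICC variants other than (1,1), weighted κ, repeated-measures designs
  (>2 ratings), and multivariable regression-calibration corrections are
  out of scope.
- The κ z-test and the Pearson/ICC standard errors are large-sample
  approximations; at very small n they are indicative only.
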