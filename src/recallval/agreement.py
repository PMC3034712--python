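"""Quantitative agreement statistics for one paired variable.

Implements the per-variable agreement toolkit for validation studies of
self-reported data: Pearson correlation with large-sample SE, paired t-test
of the mean reporting error, Bland–Altman 95% limits of agreement (raw and
expressed in reference-SD units), the one-way random-effects intraclass
correlation ICC(1,1), and the profile of mean error across quintiles of the
reference values with a one-way ANOVA for differential (systematic) error.

The Pearson correlation is insensitive to systematic error; the ICC
penalises it.  A large gap between the two flags a variable with
substantial systematic reporting error.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .data_model import (
    QUANTITATIVE,
    AgreementSummary,
    PairedSample,
    QuintileErrorProfile,
)

__all__ = [
    "pearson_with_se",
    "mean_difference_test",
    "limits_of_agreement",
    "icc_1_1",
    "quintile_error_profile",
    "summarize_agreement",
]

LOA_MULTIPLIER = 1.96  # normal-theory 95% limits; no small-sample t correction


def pearson_with_se(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its large-sample SE.

    The SE is the usual large-sample approximation ``sqrt((1 - r^2)/(n - 2))``.
    Requires n >= 3 and two non-constant vectors.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(x, y).statistic)
    se = float(np.sqrt((1.0 - r * r) / (n - 2)))
    return r, se


def mean_difference_test(sample: PairedSample) -> tuple[float, float, float, bool]:
    """Paired t-test of mean(self_report − reference) = 0.

    Returns ``(mean_diff, sd_diff, p, degenerate)`` with a two-sided p.
    Degenerate cases: a constant nonzero difference vector has zero
    within-sample variance, so the p-value is reported as its analytic
    limit 0; identically zero differences give p = 1 by convention.  Both
    are flagged.
    """
    d = sample.differences
    if d.size < 2:
        raise ValueError("paired t-test needs n >= 2")
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    if sd_diff == 0.0:
        return mean_diff, 0.0, (1.0 if mean_diff == 0.0 else 0.0), True
    p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return mean_diff, sd_diff, p, False


def limits_of_agreement(
    sample: PairedSample,
) -> tuple[float, float, float, float]:
    """Bland–Altman 95% limits of agreement, raw and in reference-SD units.

    Bounds are ``mean_diff ∓ 1.96·sd_diff``; they are centred on the mean
    difference, so systematic error makes them asymmetric about 0.  The
    scaled bounds divide each raw bound by the SD of the *reference* values:
    under a simple error model, errors of one reference-SD correspond to
    full attenuation of a linear association, so reference-SD units are the
    scale on which the limits speak to epidemiological impact.
    """
    if sample.n < 3:
        raise ValueError("limits of agreement need n >= 3")
    d = sample.differences
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    lower = mean_diff - LOA_MULTIPLIER * sd_diff
    upper = mean_diff + LOA_MULTIPLIER * sd_diff
    sd_ref = float(np.std(sample.reference, ddof=1))
    if sd_ref == 0.0:
        raise ValueError("scaled limits undefined: reference values are constant")
    return lower, upper, lower / sd_ref, upper / sd_ref


def icc_1_1(sample: PairedSample) -> tuple[float, float]:
    """One-way random-effects intraclass correlation, ICC(1,1), with SE.

    Each participant contributes k = 2 ratings (self-report and reference)
    to a one-way ANOVA over participants:

        ICC = (MS_between − MS_within) / (MS_between + (k−1)·MS_within)

    Unlike the Pearson correlation, the one-way model charges systematic
    shifts between the ratings to the within-participant mean square, so a
    constant reporting bias strictly lowers the ICC.  The SE is the Fisher
    large-sample form, which for k = 2 reduces to (1 − ICC²)/√(n − 1).
    """
    x = np.asarray(sample.self_report, float)
    y = np.asarray(sample.reference, float)
    n = x.size
    if n < 3:
        raise ValueError("ICC(1,1) needs n >= 3")
    k = 2
    row_means = (x + y) / 2.0
    grand = float(np.mean(row_means))
    ms_between = k * float(np.sum((row_means - grand) ** 2)) / (n - 1)
    # per-row within-SS for k=2 ratings is d_i^2 / 2
    ms_within = float(np.sum((x - y) ** 2) / 2.0) / n
    denom = ms_between + (k - 1) * ms_within
    if denom == 0.0:
        raise ValueError("ICC undefined: all values identical everywhere")
    icc = (ms_between - ms_within) / denom
    se = (1.0 - icc * icc) / np.sqrt(n - 1)
    return float(icc), float(se)


def quintile_error_profile(sample: PairedSample) -> QuintileErrorProfile:
    """Mean and SD of reporting error within quintiles of the reference.

    Reference values are partitioned at their empirical 20/40/60/80
    percentiles, with ties assigned to the lower stratum; tied data
    therefore produce visibly unequal stratum sizes, which is expected
    behaviour, not an error.  The one-way ANOVA tests equality of the
    stratum mean errors; strata with n < 2 are excluded from it and
    flagged.  If the error vector is constant the ANOVA is degenerate
    (zero between- and within-stratum variance) and flagged, with p = NaN.
    """
    if sample.n < 10:
        raise ValueError("quintile error profile needs n >= 10")
    ref = np.asarray(sample.reference, float)
    err = sample.differences
    edges = np.percentile(ref, [20, 40, 60, 80])
    # side='left': a value equal to an edge joins the lower stratum
    strata = np.searchsorted(edges, ref, side="left")
    ns = np.bincount(strata, minlength=5)
    means = np.full(5, np.nan)
    sds = np.full(5, np.nan)
    groups = []
    flagged = []
    for q in range(5):
        vals = err[strata == q]
        if vals.size:
            means[q] = vals.mean()
        if vals.size >= 2:
            sds[q] = vals.std(ddof=1)
            groups.append(vals)
        else:
            flagged.append(q)
    degenerate = bool(np.ptp(err) == 0)
    if degenerate or len(groups) < 2:
        anova_p = np.nan
        degenerate = True
    else:
        anova_p = float(stats.f_oneway(*groups).pvalue)
    return QuintileErrorProfile(
        variable=sample.meta.name,
        quintile_edges=edges,
        n_by_quintile=ns,
        mean_error=means,
        sd_error=sds,
        anova_p=anova_p,
        degenerate=degenerate,
        flagged_strata=flagged,
    )


def summarize_agreement(sample: PairedSample) -> AgreementSummary:
    """Assemble the full agreement record for one quantitative variable.

    With n = 2 the record is still produced, but the limits of agreement
    are flagged unreliable and correlation fields are NaN.
    """
    if sample.meta.kind != QUANTITATIVE:
        raise ValueError(
            f"agreement summary requires a quantitative variable, "
            f"got {sample.meta.kind!r}"
        )
    x = np.asarray(sample.self_report, float)
    y = np.asarray(sample.reference, float)
    mean_diff, sd_diff, t_p, degenerate = mean_difference_test(sample)

    loa_reliable = sample.n >= 3
    if loa_reliable:
        loa_lower, loa_upper, s_lower, s_upper = limits_of_agreement(sample)
        icc, icc_se = icc_1_1(sample)
        r, r_se = pearson_with_se(x, y)
    else:
        sd_ref = float(np.std(y, ddof=1))
        loa_lower = mean_diff - LOA_MULTIPLIER * sd_diff
        loa_upper = mean_diff + LOA_MULTIPLIER * sd_diff
        s_lower = loa_lower / sd_ref if sd_ref else np.nan
        s_upper = loa_upper / sd_ref if sd_ref else np.nan
        icc = icc_se = r = r_se = np.nan

    return AgreementSummary(
        variable=sample.meta.name,
        n=sample.n,
        mean_self=float(np.mean(x)),
        sd_self=float(np.std(x, ddof=1)),
        mean_ref=float(np.mean(y)),
        sd_ref=float(np.std(y, ddof=1)),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        t_p=t_p,
        loa_lower=loa_lower,
        loa_upper=loa_upper,
        scaled_loa_lower=s_lower,
        scaled_loa_upper=s_upper,
        icc=icc,
        icc_se=icc_se,
        pearson_r=r,
        pearson_se=r_se,
        degenerate=degenerate,
        loa_reliable=loa_reliable,
    )
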