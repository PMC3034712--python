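"""Regression dilution ratios, bootstrap CIs, and error-impact arithmetic.

Random error in a self-reported exposure attenuates linear disease–exposure
coefficients (log relative risks) toward the null; linear systematic error
can add to or oppose that attenuation.  The regression dilution ratio (RDR)
estimates the combined effect non-parametrically: participants are grouped
by pre-specified categories of the self-reported value, and the RDR is the
ratio of the range of the per-category *reference* means to the range of the
per-category *self-report* means.  An RDR of 1 means no net distortion;
RDR < 1 attenuation; RDR > 1 inflation (systematic scale error opposing
random error).  Confidence intervals come from a percentile bootstrap that
resamples whole participants, preserving the within-pair error structure.

A naive relative risk RR per unit self-reported exposure corresponds to a
corrected ``exp(ln(RR)/RDR)`` per unit true exposure.  Separately, the
squared self-report/reference correlation approximates the effective sample
size as a fraction of the actual one — a power loss no correction restores.
"""

from __future__ import annotations

import numpy as np

from .data_model import CategoryMeans, PairedSample, RDRResult

__all__ = [
    "category_means",
    "rdr_point",
    "rdr_bootstrap_ci",
    "regression_slope_rdr",
    "correct_relative_risk",
    "effective_sample_fraction",
    "attenuation_percent",
]

CI_MULTIPLIER = 1.96

DEFAULT_N_BOOT = 2000


def _resolve_edges(sample: PairedSample, edges) -> np.ndarray:
    """Config-supplied edges if given, else self-report quintile boundaries."""
    if edges is None:
        edges = sample.meta.category_edges
    if edges is None:
        edges = np.percentile(sample.self_report, [0, 20, 40, 60, 80, 100])
        edges = np.unique(edges)  # heavy ties can collapse quintile cuts
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("category edges must be strictly increasing, length >= 2")
    return edges


def _assign_categories(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open intervals [e_i, e_{i+1}), last closed; out of range is an error."""
    if values.min() < edges[0] or values.max() > edges[-1]:
        raise ValueError(
            "self-report values fall outside the category boundaries; "
            "every value must be assignable to exactly one category"
        )
    idx = np.searchsorted(edges, values, side="right") - 1
    np.clip(idx, 0, edges.size - 2, out=idx)  # closes the last interval
    return idx


def category_means(sample: PairedSample, edges=None) -> CategoryMeans:
    """Per-category means of self-report and reference values.

    Categories are the half-open intervals between consecutive ``edges``
    (the last closed).  When ``edges`` is None the variable's configured
    boundaries are used, falling back to empirical self-report quintiles.
    The 95% CI for each category's reference mean is mean ± 1.96·SD/√n.
    Empty categories are recorded in ``empty_categories`` and carry NaN
    means; downstream range computations exclude them.
    """
    edges = _resolve_edges(sample, edges)
    x = np.asarray(sample.self_report, float)
    y = np.asarray(sample.reference, float)
    idx = _assign_categories(x, edges)
    k = edges.size - 1
    ns = np.bincount(idx, minlength=k)
    with np.errstate(invalid="ignore"):
        mean_self = np.bincount(idx, weights=x, minlength=k) / ns
        mean_ref = np.bincount(idx, weights=y, minlength=k) / ns
    ci_lo = np.full(k, np.nan)
    ci_hi = np.full(k, np.nan)
    for c in range(k):
        if ns[c] >= 2:
            sd = y[idx == c].std(ddof=1)
            half = CI_MULTIPLIER * sd / np.sqrt(ns[c])
            ci_lo[c] = mean_ref[c] - half
            ci_hi[c] = mean_ref[c] + half
        elif ns[c] == 1:
            ci_lo[c] = ci_hi[c] = mean_ref[c]
    return CategoryMeans(
        edges=edges,
        n=ns,
        mean_self=mean_self,
        mean_ref=mean_ref,
        ref_ci_lower=ci_lo,
        ref_ci_upper=ci_hi,
        empty_categories=list(np.flatnonzero(ns == 0)),
    )


def rdr_point(categories: CategoryMeans) -> float:
    """Range-of-means regression dilution ratio.

    (max − min of category reference means) / (max − min of category
    self-report means), taken over non-empty categories — never over
    individuals.  Undefined with fewer than two non-empty categories or a
    zero self-report mean range.
    """
    occupied = categories.n > 0
    if occupied.sum() < 2:
        raise ValueError("RDR undefined: fewer than 2 non-empty categories")
    ms = categories.mean_self[occupied]
    mr = categories.mean_ref[occupied]
    self_range = np.ptp(ms)
    if self_range == 0.0:
        raise ValueError("RDR undefined: zero range of self-report category means")
    return float(np.ptp(mr) / self_range)


def rdr_bootstrap_ci(
    sample: PairedSample,
    edges=None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> RDRResult:
    """Percentile-bootstrap 95% CI for the range-of-means RDR.

    The resampling unit is the participant: paired rows are resampled
    together so the joint error structure is preserved.  Category
    boundaries stay fixed across replicates.  Replicates in which any
    originally occupied category empties, or in which the self-report mean
    range collapses to zero, are discarded and counted; more than 50%
    discarded is a failure.  Fixed (edges, n_boot, seed) make the result
    bit-reproducible.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    edges = _resolve_edges(sample, edges)
    full = category_means(sample, edges)
    point = rdr_point(full)

    x = np.asarray(sample.self_report, float)
    y = np.asarray(sample.reference, float)
    cat = _assign_categories(x, edges)
    occupied = np.flatnonzero(full.n > 0)
    k = edges.size - 1
    n = x.size

    rng = np.random.default_rng(seed)
    # category membership is fixed by the edges, so a replicate's category
    # sums reduce to bincounts over (replicate, category) codes
    stats_list = []
    n_discarded = 0
    chunk = max(1, min(n_boot, int(5_000_000 // max(n, 1)) or 1))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        draws = rng.integers(0, n, size=(b, n))
        codes = (np.arange(b)[:, None] * k + cat[draws]).ravel()
        counts = np.bincount(codes, minlength=b * k).reshape(b, k)
        sum_x = np.bincount(codes, weights=x[draws].ravel(), minlength=b * k).reshape(b, k)
        sum_y = np.bincount(codes, weights=y[draws].ravel(), minlength=b * k).reshape(b, k)
        ok = (counts[:, occupied] > 0).all(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mx = sum_x[:, occupied] / counts[:, occupied]
            my = sum_y[:, occupied] / counts[:, occupied]
        rng_x = np.ptp(np.where(counts[:, occupied] > 0, mx, np.nan), axis=1)
        rng_y = np.ptp(np.where(counts[:, occupied] > 0, my, np.nan), axis=1)
        ok &= rng_x > 0
        n_discarded += int(b - ok.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            stats_list.append((rng_y[ok] / rng_x[ok]))
        done += b
    boot = np.concatenate(stats_list)
    if n_discarded > n_boot / 2:
        raise RuntimeError(
            f"bootstrap failed: {n_discarded}/{n_boot} replicates discarded "
            "(emptied categories or collapsed self-report range); "
            "coarser categories or more data are needed"
        )
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return RDRResult(
        variable=sample.meta.name,
        categories=full,
        rdr=point,
        rdr_ci=(float(lo), float(hi)),
        n_bootstrap=n_boot,
        n_discarded=n_discarded,
        rng_seed=seed,
    )


def regression_slope_rdr(sample: PairedSample) -> float:
    """Cross-check utility: OLS slope of reference on self_report.

    For a linear conditional mean E[reference | self_report], this slope
    estimates the same attenuation factor as the range-of-means RDR.  It is
    provided for diagnostics only; the headline statistic is ``rdr_point``.
    """
    x = np.asarray(sample.self_report, float)
    y = np.asarray(sample.reference, float)
    vx = np.var(x)
    if vx == 0:
        raise ValueError("slope undefined: constant self-report vector")
    return float(np.cov(x, y, bias=True)[0, 1] / vx)


def correct_relative_risk(rr: float, rdr: float) -> float:
    """Correct a naive relative risk for reporting-error dilution.

    The RDR multiplies the log relative risk, so the corrected relative
    risk per unit *true* exposure is ``exp(ln(rr)/rdr)``.  With RDR = 1 the
    estimate is returned unchanged; a null effect (rr = 1) is a fixed point.
    """
    if rr <= 0 or rdr <= 0:
        raise ValueError("relative risk and RDR must both be positive")
    return float(np.exp(np.log(rr) / rdr))


def effective_sample_fraction(r: float) -> tuple[float, int]:
    """Power cost of reporting error, as an effective-sample-size fraction.

    The squared self-report/reference correlation approximates the
    effective sample size as a proportion of the actual one.  Returns
    ``(r**2, percent_reduction)`` with the reduction rounded to the nearest
    integer percent for display.  This loss cannot be remedied by RDR-based
    correction — only by a larger sample.
    """
    if abs(r) > 1:
        raise ValueError("correlation must satisfy |r| <= 1")
    fraction = float(r * r)
    return fraction, int(round(100.0 * (1.0 - fraction)))


def attenuation_percent(rdr: float) -> float:
    """Percent attenuation of the log relative risk implied by an RDR.

    100·(1 − RDR); negative values indicate inflation (RDR > 1), as seen
    when differential under-reporting in the upper range opposes random
    error.
    """
    return float(100.0 * (1.0 - rdr))
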