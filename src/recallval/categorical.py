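"""Agreement and association statistics for binary and ordinal variables.

Binary self-reports (e.g. ever breastfed, ever used oral contraceptives)
are compared with the reference by raw percent agreement and Cohen's kappa,
the chance-corrected agreement statistic.  Ordinal self-reports (body-size
or clothes-size categories) are related to a quantitative reference via the
Spearman correlation of the integer level ranks with the reference values,
a linear-trend p-value, and per-level reference means.  Subgroup
comparisons of categorical outcomes (agreement bands, missingness) use
Fisher's exact test, with a Monte-Carlo exact-conditional extension for
tables larger than 2×2.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .data_model import CategoricalAgreement, OrdinalAssociation, PairedSample

__all__ = [
    "kappa_agreement",
    "kappa_band",
    "ordinal_association",
    "subgroup_comparison",
]

# conventional interpretation bands for kappa; the lowest band covers
# everything at or below 0.2, including chance-level and negative values
KAPPA_BANDS = (
    (0.2, "poor"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (np.inf, "excellent"),
)


def kappa_band(kappa: float) -> str:
    """Map a kappa value to its conventional verbal band."""
    for upper, label in KAPPA_BANDS:
        # fp guard so arithmetic like 0.3/0.5 landing at 0.6000…01 stays
        # in the band its exact value belongs to
        if kappa <= upper * (1 + 1e-12) + 1e-15:
            return label
    raise AssertionError("unreachable")


def kappa_agreement(self_report, reference, variable: str = "") -> CategoricalAgreement:
    """Percent agreement and Cohen's kappa between two categorical ratings.

    kappa = (p_o − p_e)/(1 − p_e), where p_o is the observed agreement
    proportion and p_e the chance agreement from the marginal products.
    ``p_vs_chance`` is the two-sided large-sample z-test of kappa = 0,
    using the Fleiss null variance.  If both raters are constant on the
    same label (p_e = 1), kappa is undefined (NaN) but percent agreement
    is still reported.
    """
    a = np.asarray(self_report)
    b = np.asarray(reference)
    if a.shape != b.shape:
        raise ValueError("rating vectors must have equal length")
    n = a.size
    if n < 1:
        raise ValueError("empty rating vectors")
    labels = sorted(set(a.tolist()) | set(b.tolist()))
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    table = np.zeros((k, k), dtype=int)
    ai = np.fromiter((index[v] for v in a.tolist()), int, n)
    bi = np.fromiter((index[v] for v in b.tolist()), int, n)
    np.add.at(table, (ai, bi), 1)

    p = table / n
    p_o = float(np.trace(p))
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_e = float(row @ col)
    percent = 100.0 * p_o

    if p_e == 1.0:
        kappa = np.nan
        p_value = np.nan
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
        # Fleiss large-sample variance of kappa under the null of chance
        var0 = (p_e + p_e**2 - float(np.sum(row * col * (row + col)))) / (
            n * (1.0 - p_e) ** 2
        )
        if var0 <= 0:
            p_value = np.nan
        else:
            z = kappa / np.sqrt(var0)
            p_value = float(2.0 * stats.norm.sf(abs(z)))

    return CategoricalAgreement(
        variable=variable,
        labels=labels,
        table=table,
        percent_agreement=percent,
        kappa=float(kappa),
        kappa_band=kappa_band(kappa) if np.isfinite(kappa) else "undefined",
        p_vs_chance=p_value,
    )


def ordinal_association(sample: PairedSample) -> OrdinalAssociation:
    """Spearman / trend analysis of an ordinal self-report vs quantitative reference.

    Ordinal levels are scored by their integer rank (1 for the lowest
    category, 2 for the next, and so on).  ``spearman_r`` is the Spearman
    rank correlation between those scores and the reference values, with
    ties handled by midranks; ``trend_p`` comes from the least-squares
    regression of the reference on the integer scores (the one-degree-of-
    freedom linear contrast).  Per-level mean and SE of the reference are
    the quantities one plots against level.
    """
    levels = sample.meta.category_edges
    observed = sample.self_report
    if levels is None:
        levels = sorted(set(np.asarray(observed).tolist()))
    levels = list(levels)
    index = {lab: i for i, lab in enumerate(levels)}
    try:
        scores = np.array([index[v] + 1 for v in np.asarray(observed).tolist()])
    except KeyError as e:
        raise ValueError(f"observed level {e.args[0]!r} not in configured levels")
    ref = np.asarray(sample.reference, float)

    occupied = [i for i in range(len(levels)) if np.any(scores == i + 1)]
    if len(occupied) < 2:
        raise ValueError("ordinal association undefined with a single occupied level")

    ns = np.array([int(np.sum(scores == i + 1)) for i in range(len(levels))])
    means = np.array(
        [ref[scores == i + 1].mean() if ns[i] else np.nan for i in range(len(levels))]
    )
    ses = np.array(
        [
            ref[scores == i + 1].std(ddof=1) / np.sqrt(ns[i]) if ns[i] >= 2 else np.nan
            for i in range(len(levels))
        ]
    )
    rho = float(stats.spearmanr(scores, ref).statistic)
    trend_p = float(stats.linregress(scores, ref).pvalue)
    return OrdinalAssociation(
        variable=sample.meta.name,
        levels=levels,
        n_by_level=ns,
        mean_ref=means,
        se_ref=ses,
        spearman_r=rho,
        trend_p=trend_p,
    )


def _log_table_prob(table: np.ndarray) -> float:
    """Log hypergeometric probability of an r×c table given its margins."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def subgroup_comparison(
    table=None,
    *,
    outcome=None,
    factor=None,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, np.ndarray, float | None]:
    """Exact-conditional test of association in an outcome × factor table.

    Accepts either a pre-built contingency ``table`` or raw ``outcome`` and
    ``factor`` label vectors.  All-zero rows/columns are dropped with a
    warning.  For 2×2 tables the two-sided Fisher exact p is returned; for
    larger tables, an exact-conditional p is approximated by Monte-Carlo
    sampling of tables with the observed margins (Patefield's algorithm),
    scoring tables whose conditional probability does not exceed the
    observed one, and is returned with its Monte-Carlo SE.

    Returns ``(p, table, mc_se)`` with ``mc_se`` None for exact 2×2 results.
    """
    if table is None:
        if outcome is None or factor is None:
            raise ValueError("provide either a table or outcome+factor vectors")
        outcome = np.asarray(outcome)
        factor = np.asarray(factor)
        rows = sorted(set(outcome.tolist()))
        cols = sorted(set(factor.tolist()))
        table = np.zeros((len(rows), len(cols)), dtype=int)
        for i, r in enumerate(rows):
            for j, c in enumerate(cols):
                table[i, j] = int(np.sum((outcome == r) & (factor == c)))
    table = np.asarray(table, dtype=int)
    if table.sum() < 2:
        raise ValueError("contingency table needs total n >= 2")

    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping all-zero rows/columns from contingency table")
        table = table[np.ix_(np.flatnonzero(keep_r), np.flatnonzero(keep_c))]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0, table, None

    if table.shape == (2, 2):
        p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
        return p, table, None

    obs_logp = _log_table_prob(table)
    sampler = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    rng = np.random.default_rng(seed)
    draws = sampler.rvs(size=n_permutations, random_state=rng)
    logps = np.array([_log_table_prob(t) for t in draws])
    # tables at least as extreme: probability <= observed (with fp guard)
    hits = logps <= obs_logp + 1e-9
    p = float(hits.mean())
    mc_se = float(np.sqrt(p * (1.0 - p) / n_permutations))
    return p, table, mc_se
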