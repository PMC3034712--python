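"""Synthetic paired validation cohorts with an explicit error model.

Generates data with the structure the analysis assumes, so every stage is
testable without real cohort data.  The quantitative model is

    truth        T ~ Normal(mu_T, sigma_T^2)
    reference    R = T + u,          u ~ Normal(0, sigma_u^2)
    self-report  S = a + b*T + eps,  eps ~ Normal(0, sigma_eps^2)

with u, eps, T mutually independent.  ``a`` and ``b`` encode linear
systematic (differential) reporting error — e.g. heavier individuals
under-reporting weight more corresponds to b < 1; ``sigma_eps`` is random
reporting error; ``sigma_u`` > 0 makes the reference an "alloyed" gold
standard (small random error uncorrelated with everything else).  The
analytic attenuation factor

    lambda = b * sigma_T^2 / (b^2 sigma_T^2 + sigma_eps^2)

is the slope of E[R | S] and the quantity the regression dilution ratio
estimates; it is attached to each generated sample as ground-truth
metadata.  Note lambda does not depend on a or sigma_u, and b < 1 with
small sigma_eps yields lambda > 1 (systematic scale error opposing random
error — the mechanism behind RDRs slightly above 1 for weight-like
variables).

Ratio variables (waist/hip) draw the two components' reporting errors from
a bivariate normal with correlation rho_eps, reproducing the partial
cancellation of correlated errors in a ratio.  Ordinal variables threshold
the error-prone report; binary variables flip a Bernoulli reference through
a sensitivity/specificity misclassification model.  All generators are pure
functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

from .data_model import (
    BINARY,
    ORDINAL,
    QUANTITATIVE,
    PairedSample,
    VariableMeta,
)

__all__ = [
    "ErrorModelSpec",
    "simulate_quantitative",
    "simulate_ratio_pair",
    "simulate_ordinal",
    "simulate_binary",
    "expected_kappa",
    "make_cohort_fixture",
]


@dataclass(frozen=True)
class ErrorModelSpec:
    """Generative parameters for one error-prone variable.

    mu_T, sigma_T — mean and SD of the true quantity (Normal by default;
    ``distribution="lognormal"`` exponentiates the Normal draw for skewed
    variables).  a, b — additive offset and multiplicative slope of the
    systematic reporting error (value units / dimensionless).  sigma_eps —
    SD of random reporting error.  sigma_u — SD of reference-side error
    (0 = gold standard; small > 0 = alloyed).  rho_eps — correlation with
    a linked component's reporting error, used only by ratio pairs.
    round_report — round the self-report to the nearest integer, for
    heaping-prone quantities.
    """

    mu_T: float = 0.0
    sigma_T: float = 1.0
    a: float = 0.0
    b: float = 1.0
    sigma_eps: float = 0.0
    sigma_u: float = 0.0
    rho_eps: float = 0.0
    n: int = 1000
    seed: int = 0
    name: str = "x"
    units: str = ""
    distribution: str = "normal"
    round_report: bool = False

    def __post_init__(self) -> None:
        if min(self.sigma_T, self.sigma_eps, self.sigma_u) < 0:
            raise ValueError("sigma parameters must be >= 0")
        if abs(self.rho_eps) > 1:
            raise ValueError("|rho_eps| must be <= 1")
        if self.b == 0:
            raise ValueError("slope b must be nonzero")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")

    @property
    def attenuation(self) -> float:
        """Analytic attenuation lambda = b·sigma_T²/(b²sigma_T² + sigma_eps²).

        Exact for the Normal truth model; for the lognormal option it is
        the same linear-model formula applied on the latent scale and only
        approximate for the observed values.
        """
        num = self.b * self.sigma_T**2
        den = self.b**2 * self.sigma_T**2 + self.sigma_eps**2
        if den == 0:
            raise ValueError("attenuation undefined: degenerate error model")
        return num / den


def _draw_truth(spec: ErrorModelSpec, rng: np.random.Generator) -> np.ndarray:
    t = rng.normal(spec.mu_T, spec.sigma_T, spec.n)
    return np.exp(t) if spec.distribution == "lognormal" else t


def _assemble(spec, T, eps, u, ids=None) -> PairedSample:
    report = spec.a + spec.b * T + eps
    if spec.round_report:
        report = np.round(report)
    meta = VariableMeta(name=spec.name, kind=QUANTITATIVE, units=spec.units)
    return PairedSample(
        meta=meta,
        ids=np.arange(spec.n) if ids is None else ids,
        self_report=report,
        reference=T + u,
        provenance={"spec": spec, "attenuation": spec.attenuation},
    )


def simulate_quantitative(spec: ErrorModelSpec) -> PairedSample:
    """Draw one quantitative paired sample from the linear error model.

    The analytic attenuation is attached under
    ``sample.provenance["attenuation"]``."""
    rng = np.random.default_rng(spec.seed)
    T = _draw_truth(spec, rng)
    u = rng.normal(0.0, spec.sigma_u, spec.n) if spec.sigma_u else np.zeros(spec.n)
    eps = rng.normal(0.0, spec.sigma_eps, spec.n) if spec.sigma_eps else np.zeros(spec.n)
    return _assemble(spec, T, eps, u)


def simulate_ratio_pair(
    spec_numerator: ErrorModelSpec,
    spec_denominator: ErrorModelSpec,
    rho_eps: float,
    rho_truth: float = 0.0,
    seed: int | None = None,
    max_resample: int = 100,
) -> tuple[PairedSample, PairedSample, PairedSample]:
    """Two linked components with correlated reporting errors, plus their ratio.

    The components' reporting errors are drawn from a bivariate normal with
    correlation ``rho_eps`` (their truths from a bivariate normal with
    correlation ``rho_truth``, default independent).  The ratio variable
    (numerator/denominator) is computed per participant on both the
    self-report and reference sides.  Participants whose denominator is
    not strictly positive on either side are redrawn (truncation); the
    redraw count is reported in the ratio sample's provenance with a
    warning.

    Returns ``(numerator, denominator, ratio)`` PairedSamples.
    """
    if abs(rho_eps) > 1 or abs(rho_truth) > 1:
        raise ValueError("correlations must lie in [-1, 1]")
    sn, sd = spec_numerator, spec_denominator
    if sn.n != sd.n:
        raise ValueError("component specs must share n")
    n = sn.n
    rng = np.random.default_rng(sn.seed if seed is None else seed)

    def draw(size):
        zt = rng.multivariate_normal(
            [0.0, 0.0], [[1.0, rho_truth], [rho_truth, 1.0]], size
        )
        Tn = sn.mu_T + sn.sigma_T * zt[:, 0]
        Td = sd.mu_T + sd.sigma_T * zt[:, 1]
        if sn.distribution == "lognormal":
            Tn = np.exp(Tn)
        if sd.distribution == "lognormal":
            Td = np.exp(Td)
        ze = rng.multivariate_normal(
            [0.0, 0.0], [[1.0, rho_eps], [rho_eps, 1.0]], size
        )
        en = sn.sigma_eps * ze[:, 0]
        ed = sd.sigma_eps * ze[:, 1]
        un = rng.normal(0.0, sn.sigma_u, size)
        ud = rng.normal(0.0, sd.sigma_u, size)
        return Tn, Td, en, ed, un, ud

    Tn, Td, en, ed, un, ud = draw(n)
    n_redrawn = 0
    for _ in range(max_resample):
        den_report = sd.a + sd.b * Td + ed
        den_ref = Td + ud
        bad = (den_report <= 0) | (den_ref <= 0)
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        repl = draw(int(bad.sum()))
        for dst, src in zip((Tn, Td, en, ed, un, ud), repl):
            dst[bad] = src
    else:
        raise RuntimeError("could not draw positive denominators; check the spec")
    if n_redrawn:
        warnings.warn(
            f"resampled {n_redrawn} draws with non-positive denominator values"
        )

    num = _assemble(sn, Tn, en, un)
    den = _assemble(sd, Td, ed, ud)
    ratio_meta = VariableMeta(
        name=f"{sn.name}_to_{sd.name}_ratio", kind=QUANTITATIVE
    )
    ratio = PairedSample(
        meta=ratio_meta,
        ids=num.ids,
        self_report=num.self_report / den.self_report,
        reference=num.reference / den.reference,
        provenance={
            "rho_eps": rho_eps,
            "rho_truth": rho_truth,
            "n_redrawn": n_redrawn,
            "error_numerator": en,
            "error_denominator": ed,
        },
    )
    return num, den, ratio


def simulate_ordinal(spec: ErrorModelSpec, thresholds: Sequence[float]) -> PairedSample:
    """Ordinal self-report obtained by thresholding the error-prone report.

    The reported level is the count of thresholds strictly below
    ``a + b·T + eps`` (levels 0 … len(thresholds)); the reference stays
    quantitative (T + u).  A single threshold yields a binary variable.
    """
    thresholds = np.asarray(thresholds, float)
    if thresholds.ndim != 1 or thresholds.size < 1 or not np.all(
        np.diff(thresholds) > 0
    ):
        raise ValueError("thresholds must be a strictly increasing 1-d sequence")
    quant = simulate_quantitative(spec)
    levels = np.searchsorted(thresholds, quant.self_report, side="left")
    meta = VariableMeta(
        name=spec.name,
        kind=ORDINAL,
        category_edges=list(range(thresholds.size + 1)),
    )
    return PairedSample(
        meta=meta,
        ids=quant.ids,
        self_report=levels,
        reference=quant.reference,
        provenance=dict(quant.provenance, thresholds=thresholds),
    )


def expected_kappa(p_true: float, sensitivity: float, specificity: float) -> float:
    """Closed-form Cohen's kappa of the expected misclassification table.

    With reference prevalence ``p_true`` and the self-report flipping
    through (sensitivity, specificity), the expected 2×2 cell proportions
    are known exactly and kappa follows from its definition.
    """
    p11 = p_true * sensitivity
    p10 = p_true * (1.0 - sensitivity)
    p01 = (1.0 - p_true) * (1.0 - specificity)
    p00 = (1.0 - p_true) * specificity
    p_o = p11 + p00
    row1 = p11 + p01  # P(self-report = 1)
    col1 = p11 + p10  # P(reference = 1)
    p_e = row1 * col1 + (1.0 - row1) * (1.0 - col1)
    if p_e == 1.0:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def simulate_binary(
    p_true: float,
    sensitivity: float,
    specificity: float,
    n: int,
    seed: int = 0,
    name: str = "x",
) -> PairedSample:
    """Binary paired sample under a sensitivity/specificity error model.

    reference ~ Bernoulli(p_true); the self-report reproduces a true 1
    with probability ``sensitivity`` and a true 0 with probability
    ``specificity``.  The closed-form expected kappa is attached as
    ``provenance["expected_kappa"]``."""
    for label, p in (
        ("p_true", p_true),
        ("sensitivity", sensitivity),
        ("specificity", specificity),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{label} must be a probability in [0, 1]")
    rng = np.random.default_rng(seed)
    ref = rng.random(n) < p_true
    flip_up = rng.random(n) < sensitivity
    flip_dn = rng.random(n) < specificity
    report = np.where(ref, flip_up, ~flip_dn)
    meta = VariableMeta(name=name, kind=BINARY)
    return PairedSample(
        meta=meta,
        ids=np.arange(n),
        self_report=report.astype(int),
        reference=ref.astype(int),
        provenance={
            "expected_kappa": expected_kappa(p_true, sensitivity, specificity)
        },
    )


# ---------------------------------------------------------------------------
# Multi-variable cohort fixtures
# ---------------------------------------------------------------------------


def make_cohort_fixture(
    config: Mapping[str, Mapping],
    path: str | Path,
    seed: int = 0,
    n_participants: int | None = None,
) -> pd.DataFrame:
    """Write a long-format multi-variable cohort CSV for the full pipeline.

    ``config`` maps variable names to generator settings: the keys of
    ``ErrorModelSpec`` for quantitative variables, plus optionally
    ``kind`` ("quantitative" | "ordinal" | "binary"), ``thresholds``
    (ordinal), ``p_true/sensitivity/specificity`` (binary),
    ``missing_rate``, and ``missing_rate_by_subgroup`` (mapping subgroup
    label -> rate, emulating socially patterned missingness).  A
    two-level ``social_class`` subgroup column is always generated.
    Output is byte-identical for a fixed seed.
    """
    path = Path(path)
    rng = np.random.default_rng(seed)
    names = list(config)
    ns = {
        name: int(cfg.get("n", n_participants or 500)) for name, cfg in config.items()
    }
    if n_participants is not None:
        ns = {name: n_participants for name in names}
    n_max = max(ns.values())
    subgroup = np.where(rng.random(n_max) < 0.5, "manual", "non-manual")

    frames = []
    for name, cfg in config.items():
        cfg = dict(cfg)
        kind = cfg.pop("kind", QUANTITATIVE)
        missing_rate = cfg.pop("missing_rate", 0.0)
        missing_by = cfg.pop("missing_rate_by_subgroup", None)
        n = ns[name]
        var_seed = int(rng.integers(0, 2**31 - 1))
        if kind == QUANTITATIVE:
            spec = ErrorModelSpec(name=name, n=n, seed=var_seed, **cfg)
            sample = simulate_quantitative(spec)
            self_col = sample.self_report
        elif kind == ORDINAL:
            thresholds = cfg.pop("thresholds")
            spec = ErrorModelSpec(name=name, n=n, seed=var_seed, **cfg)
            sample = simulate_ordinal(spec, thresholds)
            self_col = sample.self_report
        elif kind == BINARY:
            sample = simulate_binary(
                cfg.get("p_true", 0.5),
                cfg.get("sensitivity", 1.0),
                cfg.get("specificity", 1.0),
                n,
                seed=var_seed,
                name=name,
            )
            self_col = sample.self_report
        else:
            raise ValueError(f"variable {name!r}: unknown kind {kind!r}")

        block = pd.DataFrame(
            {
                "id": [f"p{i:05d}" for i in range(n)],
                "variable": name,
                "self_report": self_col,
                "reference": sample.reference,
                "social_class": subgroup[:n],
            }
        )
        if missing_by:
            rates = np.array([missing_by.get(s, missing_rate) for s in subgroup[:n]])
        else:
            rates = np.full(n, missing_rate)
        drop = rng.random(n) < rates
        block.loc[drop, "self_report"] = np.nan
        frames.append(block)

    table = pd.concat(frames, ignore_index=True)
    table.to_csv(path, index=False, lineterminator="\n")
    return table


def alloyed_preset(spec: ErrorModelSpec, sigma_u: float = 0.1) -> ErrorModelSpec:
    """Variant of a spec whose reference carries small random error."""
    return replace(spec, sigma_u=sigma_u)
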