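"""End-to-end orchestration: config + long table in, report bundle out.

``run_pipeline`` loads the per-variable config and the paired table, runs
the kind-appropriate analyses for every variable, and writes:

    agreement.csv       quantitative agreement rows (n, means, mean
                        difference with t-test, limits of agreement raw and
                        scaled, ICC, Pearson r)
    quintile_errors.csv mean/SD reporting error by reference quintile, with
                        the one-way ANOVA p for differential error
    ordinal.csv         Spearman/trend rows for ordinal variables
    categorical.csv     percent agreement / kappa rows for binary variables
    rdr.json            full RDR results (category table, point estimate,
                        percentile-bootstrap CI, seed, attenuation band)
    figure_<var>.csv    per-category plotted quantities (mean self-report,
                        mean reference, reference CI)
    manifest.json       seed, n_boot, package version, per-variable n and
                        missing counts, and any skipped variables with the
                        reason

A variable that fails its preconditions (too few observations, constant
values, …) is skipped with a logged reason; only a global failure aborts
the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import quintile_error_profile, summarize_agreement
from .categorical import kappa_agreement, ordinal_association
from .data_model import (
    BINARY,
    ORDINAL,
    QUANTITATIVE,
    load_config,
    load_paired_table,
    result_to_dict,
)
from .dilution import DEFAULT_N_BOOT, attenuation_percent, rdr_bootstrap_ci

logger = logging.getLogger("recallval")

__all__ = ["run_pipeline", "classify_rdr", "RDR_BANDS"]

# descriptive attenuation bands; boundaries are labels, not inferential claims
RDR_BANDS = (
    (0.66, "substantial attenuation"),
    (0.86, "slight-to-moderate attenuation"),
    (np.inf, "little-or-no attenuation"),
)


def classify_rdr(rdr: float, bands=RDR_BANDS) -> str:
    """Verbal attenuation band for an RDR (boundaries overridable).

    Bands are lower-inclusive: values below the first boundary are
    "substantial attenuation", values from 0.66 through 0.86 inclusive
    "slight-to-moderate", anything above "little-or-no attenuation".
    """
    if rdr < 0:
        raise ValueError("RDR must be nonnegative")
    for i, (upper, label) in enumerate(bands):
        if (rdr < upper) if i == 0 else (rdr <= upper):
            return label
    raise AssertionError("unreachable")


def run_pipeline(
    config_path: str | Path,
    input_path: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    n_boot: int = DEFAULT_N_BOOT,
) -> dict:
    """Run every configured analysis and write the report bundle.

    Returns the manifest dict.  Individual variables failing their
    preconditions are skipped and recorded; the function raises only on
    global failure (unreadable config/input, unwritable output).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = load_config(config_path)
    samples = load_paired_table(input_path, config)

    agreement_rows, quintile_rows, ordinal_rows, categorical_rows = [], [], [], []
    rdr_results = {}
    skipped = {}
    rng = np.random.default_rng(seed)

    for name, sample in samples.items():
        kind = sample.meta.kind
        try:
            if kind == QUANTITATIVE:
                summ = summarize_agreement(sample)
                agreement_rows.append(asdict(summ))
                if sample.n >= 10:
                    prof = quintile_error_profile(sample)
                    quintile_rows.append(_quintile_row(prof))
                var_seed = int(rng.integers(0, 2**31 - 1))
                rdr = rdr_bootstrap_ci(sample, n_boot=n_boot, seed=var_seed)
                entry = result_to_dict(rdr)
                entry["band"] = classify_rdr(rdr.rdr)
                entry["attenuation_percent"] = attenuation_percent(rdr.rdr)
                rdr_results[name] = entry
                _write_figure_data(out_dir / f"figure_{name}.csv", rdr)
            elif kind == ORDINAL:
                assoc = ordinal_association(sample)
                ordinal_rows.append(_ordinal_row(assoc))
            elif kind == BINARY:
                agree = kappa_agreement(
                    sample.self_report, sample.reference, variable=name
                )
                categorical_rows.append(_categorical_row(agree))
        except (ValueError, RuntimeError) as exc:
            logger.warning("skipping %s: %s", name, exc)
            skipped[name] = str(exc)

    if agreement_rows:
        pd.DataFrame(agreement_rows).to_csv(
            out_dir / "agreement.csv", index=False, lineterminator="\n"
        )
    if quintile_rows:
        pd.DataFrame(quintile_rows).to_csv(
            out_dir / "quintile_errors.csv", index=False, lineterminator="\n"
        )
    if ordinal_rows:
        pd.DataFrame(ordinal_rows).to_csv(
            out_dir / "ordinal.csv", index=False, lineterminator="\n"
        )
    if categorical_rows:
        pd.DataFrame(categorical_rows).to_csv(
            out_dir / "categorical.csv", index=False, lineterminator="\n"
        )
    (out_dir / "rdr.json").write_text(json.dumps(rdr_results, indent=2, sort_keys=True))

    manifest = {
        "seed": seed,
        "n_boot": n_boot,
        "version": __version__,
        "variables": {
            name: {"kind": s.meta.kind, "n": s.n, "n_missing": s.n_missing}
            for name, s in samples.items()
        },
        "skipped": skipped,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _write_figure_data(path: Path, rdr) -> None:
    cats = rdr.categories
    pd.DataFrame(
        {
            "category": np.arange(cats.n.size),
            "n": cats.n,
            "mean_self": cats.mean_self,
            "mean_ref": cats.mean_ref,
            "ci_lo": cats.ref_ci_lower,
            "ci_hi": cats.ref_ci_upper,
        }
    ).to_csv(path, index=False, lineterminator="\n")


def _quintile_row(prof) -> dict:
    row = {"variable": prof.variable, "anova_p": prof.anova_p,
           "degenerate": prof.degenerate}
    for q in range(5):
        row[f"q{q + 1}_n"] = int(prof.n_by_quintile[q])
        row[f"q{q + 1}_mean_error"] = prof.mean_error[q]
        row[f"q{q + 1}_sd_error"] = prof.sd_error[q]
    return row


def _ordinal_row(assoc) -> dict:
    row = {
        "variable": assoc.variable,
        "spearman_r": assoc.spearman_r,
        "trend_p": assoc.trend_p,
    }
    for i, level in enumerate(assoc.levels):
        row[f"level_{level}_n"] = int(assoc.n_by_level[i])
        row[f"level_{level}_mean_ref"] = assoc.mean_ref[i]
        row[f"level_{level}_se_ref"] = assoc.se_ref[i]
    return row


def _categorical_row(agree) -> dict:
    return {
        "variable": agree.variable,
        "n": int(agree.table.sum()),
        "percent_agreement": agree.percent_agreement,
        "kappa": agree.kappa,
        "kappa_band": agree.kappa_band,
        "p_vs_chance": agree.p_vs_chance,
    }
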