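"""Domain types, tabular I/O, and data-preparation conversions.

The package analyses *paired* validation data: for each participant and each
variable there is a self-reported value (obtained retrospectively, typically
by questionnaire) and a reference value (measured, or collected close to the
relevant age, and treated as an at-least "alloyed" gold standard).  Input is
a long-format delimited table — one row per participant × variable — plus a
per-variable metadata configuration describing the variable kind
(quantitative / ordinal / binary), units, and any pre-specified category
boundaries used by the dilution analysis.

Missingness is handled per variable pair (complete case): a row is excluded
for a variable when either member of the pair is missing, and the excluded
count is retained so missingness itself can be analysed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableKind",
    "VariableMeta",
    "PairedSample",
    "AgreementSummary",
    "QuintileErrorProfile",
    "CategoryMeans",
    "RDRResult",
    "OrdinalAssociation",
    "CategoricalAgreement",
    "ConfigError",
    "ParseError",
    "load_config",
    "load_paired_table",
    "write_paired_table",
    "wide_to_long",
    "convert_units",
    "adjust_integer_age",
]

QUANTITATIVE = "quantitative"
ORDINAL = "ordinal"
BINARY = "binary"
VariableKind = (QUANTITATIVE, ORDINAL, BINARY)


class ConfigError(ValueError):
    """A variable or option is missing from, or inconsistent with, the config."""


class ParseError(ValueError):
    """A value in the input table could not be parsed for its declared kind."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VariableMeta:
    """Per-variable analysis plan.

    Parameters
    ----------
    name:
        Variable identifier, matching the ``variable`` column of the input.
    kind:
        ``"quantitative"``, ``"ordinal"`` or ``"binary"``; determines which
        analysis operations are legal for the variable.
    units:
        Free-text units for reporting.
    category_edges:
        For quantitative variables, the strictly increasing boundaries of the
        pre-specified self-report categories used by the dilution analysis
        (``k`` edges define ``k - 1`` half-open intervals, the last closed).
        For ordinal variables, the ordered level labels.
    reference_description:
        Free-text description of the reference measurement.
    integer_years:
        True when the self-report is recorded in whole years; the +0.5-year
        mid-year adjustment is applied only to such variables, never
        automatically.
    recode:
        Optional mapping applied to raw labels of binary/ordinal variables
        before analysis (e.g. collapsing a duration into ever/never).
    """

    name: str
    kind: str = QUANTITATIVE
    units: str = ""
    category_edges: Sequence | None = None
    reference_description: str = ""
    integer_years: bool = False
    recode: Mapping | None = None

    def __post_init__(self) -> None:
        if self.kind not in VariableKind:
            raise ConfigError(
                f"variable {self.name!r}: unknown kind {self.kind!r}; "
                f"expected one of {VariableKind}"
            )
        if self.category_edges is not None:
            edges = list(self.category_edges)
            if self.kind == QUANTITATIVE:
                arr = np.asarray(edges, dtype=float)
                if arr.ndim != 1 or arr.size < 2 or not np.all(np.diff(arr) > 0):
                    raise ConfigError(
                        f"variable {self.name!r}: category_edges must be a "
                        "strictly increasing sequence of at least 2 boundaries"
                    )
            elif self.kind == ORDINAL and len(edges) < 2:
                raise ConfigError(
                    f"variable {self.name!r}: ordinal variables need >= 2 levels"
                )


@dataclass
class PairedSample:
    """Aligned self-report / reference vectors for one variable.

    ``self_report - reference`` is the per-participant reporting error
    (difference) analysed throughout.
    """

    meta: VariableMeta
    ids: np.ndarray
    self_report: np.ndarray
    reference: np.ndarray
    subgroups: dict[str, np.ndarray] | None = None
    n_missing: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.self_report = np.asarray(self.self_report)
        self.reference = np.asarray(self.reference)
        if not (len(self.ids) == len(self.self_report) == len(self.reference)):
            raise ValueError(
                f"variable {self.meta.name!r}: ids, self_report and reference "
                "must have equal length"
            )
        if self.meta.kind == QUANTITATIVE:
            self.self_report = self.self_report.astype(float)
            self.reference = self.reference.astype(float)
            if np.isnan(self.self_report).any() or np.isnan(self.reference).any():
                raise ValueError(
                    f"variable {self.meta.name!r}: missing values must be "
                    "removed (complete-case) before constructing a PairedSample"
                )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def differences(self) -> np.ndarray:
        """Reporting errors: self_report − reference."""
        return self.self_report - self.reference


@dataclass
class AgreementSummary:
    """One variable's quantitative agreement record.

    Collects the paired-sample means and SDs, the mean reporting error with
    its paired t-test, 95% limits of agreement (raw and in reference-SD
    units), the one-way intraclass correlation ICC(1,1) and the Pearson
    correlation, each with a large-sample standard error.
    """

    variable: str
    n: int
    mean_self: float
    sd_self: float
    mean_ref: float
    sd_ref: float
    mean_diff: float
    sd_diff: float
    t_p: float
    loa_lower: float
    loa_upper: float
    scaled_loa_lower: float
    scaled_loa_upper: float
    icc: float
    icc_se: float
    pearson_r: float
    pearson_se: float
    degenerate: bool = False
    loa_reliable: bool = True


@dataclass
class QuintileErrorProfile:
    """Mean/SD of reporting error within quintiles of the reference values.

    ``anova_p`` is the one-way ANOVA p-value testing equality of the stratum
    mean errors (strata with fewer than 2 observations are excluded from the
    ANOVA and flagged)."""

    variable: str
    quintile_edges: np.ndarray
    n_by_quintile: np.ndarray
    mean_error: np.ndarray
    sd_error: np.ndarray
    anova_p: float
    degenerate: bool = False
    flagged_strata: list = field(default_factory=list)


@dataclass
class CategoryMeans:
    """Per-category means of both members within self-report categories.

    Mirrors a category-mean plot: mean reference value (with 95% CI) plotted
    against mean self-report value within each pre-specified category of the
    self-reported variable.  Empty categories are recorded and excluded from
    any range computation."""

    edges: np.ndarray
    n: np.ndarray
    mean_self: np.ndarray
    mean_ref: np.ndarray
    ref_ci_lower: np.ndarray
    ref_ci_upper: np.ndarray
    empty_categories: list = field(default_factory=list)


@dataclass
class RDRResult:
    """Non-parametric regression dilution ratio with percentile-bootstrap CI.

    ``rdr`` is the ratio of the range of per-category reference means to the
    range of per-category self-report means; perfectly reported data give 1.
    """

    variable: str
    categories: CategoryMeans
    rdr: float
    rdr_ci: tuple[float, float]
    n_bootstrap: int
    n_discarded: int
    rng_seed: int


@dataclass
class OrdinalAssociation:
    """Association of an ordinal self-report with a quantitative reference."""

    variable: str
    levels: list
    n_by_level: np.ndarray
    mean_ref: np.ndarray
    se_ref: np.ndarray
    spearman_r: float
    trend_p: float


@dataclass
class CategoricalAgreement:
    """Contingency-table agreement between two categorical ratings."""

    variable: str
    labels: list
    table: np.ndarray
    percent_agreement: float
    kappa: float
    kappa_band: str
    p_vs_chance: float


# ---------------------------------------------------------------------------
# Config and table I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ("id", "variable", "self_report", "reference")


def load_config(path: str | Path) -> dict[str, VariableMeta]:
    """Read a YAML or JSON mapping of variable name -> VariableMeta fields."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: expected a mapping of variable name -> fields")
    config: dict[str, VariableMeta] = {}
    for name, fields_ in raw.items():
        fields_ = dict(fields_ or {})
        fields_.setdefault("name", name)
        if fields_["name"] != name:
            raise ConfigError(f"{path}: key {name!r} disagrees with name field")
        config[name] = VariableMeta(**fields_)
    return config


def _coerce_config(config) -> dict[str, VariableMeta]:
    if isinstance(config, Mapping):
        return dict(config)
    return {m.name: m for m in config}


def load_paired_table(
    path: str | Path, config: Mapping[str, VariableMeta] | Sequence[VariableMeta]
) -> dict[str, PairedSample]:
    """Read a long-format paired table into one PairedSample per variable.

    The file must be delimited text (comma or tab, sniffed from the header)
    with columns ``id, variable, self_report, reference`` plus optional
    subgroup columns.  Rows with a missing value in either member are
    excluded per variable (complete case) and counted in
    ``PairedSample.n_missing``.

    Raises
    ------
    ConfigError
        If the file contains a variable absent from ``config``.
    ParseError
        If a quantitative variable has a non-numeric, non-missing value;
        the message includes the offending row index.
    """
    config = _coerce_config(config)
    path = Path(path)
    sep = "\t" if "\t" in path.open().readline() else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "variable": str})
    missing_cols = set(_TABLE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing required columns {sorted(missing_cols)}")
    subgroup_cols = [c for c in df.columns if c not in _TABLE_COLUMNS]

    unknown = set(df["variable"].unique()) - set(config)
    if unknown:
        raise ConfigError(
            f"{path}: variables not present in config: {sorted(unknown)}"
        )

    samples: dict[str, PairedSample] = {}
    for name, meta in config.items():
        block = df[df["variable"] == name]
        if block.empty:
            continue
        self_raw, ref_raw = block["self_report"], block["reference"]
        if meta.kind == QUANTITATIVE:
            self_vals = pd.to_numeric(self_raw, errors="coerce")
            ref_vals = pd.to_numeric(ref_raw, errors="coerce")
            for col_name, raw, num in (
                ("self_report", self_raw, self_vals),
                ("reference", ref_raw, ref_vals),
            ):
                bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
                if bad.any():
                    row = int(bad.idxmax())
                    raise ParseError(
                        f"variable {name!r}: non-numeric {col_name} value "
                        f"{raw.loc[row]!r} at row {row}"
                    )
        else:
            self_vals, ref_vals = self_raw, ref_raw
            if meta.recode:
                self_vals = self_vals.map(lambda v: meta.recode.get(v, v))
                ref_vals = ref_vals.map(lambda v: meta.recode.get(v, v))
        keep = self_vals.notna() & ref_vals.notna()
        samples[name] = PairedSample(
            meta=meta,
            ids=block.loc[keep, "id"].to_numpy(),
            self_report=self_vals[keep].to_numpy(),
            reference=ref_vals[keep].to_numpy(),
            subgroups={c: block.loc[keep, c].to_numpy() for c in subgroup_cols}
            or None,
            n_missing=int((~keep).sum()),
        )
    return samples


def write_paired_table(samples: Mapping[str, PairedSample], path: str | Path) -> None:
    """Write PairedSamples back to the long CSV dialect (round-trip exact).

    Floats are written with Python's shortest round-trip repr, so reloading
    reproduces every value bit-exactly."""
    frames = []
    for name, s in samples.items():
        block = pd.DataFrame(
            {
                "id": s.ids,
                "variable": name,
                "self_report": s.self_report,
                "reference": s.reference,
            }
        )
        for col, vals in (s.subgroups or {}).items():
            block[col] = vals
        frames.append(block)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, lineterminator="\n")


def wide_to_long(
    df: pd.DataFrame,
    id_col: str,
    variables: Mapping[str, tuple[str, str]],
    subgroup_cols: Sequence[str] = (),
) -> pd.DataFrame:
    """Convenience reshaper: wide table -> the long paired format.

    ``variables`` maps each variable name to the ``(self_report_column,
    reference_column)`` pair holding its two measurements."""
    frames = []
    for name, (self_col, ref_col) in variables.items():
        block = pd.DataFrame(
            {
                "id": df[id_col],
                "variable": name,
                "self_report": df[self_col],
                "reference": df[ref_col],
            }
        )
        for c in subgroup_cols:
            block[c] = df[c]
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Data-preparation conversions
# ---------------------------------------------------------------------------

_CM_PER_INCH = 2.54  # international inch
_KG_PER_LB = 0.45359237  # international avoirdupois pound
_LB_PER_STONE = 14


def convert_units(value, conversion: str):
    """Exact unit conversions used when preparing self-reported data.

    ``months_to_years`` divides by 12 without rounding; imperial conversions
    use the international definitions (1 in = 2.54 cm, 1 lb = 0.45359237 kg).
    ``stone_lb_to_kg`` takes a ``(stones, pounds)`` pair.  Negative inputs
    are a domain error: the supported quantities are nonnegative.
    """
    if conversion == "stone_lb_to_kg":
        stones, pounds = value
        stones, pounds = np.asarray(stones, float), np.asarray(pounds, float)
        if (stones < 0).any() or (pounds < 0).any():
            raise ValueError("negative values are not valid for unit conversion")
        out = (stones * _LB_PER_STONE + pounds) * _KG_PER_LB
        return float(out) if out.ndim == 0 else out

    arr = np.asarray(value, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative values are not valid for unit conversion")
    factors = {
        "inch_to_cm": _CM_PER_INCH,
        "lb_to_kg": _KG_PER_LB,
        "months_to_years": 1.0 / 12.0,
    }
    try:
        out = arr * factors[conversion]
    except KeyError:
        raise ValueError(f"unknown conversion {conversion!r}") from None
    return float(out) if out.ndim == 0 else out


def adjust_integer_age(age_years):
    """Mid-year adjustment for ages reported in whole years.

    A report of "12" covers ages 12.0–12.99…, whose mean is 12 years and
    6 months, so 0.5 is added to make whole-year reports comparable with
    exact-date data.  Defined only for integer-valued input.
    """
    arr = np.asarray(age_years, dtype=float)
    if not np.all(arr == np.floor(arr)):
        raise ValueError("mid-year adjustment is only defined for whole-year ages")
    out = arr + 0.5
    return float(out) if out.ndim == 0 else out


def result_to_dict(result) -> dict:
    """Dataclass result -> JSON-serialisable dict (numpy -> lists/floats)."""

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return _clean(obj.tolist())
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return _clean(asdict(result))
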