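"""Reading, validating and writing GWAS summary statistics and result tables.

Summary statistics arrive as tab-delimited text with a header row. Column
names vary across GWAS exports, so reading goes through a configurable
column map; a bundled synonym table covers the common conventions
(SNP/rsid, A1/effect_allele, ...). Rows violating basic invariants
(se <= 0, invalid alleles, p outside (0, 1]) are dropped and counted, never
silently repaired — with one exception: p-values of exactly 0 are floored
to the smallest positive float with a warning, since truncated exports
print 0 for genome-wide hits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger("mrkit.sumstats_io")

VALID_ALLELES = frozenset("ACGT")

#: Smallest positive double; p-values of exactly 0 are floored here.
MIN_PVAL = float(np.nextafter(0.0, 1.0))

#: Synonyms accepted for each canonical column, lower-cased.
DEFAULT_COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "variant_id": ("variant_id", "snp", "rsid", "rs_id", "id", "markername"),
    "effect_allele": ("effect_allele", "a1", "ea", "allele1"),
    "other_allele": ("other_allele", "a2", "oa", "nea", "allele2", "allele0"),
    "eaf": ("eaf", "effect_allele_frequency", "freq", "af", "frq"),
    "beta": ("beta", "b", "effect", "es"),
    "se": ("se", "standard_error", "stderr", "sebeta"),
    "pval": ("pval", "p", "pvalue", "p_value", "p-value"),
    "n": ("n", "samplesize", "sample_size", "n_total"),
}

REQUIRED_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")
OPTIONAL_FIELDS = ("eaf", "n")


@dataclass
class SummaryStatRecord:
    """One variant's association with one trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None

    @property
    def frequency_unknown(self) -> bool:
        return self.eaf is None


@dataclass
class SummaryDataset:
    """A trait's summary statistics plus dataset-level metadata."""

    trait_label: str
    records: list[SummaryStatRecord]
    default_n: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError(f"dataset '{self.trait_label}' has no valid records")
        if self.default_n is not None and self.default_n <= 0:
            raise InputError("default_n must be positive")

    def __len__(self) -> int:
        return len(self.records)

    def record_n(self, rec: SummaryStatRecord) -> float | None:
        """Per-record sample size, falling back to the dataset default."""
        return rec.n if rec.n is not None else self.default_n

    def by_id(self) -> dict[str, SummaryStatRecord]:
        return {r.variant_id: r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [r.variant_id for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "eaf": [np.nan if r.eaf is None else r.eaf for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "pval": [r.pval for r in self.records],
                "n": [np.nan if r.n is None else r.n for r in self.records],
            }
        )


def resolve_column_map(
    header: Sequence[str], column_map: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Map canonical field names to actual header columns.

    Explicit entries in ``column_map`` win; remaining fields are matched
    case-insensitively against the bundled synonym table.
    """
    lower = {c.lower(): c for c in header}
    resolved: dict[str, str] = {}
    column_map = dict(column_map or {})
    for fld in REQUIRED_FIELDS + OPTIONAL_FIELDS:
        if fld in column_map:
            col = column_map[fld]
            if col not in header:
                raise ConfigurationError(
                    f"mapped column '{col}' for field '{fld}' not in header {list(header)}"
                )
            resolved[fld] = col
            continue
        for syn in DEFAULT_COLUMN_SYNONYMS[fld]:
            if syn in lower:
                resolved[fld] = lower[syn]
                break
    missing = [f for f in REQUIRED_FIELDS if f not in resolved]
    if missing:
        raise ConfigurationError(
            f"required column(s) {missing} not found in header {list(header)}; "
            "supply a column_map"
        )
    return resolved


def _parse_float(value) -> float | None:
    if value is None:
        return None
    try:
        x = float(value)
    except (TypeError, ValueError):
        return None
    if math.isnan(x):
        return None
    return x


def _validate_row(
    variant_id, ea, oa, eaf, beta, se, pval, n
) -> tuple[SummaryStatRecord | None, str | None]:
    """Build a record from raw values, or return (None, reason)."""
    if not variant_id or not isinstance(variant_id, str):
        return None, "missing variant_id"
    ea = str(ea).strip().upper()
    oa = str(oa).strip().upper()
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        return None, f"invalid alleles {ea}/{oa}"
    if ea == oa:
        return None, "effect_allele == other_allele"
    beta = _parse_float(beta)
    se = _parse_float(se)
    pval = _parse_float(pval)
    if beta is None:
        return None, "missing beta"
    if se is None or se <= 0:
        return None, "se missing or <= 0"
    if pval is None or pval > 1 or pval < 0:
        return None, "pval outside [0, 1]"
    if pval == 0:
        logger.warning("variant %s: p-value of 0 floored to %.3e", variant_id, MIN_PVAL)
        pval = MIN_PVAL
    eaf = _parse_float(eaf)
    if eaf is not None and not (0.0 <= eaf <= 1.0):
        return None, f"eaf {eaf} outside [0, 1]"
    n = _parse_float(n)
    if n is not None and n <= 0:
        return None, "n <= 0"
    return (
        SummaryStatRecord(
            variant_id=variant_id.strip(),
            effect_allele=ea,
            other_allele=oa,
            beta=beta,
            se=se,
            pval=pval,
            eaf=eaf,
            n=n,
        ),
        None,
    )


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    default_n: float | None = None,
    trait_label: str | None = None,
) -> SummaryDataset:
    """Read a tab-delimited summary-statistics file.

    Rows violating record invariants are dropped and logged; duplicate
    variant IDs keep the first occurrence. Raises
    :class:`~mrkit.exceptions.InputError` if no valid rows remain and
    :class:`~mrkit.exceptions.ConfigurationError` for unmapped columns.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary-statistics file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    resolved = resolve_column_map(df.columns.tolist(), column_map)

    records: list[SummaryStatRecord] = []
    seen: set[str] = set()
    n_dropped = 0
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        rec, reason = _validate_row(
            row_d.get(resolved["variant_id"]),
            row_d.get(resolved["effect_allele"]),
            row_d.get(resolved["other_allele"]),
            row_d.get(resolved.get("eaf", ""), None),
            row_d.get(resolved["beta"]),
            row_d.get(resolved["se"]),
            row_d.get(resolved["pval"]),
            row_d.get(resolved.get("n", ""), None),
        )
        if rec is None:
            n_dropped += 1
            logger.warning("dropping row (%s): %s", reason, row_d)
            continue
        if rec.variant_id in seen:
            n_dropped += 1
            logger.warning("duplicate variant %s: keeping first occurrence", rec.variant_id)
            continue
        seen.add(rec.variant_id)
        records.append(rec)

    if not records:
        raise InputError(f"{path}: no valid summary-statistic rows")
    logger.info("%s: %d records loaded, %d dropped", path, len(records), n_dropped)
    ds = SummaryDataset(
        trait_label=trait_label or path.stem,
        records=records,
        default_n=default_n,
        metadata={"path": str(path), "n_dropped": n_dropped, "n_raw": len(df)},
    )
    return ds


def write_sumstats(dataset: SummaryDataset, path: str | Path) -> None:
    """Write a dataset back to tab-delimited text (canonical column names)."""
    df = dataset.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


RESULTS_COLUMNS = (
    "outcome",
    "n_snps",
    "method",
    "OR_95CI",
    "OR",
    "CI_low",
    "CI_high",
    "beta",
    "se",
    "p",
    "p_het",
    "p_pleio",
)


def write_results_table(
    estimates: Iterable,
    diagnostics: Mapping[str, Mapping[str, float]] | None,
    path: str | Path,
    outcome: str = "outcome",
) -> pd.DataFrame:
    """Write the per-method causal-effect table.

    One row per method with the odds ratio and 95% CI both as a formatted
    display cell (``OR_95CI``, 2 d.p.) and as full-precision numeric
    columns; heterogeneity/pleiotropy p-values are filled from
    ``diagnostics`` (keyed by method name) and rendered NA elsewhere.
    """
    from .estimators import format_or_ci  # local import to avoid a cycle

    estimates = list(estimates)
    if not estimates:
        raise InputError("write_results_table needs at least one estimate")
    diagnostics = diagnostics or {}
    rows = []
    for est in estimates:
        diag = diagnostics.get(est.method, {})
        rows.append(
            {
                "outcome": outcome,
                "n_snps": est.n_snps,
                "method": est.method,
                "OR_95CI": format_or_ci(est.beta, est.se),
                "OR": est.or_,
                "CI_low": est.ci_low,
                "CI_high": est.ci_high,
                "beta": est.beta,
                "se": est.se,
                "p": est.pval,
                "p_het": diag.get("p_het", np.nan),
                "p_pleio": diag.get("p_pleio", np.nan),
            }
        )
    df = pd.DataFrame(rows, columns=list(RESULTS_COLUMNS))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")
    return df


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
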