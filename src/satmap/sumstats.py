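"""Tabular inputs for post-GWAS saturation mapping.

This module owns the data model shared by the rest of the package:

* summary-statistic / COJO signal tables, held as :class:`pandas.DataFrame`
  objects with canonical column names (``snp``, ``chrom``, ``pos``,
  ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``,
  ``n`` and, for conditionally independent signals, ``beta_joint``,
  ``se_joint``, ``pval_joint``; optional QC columns ``info``, ``hwe_p``,
  ``mac``),
* PLINK-style gene range lists (``chrom start end name``), and
* the study-level QC rules (imputation accuracy, Hardy-Weinberg
  equilibrium, minor allele count).

Coordinates are 1-based and intervals are closed on both ends throughout
the package.  Alleles are stored verbatim: inputs are assumed harmonized
(as conditional-and-joint analysis outputs are) and no strand flipping is
attempted.  Only autosomes (chromosomes 1-22) are in scope.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SatmapError",
    "ColumnError",
    "EmptyInputError",
    "ParseError",
    "QCThresholds",
    "COJO_DIALECT",
    "SUMMARY_COLUMNS",
    "COJO_COLUMNS",
    "read_cojo_table",
    "write_cojo_table",
    "read_summary_table",
    "qc_filter",
    "read_gene_ranges",
    "write_gene_ranges",
    "flag_candidates",
    "validate_signals",
]


class SatmapError(Exception):
    """Base class for package errors."""


class ColumnError(SatmapError):
    """A mandatory column is missing from an input table."""


class EmptyInputError(SatmapError):
    """An input table or sequence contains no data rows."""


class ParseError(SatmapError):
    """One or more data rows violate the field contract.

    Attributes
    ----------
    lines : list of int
        1-based line numbers (header included in the count) of the
        offending rows.
    """

    def __init__(self, message: str, lines: Sequence[int]):
        super().__init__(f"{message} (lines: {', '.join(map(str, lines))})")
        self.lines = list(lines)


#: Default column dialect matching GCTA-COJO ``.jma.cojo`` headers.
COJO_DIALECT: dict[str, str] = {
    "Chr": "chrom",
    "SNP": "snp",
    "bp": "pos",
    "refA": "effect_allele",
    "freq": "eaf",
    "b": "beta",
    "se": "se",
    "p": "pval",
    "n": "n",
    "bJ": "beta_joint",
    "bJ_se": "se_joint",
    "pJ": "pval_joint",
}

#: Canonical mandatory columns of a marginal summary-statistic table.
SUMMARY_COLUMNS = ("snp", "chrom", "pos", "eaf", "beta", "se", "pval", "n")

#: Canonical mandatory columns of a conditionally independent signal table.
COJO_COLUMNS = SUMMARY_COLUMNS + ("beta_joint", "se_joint", "pval_joint")

_OPTIONAL_COLUMNS = ("effect_allele", "other_allele", "info", "hwe_p", "mac")

GWS_PVAL = 5e-8  # genome-wide significance threshold


@dataclasses.dataclass(frozen=True)
class QCThresholds:
    """Study-level SNP quality-control rules.

    A SNP is kept when ``info >= min_info``, ``hwe_p >= min_hwe_p`` and
    ``mac >= min_mac``; a rule is skipped for records where the field is
    absent.  The defaults are the study-level thresholds (imputation
    r2 > 0.3, HWE P > 1e-8, MAC > 5); the stricter reference-panel HWE
    threshold of 1e-6 can be configured here when needed.
    """

    min_info: float = 0.3
    min_hwe_p: float = 1e-8
    min_mac: float = 5.0

    def __post_init__(self) -> None:
        if self.min_info < 0 or self.min_hwe_p < 0 or self.min_mac < 0:
            raise ValueError("QC thresholds must be nonnegative")


def _numeric(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series, errors="coerce")


def _row_validity(df: pd.DataFrame, joint: bool) -> pd.Series:
    """Boolean mask of rows satisfying the record invariants."""
    ok = (
        _numeric(df["chrom"]).isin(range(1, 23))
        & (_numeric(df["pos"]) >= 1)
        & _numeric(df["eaf"]).between(0.0, 1.0)
        & (_numeric(df["se"]) > 0)
        & (_numeric(df["pval"]) > 0)
        & (_numeric(df["pval"]) <= 1)
        & (_numeric(df["n"]) > 0)
        & _numeric(df["beta"]).notna()
    )
    if joint:
        ok &= (
            (_numeric(df["se_joint"]) > 0)
            & (_numeric(df["pval_joint"]) > 0)
            & (_numeric(df["pval_joint"]) <= 1)
            & _numeric(df["beta_joint"]).notna()
        )
    return ok


def _read_table(
    path,
    dialect: Mapping[str, str],
    mandatory: Sequence[str],
) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.shape[0] == 0:
        raise EmptyInputError(f"no data rows in {path}")
    df = df.rename(columns=dict(dialect))
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ColumnError(
            f"missing mandatory column(s) {missing} in {path}; "
            f"available: {list(df.columns)}"
        )
    joint = "beta_joint" in mandatory
    valid = _row_validity(df, joint=joint)
    if not valid.all():
        bad = (np.flatnonzero(~valid.to_numpy()) + 2).tolist()  # +1 header, +1 1-based
        raise ParseError(f"unparseable or invalid mandatory fields in {path}", bad)
    keep = [c for c in list(mandatory) + list(_OPTIONAL_COLUMNS) if c in df.columns]
    out = df[keep].copy()
    for col in keep:
        if col in ("effect_allele", "other_allele", "snp"):
            continue
        out[col] = pd.to_numeric(out[col])
    out["chrom"] = out["chrom"].astype(int)
    out["pos"] = out["pos"].astype(int)
    return out.reset_index(drop=True)


def read_cojo_table(path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a table of conditionally independent GWS signals.

    Parameters
    ----------
    path
        Whitespace/tab-separated file with a header row.
    dialect
        Mapping from file column names to canonical names; defaults to the
        GCTA-COJO ``.jma.cojo`` header convention (:data:`COJO_DIALECT`).

    Returns
    -------
    pandas.DataFrame
        One row per signal, in file order, with canonical columns
        (:data:`COJO_COLUMNS` plus any optional columns present).

    Raises
    ------
    ColumnError
        If a mandatory column is absent after applying the dialect.
    EmptyInputError
        If the file has no data rows.
    ParseError
        Listing the line numbers of rows whose mandatory fields do not
        parse or violate the record invariants.
    """
    return _read_table(path, dialect or COJO_DIALECT, COJO_COLUMNS)


def read_summary_table(path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a marginal summary-statistic table (no joint-effect columns)."""
    dialect = dialect or {k: v for k, v in COJO_DIALECT.items() if not k.startswith("bJ") and k != "pJ"}
    return _read_table(path, dialect, SUMMARY_COLUMNS)


def write_cojo_table(df: pd.DataFrame, path, dialect: Mapping[str, str] | None = None) -> None:
    """Write a canonical signal table back to disk in the given dialect.

    Round-trips with :func:`read_cojo_table`: re-reading the written file
    reproduces the records.
    """
    inverse = {v: k for k, v in (dialect or COJO_DIALECT).items()}
    df.rename(columns=inverse).to_csv(path, sep="\t", index=False)


def qc_filter(
    records: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply study-level SNP QC rules.

    A record may fail several rules and then counts toward each; records
    lacking an optional QC field pass the corresponding rule vacuously.
    Idempotent: filtering an already-filtered table changes nothing.

    Returns
    -------
    (kept, report)
        ``kept``: rows passing every applicable rule, in input order.
        ``report``: removal counts keyed by rule (``info``, ``hwe_p``,
        ``mac``) plus ``removed`` (unique rows removed) and ``kept``.
    """
    if records.shape[0] == 0:
        raise EmptyInputError("qc_filter requires a non-empty table")
    fail = {}
    for col, cut in (
        ("info", thresholds.min_info),
        ("hwe_p", thresholds.min_hwe_p),
        ("mac", thresholds.min_mac),
    ):
        if col in records.columns:
            vals = _numeric(records[col])
            fail[col] = (vals < cut) & vals.notna()
        else:
            fail[col] = pd.Series(False, index=records.index)
    any_fail = fail["info"] | fail["hwe_p"] | fail["mac"]
    kept = records.loc[~any_fail].copy()
    report = {rule: int(mask.sum()) for rule, mask in fail.items()}
    report["removed"] = int(any_fail.sum())
    report["kept"] = int((~any_fail).sum())
    return kept, report


def read_gene_ranges(path) -> tuple[pd.DataFrame, int]:
    """Read a 4-column gene range list (``chrom start end name``).

    Non-autosomal entries (chromosome not in 1-22, e.g. X/Y/MT) are
    skipped and counted.  Returns ``(genes, n_skipped)`` where ``genes``
    has columns ``name, chrom, start, end, is_candidate`` (flag
    initialised to False; see :func:`flag_candidates`).

    Raises
    ------
    ParseError
        For lines with ``start > end`` or non-numeric coordinates.
    EmptyInputError
        If the file has no rows.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str,
                     names=["chrom", "start", "end", "name"])
    if df.shape[0] == 0:
        raise EmptyInputError(f"no rows in {path}")
    chrom = _numeric(df["chrom"])
    autosomal = chrom.isin(range(1, 23))
    start = _numeric(df["start"])
    end = _numeric(df["end"])
    bad_mask = autosomal & (start.isna() | end.isna() | (start > end) | (start < 1))
    if bad_mask.any():
        bad = (np.flatnonzero(bad_mask.to_numpy()) + 1).tolist()
        raise ParseError(f"invalid gene interval(s) in {path}", bad)
    genes = pd.DataFrame(
        {
            "name": df.loc[autosomal, "name"].to_numpy(),
            "chrom": chrom[autosomal].astype(int).to_numpy(),
            "start": start[autosomal].astype(int).to_numpy(),
            "end": end[autosomal].astype(int).to_numpy(),
        }
    )
    genes["is_candidate"] = False
    return genes.reset_index(drop=True), int((~autosomal).sum())


def write_gene_ranges(genes: pd.DataFrame, path) -> None:
    """Write a gene table back to the 4-column range-list layout."""
    genes[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def flag_candidates(genes: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    """Return a copy of ``genes`` with ``is_candidate`` set by name membership."""
    out = genes.copy()
    out["is_candidate"] = out["name"].isin(set(names)).to_numpy()
    return out


def validate_signals(signals: pd.DataFrame, require_joint: bool = False) -> None:
    """Assert the signal-table invariants; raise :class:`ParseError` otherwise.

    When ``require_joint`` is set, also checks that each signal is
    genome-wide significant in at least one of the marginal and joint
    tests (min(p, p_joint) < 5e-8).
    """
    needed = COJO_COLUMNS if require_joint else SUMMARY_COLUMNS
    missing = [c for c in needed if c not in signals.columns]
    if missing:
        raise ColumnError(f"missing column(s) {missing}")
    ok = _row_validity(signals, joint=require_joint)
    if require_joint:
        ok &= np.minimum(signals["pval"], signals["pval_joint"]) < GWS_PVAL
    if not ok.all():
        raise ParseError(
            "signal table violates invariants",
            (np.flatnonzero(~ok.to_numpy()) + 1).tolist(),
        )
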