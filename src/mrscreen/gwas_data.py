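"""GWAS summary statistics: reading, validation, and allele harmonization.

A :class:`SummaryDataset` holds one trait's per-SNP association table
(effect sizes on the log-odds or standardized scale, their standard
errors, p-values, allele coding and frequencies).  Two datasets are
combined into a :class:`HarmonizedSet` by aligning the outcome's effects
to the exposure's effect allele; palindromic (A/T, C/G) variants, whose
strand cannot be resolved from the alleles alone, are removed
unconditionally, and every exclusion is logged with its reason.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SummaryDataset",
    "HarmonizedSet",
    "ValidationSummary",
    "CANONICAL_COLUMNS",
    "read_summary_stats",
    "validate_frame",
    "harmonize",
    "write_summary_stats",
    "write_harmonized",
    "read_harmonized",
]

VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

#: canonical field -> default column header (GWAS Catalog harmonized naming)
CANONICAL_COLUMNS: dict[str, str] = {
    "snp_id": "variant_id",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pval": "p_value",
    "n": "n",
}

REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")

#: column order of the internal table
_FIELDS = ("snp_id", "chrom", "pos", "effect_allele", "other_allele",
           "eaf", "beta", "se", "pval", "n")


@dataclass
class ValidationSummary:
    """Row accounting for one read/validate pass."""

    rows_read: int
    rows_kept: int
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def rows_dropped(self) -> int:
        return sum(self.dropped.values())


@dataclass
class SummaryDataset:
    """One trait's GWAS summary statistics.

    ``df`` columns: snp_id, chrom, pos, effect_allele, other_allele,
    eaf, beta, se, pval, n.  ``snp_id`` is unique within a dataset.
    """

    trait_name: str
    df: pd.DataFrame
    ancestry_label: str = "EUR"
    source_id: str = ""

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def subset(self, snp_ids) -> "SummaryDataset":
        keep = self.df[self.df["snp_id"].isin(set(snp_ids))].reset_index(drop=True)
        return SummaryDataset(self.trait_name, keep, self.ancestry_label, self.source_id)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SummaryDataset({self.trait_name!r}, {self.n_snps} SNPs)"


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on a shared effect-allele orientation.

    ``df`` columns: snp_id, beta_exp, se_exp, beta_out, se_out, eaf_exp.
    ``exclusion_log`` lists ``(snp_id, reason)`` for every instrument SNP
    that did not survive harmonization, so rows + exclusions account for
    every input SNP.
    """

    exposure_name: str
    outcome_name: str
    df: pd.DataFrame
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_snp(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    @property
    def bx(self) -> np.ndarray:
        return self.df["beta_exp"].to_numpy(dtype=float)

    @property
    def sx(self) -> np.ndarray:
        return self.df["se_exp"].to_numpy(dtype=float)

    @property
    def by(self) -> np.ndarray:
        return self.df["beta_out"].to_numpy(dtype=float)

    @property
    def sy(self) -> np.ndarray:
        return self.df["se_out"].to_numpy(dtype=float)

    def drop_snps(self, snp_ids) -> "HarmonizedSet":
        """Return a copy without the named SNPs (no exclusion-log entry)."""
        bad = set(snp_ids)
        keep = self.df[~self.df["snp_id"].isin(bad)].reset_index(drop=True)
        return HarmonizedSet(self.exposure_name, self.outcome_name, keep,
                             list(self.exclusion_log))


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_summary_stats(path, column_map: dict[str, str] | None = None,
                       trait_name: str | None = None,
                       ancestry_label: str = "EUR"):
    """Read a delimited summary-statistics table.

    Parameters
    ----------
    path
        TSV or CSV file with a header row; the delimiter is auto-detected.
    column_map
        Mapping from canonical field name to the file's column header;
        unspecified fields fall back to :data:`CANONICAL_COLUMNS`.

    Returns
    -------
    (SummaryDataset, ValidationSummary)
        Rows failing type or range validation are dropped and counted by
        reason; a missing *required* column is a fatal ``ValueError``
        naming the column.
    """
    cmap = dict(CANONICAL_COLUMNS)
    if column_map:
        cmap.update(column_map)

    with open(path, "r", newline="") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ValueError(f"empty summary-statistics file: {path}")
        delim = _sniff_delimiter(header_line)
        header = next(csv.reader([header_line], delimiter=delim))
        raw = pd.read_csv(fh, sep=delim, names=header, dtype=str,
                          keep_default_na=False, na_values=["", "NA", "NaN", "nan"])

    for canonical in REQUIRED_FIELDS:
        if cmap[canonical] not in header:
            raise ValueError(
                f"required column {canonical!r} (header {cmap[canonical]!r}) "
                f"missing from {path}")

    frame = pd.DataFrame()
    for canonical in _FIELDS:
        col = cmap.get(canonical)
        frame[canonical] = raw[col] if col in raw.columns else np.nan

    clean, summary = validate_frame(frame)
    name = trait_name or str(path)
    return SummaryDataset(name, clean, ancestry_label, str(path)), summary


def validate_frame(frame: pd.DataFrame):
    """Validate and coerce a raw summary-statistics frame.

    Returns the clean frame plus a :class:`ValidationSummary`.  Rules:
    se > 0, pval in (0, 1], finite beta, single-letter A/C/G/T alleles
    that differ, eaf (when present) in [0, 1]; duplicate snp_ids keep
    the smallest-pval row.
    """
    df = frame.copy()
    n_read = len(df)
    dropped: dict[str, int] = {}

    for col in ("beta", "se", "pval", "eaf"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()

    def _drop(mask: pd.Series, reason: str):
        nonlocal df
        k = int(mask.sum())
        if k:
            dropped[reason] = dropped.get(reason, 0) + k
            df = df[~mask]

    _drop(df["snp_id"].isin(["", "nan"]), "missing snp_id")
    _drop(~df["effect_allele"].isin(VALID_ALLELES)
          | ~df["other_allele"].isin(VALID_ALLELES), "invalid alleles")
    _drop(df["effect_allele"] == df["other_allele"], "identical alleles")
    _drop(~np.isfinite(df["beta"]), "missing or nonfinite beta")
    _drop(~np.isfinite(df["se"]) | (df["se"] <= 0), "nonpositive se")
    _drop(~np.isfinite(df["pval"]) | (df["pval"] <= 0) | (df["pval"] > 1),
          "pval out of range")
    _drop(df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1)),
          "eaf out of range")
    _drop(df["n"].notna() & (df["n"] <= 0), "nonpositive n")

    if df["snp_id"].duplicated().any():
        df = df.sort_values(["pval", "snp_id"], kind="mergesort")
        dup = df["snp_id"].duplicated(keep="first")
        _drop(dup, "duplicate snp_id")
        df = df.sort_index()

    df = df.reset_index(drop=True)
    return df, ValidationSummary(n_read, len(df), dropped)


def _is_palindromic(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    return ((a1 == "A") & (a2 == "T")) | ((a1 == "T") & (a2 == "A")) | \
           ((a1 == "C") & (a2 == "G")) | ((a1 == "G") & (a2 == "C"))


def harmonize(exposure: SummaryDataset, outcome: SummaryDataset) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    Matching is by snp_id.  If the outcome's alleles are swapped relative
    to the exposure, the outcome beta's sign is flipped (and eaf would be
    mirrored); palindromic exposure SNPs are removed unconditionally;
    allele pairs that neither match nor swap are removed as ambiguous;
    SNPs absent from the outcome are removed.  Raises ``ValueError`` if
    nothing survives.
    """
    exp = exposure.df
    out = outcome.df
    sid = exp["snp_id"].to_numpy()
    ea = exp["effect_allele"].to_numpy()
    oa = exp["other_allele"].to_numpy()

    out_sid = out["snp_id"].to_numpy()
    if len(out_sid) == len(sid) and np.array_equal(out_sid, sid):
        pos = np.arange(len(sid))          # already-aligned fast path
    else:
        pos = pd.Index(out_sid).get_indexer(sid)
    found = pos >= 0
    safe = np.where(found, pos, 0)
    ea_o = out["effect_allele"].to_numpy()[safe]
    oa_o = out["other_allele"].to_numpy()[safe]
    beta_o = out["beta"].to_numpy(dtype=float)[safe]
    se_o = out["se"].to_numpy(dtype=float)[safe]

    palindromic = _is_palindromic(ea, oa)
    missing = ~found & ~palindromic
    direct = found & (ea_o == ea) & (oa_o == oa)
    swapped = found & (ea_o == oa) & (oa_o == ea)
    ambiguous = ~palindromic & ~missing & ~direct & ~swapped
    keep = ~palindromic & ~missing & ~ambiguous

    log: list[tuple[str, str]] = []
    for mask, reason in ((palindromic, "palindromic"),
                         (missing, "not found in outcome"),
                         (ambiguous, "ambiguous alleles")):
        log.extend((s, reason) for s in sid[mask])

    sign = np.where(swapped[keep], -1.0, 1.0)
    rows = pd.DataFrame({
        "snp_id": sid[keep],
        "beta_exp": exp["beta"].to_numpy(dtype=float)[keep],
        "se_exp": exp["se"].to_numpy(dtype=float)[keep],
        "beta_out": sign * beta_o[keep],
        "se_out": se_o[keep],
        "eaf_exp": exp["eaf"].to_numpy(dtype=float)[keep],
    })

    if rows.empty:
        raise ValueError(
            f"no usable instruments after harmonizing "
            f"{exposure.trait_name!r} against {outcome.trait_name!r}")
    return HarmonizedSet(exposure.trait_name, outcome.trait_name, rows, log)


def write_summary_stats(dataset: SummaryDataset, path) -> None:
    """Write a dataset as TSV with the canonical GWAS Catalog headers."""
    out = dataset.df.rename(columns=CANONICAL_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def write_harmonized(h: HarmonizedSet, path, exclusions_path=None) -> None:
    """Write harmonized rows to TSV, and optionally the exclusion log."""
    h.df.to_csv(path, sep="\t", index=False)
    if exclusions_path is not None:
        pd.DataFrame(h.exclusion_log, columns=["snp_id", "reason"]).to_csv(
            exclusions_path, sep="\t", index=False)


def read_harmonized(path, exposure_name: str = "exposure",
                    outcome_name: str = "outcome") -> HarmonizedSet:
    df = pd.read_csv(path, sep="\t")
    return HarmonizedSet(exposure_name, outcome_name, df)
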