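"""Instrument selection: significance thresholds, LD clumping, F filtering.

Instruments for an exposure are SNPs that pass a genome-wide
significance threshold (p < 5e-8, relaxed to 5e-6 when too few are
found), are mutually independent after greedy LD clumping
(r^2 <= 0.001 within a 10,000 kb window by default), and are strong
(per-SNP F >= 10), so that weak-instrument bias is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gwas_data import SummaryDataset

__all__ = [
    "SelectionConfig",
    "LDMatrix",
    "InstrumentSet",
    "select_by_pvalue",
    "clump",
    "f_statistic",
    "r2_from_summary",
    "build_instruments",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing instrument selection.

    p_primary / p_fallback / p_mediator are the genome-wide, relaxed and
    mediator-screen significance thresholds; clumping retains index SNPs
    so that every retained pair has r^2 <= clump_r2 or lies further than
    clump_window_kb apart; f_min is the weak-instrument cutoff; the
    fallback threshold engages when fewer than min_instruments SNPs pass
    p_primary.
    """

    p_primary: float = 5e-8
    p_fallback: float = 5e-6
    p_mediator: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    min_instruments: int = 3

    def __post_init__(self):
        if not (0 < self.p_primary <= self.p_fallback <= self.p_mediator < 1):
            raise ValueError("need 0 < p_primary <= p_fallback <= p_mediator < 1")
        if not (0 <= self.clump_r2 < 1):
            raise ValueError("clump_r2 must be in [0, 1)")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")
        if self.f_min < 0:
            raise ValueError("f_min must be non-negative")

    def for_mediators(self) -> "SelectionConfig":
        """Config with both p thresholds relaxed to the mediator threshold."""
        return replace(self, p_primary=self.p_mediator, p_fallback=self.p_mediator)


@dataclass
class LDMatrix:
    """Pairwise squared correlations (r^2) among a set of SNPs.

    Symmetric, unit diagonal, entries in [0, 1]; ``positions`` maps each
    snp_id to its (chrom, pos) so clumping can apply its distance window.
    """

    snp_ids: list[str]
    r2: np.ndarray
    positions: dict[str, tuple[str, int]]

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.snp_ids)
        if self.r2.shape != (m, m):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if (self.r2 < 0).any() or (self.r2 > 1 + 1e-12).any():
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def index(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} missing from LD matrix") from None

    def pair_r2(self, a: str, b: str) -> float:
        return float(self.r2[self.index(a), self.index(b)])

    # -- IO ------------------------------------------------------------
    @classmethod
    def read_square(cls, path, positions: dict[str, tuple[str, int]]) -> "LDMatrix":
        """Square TSV: header row of snp_ids, one matrix row per line."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(c) for c in df.columns]
        return cls(ids, df.to_numpy(dtype=float), positions)

    @classmethod
    def read_long(cls, path, positions: dict[str, tuple[str, int]]) -> "LDMatrix":
        """Long TSV with columns snp_a, snp_b, r2; unlisted pairs are 0."""
        df = pd.read_csv(path, sep="\t")
        ids = sorted(set(df["snp_a"]).union(df["snp_b"]))
        idx = {s: i for i, s in enumerate(ids)}
        r2 = np.eye(len(ids))
        for a, b, v in zip(df["snp_a"], df["snp_b"], df["r2"]):
            r2[idx[a], idx[b]] = r2[idx[b], idx[a]] = float(v)
        return cls(ids, r2, positions)

    def write_square(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t")


@dataclass
class InstrumentSet:
    """SNPs surviving every selection filter, with per-SNP strength."""

    exposure_name: str
    df: pd.DataFrame
    per_snp_f: dict[str, float]
    threshold_used: float
    stage_counts: dict[str, int] = field(default_factory=dict)
    weak_snps: list[str] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def dataset(self, source: SummaryDataset) -> SummaryDataset:
        """The exposure dataset restricted to the selected instruments."""
        return source.subset(self.df["snp_id"])


def select_by_pvalue(dataset: SummaryDataset, config: SelectionConfig):
    """Threshold at p_primary, falling back to p_fallback when too few pass.

    Returns ``(records, threshold_used)``; raises ``ValueError`` when no
    SNP passes even the relaxed threshold.
    """
    df = dataset.df
    primary = df[df["pval"] < config.p_primary]
    if len(primary) >= config.min_instruments:
        return primary.reset_index(drop=True), config.p_primary
    fallback = df[df["pval"] < config.p_fallback]
    if len(fallback) == 0:
        raise ValueError(
            f"no instruments for {dataset.trait_name!r} at either threshold "
            f"({config.p_primary:g}, {config.p_fallback:g})")
    if len(primary) > 0 and len(fallback) == len(primary):
        return primary.reset_index(drop=True), config.p_primary
    return fallback.reset_index(drop=True), config.p_fallback


def clump(records: pd.DataFrame, ld: LDMatrix, config: SelectionConfig) -> pd.DataFrame:
    """Greedy LD clumping.

    Candidates are ranked by ascending p-value (ties broken by genomic
    order); the best remaining SNP becomes an index SNP and removes every
    remaining same-chromosome SNP within ``clump_window_kb`` of it whose
    r^2 with it exceeds ``clump_r2``.  Index SNPs are returned in genomic
    order.  A record absent from the LD matrix is a ``KeyError`` naming
    the SNP.
    """
    if records.empty:
        return records
    sids = records["snp_id"].tolist()
    idx = np.array([ld.index(s) for s in sids])
    chroms = np.array([ld.positions[s][0] for s in sids])
    pos = np.array([ld.positions[s][1] for s in sids], dtype=float)
    pvals = records["pval"].to_numpy(dtype=float)

    order = sorted(range(len(sids)), key=lambda i: (pvals[i], chroms[i], pos[i]))
    window_bp = config.clump_window_kb * 1000.0
    removed = np.zeros(len(sids), dtype=bool)
    kept: list[int] = []
    for i in order:
        if removed[i]:
            continue
        kept.append(i)
        same_chrom = chroms == chroms[i]
        near = np.abs(pos - pos[i]) <= window_bp
        linked = ld.r2[idx[i], idx] > config.clump_r2
        hit = same_chrom & near & linked & ~removed
        hit[i] = False
        removed |= hit

    kept.sort(key=lambda i: (chroms[i], pos[i]))
    return records.iloc[kept].reset_index(drop=True)


def f_statistic(n: float, k: int, r2: float) -> float:
    """Instrument-strength F = ((N - K - 1)/K) * (R^2 / (1 - R^2)).

    N is the GWAS sample size, K the number of instruments assessed
    jointly (K = 1 for per-SNP strength), R^2 the variance of the
    exposure they explain.
    """
    if not (0 <= r2 < 1):
        raise ValueError("r2 must lie in [0, 1)")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    return ((n - k - 1) / k) * (r2 / (1 - r2))


def r2_from_summary(beta: float, se: float, n: float) -> float:
    """Per-SNP variance explained, beta^2 / (beta^2 + (n - 2) * se^2).

    The standard t-statistic-based approximation; used when the summary
    file carries no explicit r^2 column.
    """
    if n <= 2:
        raise ValueError("need n > 2")
    b2 = float(beta) ** 2
    return b2 / (b2 + (n - 2) * float(se) ** 2)


def build_instruments(dataset: SummaryDataset, ld: LDMatrix,
                      config: SelectionConfig = SelectionConfig()) -> InstrumentSet:
    """Full selection pipeline: p-threshold -> clump -> per-SNP F filter."""
    selected, threshold = select_by_pvalue(dataset, config)
    counts = {"input": len(dataset.df), "p_threshold": len(selected)}

    clumped = clump(selected, ld, config)
    counts["clumped"] = len(clumped)

    fvals, weak = {}, []
    keep_rows = []
    for row in clumped.itertuples(index=False):
        n = row.n if np.isfinite(row.n) else np.nan
        if not np.isfinite(n):
            raise ValueError(f"SNP {row.snp_id}: sample size required for F filter")
        f = f_statistic(n, 1, r2_from_summary(row.beta, row.se, n))
        if f >= config.f_min:
            fvals[row.snp_id] = f
            keep_rows.append(row)
        else:
            weak.append(row.snp_id)
    strong = pd.DataFrame(keep_rows, columns=clumped.columns)
    counts["f_filter"] = len(strong)

    return InstrumentSet(dataset.trait_name, strong, fvals, threshold,
                         counts, weak)
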