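"""Heterogeneity and pleiotropy diagnostics for an MR analysis.

Cochran's Q quantifies heterogeneity across per-SNP Wald ratios; the
MR-Egger intercept tests for average directional pleiotropy; MR-PRESSO
(pleiotropy residual sum and outlier) runs a simulation-based global
heterogeneity test, flags individual outlier SNPs, re-estimates the
causal effect without them and tests whether removing them distorts the
estimate; leave-one-out re-estimation shows whether any single SNP
drives the overall result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MRResult, egger, ivw
from .gwas_data import HarmonizedSet

__all__ = [
    "QResult",
    "PressoResult",
    "LeaveOneOutRow",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
]


@dataclass
class QResult:
    """Cochran's Q heterogeneity statistic with its chi-square p-value."""

    q: float
    df: int
    pval: float


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_pval: float
    outlier_snps: list[tuple[str, float]]
    corrected: MRResult
    raw: MRResult
    distortion_pval: float
    n_sim: int
    seed: int
    outlier_pvals: dict[str, float] = field(default_factory=dict)

    @property
    def outlier_ids(self) -> list[str]:
        return [s for s, _ in self.outlier_snps]


@dataclass
class LeaveOneOutRow:
    snp_id: str
    result: MRResult
    flagged: bool


def _ratio_stats(h: HarmonizedSet):
    ratios = h.by / h.bx
    w = h.bx**2 / h.sy**2          # 1 / var(first-order ratio)
    return ratios, w


def cochran_q(h: HarmonizedSet) -> QResult:
    """Heterogeneity of the per-SNP Wald ratios around their
    fixed-effect inverse-variance mean; upper-tail chi-square p with
    n_snp - 1 degrees of freedom."""
    if h.n_snp < 2:
        raise ValueError("cochran_q requires >= 2 instruments")
    ratios, w = _ratio_stats(h)
    mean = np.sum(w * ratios) / np.sum(w)
    q = float(np.sum(w * (ratios - mean) ** 2))
    df = h.n_snp - 1
    return QResult(q, df, float(stats.chi2.sf(q, df)))


def egger_intercept_test(h: HarmonizedSet):
    """The MR-Egger intercept triple (estimate, SE, p-value).

    A p below 0.05 is the conventional signal of average directional
    pleiotropy.
    """
    r = egger(h)
    return r.intercept, r.intercept_se, r.intercept_pval


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW slopes for every SNP, vectorized."""
    s1 = np.sum(w * bx * by)
    s2 = np.sum(w * bx * bx)
    return (s1 - w * bx * by) / (s2 - w * bx * bx)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, sig: float = 0.05,
              seed: int | None = None) -> PressoResult:
    """MR-PRESSO: residual-sum-of-squares heterogeneity test with
    per-SNP outlier detection and outlier-corrected re-estimation.

    Global test: each SNP's outcome effect is compared with the
    prediction of the IVW slope fitted without it; the observed weighted
    RSS is ranked against ``n_sim`` parametric simulations of the
    no-pleiotropy null (outcome effects drawn about those leave-one-out
    predictions, exposure effects about their observed values).
    Empirical p-values use add-one smoothing, (1 + #{>= obs})/(1 + n_sim).

    Outlier test: each SNP's observed weighted squared residual against
    its own simulated distribution, Bonferroni-corrected across SNPs;
    corrected p < ``sig`` flags the SNP.

    Distortion test: the raw-minus-corrected slope difference against
    the distribution obtained by removing random same-size SNP subsets.
    """
    if h.n_snp < 4:
        raise ValueError("insufficient instruments for MR-PRESSO (need >= 4)")
    if seed is None:
        raise ValueError("mr_presso requires an explicit seed")
    rng = np.random.default_rng(seed)
    m = h.n_snp
    bx, by, sx, sy = h.bx, h.by, h.sx, h.sy
    w = 1.0 / sy**2

    beta_loo = _loo_slopes(bx, by, w)
    pred = beta_loo * bx
    res_obs = w * (by - pred) ** 2
    rss_obs = float(np.sum(res_obs))

    # simulated null: redraw both sides, recompute LOO residuals per draw
    bxs = rng.normal(bx, sx, size=(n_sim, m))
    bys = rng.normal(pred, sy, size=(n_sim, m))
    ws = w[None, :]
    s1 = np.sum(ws * bxs * bys, axis=1, keepdims=True)
    s2 = np.sum(ws * bxs * bxs, axis=1, keepdims=True)
    loo = (s1 - ws * bxs * bys) / (s2 - ws * bxs * bxs)
    res_sim = ws * (bys - loo * bxs) ** 2
    rss_sim = res_sim.sum(axis=1)

    global_pval = (1 + int(np.sum(rss_sim >= rss_obs))) / (1 + n_sim)

    p_out = (1 + np.sum(res_sim >= res_obs[None, :], axis=0)) / (1 + n_sim)
    p_out_bonf = np.minimum(1.0, p_out * m)
    flagged = p_out_bonf < sig
    snp_ids = h.snp_ids
    outliers = [(str(snp_ids[j]), float(p_out_bonf[j]))
                for j in np.flatnonzero(flagged)]
    outlier_pvals = {str(snp_ids[j]): float(p_out_bonf[j]) for j in range(m)}

    raw = ivw(h)
    if outliers:
        corrected_h = h.drop_snps([s for s, _ in outliers])
        if corrected_h.n_snp < 2:
            raise ValueError("MR-PRESSO flagged too many SNPs to re-estimate")
        corrected = ivw(corrected_h)
        d_obs = abs(raw.beta - corrected.beta)
        k = len(outliers)
        d_sim = np.empty(n_sim)
        for i in range(n_sim):
            drop = rng.choice(m, size=k, replace=False)
            keep = np.ones(m, dtype=bool)
            keep[drop] = False
            slope = np.sum(w[keep] * bx[keep] * by[keep]) / \
                np.sum(w[keep] * bx[keep] ** 2)
            d_sim[i] = abs(raw.beta - slope)
        distortion_pval = (1 + int(np.sum(d_sim >= d_obs))) / (1 + n_sim)
    else:
        corrected = raw
        distortion_pval = float("nan")

    return PressoResult(rss_obs, float(global_pval), outliers, corrected, raw,
                        float(distortion_pval), n_sim, seed, outlier_pvals)


def leave_one_out(h: HarmonizedSet, flag_multiple: float = 1.0) -> list[LeaveOneOutRow]:
    """IVW re-estimated with each SNP removed in turn.

    A SNP is flagged when its removal flips the sign of the estimate or
    moves it by more than ``flag_multiple`` full-set standard errors.
    """
    if h.n_snp < 3:
        raise ValueError("leave_one_out requires >= 3 instruments")
    full = ivw(h)
    rows = []
    for sid in h.snp_ids:
        sub = ivw(h.drop_snps([sid]))
        flag = (np.sign(sub.beta) != np.sign(full.beta)) or \
            (abs(sub.beta - full.beta) > flag_multiple * full.se)
        rows.append(LeaveOneOutRow(str(sid), sub, bool(flag)))
    return rows
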