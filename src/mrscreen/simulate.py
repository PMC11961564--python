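"""Synthetic GWAS summary statistics with known ground truth.

Two-sample MR consumes only summary-level associations, so the
generator draws them directly: true per-SNP instrument effects gamma_j
on the exposure, optional horizontal pleiotropy alpha_j on a fraction of
instruments (balanced, directional, or correlated with instrument
strength to violate the InSIDE assumption), and observed effects as
normal draws around the truth with standard errors
1/sqrt(2 * eaf * (1 - eaf) * n) implied by allele frequency and sample
size.  Directional pleiotropy is planted relative to the
exposure-raising allele, so that "directional" is invariant to the
arbitrary allele coding of each SNP.

The triad generator adds a mediator: a disjoint block of SNPs carries
mediator-specific effects kappa_j, the mediator inherits beta1 * gamma_j
from the exposure instruments, and the outcome receives
theta_direct * gamma_j + beta2 * (mediator effect) + alpha_j, so the
true total effect is theta_direct + beta1 * beta2 and the true
proportion mediated is beta1 * beta2 / total.

An AR(1) block LD matrix (r^2 = rho^(2|i-j|) within blocks, zero
across) exercises clumping; the observed effect draws themselves are
independent across SNPs, which is the one feature of real LD the
generator does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas_data import SummaryDataset
from .instruments import LDMatrix

__all__ = ["SimConfig", "simulate_pair", "simulate_triad", "simulate_family",
           "simulate_ld", "ld_for_config"]

_CHROM = "1"
_POS0 = 1_000_000
_SPACING = 100_000  # bp between consecutive simulated SNPs
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of one simulated study.

    Defaults are the package's reference study conditions: 50 strong
    instruments (gamma_sd = 0.1 on the log-odds scale), GWAS sample
    sizes of 100,000 for exposure and outcome and 14,824 for the
    mediator (an immune-protein GWAS scale), no pleiotropy, independent
    instruments.  ``theta`` is the exposure -> outcome effect in pair
    mode; in triad mode the total effect is
    ``theta_direct + beta1 * beta2``.
    """

    m_snps: int = 50
    n_exp: int = 100_000
    n_med: int = 14_824
    n_out: int = 100_000
    gamma_sd: float = 0.1
    theta: float = 0.25
    beta1: float = -0.02
    beta2: float = 0.09
    theta_direct: float = 0.0226
    pleio_frac: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.02
    inside_violation: float = 0.0
    ld_block_size: int = 1
    ld_rho: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not (0 <= self.pleio_frac <= 1):
            raise ValueError("pleio_frac must be in [0, 1]")
        if abs(self.inside_violation) > 1:
            raise ValueError("|inside_violation| must be <= 1")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if min(self.n_exp, self.n_med, self.n_out) < 10:
            raise ValueError("sample sizes must be >= 10")
        if self.m_snps < 1 or self.ld_block_size < 1:
            raise ValueError("m_snps and ld_block_size must be positive")

    @property
    def true_total(self) -> float:
        return self.theta_direct + self.beta1 * self.beta2

    @property
    def true_proportion(self) -> float:
        return self.beta1 * self.beta2 / self.true_total


def _rng(config: SimConfig, seed: int | None):
    s = seed if seed is not None else config.seed
    if s is None:
        raise ValueError("a seed is required (pass seed= or set SimConfig.seed)")
    return np.random.default_rng(s)


def _snp_frame(rng, m: int, offset: int = 0):
    ids = [f"rs{offset + i + 1}" for i in range(m)]
    pos = _POS0 + (offset + np.arange(m)) * _SPACING
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), m)]
    ea = [p[0] for p in pairs]
    oa = [p[1] for p in pairs]
    eaf = rng.uniform(0.1, 0.9, m)
    return ids, pos, ea, oa, eaf


def _dataset(name, ids, pos, ea, oa, eaf, beta, se, n, source=""):
    from scipy import stats as _st
    pval = 2 * _st.norm.sf(np.abs(beta / se))
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    df = pd.DataFrame({
        "snp_id": ids, "chrom": _CHROM, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pval": pval,
        "n": float(n),
    })
    return SummaryDataset(name, df, "EUR", source or f"simulated:{name}")


def _pleiotropy(rng, gamma: np.ndarray, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP pleiotropic effects and the invalid-instrument mask."""
    m = len(gamma)
    n_invalid = int(round(config.pleio_frac * m))
    invalid = np.zeros(m, dtype=bool)
    alpha = np.zeros(m)
    if n_invalid == 0:
        return alpha, invalid
    invalid[rng.choice(m, n_invalid, replace=False)] = True
    eps = rng.standard_normal(n_invalid)
    if config.inside_violation != 0:
        # couple pleiotropy to instrument strength via standardized |gamma|
        g = np.abs(gamma[invalid])
        zg = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
        c = config.inside_violation
        eps = c * zg + np.sqrt(1 - c**2) * eps
    alpha[invalid] = config.pleio_mean + config.pleio_sd * eps
    return alpha, invalid


def simulate_pair(config: SimConfig, seed: int | None = None):
    """One exposure/outcome pair of summary datasets plus the truth.

    Observed exposure effects are normal about gamma_j, outcome effects
    about theta * gamma_j + sign(gamma_j) * alpha_j; both datasets share
    SNP identities, allele coding and frequencies.  Returns
    ``(exposure, outcome, truth)`` with ``truth`` a dict of every latent
    quantity.
    """
    rng = _rng(config, seed)
    m = config.m_snps
    ids, pos, ea, oa, eaf = _snp_frame(rng, m)

    gamma = rng.normal(0.0, config.gamma_sd, m)
    alpha, invalid = _pleiotropy(rng, gamma, config)
    se_x = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * config.n_exp)
    se_y = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * config.n_out)

    bx = rng.normal(gamma, se_x)
    sign = np.where(gamma >= 0, 1.0, -1.0)
    mu_y = config.theta * gamma + sign * alpha
    by = rng.normal(mu_y, se_y)

    exposure = _dataset("exposure", ids, pos, ea, oa, eaf, bx, se_x, config.n_exp)
    outcome = _dataset("outcome", ids, pos, ea, oa, eaf, by, se_y, config.n_out)
    truth = {"gamma": gamma, "alpha": alpha, "invalid": invalid,
             "theta": config.theta, "eaf": eaf, "se_x": se_x, "se_y": se_y,
             "mu_y": mu_y}
    return exposure, outcome, truth


def simulate_triad(config: SimConfig, seed: int | None = None):
    """Exposure, mediator and outcome summary datasets with a planted
    mediation path.

    2 * m_snps SNPs: the first block are exposure instruments (gamma_j),
    the second mediator-specific instruments (kappa_j); each block is
    null for the other trait.  Mediator effect per SNP is
    beta1 * gamma_j + kappa_j; outcome effect is theta_direct * gamma_j
    + beta2 * (mediator effect) + pleiotropy on invalid exposure
    instruments.  Returns ``(exposure, mediator, outcome, truth)``.
    """
    rng = _rng(config, seed)
    m = config.m_snps
    ids, pos, ea, oa, eaf = _snp_frame(rng, 2 * m)

    gamma = np.concatenate([rng.normal(0.0, config.gamma_sd, m), np.zeros(m)])
    kappa = np.concatenate([np.zeros(m), rng.normal(0.0, config.gamma_sd, m)])
    alpha_exp, invalid = _pleiotropy(rng, gamma[:m], config)
    alpha = np.concatenate([alpha_exp, np.zeros(m)])
    sign = np.where(gamma >= 0, 1.0, -1.0)

    mu_med = config.beta1 * gamma + kappa
    mu_out = config.theta_direct * gamma + config.beta2 * mu_med + sign * alpha

    se_x = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * config.n_exp)
    se_m = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * config.n_med)
    se_y = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * config.n_out)

    bx = rng.normal(gamma, se_x)
    bm = rng.normal(mu_med, se_m)
    by = rng.normal(mu_out, se_y)

    exposure = _dataset("exposure", ids, pos, ea, oa, eaf, bx, se_x, config.n_exp)
    mediator = _dataset("mediator", ids, pos, ea, oa, eaf, bm, se_m, config.n_med)
    outcome = _dataset("outcome", ids, pos, ea, oa, eaf, by, se_y, config.n_out)
    truth = {"gamma": gamma, "kappa": kappa, "alpha": alpha,
             "invalid_exposure_block": invalid,
             "beta1": config.beta1, "beta2": config.beta2,
             "theta_direct": config.theta_direct,
             "true_total": config.true_total,
             "true_proportion": config.true_proportion}
    return exposure, mediator, outcome, truth


def simulate_family(config: SimConfig, thetas, seed: int | None = None):
    """One exposure screened against a family of outcomes.

    All outcomes share the exposure's SNP frame (identities, alleles,
    frequencies); outcome *k* receives causal effect ``thetas[k]`` (0
    for a null outcome) plus whatever pleiotropy the config specifies.
    Returns ``(exposure, [outcomes], truth)``.
    """
    rng = _rng(config, seed)
    m = config.m_snps
    ids, pos, ea, oa, eaf = _snp_frame(rng, m)

    gamma = rng.normal(0.0, config.gamma_sd, m)
    se_x = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * config.n_exp)
    se_y = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * config.n_out)
    bx = rng.normal(gamma, se_x)
    exposure = _dataset("exposure", ids, pos, ea, oa, eaf, bx, se_x, config.n_exp)

    sign = np.where(gamma >= 0, 1.0, -1.0)
    outcomes = []
    alphas = []
    for k, theta in enumerate(thetas):
        alpha, _ = _pleiotropy(rng, gamma, config)
        by = rng.normal(theta * gamma + sign * alpha, se_y)
        outcomes.append(_dataset(f"outcome_{k}", ids, pos, ea, oa, eaf,
                                 by, se_y, config.n_out))
        alphas.append(alpha)
    truth = {"gamma": gamma, "thetas": list(thetas), "alphas": alphas,
             "eaf": eaf, "se_x": se_x, "se_y": se_y}
    return exposure, outcomes, truth


def simulate_ld(m_snps: int, block_size: int = 1, rho: float = 0.0,
                base_pos_spacing: int = _SPACING, snp_ids=None) -> LDMatrix:
    """Block-diagonal AR(1) LD: r^2 = rho^(2|i-j|) within blocks of
    ``block_size`` consecutive SNPs, zero across blocks; positions
    ``base_pos_spacing`` bp apart on one chromosome."""
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    if block_size < 1 or m_snps < 1:
        raise ValueError("sizes must be positive")
    ids = list(snp_ids) if snp_ids is not None else \
        [f"rs{i + 1}" for i in range(m_snps)]
    if len(ids) != m_snps:
        raise ValueError("snp_ids length must equal m_snps")
    i = np.arange(m_snps)
    same_block = (i[:, None] // block_size) == (i[None, :] // block_size)
    lag = np.abs(i[:, None] - i[None, :])
    r2 = np.where(same_block, rho ** (2.0 * lag), 0.0)
    np.fill_diagonal(r2, 1.0)
    positions = {s: (_CHROM, _POS0 + j * base_pos_spacing)
                 for j, s in enumerate(ids)}
    return LDMatrix(ids, r2, positions)


def ld_for_config(config: SimConfig, n_snps: int | None = None) -> LDMatrix:
    """The LD matrix matching a config's simulated SNP grid."""
    m = n_snps if n_snps is not None else config.m_snps
    return simulate_ld(m, config.ld_block_size, config.ld_rho)
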