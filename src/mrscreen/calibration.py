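"""Monte-Carlo validation studies for the whole pipeline.

Each study simulates summary data with known ground truth, runs the
package's own estimators on it, and reports the recovered quantities
with Monte-Carlo standard errors — the package's evidence that its
estimators are calibrated under the model they assume.  All studies are
fully seeded; replicate seeds derive from the study seed through
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import numpy as np

from .estimators import egger, ivw, weighted_median
from .gwas_data import HarmonizedSet, harmonize
from .instruments import SelectionConfig, clump
from .mediation import mediate, mediation_ci_coverage
from .screen import ScreenOptions, run_forward_screen
from .sensitivity import cochran_q, mr_presso
from .simulate import SimConfig, ld_for_config, simulate_family, simulate_ld, simulate_pair

__all__ = [
    "ivw_recovery_study", "type1_error_study", "pleiotropy_robustness_study",
    "presso_outlier_study", "presso_calibration_study",
    "delta_coverage_study", "mediation_identity_study",
    "clump_oracle_study", "median_oracle_study", "ivw_oracle_study",
    "q_oracle_study", "familywise_error_study", "printed_or_decomposition",
]


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def _mean_mcse(x) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))


def ivw_recovery_study(seed: int, n_rep: int = 500,
                       config: SimConfig = SimConfig()) -> dict:
    """Mean IVW estimate over replicate studies with a true effect
    (default theta = 0.25, 50 instruments, n = 100,000)."""
    est = []
    for s in _seeds(seed, n_rep):
        e, o, _ = simulate_pair(config, seed=int(s))
        est.append(ivw(harmonize(e, o)).beta)
    mean, mcse = _mean_mcse(est)
    return {"mean": mean, "mcse": mcse, "truth": config.theta, "n_rep": n_rep}


def type1_error_study(seed: int, n_rep: int = 2000) -> dict:
    """IVW rejection rate at 0.05 under the global null (theta = 0)."""
    config = SimConfig(theta=0.0)
    rej = 0
    for s in _seeds(seed, n_rep):
        e, o, _ = simulate_pair(config, seed=int(s))
        rej += ivw(harmonize(e, o)).pval < 0.05
    return {"rate": rej / n_rep, "n_rep": n_rep}


def pleiotropy_robustness_study(seed: int, n_rep: int = 500,
                                pleio_frac: float = 0.4,
                                pleio_mean: float = 0.05) -> dict:
    """IVW, weighted median and Egger intercept under directional
    pleiotropy on a fraction of instruments (InSIDE holding).

    The planted pleiotropy acts on the exposure-raising allele, so the
    Egger intercept's estimand is pleio_frac * pleio_mean while the
    truth for the slope estimators remains theta.
    """
    config = SimConfig(pleio_frac=pleio_frac, pleio_mean=pleio_mean)
    ivw_b, wm_b, icept = [], [], []
    for s in _seeds(seed, n_rep):
        e, o, _ = simulate_pair(config, seed=int(s))
        h = harmonize(e, o)
        ivw_b.append(ivw(h).beta)
        wm_b.append(weighted_median(h, n_boot=0).beta)
        icept.append(egger(h).intercept)
    out = {"truth": config.theta,
           "intercept_truth": pleio_frac * pleio_mean, "n_rep": n_rep}
    out["ivw_mean"], out["ivw_mcse"] = _mean_mcse(ivw_b)
    out["wm_mean"], out["wm_mcse"] = _mean_mcse(wm_b)
    out["intercept_mean"], out["intercept_mcse"] = _mean_mcse(icept)
    return out


def _plant_outlier(h: HarmonizedSet, ratio_mult: float,
                   theta: float) -> tuple[HarmonizedSet, str]:
    """Give the strongest instrument an outlying Wald ratio."""
    df = h.df.copy()
    j = int(np.argmax(np.abs(df["beta_exp"])))
    df.loc[j, "beta_out"] = ratio_mult * theta * df.loc[j, "beta_exp"]
    return HarmonizedSet(h.exposure_name, h.outcome_name, df), \
        str(df.loc[j, "snp_id"])


def presso_outlier_study(seed: int, n_rep: int = 200, m_snps: int = 30,
                         n_sim: int = 1000, ratio_mult: float = 10.0) -> dict:
    """Detection rate for one planted 10x-ratio outlier among 30 SNPs,
    and how often outlier-corrected IVW lands closer to the truth."""
    config = SimConfig(m_snps=m_snps)
    seeds = _seeds(seed, 2 * n_rep)
    flagged = closer = 0
    for i in range(n_rep):
        e, o, _ = simulate_pair(config, seed=int(seeds[i]))
        h, planted = _plant_outlier(harmonize(e, o), ratio_mult, config.theta)
        res = mr_presso(h, n_sim=n_sim, seed=int(seeds[n_rep + i]))
        flagged += planted in res.outlier_ids
        closer += abs(res.corrected.beta - config.theta) < \
            abs(res.raw.beta - config.theta)
    return {"flag_rate": flagged / n_rep, "corrected_closer_rate": closer / n_rep,
            "n_rep": n_rep}


def presso_calibration_study(seed: int, n_rep: int = 500, m_snps: int = 30,
                             n_sim: int = 1000) -> dict:
    """Global-test rejection rate on homogeneous (no-outlier) data."""
    config = SimConfig(m_snps=m_snps)
    seeds = _seeds(seed, 2 * n_rep)
    rej = 0
    for i in range(n_rep):
        e, o, _ = simulate_pair(config, seed=int(seeds[i]))
        res = mr_presso(harmonize(e, o), n_sim=n_sim,
                        seed=int(seeds[n_rep + i]))
        rej += res.global_pval < 0.05
    return {"rate": rej / n_rep, "n_rep": n_rep}


def delta_coverage_study(seed: int, n_rep: int = 5000) -> dict:
    """Coverage of the 95% delta CI for beta1 * beta2
    (beta1 = 0.2, beta2 = 0.3, se = 0.02)."""
    cov = mediation_ci_coverage(0.2, 0.3, 0.02, 0.02, n_rep=n_rep, seed=seed)
    return {"coverage": cov, "n_rep": n_rep}


def mediation_identity_study(seed: int, n_rep: int = 1000) -> dict:
    """Worst-case error of the decomposition identities on random inputs."""
    rng = np.random.default_rng(seed)
    worst_sum = worst_prop = 0.0
    for _ in range(n_rep):
        b0, b1, b2 = rng.uniform(-1, 1, 3)
        s0, s1, s2 = rng.uniform(0.001, 0.5, 3)
        m = mediate((b0, s0), (b1, s1), (b2, s2))
        worst_sum = max(worst_sum, abs(m.indirect + m.direct - m.beta_total))
        if m.proportion_defined:
            worst_prop = max(worst_prop,
                             abs(m.proportion * m.beta_total - m.indirect))
    return {"max_sum_identity_error": worst_sum,
            "max_proportion_identity_error": worst_prop, "n_rep": n_rep}


# ---------------------------------------------------------------------------
# oracle-equivalence studies

def _clump_violations(kept, all_df, ld, cfg) -> int:
    window = cfg.clump_window_kb * 1000.0
    kept_rows = list(kept.itertuples(index=False))
    removed = all_df[~all_df["snp_id"].isin(set(kept["snp_id"]))]
    bad = 0
    for i, a in enumerate(kept_rows):
        for b in kept_rows[i + 1:]:
            ca, pa = ld.positions[a.snp_id]
            cb, pb = ld.positions[b.snp_id]
            if ca == cb and abs(pa - pb) <= window and \
                    ld.pair_r2(a.snp_id, b.snp_id) > cfg.clump_r2:
                bad += 1
    for r in removed.itertuples(index=False):
        cr, pr = ld.positions[r.snp_id]
        if not any(ld.positions[a.snp_id][0] == cr
                   and abs(ld.positions[a.snp_id][1] - pr) <= window
                   and ld.pair_r2(a.snp_id, r.snp_id) > cfg.clump_r2
                   and (a.pval, *ld.positions[a.snp_id]) < (r.pval, cr, pr)
                   for a in kept_rows):
            bad += 1
    return bad


def clump_oracle_study(seed: int, n_instances: int = 500,
                       max_snps: int = 15) -> dict:
    """Exhaustive pairwise verification of clumping on random small
    instances: every retained pair unlinked-or-distant, every removal
    explained by a better retained SNP."""
    import pandas as pd
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_instances):
        m = int(rng.integers(2, max_snps + 1))
        block = int(rng.integers(1, max(2, m)))
        ld = simulate_ld(m, block_size=block, rho=float(rng.uniform(0, 0.95)),
                         base_pos_spacing=int(rng.choice([10_000, 5_000_000])))
        df = pd.DataFrame({
            "snp_id": ld.snp_ids,
            "chrom": "1",
            "pos": [ld.positions[s][1] for s in ld.snp_ids],
            "pval": rng.uniform(1e-12, 1e-6, m),
        })
        cfg = SelectionConfig(clump_r2=float(rng.choice([0.001, 0.1, 0.5])))
        violations += _clump_violations(clump(df, ld, cfg), df, ld, cfg)
    return {"violations": violations, "n_instances": n_instances}


def median_oracle_study(seed: int, n_instances: int = 500) -> dict:
    """Weighted median vs an independent scan of the piecewise-linear
    weighted cumulative-ratio function."""
    from .estimators import _weighted_median_point
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        m = int(rng.integers(3, 15))
        r = rng.normal(0.5, 0.5, m)
        w = rng.uniform(0.01, 1, m)
        order = np.argsort(r)
        rs, ws = r[order], w[order] / w.sum()
        knots = np.cumsum(ws) - 0.5 * ws
        if knots[0] >= 0.5:
            oracle = rs[0]
        elif knots[-1] < 0.5:
            oracle = rs[-1]
        else:
            oracle = float(np.interp(0.5, knots, rs))
        worst = max(worst, abs(_weighted_median_point(r, w) - oracle))
    return {"max_abs_diff": worst, "n_instances": n_instances}


def _random_h(rng, m) -> HarmonizedSet:
    import pandas as pd
    bx = rng.normal(0.1, 0.05, m)
    by = rng.normal(0.0, 0.05, m)
    sy = rng.uniform(0.005, 0.05, m)
    df = pd.DataFrame({"snp_id": [f"rs{i}" for i in range(m)],
                       "beta_exp": bx, "se_exp": sy, "beta_out": by,
                       "se_out": sy, "eaf_exp": 0.5})
    return HarmonizedSet("x", "y", df)


def ivw_oracle_study(seed: int, n_instances: int = 1000) -> dict:
    """IVW vs a generic no-intercept weighted-least-squares fit."""
    import statsmodels.api as sm
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        m = int(rng.integers(2, 30))
        h = _random_h(rng, m)
        fit = sm.WLS(h.by, h.bx, weights=1 / h.sy**2).fit()
        worst = max(worst, abs(ivw(h).beta - float(fit.params[0])))
    return {"max_abs_diff": worst, "n_instances": n_instances}


def q_oracle_study(seed: int, n_instances: int = 100) -> dict:
    """Cochran's Q vs a generic inverse-variance meta-analysis."""
    from statsmodels.stats.meta_analysis import combine_effects
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        m = int(rng.integers(2, 20))
        h = _random_h(rng, m)
        ratios = h.by / h.bx
        var = (h.sy / np.abs(h.bx)) ** 2
        q_o = float(combine_effects(ratios, var).test_homogeneity()[0])
        worst = max(worst, abs(cochran_q(h).q - q_o))
    return {"max_abs_diff": worst, "n_instances": n_instances}


def familywise_error_study(seed: int, n_families: int = 2000,
                           n_outcomes: int = 13) -> dict:
    """Fraction of all-null outcome families yielding any
    Bonferroni-strong verdict (family size = number of outcomes)."""
    config = SimConfig(theta=0.0)
    ld = ld_for_config(config)
    opts = ScreenOptions(methods=("ivw",), n_boot=0, run_sensitivity=False)
    seeds = _seeds(seed, 2 * n_families)
    hits = 0
    for i in range(n_families):
        exp, outs, _ = simulate_family(config, [0.0] * n_outcomes,
                                       seed=int(seeds[i]))
        rows = run_forward_screen(exp, outs, ld, seed=int(seeds[n_families + i]),
                                  options=opts)
        hits += any(r.verdict == "strong" for r in rows)
    return {"rate": hits / n_families, "n_families": n_families}


def printed_or_decomposition() -> dict:
    """Mediation decomposition evaluated at published step odds ratios
    (exposure -> mediator OR 0.9804, mediator -> outcome OR 1.0954,
    total OR 1.021), reported on the log-OR scale."""
    b0, b1, b2 = np.log(1.021), np.log(0.9804), np.log(1.0954)
    m = mediate((b0, 0.009), (b1, 0.0087), (b2, 0.029))
    return {"indirect": m.indirect, "proportion": m.proportion,
            "direct": m.direct, "proportion_pct": 100 * m.proportion}


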