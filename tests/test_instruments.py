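"""Instrument selection: thresholds, clumping, F statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrscreen.instruments import (LDMatrix, SelectionConfig, build_instruments,
                                  clump, f_statistic, r2_from_summary,
                                  select_by_pvalue)
from mrscreen.simulate import SimConfig, simulate_ld, simulate_pair

from conftest import make_dataset


# ---------------------------------------------------------------------------
# p-value thresholding

def test_primary_threshold_applies():
    ds = make_dataset(snp_id=["rs1", "rs2"], pval=[4e-8, 1e-3])
    recs, used = select_by_pvalue(ds, SelectionConfig())
    assert len(recs) == 1 and used == 5e-8


def test_fallback_threshold_engages_below_min_count():
    ds = make_dataset(snp_id=["rs1", "rs2", "rs3"], pval=[1e-7, 2e-7, 9e-7])
    recs, used = select_by_pvalue(ds, SelectionConfig())
    assert len(recs) == 3 and used == 5e-6


def test_no_instruments_at_either_threshold_fatal():
    ds = make_dataset(snp_id=["rs1"], pval=[1e-3])
    with pytest.raises(ValueError, match="either threshold"):
        select_by_pvalue(ds, SelectionConfig())


def test_selection_config_validation():
    with pytest.raises(ValueError):
        SelectionConfig(p_primary=1e-5, p_fallback=1e-8)
    with pytest.raises(ValueError):
        SelectionConfig(clump_r2=1.5)


# ---------------------------------------------------------------------------
# clumping

def _clump_oracle_violations(kept_df, all_df, ld, config):
    """Exhaustive verification of a clumping output.

    Every retained pair must be unlinked (r^2 <= threshold) or distant;
    every removed SNP must be explained by a retained SNP with better
    (pval, chrom, pos) priority that is linked and within the window.
    """
    window = config.clump_window_kb * 1000.0
    kept = list(kept_df.itertuples(index=False))
    removed = all_df[~all_df["snp_id"].isin(set(kept_df["snp_id"]))]
    bad = []
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            ca, pa = ld.positions[a.snp_id]
            cb, pb = ld.positions[b.snp_id]
            if ca == cb and abs(pa - pb) <= window and \
                    ld.pair_r2(a.snp_id, b.snp_id) > config.clump_r2:
                bad.append(("linked pair retained", a.snp_id, b.snp_id))
    for r in removed.itertuples(index=False):
        cr, pr = ld.positions[r.snp_id]
        explained = False
        for a in kept:
            ca, pa = ld.positions[a.snp_id]
            if ca == cr and abs(pa - pr) <= window and \
                    ld.pair_r2(a.snp_id, r.snp_id) > config.clump_r2 and \
                    (a.pval, ca, pa) < (r.pval, cr, pr):
                explained = True
                break
        if not explained:
            bad.append(("unexplained removal", r.snp_id))
    return bad


def _random_instance(rng, m):
    block = int(rng.integers(1, max(2, m // 2)))
    rho = float(rng.uniform(0, 0.95))
    ld = simulate_ld(m, block_size=block, rho=rho, base_pos_spacing=5_000_000)
    ds = make_dataset(snp_id=ld.snp_ids,
                      pos=[ld.positions[s][1] for s in ld.snp_ids],
                      pval=list(rng.uniform(1e-12, 1e-6, m)))
    cfg = SelectionConfig(clump_r2=float(rng.choice([0.001, 0.1, 0.5])),
                          clump_window_kb=float(rng.choice([10_000, 20_000])))
    return ds, ld, cfg


def test_unlinked_snps_both_retained():
    ld = simulate_ld(2, rho=0.0)
    ds = make_dataset(snp_id=["rs1", "rs2"], pos=[1_000_000, 1_100_000],
                      pval=[1e-10, 1e-9])
    out = clump(ds.df, ld, SelectionConfig())
    assert len(out) == 2


def test_greedy_dominance_removes_weaker_linked_snp():
    ld = simulate_ld(2, block_size=2, rho=np.sqrt(0.5), base_pos_spacing=10_000)
    ds = make_dataset(snp_id=["rs1", "rs2"], pos=[1_000_000, 1_010_000],
                      pval=[1e-10, 1e-9])
    out = clump(ds.df, ld, SelectionConfig())
    assert out["snp_id"].tolist() == ["rs1"]


def test_clump_matches_exhaustive_oracle_on_small_instances():
    rng = np.random.default_rng(11)
    for _ in range(100):
        m = int(rng.integers(2, 16))
        ds, ld, cfg = _random_instance(rng, m)
        out = clump(ds.df, ld, cfg)
        assert _clump_oracle_violations(out, ds.df, ld, cfg) == []


def test_clump_order_invariant_and_idempotent():
    rng = np.random.default_rng(4)
    ds, ld, cfg = _random_instance(rng, 12)
    out = clump(ds.df, ld, cfg)
    shuffled = ds.df.sample(frac=1.0, random_state=0).reset_index(drop=True)
    out2 = clump(shuffled, ld, cfg)
    assert out["snp_id"].tolist() == out2["snp_id"].tolist()
    again = clump(out, ld, cfg)
    assert again["snp_id"].tolist() == out["snp_id"].tolist()


def test_clump_missing_snp_names_it():
    ld = simulate_ld(1)
    ds = make_dataset(snp_id=["rsX"], pval=[1e-10])
    with pytest.raises(KeyError, match="rsX"):
        clump(ds.df, ld, SelectionConfig())


# ---------------------------------------------------------------------------
# instrument strength

def test_f_statistic_formula():
    assert f_statistic(1000, 1, 0.01) == pytest.approx(998 * 0.01 / 0.99)
    assert f_statistic(1000, 1, 0.0) == 0.0
    assert f_statistic(1002, 1, 0.5) == pytest.approx(1000.0)


def test_f_statistic_domain_errors():
    with pytest.raises(ValueError):
        f_statistic(1000, 1, 1.0)
    with pytest.raises(ValueError):
        f_statistic(2, 1, 0.1)


def test_r2_from_summary():
    assert r2_from_summary(0.0, 0.01, 1000) == 0.0
    expect = 0.01 / (0.01 + 9998 * 0.0001)
    assert r2_from_summary(0.1, 0.01, 10_000) == pytest.approx(expect)
    with pytest.raises(ValueError):
        r2_from_summary(0.1, 0.01, 2)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0.01, 0.5), st.floats(0.001, 0.02),
       st.integers(1000, 500_000))
def test_f_from_r2_approximates_z_squared(beta, se, n):
    """F with k=1 from the t-based r^2 tracks (beta/se)^2 for large n."""
    f = f_statistic(n, 1, r2_from_summary(beta, se, n))
    z2 = (beta / se) ** 2
    assert f == pytest.approx(z2, rel=0.01)


# ---------------------------------------------------------------------------
# full pipeline

def test_build_instruments_keeps_strong_independent_snps():
    exp, _, _ = simulate_pair(SimConfig(m_snps=50), seed=9)
    strong = exp.df[exp.df["pval"] < 5e-8]
    ld = simulate_ld(50)
    inst = build_instruments(exp, ld, SelectionConfig())
    assert inst.n_snps == len(strong)
    assert all(f >= 10 for f in inst.per_snp_f.values())
    counts = inst.stage_counts
    assert counts["input"] >= counts["p_threshold"] >= counts["clumped"] \
        >= counts["f_filter"]


def test_build_instruments_drops_weak_f():
    exp, _, _ = simulate_pair(SimConfig(m_snps=30), seed=9)
    df = exp.df.copy()
    sel = df["pval"] < 5e-8
    weak_ids = df.loc[sel, "snp_id"].iloc[:3].tolist()
    # inflate se so F < 10 while keeping the recorded pval significant
    df.loc[df["snp_id"].isin(weak_ids), "se"] = \
        np.abs(df.loc[df["snp_id"].isin(weak_ids), "beta"]) / 2.0
    from mrscreen.gwas_data import SummaryDataset
    inst = build_instruments(SummaryDataset("e", df), simulate_ld(30),
                             SelectionConfig())
    assert set(inst.weak_snps) == set(weak_ids)
    assert not set(weak_ids) & set(inst.df["snp_id"])
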