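"""Forward/reverse/mediator screens, Bonferroni tiers, replication."""

import numpy as np
import pytest

from mrscreen.screen import (ScreenOptions, bonferroni, replicate,
                             run_forward_screen, run_mediator_screen,
                             run_reverse_screen)
from mrscreen.simulate import (SimConfig, ld_for_config, simulate_family,
                               simulate_ld, simulate_pair, simulate_triad)

FAST = ScreenOptions(n_boot=0, run_sensitivity=False)


def test_bonferroni_arithmetic():
    np.testing.assert_allclose(bonferroni([0.015], 13), [0.195])
    np.testing.assert_allclose(bonferroni([1.0], 7), [1.0])
    np.testing.assert_allclose(bonferroni([0.001], 13), [0.013])
    with pytest.raises(ValueError):
        bonferroni([0.5], 0)


def test_forward_screen_verdict_tiers_and_ranking():
    cfg = SimConfig(m_snps=50)
    exp, outs, _ = simulate_family(cfg, [0.0] * 6 + [0.25] + [0.0] * 6,
                                   seed=17)
    rows = run_forward_screen(exp, outs, ld_for_config(cfg), seed=3,
                              options=FAST)
    assert len(rows) == 13
    assert all(r.family_size == 13 for r in rows)
    best = min(rows, key=lambda r: r.pval_raw)
    assert best.outcome == "outcome_6"
    assert best.verdict == "strong"
    for r in rows:
        assert r.pval_bonferroni == pytest.approx(min(1.0, r.pval_raw * 13))
        expect = "strong" if r.pval_bonferroni < 0.05 else \
            ("potential" if r.pval_raw < 0.05 else "null")
        assert r.verdict == expect


def test_screen_invariant_to_outcome_order():
    cfg = SimConfig(m_snps=30)
    exp, outs, _ = simulate_family(cfg, [0.0, 0.25, 0.1], seed=23)
    ld = ld_for_config(cfg)
    rows = run_forward_screen(exp, outs, ld, seed=5, options=FAST)
    rows_rev = run_forward_screen(exp, outs[::-1], ld, seed=5, options=FAST)
    a = {r.outcome: r.primary_result.beta for r in rows}
    b = {r.outcome: r.primary_result.beta for r in rows_rev}
    assert a == b


def test_empty_outcome_list_returns_empty():
    cfg = SimConfig(m_snps=10)
    exp, _, _ = simulate_pair(cfg, seed=2)
    assert run_forward_screen(exp, [], ld_for_config(cfg), seed=1) == []


def test_outcome_failure_is_nonfatal():
    cfg = SimConfig(m_snps=20)
    exp, outs, _ = simulate_family(cfg, [0.25, 0.0], seed=31)
    # an outcome sharing no SNPs with the exposure cannot be harmonized
    broken = outs[1]
    broken.df["snp_id"] = [f"zz{i}" for i in range(len(broken.df))]
    rows = run_forward_screen(exp, outs, ld_for_config(cfg), seed=4,
                              options=FAST)
    status = {r.outcome: r.status for r in rows}
    assert status["outcome_0"] == "ok"
    assert status["outcome_1"] == "failed"
    assert "no usable instruments" in \
        next(r for r in rows if r.status == "failed").message


def test_full_screen_runs_sensitivity_suite():
    cfg = SimConfig(m_snps=20)
    exp, outs, _ = simulate_family(cfg, [0.25], seed=41)
    rows = run_forward_screen(exp, outs, ld_for_config(cfg), seed=6,
                              options=ScreenOptions(n_boot=50, presso_n_sim=200))
    s = rows[0].sensitivity
    assert s is not None and s.q is not None
    assert s.egger_intercept is not None
    assert s.presso is not None
    assert len(rows[0].secondary_results) == 3


def test_reverse_screen_uses_outcome_instruments():
    cfg = SimConfig(m_snps=30, theta=0.25)
    exp, out, _ = simulate_pair(cfg, seed=51)
    ld = ld_for_config(cfg)
    rows = run_reverse_screen([out], exp, ld, seed=7, options=FAST)
    assert rows[0].exposure == "outcome" and rows[0].outcome == "exposure"
    fwd = run_forward_screen(exp, [out], ld, seed=7, options=FAST)
    # role swap changes which trait supplies the instruments
    assert rows[0].n_instruments != fwd[0].n_instruments or \
        rows[0].threshold_used != fwd[0].threshold_used or \
        rows[0].primary_result.beta != fwd[0].primary_result.beta


def test_directionality_forward_detects_reverse_null():
    """X -> Y but not Y -> X: Y has its own genetic architecture and
    X's per-SNP effects on Y stay below genome-wide significance, so
    the forward screen detects the effect while the reverse screen,
    instrumenting Y's own signal, stays null."""
    detected_fwd = detected_rev = 0
    n_rep = 40
    # the triad's mediator is a trait with its own instruments that the
    # exposure affects (here with effect 0.05); use it as Y
    cfg = SimConfig(m_snps=40, beta1=0.05, beta2=0.0, n_med=200_000)
    ld = ld_for_config(cfg, 2 * cfg.m_snps)
    for i in range(n_rep):
        exp, y, _, _ = simulate_triad(cfg, seed=6000 + i)
        fwd = run_forward_screen(exp, [y], ld, seed=i, options=FAST)
        detected_fwd += fwd[0].pval_raw < 0.05
        rev = run_reverse_screen([y], exp, ld, seed=i, options=FAST)
        if rev[0].status == "ok":
            detected_rev += rev[0].pval_raw < 0.05
    assert detected_fwd >= 0.9 * n_rep
    assert detected_rev <= 0.2 * n_rep


# ---------------------------------------------------------------------------
# mediator screen

def test_mediator_screen_recovers_planted_path():
    """A strongly-instrumented mediator panel with one true path
    (beta1 = -0.02, beta2 = 0.09) survives both steps most of the time."""
    hits = 0
    n_rep = 25
    cfg = SimConfig(m_snps=50, n_med=250_000, beta1=-0.02, beta2=0.09,
                    theta_direct=0.0226)
    for i in range(n_rep):
        exp, med, out, _ = simulate_triad(cfg, seed=7000 + i)
        ld = ld_for_config(cfg, 2 * cfg.m_snps)
        res = run_mediator_screen(exp, [med], out, ld, seed=i, options=FAST)
        if res.mediations:
            hits += 1
            name, m = res.mediations[0]
            assert name == "mediator"
            # decomposition identity propagates to estimates
            assert m.indirect + m.direct == pytest.approx(m.beta_total)
    assert hits >= 0.8 * n_rep


def test_mediator_screen_empty_panel():
    cfg = SimConfig(m_snps=20)
    exp, out, _ = simulate_pair(cfg, seed=61)
    res = run_mediator_screen(exp, [], out, ld_for_config(cfg), seed=1,
                              options=FAST)
    assert res.step_a == [] and res.mediations == []
    assert res.total.status == "ok"


def test_mediator_without_instruments_logged_not_fatal():
    cfg = SimConfig(m_snps=20)
    exp, med, out, _ = simulate_triad(cfg, seed=71)
    null_med = med.subset(med.df["snp_id"])  # copy
    null_med.df["pval"] = 0.5  # nothing passes even the mediator threshold
    null_med.trait_name = "null_mediator"
    res = run_mediator_screen(exp, [null_med], out,
                              ld_for_config(cfg, 40), seed=2, options=FAST)
    assert res.step_a[0].status == "failed"
    assert res.survivors_a == []


# ---------------------------------------------------------------------------
# replication

def test_replication_confirms_same_truth_and_rejects_discordant():
    cfg = SimConfig(m_snps=40, theta=0.25)
    ld = ld_for_config(cfg)
    # two outcome cohorts drawn from the same truth and SNP frame
    exp, outs, _ = simulate_family(cfg, [0.25, 0.25], seed=81)
    out, rep_out = outs
    rows = run_forward_screen(exp, [out], ld, seed=8, family_m=1,
                              options=FAST)
    assert rows[0].verdict in ("strong", "potential")

    _, verdict = replicate(rows[0], exp, rep_out, ld, seed=9, options=FAST)
    assert verdict == "replicated"

    # sign-discordant significant replication is rejected
    flipped = rep_out.subset(rep_out.df["snp_id"])
    flipped.df["beta"] = -flipped.df["beta"]
    _, verdict = replicate(rows[0], exp, flipped, ld, seed=9, options=FAST)
    assert verdict == "not replicated"


def test_replication_requires_significant_primary():
    cfg = SimConfig(m_snps=20, theta=0.0)
    ld = ld_for_config(cfg)
    exp, outs, _ = simulate_family(cfg, [0.0], seed=91)
    rows = run_forward_screen(exp, outs, ld, seed=10, options=FAST)
    if rows[0].verdict == "null":
        with pytest.raises(ValueError, match="primary verdict"):
            replicate(rows[0], exp, outs[0], ld, seed=11)
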