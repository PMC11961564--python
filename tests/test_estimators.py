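"""MR estimators: examples, oracles and invariances."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mrscreen.estimators import (_weighted_median_point, _weighted_mode_point,
                                 egger, ivw, run_all_methods, wald_ratio,
                                 weighted_median, weighted_mode)
from mrscreen.simulate import SimConfig, simulate_pair
from mrscreen.gwas_data import harmonize

from conftest import make_harmonized


# ---------------------------------------------------------------------------
# Wald ratio

def test_wald_ratio_direct():
    r = wald_ratio(0.2, 0.01, 0.1, 0.02)
    assert r.beta == pytest.approx(0.5)
    assert r.se == pytest.approx(0.1)
    assert r.or_ == pytest.approx(np.exp(0.5))


def test_wald_ratio_null_outcome():
    r = wald_ratio(0.2, 0.01, 0.0, 0.02)
    assert r.beta == 0.0
    assert r.pval == pytest.approx(1.0)


def test_wald_ratio_sign_invariance_and_null_instrument():
    a = wald_ratio(0.2, 0.01, 0.1, 0.02)
    b = wald_ratio(-0.2, 0.01, -0.1, 0.02)
    assert a.beta == pytest.approx(b.beta)
    with pytest.raises(ValueError, match="null instrument"):
        wald_ratio(0.0, 0.01, 0.1, 0.02)


# ---------------------------------------------------------------------------
# IVW

def test_ivw_consensus_is_exact():
    h = make_harmonized([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.01, 0.01, 0.01])
    r = ivw(h)
    assert r.beta == pytest.approx(0.5, abs=1e-14)
    # residuals are zero, under-dispersion floored: fixed-effect SE
    assert r.se == pytest.approx(np.sqrt(1 / 1400), abs=1e-12)


def test_ivw_matches_wls_oracle():
    rng = np.random.default_rng(2)
    for _ in range(200):
        m = int(rng.integers(2, 30))
        h = make_harmonized(rng.normal(0.1, 0.05, m), rng.normal(0, 0.05, m),
                            rng.uniform(0.005, 0.05, m))
        fit = sm.WLS(h.by, h.bx, weights=1 / h.sy**2).fit()
        assert abs(ivw(h).beta - fit.params[0]) < 1e-10


def test_ivw_requires_two_snps():
    h = make_harmonized([0.1], [0.05], [0.01])
    with pytest.raises(ValueError, match="wald_ratio"):
        ivw(h)


def test_ivw_random_effects_se_never_below_fixed():
    rng = np.random.default_rng(3)
    h = make_harmonized(rng.normal(0.1, 0.05, 20),
                        rng.normal(0, 0.2, 20), 0.01)
    assert ivw(h, random_effects=True).se >= \
        ivw(h, random_effects=False).se - 1e-15


# ---------------------------------------------------------------------------
# MR-Egger

def test_egger_exact_on_noiseless_line():
    bx = np.array([0.05, 0.1, 0.2, 0.3])
    by = 0.02 + 0.4 * bx
    r = egger(make_harmonized(bx, by, 0.01))
    assert r.beta == pytest.approx(0.4, abs=1e-12)
    assert r.intercept == pytest.approx(0.02, abs=1e-12)


def test_egger_matches_wls_oracle_with_orientation():
    rng = np.random.default_rng(5)
    for _ in range(100):
        m = int(rng.integers(3, 25))
        h = make_harmonized(rng.normal(0, 0.1, m), rng.normal(0, 0.05, m),
                            rng.uniform(0.005, 0.05, m))
        flip = np.where(h.bx >= 0, 1.0, -1.0)
        fit = sm.WLS(flip * h.by, sm.add_constant(flip * h.bx),
                     weights=1 / h.sy**2).fit()
        r = egger(h)
        assert abs(r.beta - fit.params[1]) < 1e-10
        assert abs(r.intercept - fit.params[0]) < 1e-10


def test_egger_equals_ivw_for_zero_intercept_homogeneous_data():
    bx = np.array([0.1, 0.2, 0.3, 0.4])
    by = 0.5 * bx
    h = make_harmonized(bx, by, [0.01, 0.02, 0.01, 0.03])
    assert egger(h).beta == pytest.approx(ivw(h).beta, abs=1e-10)


def test_egger_needs_three():
    with pytest.raises(ValueError, match=">= 3"):
        egger(make_harmonized([0.1, 0.2], [0.05, 0.1], 0.01))


# ---------------------------------------------------------------------------
# weighted median

def test_weighted_median_symmetric():
    h = make_harmonized([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], 1.0)
    assert weighted_median(h, n_boot=0).beta == pytest.approx(2.0)


def test_weighted_median_dominant_weight():
    # one SNP carries 90% of the inverse-variance weight at ratio 0.7
    bx = np.array([3.0, 1.0, 1.0])
    w_target = np.array([0.9, 0.05, 0.05])
    sy = bx / np.sqrt(w_target * 180)
    by = np.array([0.7, 0.2, 1.5]) * bx
    h = make_harmonized(bx, by, sy)
    assert weighted_median(h, n_boot=0).beta == pytest.approx(0.7)


def _brute_force_median(ratios, weights):
    """Scan the piecewise-linear weighted cumulative distribution."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    w = w / w.sum()
    knots = np.cumsum(w) - 0.5 * w
    if knots[0] >= 0.5:
        return r[0]
    if knots[-1] < 0.5:
        return r[-1]
    return float(np.interp(0.5, knots, r))


def test_weighted_median_matches_brute_force():
    rng = np.random.default_rng(8)
    for _ in range(300):
        m = int(rng.integers(3, 12))
        r = rng.normal(0.5, 0.5, m)
        w = rng.uniform(0.01, 1, m)
        assert abs(_weighted_median_point(r, w) - _brute_force_median(r, w)) \
            < 1e-12


def test_weighted_median_bootstrap_se_reproducible(toy_harmonized):
    a = weighted_median(toy_harmonized, n_boot=200, seed=42)
    b = weighted_median(toy_harmonized, n_boot=200, seed=42)
    assert a.se == b.se and a.se > 0


# ---------------------------------------------------------------------------
# weighted mode

def test_weighted_mode_point_mass():
    bx = np.array([1.0, 2.0, 0.5])
    h = make_harmonized(bx, 0.4 * bx, 0.01)
    r = weighted_mode(h, n_boot=0)
    assert r.beta == pytest.approx(0.4)
    assert r.se == 0.0


def test_weighted_mode_finds_majority_cluster():
    rng = np.random.default_rng(1)
    ratios = np.concatenate([0.5 + 0.01 * rng.standard_normal(7),
                             [5.0, 5.1, 4.9]])
    h = make_harmonized(np.ones(10), ratios, 1.0)
    assert abs(weighted_mode(h, n_boot=0).beta - 0.5) < 0.05


def test_weighted_mode_grid_refinement():
    rng = np.random.default_rng(2)
    ratios = rng.normal(0.3, 0.1, 15)
    w = rng.uniform(0.1, 1, 15)
    w = w / w.sum()
    a = _weighted_mode_point(ratios, w, 1.0, n_grid=2001)
    b = _weighted_mode_point(ratios, w, 1.0, n_grid=4001)
    from mrscreen.estimators import _silverman
    hband = _silverman(ratios, 1.0)
    step = (np.ptp(ratios) + 6 * hband) / 2000
    assert abs(a - b) < step / 2 + 1e-12


# ---------------------------------------------------------------------------
# dispatch and invariances

def test_run_all_methods_dispatch():
    h1 = make_harmonized([0.2], [0.1], 0.01)
    res = run_all_methods(h1)
    assert [r.method for r in res.results] == ["wald_ratio"]

    h2 = make_harmonized([0.2, 0.3], [0.1, 0.15], 0.01)
    res = run_all_methods(h2)
    assert [r.method for r in res.results] == ["ivw"]
    assert len(res.wald_ratios) == 2

    exp, out, _ = simulate_pair(SimConfig(m_snps=5), seed=21)
    res = run_all_methods(harmonize(exp, out), seed=0, n_boot=50)
    assert sorted(r.method for r in res.results) == \
        ["egger", "ivw", "weighted_median", "weighted_mode"]
    assert res.direction_consistent


def test_direction_consistency_flag_false_on_constructed_case():
    # strong positive slope among strong SNPs, negative offset pattern
    # that flips the egger fit's sign
    bx = np.array([0.10, 0.12, 0.30, 0.32, 0.34])
    by = np.array([0.09, 0.094, 0.01, 0.012, 0.014])
    h = make_harmonized(bx, by, 0.005)
    res = run_all_methods(h, seed=1, n_boot=0)
    assert not res.direction_consistent


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(0.2, 5.0), st.integers(0, 10_000))
def test_scale_equivariance(c, seed):
    """Rescaling the outcome by c rescales every estimate and SE by c."""
    rng = np.random.default_rng(seed)
    m = 8
    bx = rng.normal(0.1, 0.05, m)
    by = rng.normal(0.05, 0.03, m)
    sy = rng.uniform(0.005, 0.02, m)
    h = make_harmonized(bx, by, sy)
    hc = make_harmonized(bx, c * by, c * sy)
    for f in (ivw, egger):
        a, b = f(h), f(hc)
        assert b.beta == pytest.approx(c * a.beta, rel=1e-9)
        assert b.se == pytest.approx(c * a.se, rel=1e-9)
    assert weighted_median(hc, n_boot=0).beta == \
        pytest.approx(c * weighted_median(h, n_boot=0).beta, rel=1e-9)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_orientation_invariance(seed):
    """Jointly flipping (beta_exp, beta_out) signs of any rows leaves
    IVW, Egger, weighted median and weighted mode unchanged."""
    rng = np.random.default_rng(seed)
    m = 9
    bx = rng.normal(0.1, 0.05, m)
    by = rng.normal(0.05, 0.03, m)
    sy = rng.uniform(0.005, 0.02, m)
    flip = rng.choice([-1.0, 1.0], m)
    h = make_harmonized(bx, by, sy)
    hf = make_harmonized(flip * bx, flip * by, sy)
    assert ivw(hf).beta == pytest.approx(ivw(h).beta, rel=1e-9)
    assert egger(hf).beta == pytest.approx(egger(h).beta, rel=1e-9)
    assert weighted_median(hf, n_boot=0).beta == \
        pytest.approx(weighted_median(h, n_boot=0).beta, rel=1e-9)
    assert weighted_mode(hf, n_boot=0).beta == \
        pytest.approx(weighted_mode(h, n_boot=0).beta, rel=1e-9)


def test_ci_contains_estimate_and_or_is_exp(toy_harmonized):
    for r in run_all_methods(toy_harmonized, seed=3, n_boot=50).results:
        assert r.ci_low <= r.beta <= r.ci_high
        assert r.or_ == pytest.approx(np.exp(r.beta))
        assert 0 < r.pval <= 1
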