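"""Summary-data MR estimators: Wald ratio, IVW, MR-Egger, weighted
median, weighted mode.

All estimators consume a :class:`~mrscreen.gwas_data.HarmonizedSet`
(per-SNP exposure and outcome effects on a shared effect allele) and
return an :class:`MRResult` carrying the causal estimate on the log-odds
scale together with its standard error, 95% CI, p-value and the
exponentiated odds-ratio counterparts.

The inverse-variance-weighted (IVW) estimator is the primary method: a
weighted regression of outcome on exposure effects through the origin,
weights 1/se_out^2, with a multiplicative random-effects standard error
whose residual scale is floored at 1 (under-dispersion never shrinks the
SE below the fixed-effect value).  MR-Egger adds an intercept that
absorbs average directional pleiotropy; the weighted median is
consistent when at least half the weight comes from valid instruments;
the weighted mode assumes only that the largest cluster of Wald ratios
is valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gwas_data import HarmonizedSet

__all__ = [
    "MRResult",
    "MethodResults",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "run_all_methods",
]

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MRResult:
    """One estimator's causal estimate for an exposure/outcome pair."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_: float
    or_ci_low: float
    or_ci_high: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snp: int,
                     t_df: int | None = None, **kw) -> "MRResult":
        """Build a result from a point estimate and its SE.

        Normal-approximation CI and p by default; a t reference
        distribution with ``t_df`` degrees of freedom when given.
        """
        beta = float(beta)
        se = float(se)
        if se > 0 and np.isfinite(se):
            if t_df is not None:
                q = float(stats.t.ppf(0.975, t_df))
                pval = float(2 * stats.t.sf(abs(beta / se), t_df))
            else:
                q = Z95
                pval = float(2 * stats.norm.sf(abs(beta / se)))
            lo, hi = beta - q * se, beta + q * se
        else:
            lo = hi = beta
            pval = 1.0 if beta == 0 else float("nan")
        pval = min(max(pval, np.nextafter(0, 1)), 1.0) if np.isfinite(pval) else pval
        return cls(method, beta, se, lo, hi, pval,
                   float(np.exp(beta)), float(np.exp(lo)), float(np.exp(hi)),
                   n_snp, **kw)


@dataclass
class MethodResults:
    """Results of every applicable estimator for one pair."""

    results: list[MRResult]
    direction_consistent: bool
    wald_ratios: list[MRResult] = field(default_factory=list)

    def __iter__(self):
        return iter(self.results)

    def get(self, method: str) -> MRResult:
        for r in self.results:
            if r.method == method:
                return r
        raise KeyError(method)

    @property
    def primary(self) -> MRResult:
        """The headline estimate: IVW when available, else the Wald ratio."""
        for name in ("ivw", "wald_ratio"):
            try:
                return self.get(name)
            except KeyError:
                continue
        return self.results[0]


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               second_order: bool = False) -> MRResult:
    """Single-SNP causal estimate beta_out / beta_exp.

    First-order SE se_out/|beta_exp| by default; the second-order option
    adds the exposure-noise term.
    """
    if beta_exp == 0:
        raise ValueError("null instrument: beta_exp = 0")
    b = beta_out / beta_exp
    if second_order:
        se = np.sqrt(se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4)
    else:
        se = se_out / abs(beta_exp)
    return MRResult.from_beta_se("wald_ratio", b, se, 1)


def _ivw_point(bx, by, w):
    swx2 = np.sum(w * bx * bx)
    return np.sum(w * bx * by) / swx2, swx2


def ivw(h: HarmonizedSet, random_effects: bool = True) -> MRResult:
    """Inverse-variance-weighted estimate.

    Weighted no-intercept regression of beta_out on beta_exp with
    weights 1/se_out^2; with ``random_effects`` the SE is multiplied by
    max(1, residual scale), i.e. multiplicative random effects with
    under-dispersion floored at 1.
    """
    if h.n_snp < 2:
        raise ValueError("IVW requires >= 2 instruments; use wald_ratio")
    bx, by, sy = h.bx, h.by, h.sy
    w = 1.0 / sy**2
    beta, swx2 = _ivw_point(bx, by, w)
    se = np.sqrt(1.0 / swx2)
    if random_effects:
        sigma2 = np.sum(w * (by - beta * bx) ** 2) / (h.n_snp - 1)
        se *= max(1.0, np.sqrt(sigma2))
    return MRResult.from_beta_se("ivw", beta, se, h.n_snp)


def egger(h: HarmonizedSet) -> MRResult:
    """MR-Egger regression: weighted fit of beta_out on beta_exp with an
    intercept, rows oriented so beta_exp >= 0.

    The slope is the pleiotropy-adjusted causal estimate; the intercept
    estimates average directional pleiotropy.  SEs carry the same
    max(1, residual scale) multiplier as IVW; p-values use a t
    distribution with n_snp - 2 degrees of freedom.
    """
    if h.n_snp < 3:
        raise ValueError("egger requires >= 3 instruments")
    flip = np.sign(h.bx)
    flip[flip == 0] = 1.0
    bx, by, sy = flip * h.bx, flip * h.by, h.sy
    w = 1.0 / sy**2

    sw = np.sum(w)
    mx = np.sum(w * bx) / sw
    my = np.sum(w * by) / sw
    sxx = np.sum(w * (bx - mx) ** 2)
    sxy = np.sum(w * (bx - mx) * (by - my))
    if sxx == 0:
        raise ValueError("egger undefined: no spread in instrument strengths")
    slope = sxy / sxx
    intercept = my - slope * mx

    df = h.n_snp - 2
    resid = by - intercept - slope * bx
    sigma2 = np.sum(w * resid**2) / df
    scale = max(1.0, sigma2)
    se_slope = np.sqrt(scale / sxx)
    se_int = np.sqrt(scale * (1.0 / sw + mx**2 / sxx))
    int_p = float(2 * stats.t.sf(abs(intercept / se_int), df)) if se_int > 0 else 1.0

    return MRResult.from_beta_se(
        "egger", slope, se_slope, h.n_snp, t_df=df,
        intercept=float(intercept), intercept_se=float(se_int),
        intercept_pval=min(int_p, 1.0))


def _ratios_weights(bx, by, sy):
    r = by / bx
    w = bx**2 / sy**2
    return r, w / np.sum(w)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with the midpoint-interpolation convention."""
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    p = np.cumsum(w) - 0.5 * w
    if p[0] >= 0.5:
        return float(r[0])
    if p[-1] < 0.5:
        return float(r[-1])
    j = int(np.searchsorted(p, 0.5))
    return float(r[j - 1] + (r[j] - r[j - 1]) * (0.5 - p[j - 1]) / (p[j] - p[j - 1]))


def _median_boot(h: HarmonizedSet, n_boot: int, rng) -> float:
    bx = rng.normal(h.bx, h.sx, size=(n_boot, h.n_snp))
    by = rng.normal(h.by, h.sy, size=(n_boot, h.n_snp))
    r = by / bx
    w = bx**2 / h.sy**2
    w = w / w.sum(axis=1, keepdims=True)
    order = np.argsort(r, axis=1, kind="mergesort")
    r = np.take_along_axis(r, order, axis=1)
    w = np.take_along_axis(w, order, axis=1)
    p = np.cumsum(w, axis=1) - 0.5 * w
    below = (p < 0.5).sum(axis=1)
    est = np.empty(n_boot)
    first = below == 0
    last = below == h.n_snp
    mid = ~(first | last)
    est[first] = r[first, 0]
    est[last] = r[last, -1]
    j = below[mid]
    i = np.arange(n_boot)[mid]
    p0, p1 = p[i, j - 1], p[i, j]
    r0, r1 = r[i, j - 1], r[i, j]
    est[mid] = r0 + (r1 - r0) * (0.5 - p0) / (p1 - p0)
    return float(np.std(est, ddof=1))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MRResult:
    """Weighted median of per-SNP Wald ratios.

    Ratio weights bx^2/se_out^2 (inverse variance of the first-order
    ratio); the estimate interpolates the weighted cumulative
    distribution at weight 0.5.  The SE comes from a parametric
    bootstrap (``n_boot`` resamples of bx, by from normals centred on
    the observed values); ``n_boot=0`` skips it and reports a NaN SE.
    """
    if h.n_snp < 3:
        raise ValueError("weighted_median requires >= 3 instruments")
    r, w = _ratios_weights(h.bx, h.by, h.sy)
    point = _weighted_median_point(r, w)
    if n_boot <= 0:
        return MRResult.from_beta_se("weighted_median", point, float("nan"), h.n_snp)
    if seed is None:
        raise ValueError("weighted_median bootstrap requires an explicit seed")
    se = _median_boot(h, n_boot, np.random.default_rng(seed))
    return MRResult.from_beta_se("weighted_median", point, se, h.n_snp)


def _silverman(r: np.ndarray, factor: float) -> float:
    m = len(r)
    sd = float(np.std(r, ddof=1))
    iqr = float(np.subtract(*np.percentile(r, [75, 25]))) / 1.34
    s = min(sd, iqr) if iqr > 0 else sd
    return factor * 0.9 * s * m ** (-0.2)


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray,
                         bandwidth_factor: float, n_grid: int = 2001) -> float:
    h = _silverman(ratios, bandwidth_factor)
    if h <= 0:
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, n_grid)
    dens = weights @ np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2)
    return float(grid[int(np.argmax(dens))])


def weighted_mode(h: HarmonizedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int | None = None) -> MRResult:
    """Weighted mode: argmax of a Gaussian kernel density over the Wald
    ratios, kernel masses equal to the inverse-variance ratio weights.

    Bandwidth follows Silverman's rule scaled by ``bandwidth_factor``;
    the density is maximised on a 2001-point grid spanning the ratio
    range plus three bandwidths.  SE by parametric bootstrap as in
    :func:`weighted_median`.  If every ratio is identical the common
    ratio is returned with zero SE.
    """
    if h.n_snp < 3:
        raise ValueError("weighted_mode requires >= 3 instruments")
    r, w = _ratios_weights(h.bx, h.by, h.sy)
    if np.ptp(r) == 0:
        return MRResult.from_beta_se("weighted_mode", r[0], 0.0, h.n_snp)
    point = _weighted_mode_point(r, w, bandwidth_factor)
    if n_boot <= 0:
        return MRResult.from_beta_se("weighted_mode", point, float("nan"), h.n_snp)
    if seed is None:
        raise ValueError("weighted_mode bootstrap requires an explicit seed")
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(h.bx, h.sx)
        by = rng.normal(h.by, h.sy)
        rb, wb = _ratios_weights(bx, by, h.sy)
        if np.ptp(rb) == 0:
            boots[b] = rb[0]
        else:
            boots[b] = _weighted_mode_point(rb, wb, bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    return MRResult.from_beta_se("weighted_mode", point, se, h.n_snp)


_ALL_METHODS = ("ivw", "egger", "weighted_median", "weighted_mode")


def run_all_methods(h: HarmonizedSet, seed: int | None = None,
                    n_boot: int = 1000,
                    bandwidth_factor: float = 1.0,
                    methods: tuple[str, ...] | None = None) -> MethodResults:
    """Run every estimator the instrument count permits.

    One SNP gives the Wald ratio alone; two give IVW (with the per-SNP
    Wald ratios reported alongside); three or more give IVW, MR-Egger,
    weighted median and weighted mode.  ``direction_consistent`` records
    whether every method's estimate shares the IVW sign — the
    concordance check used when screening many outcomes.
    """
    if h.n_snp == 0:
        raise ValueError("empty harmonized set")
    if h.n_snp <= 2:
        wald = [wald_ratio(bx, sx, by, sy)
                for bx, sx, by, sy in zip(h.bx, h.sx, h.by, h.sy)]
        if h.n_snp == 1:
            return MethodResults([wald[0]], True, wald)
        return MethodResults([ivw(h)], True, wald)

    wanted = methods or _ALL_METHODS
    results = []
    for name in wanted:
        if name == "ivw":
            results.append(ivw(h))
        elif name == "egger":
            results.append(egger(h))
        elif name == "weighted_median":
            results.append(weighted_median(h, n_boot=n_boot, seed=seed))
        elif name == "weighted_mode":
            results.append(weighted_mode(h, bandwidth_factor=bandwidth_factor,
                                         n_boot=n_boot, seed=seed))
        else:
            raise ValueError(f"unknown method {name!r}")
    ref = next((r for r in results if r.method == "ivw"), results[0])
    consistent = all(np.sign(r.beta) == np.sign(ref.beta) for r in results)
    return MethodResults(results, bool(consistent))
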