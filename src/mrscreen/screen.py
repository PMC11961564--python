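"""Study-design orchestration: forward, reverse and mediator screens.

A *screen* runs one exposure against a family of outcomes: instrument
selection, harmonization, every applicable estimator, the sensitivity
suite, and Bonferroni correction across the family.  Verdicts follow
the two-tier convention: raw p < 0.05 is *potential*, Bonferroni-
corrected p < 0.05 is *strong*.  The reverse screen swaps roles (each
outcome becomes the exposure); the mediator screen applies the two-step
design — mediator -> outcome first, exposure -> mediator second,
mediation decomposition on the survivors — and a replication run
confirms a primary finding in an independent cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .estimators import MethodResults, MRResult, ivw, run_all_methods
from .gwas_data import HarmonizedSet, SummaryDataset, harmonize
from .instruments import InstrumentSet, LDMatrix, SelectionConfig, build_instruments
from .mediation import MediationResult, mediate
from .sensitivity import PressoResult, QResult, cochran_q, egger_intercept_test, mr_presso

log = logging.getLogger("mrscreen")

__all__ = [
    "ScreenOptions",
    "SensitivitySummary",
    "ScreenRow",
    "MediatorScreenResult",
    "bonferroni",
    "run_forward_screen",
    "run_reverse_screen",
    "run_mediator_screen",
    "replicate",
]


@dataclass(frozen=True)
class ScreenOptions:
    """Estimator and sensitivity settings applied to every pair.

    ``methods=None`` means every estimator the instrument count allows;
    calibration studies may restrict to ``("ivw",)``.  ``n_boot=0``
    skips bootstrap SEs.  ``run_sensitivity=False`` skips the
    heterogeneity/pleiotropy suite (the verdicts depend only on the
    primary IVW p-value).
    """

    methods: tuple[str, ...] | None = None
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    run_sensitivity: bool = True
    presso_n_sim: int = 1000
    presso_sig: float = 0.05
    require_direction_consistent: bool = True


@dataclass
class SensitivitySummary:
    q: QResult | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    presso: PressoResult | None = None
    corrected_ivw: MRResult | None = None


@dataclass
class ScreenRow:
    """One exposure/outcome pair's full screening record."""

    exposure: str
    outcome: str
    direction: str  # "forward" | "reverse"
    status: str = "ok"  # "ok" | "failed"
    message: str = ""
    n_instruments: int = 0
    threshold_used: float | None = None
    primary_result: MRResult | None = None
    secondary_results: list[MRResult] = field(default_factory=list)
    direction_consistent: bool | None = None
    sensitivity: SensitivitySummary | None = None
    pval_raw: float | None = None
    pval_bonferroni: float | None = None
    verdict: str = "null"
    family_size: int = 1
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)


def bonferroni(pvals, m: int):
    """Bonferroni-adjusted p-values, min(1, p * m) for family size m."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    p = np.asarray(pvals, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(1.0, p * m)


def _verdict(p_raw: float, p_adj: float) -> str:
    if p_adj < 0.05:
        return "strong"
    if p_raw < 0.05:
        return "potential"
    return "null"


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _sensitivity_suite(h: HarmonizedSet, opts: ScreenOptions,
                       seed: int) -> SensitivitySummary:
    s = SensitivitySummary()
    if h.n_snp >= 2:
        s.q = cochran_q(h)
    if h.n_snp >= 3:
        s.egger_intercept, s.egger_intercept_se, s.egger_intercept_pval = \
            egger_intercept_test(h)
    if h.n_snp >= 4:
        s.presso = mr_presso(h, n_sim=opts.presso_n_sim, sig=opts.presso_sig,
                             seed=seed)
        if s.presso.outlier_snps:
            # manual re-run without the flagged SNPs, reported alongside
            # the corrected estimate MR-PRESSO itself produces
            s.corrected_ivw = ivw(h.drop_snps(s.presso.outlier_ids))
    return s


def _screen_pair(instruments: InstrumentSet, exposure: SummaryDataset,
                 outcome: SummaryDataset, direction: str,
                 opts: ScreenOptions, seed: int) -> ScreenRow:
    row = ScreenRow(exposure=exposure.trait_name, outcome=outcome.trait_name,
                    direction=direction)
    try:
        h = harmonize(instruments.dataset(exposure), outcome)
        row.exclusion_log = h.exclusion_log
        row.n_instruments = h.n_snp
        row.threshold_used = instruments.threshold_used
        res = run_all_methods(h, seed=seed, n_boot=opts.n_boot,
                              bandwidth_factor=opts.bandwidth_factor,
                              methods=opts.methods if h.n_snp >= 3 else None)
        row.primary_result = res.primary
        row.secondary_results = [r for r in res.results if r is not res.primary]
        row.direction_consistent = res.direction_consistent
        row.pval_raw = res.primary.pval
        if opts.run_sensitivity:
            row.sensitivity = _sensitivity_suite(h, opts, seed)
    except (ValueError, KeyError) as exc:
        row.status = "failed"
        row.message = str(exc)
        log.warning("screen pair %s -> %s failed: %s",
                    exposure.trait_name, outcome.trait_name, exc)
    return row


def _apply_family_correction(rows: list[ScreenRow], m: int | None):
    ok = [r for r in rows if r.status == "ok"]
    family = m if m is not None else max(1, len(rows))
    for r in rows:
        r.family_size = family
    if not ok:
        return
    adj = bonferroni([r.pval_raw for r in ok], family)
    for r, pa in zip(ok, adj):
        r.pval_bonferroni = float(pa)
        r.verdict = _verdict(r.pval_raw, pa)


def run_forward_screen(exposure: SummaryDataset, outcomes, ld: LDMatrix,
                       config: SelectionConfig = SelectionConfig(),
                       seed: int = 0, family_m: int | None = None,
                       options: ScreenOptions = ScreenOptions()) -> list[ScreenRow]:
    """Screen one exposure against a family of outcomes.

    Instruments are selected once from the exposure; each outcome is
    harmonized and analysed independently, and outcome-level failures
    are recorded rather than raised so the screen always completes.
    Bonferroni family size defaults to the number of outcomes.
    """
    outcomes = list(outcomes)
    if not outcomes:
        log.warning("forward screen called with an empty outcome list")
        return []
    instruments = build_instruments(exposure, ld, config)
    log.info("forward screen: %d instruments for %s (threshold %g, stages %s)",
             instruments.n_snps, exposure.trait_name,
             instruments.threshold_used, instruments.stage_counts)
    seeds = _child_seeds(seed, len(outcomes))
    rows = [_screen_pair(instruments, exposure, out, "forward", options, s)
            for out, s in zip(outcomes, seeds)]
    _apply_family_correction(rows, family_m)
    return rows


def run_reverse_screen(outcomes, exposure: SummaryDataset,
                       ld_by_trait, config: SelectionConfig = SelectionConfig(),
                       seed: int = 0, family_m: int | None = None,
                       options: ScreenOptions = ScreenOptions()) -> list[ScreenRow]:
    """Reverse direction: each outcome becomes the exposure in turn.

    ``ld_by_trait`` is either one LDMatrix shared by every trait or a
    mapping from trait name to LDMatrix.  Instrument selection
    (including the p-threshold fallback and F filter) runs per reverse
    exposure.
    """
    outcomes = list(outcomes)
    rows: list[ScreenRow] = []
    seeds = _child_seeds(seed, len(outcomes))
    for out_ds, s in zip(outcomes, seeds):
        ld = ld_by_trait.get(out_ds.trait_name) if isinstance(ld_by_trait, dict) \
            else ld_by_trait
        try:
            inst = build_instruments(out_ds, ld, config)
            log.info("reverse screen: %d instruments for %s",
                     inst.n_snps, out_ds.trait_name)
            rows.append(_screen_pair(inst, out_ds, exposure, "reverse",
                                     options, s))
        except (ValueError, KeyError) as exc:
            rows.append(ScreenRow(exposure=out_ds.trait_name,
                                  outcome=exposure.trait_name,
                                  direction="reverse", status="failed",
                                  message=str(exc)))
            log.warning("reverse screen %s failed: %s", out_ds.trait_name, exc)
    _apply_family_correction(rows, family_m)
    return rows


@dataclass
class MediatorScreenResult:
    """Audit trail of the two-step mediator screen."""

    total: ScreenRow
    step_a: list[ScreenRow]                 # mediator -> outcome, all mediators
    step_b: list[ScreenRow]                 # exposure -> mediator, step-A survivors
    mediations: list[tuple[str, MediationResult]]  # step-B survivors
    survivors_a: list[str] = field(default_factory=list)
    survivors_b: list[str] = field(default_factory=list)


def run_mediator_screen(exposure: SummaryDataset, mediators, outcome: SummaryDataset,
                        ld, config: SelectionConfig = SelectionConfig(),
                        seed: int = 0,
                        options: ScreenOptions = ScreenOptions()) -> MediatorScreenResult:
    """Two-step mediation screen.

    Step A: each mediator -> outcome by MR with mediator instruments
    selected at the relaxed p_mediator threshold; survivors need IVW
    p < 0.05 (and direction-consistent secondary methods unless
    disabled).  Step B: exposure -> each surviving mediator, keep IVW
    p < 0.05.  Step C: delta-method mediation decomposition of the
    exposure -> outcome total effect through each survivor.  Mediators
    without usable instruments are logged as failed rows, never fatal.
    """
    mediators = list(mediators)
    med_config = config.for_mediators()
    seeds = _child_seeds(seed, 2 * len(mediators) + 1)

    exp_inst = build_instruments(exposure, _ld_for(ld, exposure.trait_name), config)
    total_row = _screen_pair(exp_inst, exposure, outcome, "forward",
                             options, seeds[-1])
    if total_row.status != "ok":
        raise ValueError(f"total-effect estimation failed: {total_row.message}")

    step_a: list[ScreenRow] = []
    survivors_a: list[str] = []
    for med, s in zip(mediators, seeds[:len(mediators)]):
        try:
            inst = build_instruments(med, _ld_for(ld, med.trait_name), med_config)
            row = _screen_pair(inst, med, outcome, "forward", options, s)
        except (ValueError, KeyError) as exc:
            row = ScreenRow(exposure=med.trait_name, outcome=outcome.trait_name,
                            direction="forward", status="failed", message=str(exc))
        step_a.append(row)
        if row.status == "ok" and row.pval_raw < 0.05 and (
                not options.require_direction_consistent
                or row.direction_consistent):
            survivors_a.append(med.trait_name)

    step_b: list[ScreenRow] = []
    survivors_b: list[str] = []
    by_name = {m.trait_name: m for m in mediators}
    for name, s in zip(survivors_a, seeds[len(mediators):2 * len(mediators)]):
        row = _screen_pair(exp_inst, exposure, by_name[name], "forward",
                           options, s)
        step_b.append(row)
        if row.status == "ok" and row.pval_raw < 0.05:
            survivors_b.append(name)

    mediations = []
    a_by_name = {r.exposure: r for r in step_a}
    b_by_name = {r.outcome: r for r in step_b}
    for name in survivors_b:
        med = mediate(total_row.primary_result,
                      b_by_name[name].primary_result,
                      a_by_name[name].primary_result)
        mediations.append((name, med))

    _apply_family_correction(step_a, len(mediators))
    return MediatorScreenResult(total_row, step_a, step_b, mediations,
                                survivors_a, survivors_b)


def _ld_for(ld, trait_name: str) -> LDMatrix:
    return ld.get(trait_name) if isinstance(ld, dict) else ld


def replicate(primary_row: ScreenRow, exposure: SummaryDataset,
              replication_outcome: SummaryDataset, ld: LDMatrix,
              config: SelectionConfig = SelectionConfig(), seed: int = 0,
              options: ScreenOptions = ScreenOptions()):
    """Re-run a primary finding against an independent replication cohort.

    Verdict "replicated" requires p < 0.05 with the same effect sign as
    the primary analysis; only strong/potential primary findings
    qualify.
    """
    if primary_row.verdict not in ("strong", "potential"):
        raise ValueError("replication requires a strong or potential primary verdict")
    inst = build_instruments(exposure, ld, config)
    row = _screen_pair(inst, exposure, replication_outcome, "forward",
                       options, seed)
    if row.status != "ok":
        return row, "failed"
    same_sign = np.sign(row.primary_result.beta) == \
        np.sign(primary_row.primary_result.beta)
    verdict = "replicated" if (row.pval_raw < 0.05 and same_sign) \
        else "not replicated"
    return row, verdict
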