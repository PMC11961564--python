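"""Run configuration, result tables, and on-disk artifacts.

The screen's outputs are plain TSV tables: a master results table (one
row per exposure/outcome/method), a sensitivity table, a mediation
table, per-pair exclusion logs, forest- and scatter-plot data tables,
plus a JSON run manifest (inputs, config hash, seed, version) and a
human-readable log of per-stage counts.  Figure rendering is optional;
the tables carry the numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gwas_data import read_summary_stats
from .instruments import LDMatrix, SelectionConfig
from .mediation import MediationResult
from .screen import (ScreenOptions, ScreenRow, replicate, run_forward_screen,
                     run_mediator_screen, run_reverse_screen)
from .simulate import SimConfig, ld_for_config, simulate_pair, simulate_triad
from .gwas_data import write_summary_stats

log = logging.getLogger("mrscreen")

__all__ = ["RunConfig", "run_from_config", "results_table", "sensitivity_table",
           "mediation_table", "forest_table", "write_screen_outputs"]


@dataclass
class RunConfig:
    """Validated contents of a run configuration file (YAML)."""

    command: str
    seed: int
    out_dir: str
    exposure: str | None = None
    outcomes: list[str] = field(default_factory=list)
    mediators: list[str] = field(default_factory=list)
    outcome: str | None = None
    replication_outcome: str | None = None
    ld: str | None = None
    ld_format: str = "square"
    family_m: int | None = None
    selection: dict = field(default_factory=dict)
    estimators: dict = field(default_factory=dict)
    sensitivity: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    column_map: dict = field(default_factory=dict)

    _COMMANDS = ("simulate", "screen", "reverse", "mediate", "replicate")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config missing required field 'seed'")
        if "command" not in raw:
            raise ValueError("config missing required field 'command'")
        if "out_dir" not in raw:
            raise ValueError("config missing required field 'out_dir'")
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.command not in cls._COMMANDS:
            raise ValueError(f"unknown command {cfg.command!r}")
        base = Path(path).parent
        for name in ("exposure", "outcome", "replication_outcome", "ld"):
            val = getattr(cfg, name)
            if val is not None:
                p = (base / val) if not Path(val).is_absolute() else Path(val)
                if not p.exists():
                    raise ValueError(f"config path for {name!r} does not exist: {p}")
                setattr(cfg, name, str(p))
        for name in ("outcomes", "mediators"):
            resolved = []
            for val in getattr(cfg, name):
                p = (base / val) if not Path(val).is_absolute() else Path(val)
                if not p.exists():
                    raise ValueError(f"config path in {name!r} does not exist: {p}")
                resolved.append(str(p))
            setattr(cfg, name, resolved)
        return cfg

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(**self.selection)

    def screen_options(self) -> ScreenOptions:
        kw = {}
        if "n_boot" in self.estimators:
            kw["n_boot"] = int(self.estimators["n_boot"])
        if "bandwidth_factor" in self.estimators:
            kw["bandwidth_factor"] = float(self.estimators["bandwidth_factor"])
        if "methods" in self.estimators:
            kw["methods"] = tuple(self.estimators["methods"])
        if "n_sim" in self.sensitivity:
            kw["presso_n_sim"] = int(self.sensitivity["n_sim"])
        if "sig" in self.sensitivity:
            kw["presso_sig"] = float(self.sensitivity["sig"])
        if "run" in self.sensitivity:
            kw["run_sensitivity"] = bool(self.sensitivity["run"])
        return ScreenOptions(**kw)


# ---------------------------------------------------------------------------
# result tables

_RESULT_COLS = ["exposure", "outcome", "direction", "method", "n_snp", "beta",
                "se", "ci_low", "ci_high", "pval", "or", "or_ci_low",
                "or_ci_high", "pval_bonferroni", "family_m", "verdict",
                "direction_consistent", "status", "message"]


def results_table(rows: list[ScreenRow]) -> pd.DataFrame:
    """Master results TSV: one row per (exposure, outcome, method)."""
    recs = []
    for row in rows:
        if row.status != "ok":
            recs.append(dict.fromkeys(_RESULT_COLS) | {
                "exposure": row.exposure, "outcome": row.outcome,
                "direction": row.direction, "status": row.status,
                "message": row.message})
            continue
        for res, primary in [(row.primary_result, True)] + \
                [(r, False) for r in row.secondary_results]:
            recs.append({
                "exposure": row.exposure, "outcome": row.outcome,
                "direction": row.direction, "method": res.method,
                "n_snp": res.n_snp, "beta": res.beta, "se": res.se,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "pval": res.pval, "or": res.or_,
                "or_ci_low": res.or_ci_low, "or_ci_high": res.or_ci_high,
                "pval_bonferroni": row.pval_bonferroni if primary else np.nan,
                "family_m": row.family_size,
                "verdict": row.verdict if primary else "",
                "direction_consistent": row.direction_consistent,
                "status": row.status, "message": row.message})
    return pd.DataFrame(recs, columns=_RESULT_COLS)


def sensitivity_table(rows: list[ScreenRow]) -> pd.DataFrame:
    """One row per pair: Q, Egger intercept, MR-PRESSO summary."""
    recs = []
    for row in rows:
        s = row.sensitivity
        rec = {"exposure": row.exposure, "outcome": row.outcome,
               "q": np.nan, "q_df": np.nan, "q_pval": np.nan,
               "egger_intercept": np.nan, "egger_intercept_se": np.nan,
               "egger_intercept_pval": np.nan,
               "presso_global_rss": np.nan, "presso_global_pval": np.nan,
               "presso_outliers": "", "presso_distortion_pval": np.nan,
               "corrected_beta": np.nan, "corrected_pval": np.nan}
        if s is not None:
            if s.q is not None:
                rec.update(q=s.q.q, q_df=s.q.df, q_pval=s.q.pval)
            if s.egger_intercept is not None:
                rec.update(egger_intercept=s.egger_intercept,
                           egger_intercept_se=s.egger_intercept_se,
                           egger_intercept_pval=s.egger_intercept_pval)
            if s.presso is not None:
                rec.update(presso_global_rss=s.presso.global_rss,
                           presso_global_pval=s.presso.global_pval,
                           presso_outliers=",".join(s.presso.outlier_ids),
                           presso_distortion_pval=s.presso.distortion_pval)
                if s.corrected_ivw is not None:
                    rec.update(corrected_beta=s.corrected_ivw.beta,
                               corrected_pval=s.corrected_ivw.pval)
        recs.append(rec)
    return pd.DataFrame(recs)


def mediation_table(mediations: list[tuple[str, MediationResult]],
                    exposure: str, outcome: str) -> pd.DataFrame:
    recs = []
    for name, m in mediations:
        rec = {"exposure": exposure, "mediator": name, "outcome": outcome}
        rec.update(asdict(m))
        recs.append(rec)
    return pd.DataFrame(recs)


def forest_table(rows: list[ScreenRow]) -> pd.DataFrame:
    """Plot-ready table behind a forest plot: OR and CI per
    (outcome, method), primary method first."""
    if not rows:
        raise ValueError("forest_table requires a non-empty screen")
    df = results_table([r for r in rows if r.status == "ok"])
    return df[["outcome", "method", "n_snp", "or", "or_ci_low", "or_ci_high",
               "pval", "verdict"]]


def scatter_table(h) -> pd.DataFrame:
    """Per-SNP effect pairs behind a scatter plot."""
    return h.df[["snp_id", "beta_exp", "se_exp", "beta_out", "se_out"]].copy()


# ---------------------------------------------------------------------------
# orchestrated runs

def _config_hash(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def _write_manifest(out: Path, cfg: RunConfig, config_path) -> None:
    manifest = {
        "command": cfg.command,
        "seed": cfg.seed,
        "config_file": str(config_path),
        "config_sha256": _config_hash(config_path),
        "mrscreen_version": __version__,
        "inputs": {
            "exposure": cfg.exposure, "outcomes": cfg.outcomes,
            "mediators": cfg.mediators, "outcome": cfg.outcome,
            "replication_outcome": cfg.replication_outcome, "ld": cfg.ld,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _read(cfg: RunConfig, path, name=None):
    ds, summary = read_summary_stats(path, column_map=cfg.column_map or None,
                                     trait_name=name or Path(path).stem)
    log.info("read %s: %d rows kept, %d dropped %s", path, summary.rows_kept,
             summary.rows_dropped, summary.dropped or "")
    return ds


def _read_ld(cfg: RunConfig, datasets) -> LDMatrix:
    positions = {}
    for ds in datasets:
        for row in ds.df.itertuples(index=False):
            positions.setdefault(row.snp_id, (str(row.chrom), int(row.pos)))
    if cfg.ld_format == "long":
        return LDMatrix.read_long(cfg.ld, positions)
    return LDMatrix.read_square(cfg.ld, positions)


def write_screen_outputs(out_dir, rows: list[ScreenRow]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_table(rows).to_csv(out / "results.tsv", sep="\t", index=False)
    sensitivity_table(rows).to_csv(out / "sensitivity.tsv", sep="\t", index=False)
    forest_table(rows).to_csv(out / "forest.tsv", sep="\t", index=False)
    excl = [{"exposure": r.exposure, "outcome": r.outcome, "snp_id": s,
             "reason": why} for r in rows for s, why in r.exclusion_log]
    pd.DataFrame(excl, columns=["exposure", "outcome", "snp_id", "reason"]).to_csv(
        out / "exclusions.tsv", sep="\t", index=False)


def run_from_config(config_path) -> int:
    """Execute the subcommand a config file describes; returns 0 on
    success.  Validation problems raise ``ValueError`` before anything
    is written; outcome-level failures inside a screen are warnings."""
    cfg = RunConfig.from_file(config_path)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        _dispatch(cfg)
        _write_manifest(out, cfg, config_path)
    finally:
        log.removeHandler(handler)
        handler.close()
    return 0


def _dispatch(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    sel = cfg.selection_config()
    opts = cfg.screen_options()

    if cfg.command == "simulate":
        mode = cfg.simulate.get("mode", "pair")
        sim = SimConfig(**{k: v for k, v in cfg.simulate.items() if k != "mode"},
                        seed=cfg.seed)
        if mode == "triad":
            exp, med, outc, _ = simulate_triad(sim)
            write_summary_stats(med, out / "mediator.tsv")
            n_ld = 2 * sim.m_snps
        else:
            exp, outc, _ = simulate_pair(sim)
            n_ld = sim.m_snps
        write_summary_stats(exp, out / "exposure.tsv")
        write_summary_stats(outc, out / "outcome.tsv")
        ld_for_config(sim, n_ld).write_square(out / "ld.tsv")
        log.info("simulated %s: %d SNPs, seed %d, theta %g",
                 mode, n_ld, cfg.seed, sim.theta)
        return

    if cfg.command == "screen":
        exposure = _read(cfg, cfg.exposure)
        outcomes = [_read(cfg, p) for p in cfg.outcomes]
        ld = _read_ld(cfg, [exposure])
        rows = run_forward_screen(exposure, outcomes, ld, sel, cfg.seed,
                                  cfg.family_m, opts)
        write_screen_outputs(out, rows)
        return

    if cfg.command == "reverse":
        exposure = _read(cfg, cfg.exposure)
        outcomes = [_read(cfg, p) for p in cfg.outcomes]
        ld = _read_ld(cfg, outcomes)
        rows = run_reverse_screen(outcomes, exposure, ld, sel, cfg.seed,
                                  cfg.family_m, opts)
        write_screen_outputs(out, rows)
        return

    if cfg.command == "mediate":
        exposure = _read(cfg, cfg.exposure)
        outcome = _read(cfg, cfg.outcome)
        mediators = [_read(cfg, p) for p in cfg.mediators]
        ld = _read_ld(cfg, [exposure] + mediators)
        res = run_mediator_screen(exposure, mediators, outcome, ld, sel,
                                  cfg.seed, opts)
        write_screen_outputs(out, [res.total] + res.step_a + res.step_b)
        mediation_table(res.mediations, exposure.trait_name,
                        outcome.trait_name).to_csv(
            out / "mediation.tsv", sep="\t", index=False)
        return

    if cfg.command == "replicate":
        exposure = _read(cfg, cfg.exposure)
        outcomes = [_read(cfg, p) for p in cfg.outcomes]
        replication = _read(cfg, cfg.replication_outcome)
        ld = _read_ld(cfg, [exposure])
        rows = run_forward_screen(exposure, outcomes, ld, sel, cfg.seed,
                                  cfg.family_m, opts)
        candidates = [r for r in rows if r.verdict in ("strong", "potential")]
        rep_rows = []
        for r in candidates:
            rep, verdict = replicate(r, exposure, replication, ld, sel,
                                     cfg.seed, opts)
            rep_rows.append({"exposure": r.exposure, "outcome": r.outcome,
                             "replication": replication.trait_name,
                             "primary_pval": r.pval_raw,
                             "replication_pval": rep.pval_raw,
                             "replication_beta":
                                 rep.primary_result.beta
                                 if rep.primary_result else np.nan,
                             "verdict": verdict})
        write_screen_outputs(out, rows)
        pd.DataFrame(rep_rows).to_csv(out / "replication.tsv", sep="\t",
                                      index=False)
        return
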