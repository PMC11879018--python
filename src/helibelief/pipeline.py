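"""End-to-end synthetic-cohort study: simulate, model, analyse, report.

``run_study`` executes the full analysis sequence on a simulated two-group
cohort sharing one task schedule: observer traces in empirical conditioning
per subject, learning-rate summaries and performance errors, per-subject
belief-update regressions, group comparisons, the group-status logistic
model, symptom regressions, and (optionally) a per-subject VOI-level fMRI
simulation/recovery stage. All randomness descends from one master seed via
named spawned sub-seeds, so reruns with the same config are bit-identical
and adding subjects never perturbs existing ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .behavior import (
    bacs_composite,
    empirical_learning_rates,
    exclusion_screen,
    fit_group_logistic,
    fit_symptom_regressions,
    fit_update_regression,
    group_compare,
    performance_error,
    post_changepoint_learning,
)
from .fmridesign import (
    ScanConfig,
    build_design_matrix,
    fit_glm,
    group_beta_compare,
    simulate_bold,
    voi_correlate,
)
from .observer import ObserverConfig, run_observer
from .taskgen import (
    HC_PARAMS,
    PSD_PARAMS,
    AgentParams,
    TaskConfig,
    events_frame,
    simulate_cohort,
)

__all__ = ["StudyConfig", "load_config", "run_study", "StudyReport"]

logger = logging.getLogger(__name__)


class AgentParamsModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    w_pe: float = 0.75
    w_cpp: float = 0.15
    w_ru: float = 0.15
    w_reward: float = 0.03
    intercept_bias: float = 0.0
    edge_weight: float = 0.0
    motor_noise_sd: float = 2.0
    lapse_prob: float = 0.01
    perseveration_prob: float = 0.02
    miss_prob: float = 0.04

    def to_params(self) -> AgentParams:
        return AgentParams(**self.model_dump())


class TaskModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_runs: int = 4
    trials_per_run: int = 70
    noise_sd_by_run: list[float] = Field(default=[2.3, 4.6, 2.3, 4.6])
    hazard: float = 0.125
    reward_prob: float = 0.5
    catch_halfwidth: float = 5.0
    mean_margin: float = 10.0

    @field_validator("hazard")
    @classmethod
    def _hazard_range(cls, v: float) -> float:
        if not 0.0 <= v < 1.0:
            raise ValueError("hazard must be in [0, 1)")
        return v

    def to_config(self, seed: int) -> TaskConfig:
        return TaskConfig(
            n_runs=self.n_runs,
            trials_per_run=self.trials_per_run,
            noise_sd_by_run=tuple(self.noise_sd_by_run),
            hazard=self.hazard,
            reward_prob=self.reward_prob,
            catch_halfwidth=self.catch_halfwidth,
            mean_margin=self.mean_margin,
            seed=seed,
        )


class ObserverModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hazard: float = 0.125
    tau_init: float = 0.5
    missing_policy: Literal["freeze", "advance"] = "freeze"


class AnalysisModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    category_bounds: tuple[float, float] = (0.1, 0.9)
    reward_coding: Literal["interaction", "main"] = "interaction"
    performance_mode: Literal["mean", "sum"] = "mean"
    pe_floor: float = 1.0


class FmriModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    tr: float = 0.8
    noise_sd: float = 2.0
    ar1_rho: float = 0.3
    whitening: Literal["none", "ar1"] = "ar1"
    cpp_beta_scale: float = 4.0  # true CPP-modulator beta = scale * subject w_cpp


class StudyConfig(BaseModel):
    """Schema-checked study configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    n_hc: int = 40
    n_psd: int = 19
    task: TaskModel = Field(default_factory=TaskModel)
    observer: ObserverModel = Field(default_factory=ObserverModel)
    hc_agent: AgentParamsModel = Field(default_factory=lambda: AgentParamsModel(**_params_dict(HC_PARAMS)))
    psd_agent: AgentParamsModel = Field(default_factory=lambda: AgentParamsModel(**_params_dict(PSD_PARAMS)))
    analysis: AnalysisModel = Field(default_factory=AnalysisModel)
    fmri: FmriModel = Field(default_factory=FmriModel)


def _params_dict(p: AgentParams) -> dict[str, float]:
    return {
        k: getattr(p, k)
        for k in (
            "w_pe", "w_cpp", "w_ru", "w_reward", "intercept_bias", "edge_weight",
            "motor_noise_sd", "lapse_prob", "perseveration_prob", "miss_prob",
        )
    }


def load_config(path: str | Path | None = None) -> StudyConfig:
    """Load and validate a YAML study config; empty/missing content = defaults."""
    if path is None:
        return StudyConfig()
    raw = yaml.safe_load(Path(path).read_text())
    return StudyConfig(**(raw or {}))


class StudyReport(dict):
    """Dict-backed report with a stable content hash (provenance included)."""

    def content_hash(self) -> str:
        payload = json.dumps(self, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()


def _observer_trace(record, cfg: StudyConfig, schedule):
    obs_cfg = ObserverConfig(
        hazard=cfg.observer.hazard,
        noise_sd=float(schedule.noise_sd[0]),
        tau_init=cfg.observer.tau_init,
        conditioning="empirical",
        missing_policy=cfg.observer.missing_policy,
    )
    return run_observer(
        record.outcome,
        obs_cfg,
        predictions=record.prediction,
        run=record.run,
        run_noise_map=list(schedule.config.noise_sd_by_run),
        missing=record.missing,
    )


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Run the full analysis sequence; optionally persist intermediates.

    Returns a :class:`StudyReport` with per-group behavioural summaries,
    the per-subject coefficient table, group and symptom model outputs and
    (if enabled) fMRI recovery metrics. When ``out_dir`` is given, tidy CSV
    intermediates (cohort table, traces, coefficients) and the JSON report
    are written there.
    """
    cfg = config
    schedule, cohort, records = simulate_cohort(
        cfg.n_hc,
        cfg.n_psd,
        hc_params=cfg.hc_agent.to_params(),
        psd_params=cfg.psd_agent.to_params(),
        seed=cfg.seed,
        task_config=cfg.task.to_config(seed=cfg.seed),
        hazard_belief=cfg.observer.hazard,
    )
    logger.info("stage cohort: %d subjects, %d trials", len(records), len(schedule))

    rows = []
    traces = []
    resid_by_subject = {}
    for rec in records:
        trace = _observer_trace(rec, cfg, schedule)
        traces.append(trace)
        lr = empirical_learning_rates(
            rec, schedule, pe_floor=cfg.analysis.pe_floor, bounds=cfg.analysis.category_bounds
        )
        reg = fit_update_regression(rec, trace, reward_coding=cfg.analysis.reward_coding)
        screen = exclusion_screen(rec)
        resid_by_subject[rec.subject] = reg.residuals
        rows.append(
            {
                "subject": rec.subject,
                "performance_error": performance_error(rec, schedule, mode=cfg.analysis.performance_mode),
                "mean_lr": lr.mean_lr,
                "lr_post_cp": post_changepoint_learning(rec, schedule, pe_floor=cfg.analysis.pe_floor),
                "frac_non": lr.frac_non,
                "frac_moderate": lr.frac_moderate,
                "frac_total": lr.frac_total,
                "n_aberrant": lr.n_aberrant,
                "r2": reg.r2,
                **{f"beta_{k}": v for k, v in reg.coef.items()},
                **{k: v for k, v in screen.items()},
            }
        )
    subject_stats = pd.DataFrame(rows)
    table = cohort.merge(subject_stats, on="subject")
    group = table["group"].to_numpy()

    behavioural = {}
    for metric in ("performance_error", "mean_lr", "lr_post_cp", "frac_non", "frac_moderate", "frac_total", "r2"):
        behavioural[metric] = group_compare(table[metric].to_numpy(), group)

    coef_cols = {"pe": "beta_pe", "pe_x_cpp": "beta_pe_x_cpp", "pe_x_ru": "beta_pe_x_ru", "reward": "beta_reward"}
    coef_table = table[list(coef_cols.values())].rename(columns={v: k for k, v in coef_cols.items()})
    logistic = fit_group_logistic(coef_table, group)

    bacs_cols = [c for c in table.columns if c.startswith("bacs_")]
    hc_ref = pd.DataFrame(
        {
            "mean": table.loc[group == 0, bacs_cols].mean(),
            "sd": table.loc[group == 0, bacs_cols].std(ddof=1),
        }
    )
    table["bacs_composite"] = bacs_composite(table[bacs_cols], hc_ref)

    pdi_model = fit_symptom_regressions(table["pdi"].to_numpy(), coef_table)
    psd_mask = group == 1
    panss_models = {}
    for scale in ("panss_pos", "panss_neg", "panss_gen"):
        try:
            panss_models[scale] = fit_symptom_regressions(
                table.loc[psd_mask, scale].to_numpy(),
                coef_table.loc[psd_mask].reset_index(drop=True),
            ).to_dict()
        except ValueError as err:  # clinical subsample too small for the model
            logger.warning("skipping %s regression: %s", scale, err)
            panss_models[scale] = {"skipped": str(err)}
    perf_pdi = fit_symptom_regressions(
        table["pdi"].to_numpy(),
        table[["performance_error"]],
        covariates=table[["bacs_verbal_memory", "bacs_processing_speed"]],
    )

    report = StudyReport(
        version=__version__,
        seed=cfg.seed,
        n_trials=len(schedule),
        n_subjects=len(records),
        behavioural={k: v for k, v in behavioural.items()},
        logistic=logistic["coef"].to_dict() | {f"p_{k}": v for k, v in logistic["p"].to_dict().items()},
        pdi_model=pdi_model.to_dict(),
        panss_models=panss_models,
        performance_pdi=perf_pdi.to_dict(),
        provenance={
            "hc_agent": cfg.hc_agent.model_dump(),
            "psd_agent": cfg.psd_agent.model_dump(),
            "task": cfg.task.model_dump(),
        },
    )

    if cfg.fmri.enabled:
        report["fmri"] = _fmri_stage(cfg, schedule, records, traces, resid_by_subject, table)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        schedule.to_frame().to_csv(out / "schedule.csv", index=False)
        table.to_csv(out / "cohort_table.csv", index=False)
        trace_frames = []
        for rec, tr in zip(records, traces):
            f = tr.to_frame()
            f.insert(0, "subject", rec.subject)
            trace_frames.append(f)
        pd.concat(trace_frames, ignore_index=True).to_csv(out / "traces.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _fmri_stage(cfg, schedule, records, traces, resid_by_subject, table) -> dict[str, Any]:
    """Per-subject VOI simulation/recovery: BOLD with CPP beta tied to w_cpp."""
    scan_cfg = ScanConfig(tr=cfg.fmri.tr, noise_sd=cfg.fmri.noise_sd, ar1_rho=cfg.fmri.ar1_rho)
    ss = np.random.SeedSequence(cfg.seed).spawn(len(records) + 1)
    voi_betas = []
    true_betas = []
    for i, (rec, trace) in enumerate(zip(records, traces)):
        events = events_frame(rec, seed=ss[i])
        mods = {
            "outcome": rec.outcome,
            "cpp": trace.cpp,
            "ru": trace.ru,
            "reward": rec.reward.astype(float),
            "residual": resid_by_subject[rec.subject],
        }
        # residuals are NaN on fitted-out trials; neutral value for design only
        mods["residual"] = np.nan_to_num(mods["residual"], nan=0.0)
        mods["cpp"] = np.nan_to_num(mods["cpp"], nan=0.0)
        design = build_design_matrix(events, mods, scan_cfg, motion_seed=int(ss[i].generate_state(1)[0] % 2**31))
        w_cpp = float(table.loc[table["subject"] == rec.subject, "true_w_cpp"].iloc[0])
        truth = {"onset": 1.0, "mod_outcome": 0.5, "mod_cpp": cfg.fmri.cpp_beta_scale * w_cpp,
                 "mod_ru": 0.5, "mod_reward": 0.3, "mod_residual": 0.2}
        y = simulate_bold(design, truth, scan_cfg, seed=ss[i])
        res = fit_glm(y, design, whitening=cfg.fmri.whitening)
        voi_betas.append(float(res.beta.loc["mod_cpp"].iloc[0]))
        true_betas.append(truth["mod_cpp"])
    voi = np.array(voi_betas)
    group = table["group"].to_numpy()
    age = table["age"].to_numpy()
    comp = group_beta_compare(voi, group, age)
    corr = voi_correlate(voi, table[["pdi", "bacs_composite"]])
    rmse = float(np.sqrt(np.mean((voi - np.array(true_betas)) ** 2)))
    return {
        "voi_group": comp,
        "voi_correlations": corr.to_dict(),
        "cpp_beta_recovery_rmse": rmse,
        "n_scans_total": None,
    }
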