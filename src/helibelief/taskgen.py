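"""Helicopter-task schedule generation and synthetic behaving agents.

The predictive inference ("helicopter") task: on each trial the participant
places a prediction on a 0-100 screen scale for where a bag will drop. Bags
fall from a hidden helicopter whose location is stable most of the time but
relocates completely at unannounced change points; bag locations scatter
around the helicopter with run-wise Gaussian noise (SD 2.3 in runs 1 and 3,
4.6 in runs 2 and 4 by default). Bags are randomly labelled money or sand;
a bag is caught when the prediction is within +/-5 screen units of the drop.

Agents update their predictions by a generative mirror of the belief-update
regression analysed downstream: the intended update mixes the prediction
error scaled by weights on PE, PE x CPP, PE x RU x (1-CPP) and PE x reward,
plus an edge-repulsion term and motor noise, with occasional lapses
(random prediction), perseveration (no update) and missing responses. The
agent's CPP and RU are computed online from its own prediction errors via
:mod:`helibelief.observer`, so the generative and analysis models share one
set of recursions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .observer import (
    ObserverConfig,
    change_point_probability,
    model_learning_rate,
    relative_uncertainty_update,
)

__all__ = [
    "TaskConfig",
    "TaskSchedule",
    "AgentParams",
    "BehaviorRecord",
    "ConfigurationError",
    "generate_schedule",
    "simulate_agent",
    "simulate_normative_agent",
    "fixed_lr_params",
    "simulate_cohort",
    "CovariateModel",
    "HC_PARAMS",
    "PSD_PARAMS",
    "events_frame",
    "write_events_tsv",
    "read_events_tsv",
]


class ConfigurationError(ValueError):
    """Invalid task or agent configuration; the message names the field."""


@dataclass(frozen=True)
class TaskConfig:
    """Task structure: 4 runs x 70 trials, alternating noise regimes."""

    n_runs: int = 4
    trials_per_run: int = 70
    scale_min: float = 0.0
    scale_max: float = 100.0
    noise_sd_by_run: tuple[float, ...] = (2.3, 4.6, 2.3, 4.6)
    hazard: float = 0.125
    reward_prob: float = 0.5
    catch_halfwidth: float = 5.0
    mean_margin: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_run < 2:
            raise ConfigurationError("trials_per_run must be >= 2")
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")
        if not self.scale_min < self.scale_max:
            raise ConfigurationError("scale_min must be < scale_max")
        if len(self.noise_sd_by_run) != self.n_runs:
            raise ConfigurationError(
                f"noise_sd_by_run must have n_runs={self.n_runs} entries"
            )
        if any(sd <= 0 for sd in self.noise_sd_by_run):
            raise ConfigurationError("noise_sd_by_run entries must be > 0")
        if not 0.0 <= self.hazard < 1.0:
            raise ConfigurationError("hazard must be in [0, 1)")
        if not 0.0 <= self.reward_prob <= 1.0:
            raise ConfigurationError("reward_prob must be in [0, 1]")
        if self.catch_halfwidth < 0:
            raise ConfigurationError("catch_halfwidth must be >= 0")
        width = self.scale_max - self.scale_min
        if not 0.0 <= self.mean_margin < width / 2:
            raise ConfigurationError("mean_margin must be in [0, half scale width)")

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run

    @property
    def scale_width(self) -> float:
        return self.scale_max - self.scale_min

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.scale_min + self.scale_max)


@dataclass
class TaskSchedule:
    """Generative truth per trial; all arrays have length n_runs*trials_per_run."""

    config: TaskConfig
    run: np.ndarray
    mean: np.ndarray
    is_change_point: np.ndarray
    outcome: np.ndarray
    noise_sd: np.ndarray
    reward: np.ndarray

    def __len__(self) -> int:
        return len(self.outcome)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self)),
                "run": self.run,
                "mean": self.mean,
                "is_change_point": self.is_change_point.astype(int),
                "outcome": self.outcome,
                "noise_sd": self.noise_sd,
                "reward": self.reward.astype(int),
            }
        )


@dataclass(frozen=True)
class AgentParams:
    """Generative weights of a simulated participant.

    ``w_pe``/``w_cpp``/``w_ru``/``w_reward`` scale the prediction error, its
    interaction with change-point probability, with relative uncertainty
    (x (1-CPP)) and with the reward label; they live on the same scale as the
    downstream regression coefficients. ``edge_weight`` repels predictions
    from the screen edges via a cubic term; motor noise, lapses,
    perseveration and missing responses add realistic non-idealities.
    """

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

    def __post_init__(self) -> None:
        for name in ("lapse_prob", "perseveration_prob", "miss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.motor_noise_sd < 0:
            raise ConfigurationError("motor_noise_sd must be >= 0")


# Cohort presets: the control-like agent tracks the normative weights the
# healthy group exhibits (strong PE use, clear CPP scaling); the PSD-like
# regime down-weights CPP and PE, adds perseveration/non-updates and noisier
# responding.
HC_PARAMS = AgentParams()
PSD_PARAMS = AgentParams(
    w_pe=0.65,
    w_cpp=0.05,
    w_ru=0.20,
    w_reward=0.03,
    motor_noise_sd=3.0,
    lapse_prob=0.03,
    perseveration_prob=0.08,
    miss_prob=0.04,
)


@dataclass
class BehaviorRecord:
    """One participant's (or agent's) per-trial behaviour.

    ``prediction`` is NaN on missing trials. ``pe`` and ``update`` are
    derived: ``pe[t] = outcome[t] - prediction[t]`` and
    ``update[t] = prediction[t+1] - prediction[t]`` within a run (NaN on the
    last trial of each run and wherever either prediction is missing).
    """

    prediction: np.ndarray
    outcome: np.ndarray
    reward: np.ndarray
    missing: np.ndarray
    run: np.ndarray
    caught: np.ndarray
    response_time: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject: str = "agent"

    def __post_init__(self) -> None:
        n = len(self.prediction)
        if self.response_time is None:
            self.response_time = np.full(n, np.nan)

    def __len__(self) -> int:
        return len(self.prediction)

    @property
    def pe(self) -> np.ndarray:
        return self.outcome - self.prediction

    @property
    def update(self) -> np.ndarray:
        u = np.full(len(self), np.nan)
        nxt = self.prediction[1:] - self.prediction[:-1]
        same_run = self.run[1:] == self.run[:-1]
        u[:-1] = np.where(same_run, nxt, np.nan)
        return u

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self)),
                "run": self.run,
                "prediction": self.prediction,
                "outcome": self.outcome,
                "pe": self.pe,
                "update": self.update,
                "reward": self.reward.astype(int),
                "caught": self.caught.astype(int),
                "missing": self.missing.astype(int),
            }
        )


def generate_schedule(config: TaskConfig) -> TaskSchedule:
    """Draw a task schedule: change points, hidden means, outcomes, rewards.

    Change points occur per trial with probability ``config.hazard`` (the
    first trial of each run is a forced change point: runs restart the
    helicopter). New means are uniform on the scale with a margin from the
    edges; outcomes are Gaussian around the mean, redrawn until on-scale
    (rejection, not clipping, to avoid point masses at the edges). Identical
    config (incl. seed) gives bit-identical schedules.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    run = np.repeat(np.arange(config.n_runs), config.trials_per_run)
    noise_sd = np.asarray(config.noise_sd_by_run, dtype=float)[run]

    lo = config.scale_min + config.mean_margin
    hi = config.scale_max - config.mean_margin
    mean = np.empty(n)
    is_cp = np.zeros(n, dtype=bool)
    outcome = np.empty(n)
    mu = 0.0
    for t in range(n):
        first_of_run = t % config.trials_per_run == 0
        cp = first_of_run or (rng.random() < config.hazard)
        if cp:
            mu = rng.uniform(lo, hi)
        is_cp[t] = cp
        mean[t] = mu
        while True:
            x = mu + noise_sd[t] * rng.standard_normal()
            if config.scale_min <= x <= config.scale_max:
                outcome[t] = x
                break
    reward = rng.random(n) < config.reward_prob
    return TaskSchedule(
        config=config,
        run=run,
        mean=mean,
        is_change_point=is_cp,
        outcome=outcome,
        noise_sd=noise_sd,
        reward=reward,
    )


def simulate_agent(
    schedule: TaskSchedule,
    params: AgentParams,
    hazard_belief: float = 0.125,
    seed: int | np.random.SeedSequence = 0,
    subject: str = "agent",
) -> BehaviorRecord:
    """Simulate one agent on a schedule.

    The agent's internal observer runs on its own prediction errors with the
    true run-wise noise SDs and subjective hazard ``hazard_belief``. Each
    trial the intended update is

    ``intercept + w_pe*d + w_cpp*d*cpp + w_ru*d*ru*(1-cpp) + w_reward*d*r
      + edge_weight*((B-mid)/half)^3*half + N(0, motor_noise_sd^2)``

    optionally replaced by a lapse (uniform prediction) or perseveration
    (no update); predictions are clipped to the scale. Missing trials record
    no prediction and freeze both the internal belief and the observer state.
    """
    cfg = schedule.config
    obs_cfg = ObserverConfig(hazard=hazard_belief, noise_sd=float(schedule.noise_sd[0]))
    rng = np.random.default_rng(seed)
    n = len(schedule)
    half = cfg.scale_width / 2.0
    mid = cfg.midpoint

    prediction = np.full(n, np.nan)
    missing = np.zeros(n, dtype=bool)
    caught = np.zeros(n, dtype=bool)
    rt = np.full(n, np.nan)

    b = mid
    tau = obs_cfg.tau_init
    prev_run = -1
    for t in range(n):
        if schedule.run[t] != prev_run:
            b = mid
            tau = obs_cfg.tau_init
            prev_run = schedule.run[t]
        u = rng.random(3)  # miss / lapse / perseveration, fixed draw count per trial
        if u[0] < params.miss_prob:
            missing[t] = True
            continue
        prediction[t] = b
        rt[t] = min(0.3 + rng.gamma(2.0, 0.45), 2.95)
        x = float(schedule.outcome[t])
        d = x - b
        caught[t] = abs(d) <= cfg.catch_halfwidth
        sd = float(schedule.noise_sd[t])
        omega = change_point_probability(d, tau, obs_cfg, sd)
        r = float(schedule.reward[t])
        if u[1] < params.lapse_prob:
            b_next = rng.uniform(cfg.scale_min, cfg.scale_max)
        elif u[2] < params.perseveration_prob:
            b_next = b
        else:
            upd = (
                params.intercept_bias
                + params.w_pe * d
                + params.w_cpp * d * omega
                + params.w_ru * d * tau * (1.0 - omega)
                + params.w_reward * d * r
                + params.edge_weight * ((b - mid) / half) ** 3 * half
                + params.motor_noise_sd * rng.standard_normal()
            )
            b_next = min(max(b + upd, cfg.scale_min), cfg.scale_max)
        tau = relative_uncertainty_update(d, tau, omega, sd)
        b = b_next

    return BehaviorRecord(
        prediction=prediction,
        outcome=schedule.outcome.copy(),
        reward=schedule.reward.copy(),
        missing=missing,
        run=schedule.run.copy(),
        caught=caught,
        response_time=rt,
        subject=subject,
    )


def simulate_normative_agent(
    schedule: TaskSchedule, hazard_belief: float = 0.125, seed: int = 0
) -> BehaviorRecord:
    """Noise-free agent updating exactly by the model learning rate alpha*delta."""
    params = AgentParams(
        w_pe=0.0,
        w_cpp=0.0,
        w_ru=0.0,
        w_reward=0.0,
        motor_noise_sd=0.0,
        lapse_prob=0.0,
        perseveration_prob=0.0,
        miss_prob=0.0,
    )
    # w_pe carries PE*1; the normative LR alpha = cpp + (1-cpp)*ru decomposes as
    # d*cpp + d*ru*(1-cpp), i.e. unit weights on the two interaction terms.
    params = replace(params, w_cpp=1.0, w_ru=1.0)
    return simulate_agent(schedule, params, hazard_belief, seed, subject="normative")


def fixed_lr_params(lr: float) -> AgentParams:
    """Noise-free agent that always updates a fixed fraction ``lr`` of the PE."""
    return AgentParams(
        w_pe=lr,
        w_cpp=0.0,
        w_ru=0.0,
        w_reward=0.0,
        motor_noise_sd=0.0,
        lapse_prob=0.0,
        perseveration_prob=0.0,
        miss_prob=0.0,
    )


@dataclass(frozen=True)
class CovariateModel:
    """Distributions for cohort covariates and their coupling to behaviour.

    Group means/SDs default to the demographics and cognition of a
    40-control vs 19-psychosis-spectrum cohort (age, delusional-ideation
    inventory, clinician-rated symptom scales, six cognitive domains).
    ``symptom_loadings`` maps a symptom column to ``{weight_name: loading}``:
    the symptom gets ``loading * (w - mean_w)/sd_w`` added, coupling symptom
    scores to agent weights for recovery tests. Setting all loadings to zero
    makes symptoms independent of behaviour (null cohorts).
    """

    age: tuple[tuple[float, float], tuple[float, float]] = ((29.3, 11.38), (35.8, 9.67))
    pdi: tuple[tuple[float, float], tuple[float, float]] = ((2.9, 3.53), (14.68, 10.04))
    panss_pos: tuple[float, float] = (16.32, 6.98)
    panss_neg: tuple[float, float] = (11.32, 3.21)
    panss_gen: tuple[float, float] = (28.63, 6.44)
    bacs_domains: tuple[str, ...] = (
        "verbal_memory",
        "working_memory",
        "motor_speed",
        "verbal_fluency",
        "attention",
        "processing_speed",
    )
    bacs_means: tuple[tuple[float, ...], tuple[float, ...]] = (
        (54.5, 21.3, 78.7, 28.2, 36.5, 65.1),
        (45.2, 29.6, 76.6, 27.8, 24.4, 52.9),
    )
    bacs_sds: tuple[tuple[float, ...], tuple[float, ...]] = (
        (7.6, 3.6, 13.5, 6.9, 17.5, 13.7),
        (11.8, 4.3, 14.7, 8.0, 7.26, 10.3),
    )
    symptom_loadings: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = (
        ("pdi", (("w_cpp", -2.0), ("w_ru", 2.0))),
    )

    def draw(
        self, group: int, weights: dict[str, float], weight_ref: dict[str, tuple[float, float]], rng: np.random.Generator
    ) -> dict[str, float]:
        g = int(group)
        cov: dict[str, float] = {}
        m, s = self.age[g]
        cov["age"] = float(np.clip(rng.normal(m, s), 18, 65))
        m, s = self.pdi[g]
        cov["pdi"] = max(0.0, rng.normal(m, s))
        if g == 1:
            cov["panss_pos"] = max(7.0, rng.normal(*self.panss_pos))
            cov["panss_neg"] = max(7.0, rng.normal(*self.panss_neg))
            cov["panss_gen"] = max(16.0, rng.normal(*self.panss_gen))
        else:
            cov["panss_pos"] = cov["panss_neg"] = cov["panss_gen"] = np.nan
        for i, dom in enumerate(self.bacs_domains):
            cov[f"bacs_{dom}"] = rng.normal(self.bacs_means[g][i], self.bacs_sds[g][i])
        for symptom, loadings in self.symptom_loadings:
            if symptom in cov and np.isfinite(cov[symptom]):
                shift = 0.0
                for wname, loading in loadings:
                    mu_w, sd_w = weight_ref[wname]
                    if sd_w > 0:
                        shift += loading * (weights[wname] - mu_w) / sd_w
                cov[symptom] = max(0.0, cov[symptom] + shift)
        return cov


#: Between-subject SD of the generative weights within a group.
WEIGHT_JITTER_SD = {"w_pe": 0.08, "w_cpp": 0.05, "w_ru": 0.08, "w_reward": 0.03}


def _jitter_params(base: AgentParams, rng: np.random.Generator) -> AgentParams:
    kw = {}
    for name, sd in WEIGHT_JITTER_SD.items():
        kw[name] = getattr(base, name) + sd * rng.standard_normal()
    kw["w_pe"] = max(0.05, kw["w_pe"])
    return replace(base, **kw)


def simulate_cohort(
    n_hc: int,
    n_psd: int,
    hc_params: AgentParams = HC_PARAMS,
    psd_params: AgentParams = PSD_PARAMS,
    covariate_model: CovariateModel | None = None,
    seed: int = 0,
    task_config: TaskConfig | None = None,
    hazard_belief: float = 0.125,
) -> tuple[TaskSchedule, pd.DataFrame, list[BehaviorRecord]]:
    """Simulate a two-group cohort on one shared schedule.

    Returns the schedule (fixed across participants, as in the scanner
    protocol), a cohort table with group labels, covariates and the true
    generative weights per subject (provenance for recovery tests), and the
    per-subject behaviour records. Subject-level randomness is spawned from
    the master seed so adding subjects never perturbs existing ones.
    """
    if n_hc < 1 or n_psd < 1:
        raise ConfigurationError("group sizes must be >= 1")
    covariate_model = covariate_model or CovariateModel()
    task_config = task_config or TaskConfig(seed=seed)
    schedule = generate_schedule(task_config)

    master = np.random.SeedSequence(seed)
    sched_ss, cov_ss, *subj_ss = master.spawn(2 + n_hc + n_psd)
    cov_rng = np.random.default_rng(cov_ss)

    weight_ref = {
        name: (
            0.5 * (getattr(hc_params, name) + getattr(psd_params, name)),
            WEIGHT_JITTER_SD[name],
        )
        for name in WEIGHT_JITTER_SD
    }

    rows = []
    records = []
    groups = [0] * n_hc + [1] * n_psd
    for i, g in enumerate(groups):
        base = hc_params if g == 0 else psd_params
        params = _jitter_params(base, cov_rng)
        sid = f"{'hc' if g == 0 else 'psd'}{i:03d}"
        rec = simulate_agent(schedule, params, hazard_belief, subj_ss[i], subject=sid)
        records.append(rec)
        weights = {n: getattr(params, n) for n in WEIGHT_JITTER_SD}
        cov = covariate_model.draw(g, weights, weight_ref, cov_rng)
        row = {"subject": sid, "group": g, **cov}
        row.update({f"true_{k}": v for k, v in weights.items()})
        row["true_perseveration_prob"] = params.perseveration_prob
        row["true_motor_noise_sd"] = params.motor_noise_sd
        rows.append(row)
    return schedule, pd.DataFrame(rows), records


# --- events TSV (BIDS-style) -------------------------------------------------

_FIXATION_S = 0.5
_FEEDBACK_S = 1.5
_DECISION_MAX_S = 3.0
_ITI_MEAN_S = 2.0


def events_frame(
    record: BehaviorRecord, seed: int | np.random.SeedSequence = 0
) -> pd.DataFrame:
    """Per-trial events with onsets/durations in seconds.

    Trial template: fixation (0.5 s), decision window (response time, capped
    at 3 s), bag drop at the response (the modelled 1-s event), feedback
    (1.5 s), jittered inter-trial interval (uniform 1-3 s, mean 2 s). Missing
    trials span the whole decision window and are flagged for the error-trial
    regressor. Runs restart the clock at zero.
    """
    rng = np.random.default_rng(seed)
    n = len(record)
    onset = np.empty(n)
    duration = np.empty(n)
    t = 0.0
    prev_run = record.run[0]
    for i in range(n):
        if record.run[i] != prev_run:
            t = 0.0
            prev_run = record.run[i]
        iti = rng.uniform(1.0, 3.0)
        if record.missing[i]:
            onset[i] = t + _FIXATION_S
            duration[i] = _DECISION_MAX_S
            t += _FIXATION_S + _DECISION_MAX_S + _FEEDBACK_S + iti
        else:
            rt = record.response_time[i]
            if not np.isfinite(rt):
                rt = 1.2
            onset[i] = t + _FIXATION_S + rt  # bag drop at the response
            duration[i] = 1.0
            t += _FIXATION_S + rt + _FEEDBACK_S + iti
    frame = record.to_frame()
    frame.insert(0, "onset", onset)
    frame.insert(1, "duration", duration)
    return frame


def write_events_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.6g")


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])
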