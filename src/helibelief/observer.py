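"""Reduced-Bayesian observer for change-point predictive inference.

The observer tracks a hidden mean on a bounded screen scale (0-100) that is
stable most of the time but relocates completely at unannounced change points
(hazard ``H`` per trial). Outcomes are the hidden mean plus Gaussian noise of
known standard deviation ``sigma_n``. The fully Bayesian posterior over the
mean is a mixture that grows with the number of possible change-point times;
this observer approximates it with a single Gaussian of matched mean and
variance, which yields three interpretable per-trial quantities:

* change-point probability ``omega`` (CPP): posterior probability that the
  current outcome came from a relocated mean rather than noise,
* relative uncertainty ``tau`` (RU): the share of total predictive variance
  attributable to uncertainty about the mean,
  ``tau = sigma_belief^2 / (sigma_belief^2 + sigma_n^2)``,
* learning rate ``alpha = omega + (1 - omega) * tau``, the fraction of the
  prediction error incorporated into the belief update.

Two conditioning modes are supported: ``self`` propagates the model's own
belief (the normative agent), while ``empirical`` replaces the belief each
trial with a participant's actual prediction so that CPP/RU trajectories are
driven by the individually observed prediction errors.

A grid-based full-Bayes filter (:func:`full_bayes_oracle`) is included as a
validation oracle: it performs exact Bayesian filtering on a discretized mean
and is used only to check the reduced observer, never to replace it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ObserverConfig",
    "ObserverTrace",
    "InvalidStateError",
    "change_point_probability",
    "relative_uncertainty_update",
    "model_learning_rate",
    "run_observer",
    "full_bayes_oracle",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


class InvalidStateError(ValueError):
    """Observer reached a degenerate state (e.g. relative uncertainty = 1)."""


@dataclass(frozen=True)
class ObserverConfig:
    """Parameters of the reduced-Bayesian observer.

    Parameters
    ----------
    hazard:
        Prior per-trial probability of a change point, 0 < H < 1.
    noise_sd:
        Outcome noise standard deviation in screen units (may be overridden
        per run in :func:`run_observer`).
    scale_width:
        Width of the outcome scale in screen units; the change-point
        predictive density is uniform 1/W over the full scale.
    tau_init:
        Relative uncertainty at the start of each run (runs restart the
        hidden mean, so uncertainty resets).
    conditioning:
        ``"self"`` propagates the model belief; ``"empirical"`` uses the
        participant's actual predictions.
    missing_policy:
        ``"freeze"`` leaves the observer state untouched on missing trials
        (no observation was processed); ``"advance"`` updates CPP/RU from the
        outcome even though no prediction was recorded.
    """

    hazard: float = 0.125
    noise_sd: float = 2.3
    scale_width: float = 100.0
    tau_init: float = 0.5
    conditioning: Literal["self", "empirical"] = "self"
    missing_policy: Literal["freeze", "advance"] = "freeze"

    def __post_init__(self) -> None:
        if not 0.0 < self.hazard < 1.0:
            raise ValueError(f"hazard must be in (0, 1), got {self.hazard}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.scale_width <= 0:
            raise ValueError(f"scale_width must be > 0, got {self.scale_width}")
        if not 0.0 <= self.tau_init < 1.0:
            raise ValueError(f"tau_init must be in [0, 1), got {self.tau_init}")
        if self.conditioning not in ("self", "empirical"):
            raise ValueError(f"unknown conditioning mode {self.conditioning!r}")
        if self.missing_policy not in ("freeze", "advance"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass
class ObserverTrace:
    """Per-trial observer quantities; all arrays share one length.

    ``belief`` and ``ru`` are the pre-outcome state of trial ``t``; ``cpp``,
    ``lr`` and ``pe`` refer to the outcome observed on trial ``t``. The
    invariant ``lr = cpp + (1 - cpp) * ru`` holds element-wise on non-missing
    trials.
    """

    belief: np.ndarray
    pe: np.ndarray
    cpp: np.ndarray
    ru: np.ndarray
    lr: np.ndarray
    run: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.belief)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-trial frame with columns cpp, ru, lr_model, belief, pe."""
        return pd.DataFrame(
            {
                "run": self.run,
                "trial": np.arange(len(self.belief)),
                "cpp": self.cpp,
                "ru": self.ru,
                "lr_model": self.lr,
                "belief": self.belief,
                "pe": self.pe,
            }
        )


def change_point_probability(
    delta: float, tau: float, cfg: ObserverConfig, noise_sd: float | None = None
) -> float:
    """Posterior probability that a prediction error reflects a change point.

    ``omega = H/W / (H/W + (1-H) * phi(delta; 0, sigma_n^2 / (1-tau)))`` where
    ``sigma_n^2 / (1-tau) = sigma_n^2 + sigma_belief^2`` is the total
    predictive variance under no change and ``1/W`` the uniform predictive
    density under a change. Large surprising errors (unlikely under the
    stable-environment Gaussian) push omega toward 1.
    """
    if tau >= 1.0:
        raise InvalidStateError(
            "relative uncertainty reached 1: predictive variance is degenerate"
        )
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    total_var = sd * sd / (1.0 - tau)
    dens_stable = math.exp(-0.5 * delta * delta / total_var) / (
        _SQRT_2PI * math.sqrt(total_var)
    )
    dens_change = 1.0 / cfg.scale_width
    h = cfg.hazard
    num = h * dens_change
    return num / (num + (1.0 - h) * dens_stable)


def relative_uncertainty_update(
    delta: float, tau: float, omega: float, noise_sd: float
) -> float:
    """One-step update of relative uncertainty after observing an outcome.

    The posterior over the mean is a mixture of the "no change" and "change"
    branches; matching its variance gives

    ``N = omega*sigma_n^2 + (1-omega)*tau*sigma_n^2
         + omega*(1-omega)*(delta*(1-tau))^2``

    and the new relative uncertainty ``tau' = N / (N + sigma_n^2)``. At
    ``omega = 0`` this reduces to ``tau/(tau+1)`` (slow decay with stable
    observations); at ``omega = 1`` it resets to 0.5 (one observation's worth
    of information about a fresh mean).
    """
    s2 = noise_sd * noise_sd
    n = omega * s2 + (1.0 - omega) * tau * s2
    n += omega * (1.0 - omega) * (delta * (1.0 - tau)) ** 2
    return n / (n + s2)


def model_learning_rate(omega: float, tau: float) -> float:
    """Normative learning rate ``alpha = omega + (1 - omega) * tau``."""
    return omega + (1.0 - omega) * tau


def _per_trial_noise(
    n_trials: int,
    run: np.ndarray,
    cfg: ObserverConfig,
    run_noise_map: dict[int, float] | Sequence[float] | None,
) -> np.ndarray:
    if run_noise_map is None:
        return np.full(n_trials, cfg.noise_sd, dtype=float)
    if isinstance(run_noise_map, dict):
        return np.array([run_noise_map[int(r)] for r in run], dtype=float)
    arr = np.asarray(run_noise_map, dtype=float)
    return arr[run]


def run_observer(
    outcomes: np.ndarray,
    cfg: ObserverConfig,
    *,
    predictions: np.ndarray | None = None,
    run: np.ndarray | None = None,
    run_noise_map: dict[int, float] | Sequence[float] | None = None,
    missing: np.ndarray | None = None,
    initial_belief: float = 50.0,
) -> ObserverTrace:
    """Run the CPP/RU/LR recursions over a session.

    Parameters
    ----------
    outcomes:
        Observed outcome locations per trial (screen units, finite).
    cfg:
        Observer configuration; in ``empirical`` mode ``predictions`` must be
        supplied (NaN predictions mark missing trials).
    run:
        Run index per trial; relative uncertainty resets to ``tau_init`` and
        (in self mode) the belief resets to ``initial_belief`` at each run
        boundary. Defaults to a single run.
    run_noise_map:
        Noise SD per run (dict or sequence indexed by run); defaults to
        ``cfg.noise_sd`` everywhere.
    missing:
        Boolean flags; missing trials propagate the observer state according
        to ``cfg.missing_policy`` and carry NaN cpp/lr/pe.
    """
    x = np.asarray(outcomes, dtype=float)
    n = len(x)
    if run is None:
        run = np.zeros(n, dtype=int)
    else:
        run = np.asarray(run, dtype=int)
    if cfg.conditioning == "empirical":
        if predictions is None:
            raise ValueError("empirical conditioning requires predictions")
        predictions = np.asarray(predictions, dtype=float)
        if len(predictions) != n:
            raise ValueError(
                f"length mismatch: {len(predictions)} predictions vs {n} outcomes"
            )
    if missing is None:
        if cfg.conditioning == "empirical":
            missing = ~np.isfinite(predictions)
        else:
            missing = np.zeros(n, dtype=bool)
    else:
        missing = np.asarray(missing, dtype=bool)
    if not np.all(np.isfinite(x[~missing])):
        raise ValueError("outcomes must be finite on non-missing trials")

    sd = _per_trial_noise(n, run, cfg, run_noise_map)
    belief = np.empty(n)
    pe = np.full(n, np.nan)
    cpp = np.full(n, np.nan)
    ru = np.empty(n)
    lr = np.full(n, np.nan)

    tau = cfg.tau_init
    b = initial_belief
    prev_run = None
    for t in range(n):
        if run[t] != prev_run:
            tau = cfg.tau_init
            b = initial_belief
            prev_run = run[t]
        if cfg.conditioning == "empirical" and np.isfinite(predictions[t]):
            b = float(predictions[t])
        belief[t] = b
        ru[t] = tau
        if missing[t]:
            if cfg.missing_policy == "advance":
                d = x[t] - b
                om = change_point_probability(d, tau, cfg, sd[t])
                tau = relative_uncertainty_update(d, tau, om, sd[t])
                if cfg.conditioning == "self":
                    b = b + model_learning_rate(om, tau) * d
            continue
        d = x[t] - b
        om = change_point_probability(d, tau, cfg, sd[t])
        al = model_learning_rate(om, tau)
        pe[t] = d
        cpp[t] = om
        lr[t] = al
        tau = relative_uncertainty_update(d, tau, om, sd[t])
        if cfg.conditioning == "self":
            b = b + al * d

    return ObserverTrace(belief=belief, pe=pe, cpp=cpp, ru=ru, lr=lr, run=run)


def full_bayes_oracle(
    outcomes: np.ndarray,
    cfg: ObserverConfig,
    *,
    run: np.ndarray | None = None,
    run_noise_map: dict[int, float] | Sequence[float] | None = None,
    grid_resolution: int = 401,
    scale: tuple[float, float] = (0.0, 100.0),
) -> pd.DataFrame:
    """Exact Bayesian filtering on a discretized hidden mean (validation only).

    The hidden mean lives on a uniform grid over ``scale``; each trial it
    relocates with probability ``cfg.hazard`` to a uniform draw, and the
    outcome likelihood is Gaussian with the (known) run noise SD. Returns a
    frame with per-trial columns ``post_mean`` (posterior mean after seeing
    the outcome) and ``change_prob`` (posterior change-point probability).
    """
    if grid_resolution < 201:
        raise ValueError("grid_resolution must be at least 201 points")
    x = np.asarray(outcomes, dtype=float)
    n = len(x)
    if run is None:
        run = np.zeros(n, dtype=int)
    else:
        run = np.asarray(run, dtype=int)
    sd = _per_trial_noise(n, run, cfg, run_noise_map)

    grid = np.linspace(scale[0], scale[1], grid_resolution)
    uniform = np.full(grid_resolution, 1.0 / grid_resolution)
    h = cfg.hazard

    post_mean = np.empty(n)
    change_prob = np.empty(n)
    prior = uniform.copy()
    prev_run = None
    for t in range(n):
        if run[t] != prev_run:
            prior = uniform.copy()
            prev_run = run[t]
        lik = np.exp(-0.5 * ((x[t] - grid) / sd[t]) ** 2) / (sd[t] * _SQRT_2PI)
        ev_change = h * float(uniform @ lik)
        ev_stay = (1.0 - h) * float(prior @ lik)
        change_prob[t] = ev_change / (ev_change + ev_stay)
        pred = (1.0 - h) * prior + h * uniform
        post = pred * lik
        post /= post.sum()
        post_mean[t] = float(post @ grid)
        prior = post

    return pd.DataFrame(
        {"run": run, "trial": np.arange(n), "post_mean": post_mean, "change_prob": change_prob}
    )
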