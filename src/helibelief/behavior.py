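"""Behavioural statistics for the predictive inference task.

Trial-wise empirical learning rates (update divided by the preceding
prediction error, clipped to [0, 1] for aggregation), update-category
fractions, performance error against the hidden mean, the belief-update
regression with CPP/RU interaction regressors, automated exclusion
screening, and the group/symptom-level models (Welch + Wilcoxon group
comparisons, logistic regression of group status on model coefficients,
linear symptom regressions, cognitive composite z-scores).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .observer import ObserverTrace
from .taskgen import BehaviorRecord, TaskSchedule

__all__ = [
    "LearningRateSummary",
    "UpdateRegressionResult",
    "empirical_learning_rates",
    "categorize_updates",
    "performance_error",
    "post_changepoint_learning",
    "fit_update_regression",
    "exclusion_screen",
    "group_compare",
    "fit_group_logistic",
    "fit_symptom_regressions",
    "bacs_composite",
]

logger = logging.getLogger(__name__)

#: Trials with |PE| below this floor are excluded from LR computation
#: (raw LR is undefined/explosive at PE ~ 0).
PE_FLOOR = 1.0

#: Default update-category bounds (figure-caption convention):
#: non-update LR < 0.1, moderate 0.1 <= LR < 0.9, total LR >= 0.9.
CATEGORY_BOUNDS = (0.1, 0.9)

#: Raw LRs below this mark aberrant responding (opposite-direction updates
#: beyond noise) for the switchable follow-up filter.
ABERRANT_LR = -0.1


@dataclass
class LearningRateSummary:
    raw_lr: np.ndarray
    clipped_lr: np.ndarray
    mean_lr: float
    mean_lr_post_cp: float
    frac_non: float
    frac_moderate: float
    frac_total: float
    n_aberrant: int
    n_trials: int


@dataclass
class UpdateRegressionResult:
    """Per-subject belief-update regression output.

    ``coef`` maps regressor name to its OLS estimate; ``residuals`` is
    full-session length with NaN on trials excluded from the fit (missing
    predictions, run-final trials, dropped columns do not affect rows).
    """

    coef: dict[str, float]
    pvalues: dict[str, float]
    r2: float
    residuals: np.ndarray
    n_trials: int
    dropped: list[str] = field(default_factory=list)


def _lr_arrays(record: BehaviorRecord, pe_floor: float = PE_FLOOR):
    pe = record.pe
    update = record.update
    valid = np.isfinite(pe) & np.isfinite(update) & (np.abs(pe) >= pe_floor)
    return pe, update, valid


def empirical_learning_rates(
    record: BehaviorRecord,
    schedule: TaskSchedule | None = None,
    *,
    pe_floor: float = PE_FLOOR,
    bounds: tuple[float, float] = CATEGORY_BOUNDS,
    exclude_aberrant: bool = False,
) -> LearningRateSummary:
    """Trial-wise learning rates LR_t = update_t / pe_t with clipping.

    ``update_t`` is the belief revision that follows the prediction error of
    trial ``t``. For aggregate statistics LRs above 1 are set to 1 and
    negative LRs to 0; raw values are retained so that strongly negative LRs
    (< -0.1, likely aberrant responding) can be counted and, with
    ``exclude_aberrant``, removed from the aggregates.
    """
    pe, update, valid = _lr_arrays(record, pe_floor)
    if not valid.any():
        raise ValueError("no valid trials: all predictions missing or PE below floor")
    raw = np.full(len(record), np.nan)
    raw[valid] = update[valid] / pe[valid]
    n_aberrant = int(np.sum(raw[valid] < ABERRANT_LR))
    use = valid.copy()
    if exclude_aberrant:
        use &= ~(raw < ABERRANT_LR)
    clipped = np.clip(raw, 0.0, 1.0)
    frac_non, frac_mod, frac_tot = categorize_updates(clipped[use], bounds=bounds)
    if schedule is not None:
        mean_post = post_changepoint_learning(record, schedule, pe_floor=pe_floor)
    else:
        mean_post = np.nan
    return LearningRateSummary(
        raw_lr=raw,
        clipped_lr=np.where(use, clipped, np.nan),
        mean_lr=float(np.mean(clipped[use])),
        mean_lr_post_cp=mean_post,
        frac_non=frac_non,
        frac_moderate=frac_mod,
        frac_total=frac_tot,
        n_aberrant=n_aberrant,
        n_trials=int(use.sum()),
    )


def categorize_updates(
    clipped_lr: np.ndarray, bounds: tuple[float, float] = CATEGORY_BOUNDS
) -> tuple[float, float, float]:
    """Fractions of non- (< low), moderate- and total- (>= high) updates."""
    lr = np.asarray(clipped_lr, dtype=float)
    lr = lr[np.isfinite(lr)]
    if lr.size == 0:
        return (np.nan, np.nan, np.nan)
    if np.any((lr < 0) | (lr > 1)):
        raise ValueError("clipped LRs must lie in [0, 1]")
    low, high = bounds
    n = lr.size
    non = float(np.sum(lr < low)) / n
    total = float(np.sum(lr >= high)) / n
    return (non, 1.0 - non - total, total)


def performance_error(
    record: BehaviorRecord, schedule: TaskSchedule, mode: str = "mean"
) -> float:
    """Deviance |prediction - hidden mean| of each block, aggregated.

    Blocks are stretches sharing one hidden mean (separated by change
    points). ``mode="sum"`` sums the deviance within each block and then
    across blocks (the raw summed-deviance reading); ``mode="mean"``, the
    default, divides that total by the number of trials, i.e. a per-trial
    average on the scale of the cohort summary table. Missing trials are
    excluded.
    """
    if len(record) != len(schedule):
        raise ValueError("record and schedule lengths differ")
    dev = np.abs(record.prediction - schedule.mean)
    block = np.cumsum(schedule.is_change_point.astype(int))
    ok = np.isfinite(dev)
    per_block = pd.DataFrame({"block": block[ok], "dev": dev[ok]}).groupby("block")["dev"].sum()
    if mode == "mean":
        return float(per_block.sum() / ok.sum())
    if mode == "sum":
        return float(per_block.sum())
    raise ValueError(f"unknown mode {mode!r}")


def post_changepoint_learning(
    record: BehaviorRecord,
    schedule: TaskSchedule,
    *,
    window: int = 1,
    pe_floor: float = PE_FLOOR,
) -> float:
    """Mean clipped LR in response to outcomes at (and ``window-1`` after) change points.

    Uses the schedule's true change-point flags; the LR at the change trial
    is the update that follows the first outcome from the relocated mean,
    i.e. the fast-updating response the task rewards.
    """
    if not schedule.is_change_point.any():
        raise ValueError("schedule contains no change points")
    pe, update, valid = _lr_arrays(record, pe_floor)
    sel = np.zeros(len(record), dtype=bool)
    cp_idx = np.flatnonzero(schedule.is_change_point)
    for k in range(window):
        idx = cp_idx + k
        idx = idx[idx < len(record)]
        sel[idx] = True
    use = sel & valid
    if not use.any():
        return np.nan
    lr = np.clip(update[use] / pe[use], 0.0, 1.0)
    return float(np.mean(lr))


_REGRESSOR_NAMES = ("pe", "pe_x_cpp", "pe_x_ru", "reward", "edge")


def fit_update_regression(
    record: BehaviorRecord,
    trace: ObserverTrace,
    *,
    midpoint: float = 50.0,
    halfwidth: float = 50.0,
    reward_coding: str = "interaction",
) -> UpdateRegressionResult:
    """OLS of the trial-wise belief update on model-derived regressors.

    Regressors (all centred before entering the fit, plus an intercept for a
    left/rightward tendency): the signed PE, PE x CPP, PE x RU x (1 - CPP),
    the reward term (PE x reward by default, a main-effect binary with
    ``reward_coding="main"``) and the cubic edge term
    ``((prediction - midpoint)/halfwidth)^3``. CPP and RU enter as
    interactions with PE so each captures its unique contribution to the
    update. Zero-variance columns are dropped with a logged warning. The
    per-trial residuals (NaN where excluded) feed the fMRI modulator stage.
    """
    pe = record.pe
    update = record.update
    r = record.reward.astype(float)
    reward_term = pe * r if reward_coding == "interaction" else r
    edge = ((record.prediction - midpoint) / halfwidth) ** 3
    cols = {
        "pe": pe,
        "pe_x_cpp": pe * trace.cpp,
        "pe_x_ru": pe * trace.ru * (1.0 - trace.cpp),
        "reward": reward_term,
        "edge": edge,
    }
    X = pd.DataFrame(cols)
    ok = np.isfinite(update) & np.all(np.isfinite(X.to_numpy()), axis=1)
    if ok.sum() < len(cols) + 2:
        raise ValueError("too few valid trials for the update regression")
    Xv = X.loc[ok]
    dropped = [c for c in Xv.columns if np.std(Xv[c].to_numpy()) < 1e-12]
    if dropped:
        logger.warning("dropping zero-variance regressor(s): %s", dropped)
        Xv = Xv.drop(columns=dropped)
    Xc = Xv - Xv.mean()
    design = sm.add_constant(Xc, prepend=True)
    fit = sm.OLS(update[ok], design).fit()
    coef = {"intercept": float(fit.params["const"])}
    pvals = {"intercept": float(fit.pvalues["const"])}
    for name in _REGRESSOR_NAMES:
        coef[name] = float(fit.params.get(name, np.nan))
        pvals[name] = float(fit.pvalues.get(name, np.nan))
    residuals = np.full(len(record), np.nan)
    residuals[np.flatnonzero(ok)] = fit.resid
    return UpdateRegressionResult(
        coef=coef,
        pvalues=pvals,
        r2=float(fit.rsquared),
        residuals=residuals,
        n_trials=int(ok.sum()),
        dropped=dropped,
    )


def exclusion_screen(
    record: BehaviorRecord,
    *,
    missing_frac_max: float = 0.25,
    random_corr_floor: float = 0.2,
    repetitive_var_floor: float = 1.0,
) -> dict[str, bool]:
    """Advisory data-quality flags; nothing is dropped silently.

    Flags a subject when more than 25% of trials are missing, when
    predictions do not track outcomes (correlation below floor - the
    automated proxy for visually identified random responding), or when
    prediction variance is near zero (repetitive responding).
    """
    miss_frac = float(np.mean(record.missing))
    pred = record.prediction
    ok = np.isfinite(pred)
    repetitive = bool(np.var(pred[ok]) < repetitive_var_floor) if ok.sum() >= 2 else True
    random_flag = False
    if ok.sum() >= 3 and not repetitive:
        r = np.corrcoef(pred[ok], record.outcome[ok])[0, 1]
        random_flag = bool(np.isnan(r) or r < random_corr_floor)
    return {
        "excluded_missing": miss_frac > missing_frac_max,
        "flag_random": random_flag,
        "flag_repetitive": repetitive,
        "missing_frac": miss_frac,
    }


def _mad_outliers(x: np.ndarray, thresh: float = 3.0) -> np.ndarray:
    med = np.median(x)
    mad = stats.median_abs_deviation(x, scale="normal")
    if mad == 0:
        return np.zeros(len(x), dtype=bool)
    return np.abs(x - med) / mad > thresh


def group_compare(
    metric: np.ndarray,
    group: np.ndarray,
    *,
    exclude_outliers: bool = False,
    mad_thresh: float = 3.0,
) -> dict[str, float]:
    """Welch t-test plus Wilcoxon rank-sum between two groups.

    With ``exclude_outliers`` values more than ``mad_thresh`` normalized MADs
    from their group median are removed before testing (the sensitivity
    re-analysis); the report carries both statistics either way.
    """
    metric = np.asarray(metric, dtype=float)
    group = np.asarray(group)
    a = metric[group == 0]
    b = metric[group == 1]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    n_excluded = 0
    if exclude_outliers:
        keep_a, keep_b = ~_mad_outliers(a, mad_thresh), ~_mad_outliers(b, mad_thresh)
        n_excluded = int((~keep_a).sum() + (~keep_b).sum())
        a, b = a[keep_a], b[keep_b]
    t, p_t = stats.ttest_ind(a, b, equal_var=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ties warning on discrete metrics
        w, p_w = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "mean_hc": float(np.mean(a)),
        "mean_psd": float(np.mean(b)),
        "sd_hc": float(np.std(a, ddof=1)),
        "sd_psd": float(np.std(b, ddof=1)),
        "t": float(t),
        "p_t": float(p_t),
        "wilcoxon_u": float(w),
        "p_wilcoxon": float(p_w),
        "n_excluded": n_excluded,
    }


def fit_group_logistic(
    coef_table: pd.DataFrame,
    group: np.ndarray,
    covariates: pd.DataFrame | None = None,
    predictors: tuple[str, ...] = ("pe", "pe_x_cpp", "pe_x_ru", "reward"),
) -> pd.DataFrame:
    """Logistic regression of group status on per-subject update coefficients.

    Optional covariates (age, cognitive domains) enter as main effects. On
    (quasi-)separation the fit falls back to an L2-penalized logistic
    regression (coefficients reported, Wald p-values set to NaN) with a
    logged warning. Returns a frame indexed by predictor with columns
    ``coef``, ``z``, ``p``.
    """
    X = coef_table.loc[:, list(predictors)].copy()
    if covariates is not None:
        for c in covariates.columns:
            X[c] = covariates[c].to_numpy()
    if (X.std() < 1e-12).any():
        bad = list(X.columns[X.std() < 1e-12])
        raise ValueError(f"constant predictor column(s): {bad}")
    y = np.asarray(group, dtype=float)
    design = sm.add_constant(X, prepend=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=False, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        if (
            not converged
            or not np.all(np.isfinite(fit.bse))
            or np.max(np.abs(fit.params)) > 1e3
            or np.max(fit.bse) > 1e3
        ):
            raise np.linalg.LinAlgError("unstable logistic fit (separation)")
        out = pd.DataFrame(
            {"coef": fit.params, "z": fit.tvalues, "p": fit.pvalues}
        )
    except (np.linalg.LinAlgError, PerfectSeparationError):
        logger.warning("separation in group logistic; using L2-penalized fallback")
        from sklearn.linear_model import LogisticRegression

        Xs = (X - X.mean()) / X.std()
        lr = LogisticRegression(C=1.0, max_iter=1000).fit(Xs.to_numpy(), y)
        coefs = lr.coef_.ravel() / X.std().to_numpy()  # back to raw scale
        out = pd.DataFrame(
            {
                "coef": np.concatenate([[lr.intercept_[0]], coefs]),
                "z": np.nan,
                "p": np.nan,
            },
            index=["const"] + list(X.columns),
        )
        out.attrs["penalized"] = True
    out.attrs.setdefault("penalized", False)
    return out


def fit_symptom_regressions(
    outcome: np.ndarray,
    predictors: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """OLS of a symptom score (or performance) on model coefficients.

    Used for delusional-ideation scores across the whole sample and symptom
    scales within the clinical group, optionally controlling for cognitive
    covariates. Rows with any NaN are dropped listwise.
    """
    X = predictors.copy()
    if covariates is not None:
        for c in covariates.columns:
            X[c] = covariates[c].to_numpy()
    y = np.asarray(outcome, dtype=float)
    ok = np.isfinite(y) & np.all(np.isfinite(X.to_numpy()), axis=1)
    if ok.sum() <= X.shape[1] + 1:
        raise ValueError("too few complete observations for the regression")
    fit = sm.OLS(y[ok], sm.add_constant(X.loc[ok], prepend=True)).fit()
    return pd.DataFrame({"coef": fit.params, "t": fit.tvalues, "p": fit.pvalues})


def bacs_composite(
    scores: pd.DataFrame, reference: pd.DataFrame
) -> np.ndarray:
    """Cognitive composite: per-domain z against reference (control) stats, averaged.

    ``reference`` has one row per domain with columns ``mean`` and ``sd``
    (typically the control group's). Domains with zero reference SD raise.
    """
    zs = []
    for dom in scores.columns:
        m = float(reference.loc[dom, "mean"])
        s = float(reference.loc[dom, "sd"])
        if s == 0:
            raise ValueError(f"zero reference SD for domain {dom!r}")
        zs.append((scores[dom].to_numpy(dtype=float) - m) / s)
    return np.nanmean(np.column_stack(zs), axis=1)
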