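"""Tests for learning-rate statistics, the update regression and group models."""

import numpy as np
import pandas as pd
import pytest

from helibelief.behavior import (
    bacs_composite,
    categorize_updates,
    empirical_learning_rates,
    exclusion_screen,
    fit_group_logistic,
    fit_symptom_regressions,
    fit_update_regression,
    group_compare,
    performance_error,
    post_changepoint_learning,
)
from helibelief.observer import ObserverConfig, run_observer
from helibelief.taskgen import (
    BehaviorRecord,
    TaskConfig,
    fixed_lr_params,
    generate_schedule,
    simulate_agent,
    simulate_normative_agent,
)


def _record_from(predictions, outcomes, run=None, reward=None):
    predictions = np.asarray(predictions, dtype=float)
    n = len(predictions)
    outcomes = np.asarray(outcomes, dtype=float)
    run = np.zeros(n, dtype=int) if run is None else np.asarray(run)
    reward = np.zeros(n, dtype=bool) if reward is None else np.asarray(reward)
    return BehaviorRecord(
        prediction=predictions,
        outcome=outcomes,
        reward=reward,
        missing=~np.isfinite(predictions),
        run=run,
        caught=np.zeros(n, dtype=bool),
    )


class TestEmpiricalLearningRates:
    def test_clipping_rules(self):
        """LR = update/PE; negatives clip to 0 and values above 1 clip to 1."""
        # predictions 50, 60, 45, 80 with outcomes placed to give PEs 20, 20, 20
        rec = _record_from([50, 60, 45, 80], [70, 80, 65, 50])
        s = empirical_learning_rates(rec)
        assert s.raw_lr[0] == pytest.approx(0.5)      # U=10 after PE=20
        assert s.raw_lr[1] == pytest.approx(-0.75)    # U=-15 after PE=20
        assert s.raw_lr[2] == pytest.approx(1.75)     # U=35 after PE=20
        assert s.clipped_lr[0] == pytest.approx(0.5)
        assert s.clipped_lr[1] == 0.0
        assert s.clipped_lr[2] == 1.0
        assert s.n_aberrant == 1  # raw -0.75 < -0.1

    def test_aberrant_exclusion_switch(self):
        rec = _record_from([50, 60, 45, 80], [70, 80, 65, 50])
        kept = empirical_learning_rates(rec, exclude_aberrant=True)
        assert kept.n_trials == 2  # the -0.75 trial dropped

    def test_small_pe_trials_excluded(self):
        """Trials with |PE| below the floor are excluded (LR undefined at PE~0)."""
        rec = _record_from([50, 50, 70], [50.4, 70, 70])
        s = empirical_learning_rates(rec)
        assert np.isnan(s.raw_lr[0])
        assert s.n_trials == 1

    def test_all_missing_raises(self):
        rec = _record_from([np.nan, np.nan, np.nan], [50, 50, 50])
        with pytest.raises(ValueError, match="no valid trials"):
            empirical_learning_rates(rec)


class TestCategorizeUpdates:
    def test_caption_bounds(self):
        """Non-update below 0.1, total at/above 0.9 (figure-caption convention)."""
        non, mod, tot = categorize_updates(np.array([0.05, 0.95, 0.5]))
        assert (non, mod, tot) == (pytest.approx(1 / 3),) * 3
        assert categorize_updates(np.array([0.9]))[2] == 1.0
        assert categorize_updates(np.array([0.1]))[1] == 1.0

    def test_alternative_body_text_bound(self):
        non, _, _ = categorize_updates(np.array([0.005, 0.05]), bounds=(0.01, 0.9))
        assert non == pytest.approx(0.5)

    def test_invariant_under_permutation(self, rng):
        lrs = rng.uniform(0, 1, 100)
        assert categorize_updates(lrs) == categorize_updates(rng.permutation(lrs))

    def test_fractions_sum_to_one(self, rng):
        fracs = categorize_updates(rng.uniform(0, 1, 57))
        assert sum(fracs) == pytest.approx(1.0)


class TestPerformanceError:
    def test_exact_tracking_and_constant_offset(self, short_schedule):
        perfect = _record_from(short_schedule.mean, short_schedule.outcome,
                               run=short_schedule.run)
        assert performance_error(perfect, short_schedule) == 0.0
        offset = _record_from(short_schedule.mean + 3, short_schedule.outcome,
                              run=short_schedule.run)
        assert performance_error(offset, short_schedule) == pytest.approx(3.0)

    def test_sum_mode_larger_than_mean_mode(self, short_schedule):
        rec = simulate_agent(short_schedule, fixed_lr_params(1.0), seed=0)
        assert performance_error(rec, short_schedule, mode="sum") > performance_error(
            rec, short_schedule, mode="mean"
        )

    def test_normative_beats_full_update(self):
        wins = []
        for seed in range(30):
            s = generate_schedule(TaskConfig(seed=800 + seed))
            wins.append(
                performance_error(simulate_normative_agent(s, seed=seed), s)
                < performance_error(simulate_agent(s, fixed_lr_params(1.0), seed=seed), s)
            )
        assert np.mean(wins) > 0.5

    def test_misaligned_lengths_raise(self, short_schedule):
        rec = _record_from([50, 60], [55, 65])
        with pytest.raises(ValueError, match="lengths differ"):
            performance_error(rec, short_schedule)


class TestPostChangePointLearning:
    def test_delta_rule_and_frozen_agents(self, default_schedule):
        fast = simulate_agent(default_schedule, fixed_lr_params(1.0), seed=0)
        slow = simulate_agent(default_schedule, fixed_lr_params(0.0), seed=0)
        assert post_changepoint_learning(fast, default_schedule) == pytest.approx(1.0)
        assert post_changepoint_learning(slow, default_schedule) == pytest.approx(0.0)

    def test_normative_post_cp_exceeds_overall(self, default_schedule):
        """CPP spikes at change points, so the normative post-CP LR beats its mean LR."""
        rec = simulate_normative_agent(default_schedule, seed=1)
        summary = empirical_learning_rates(rec, default_schedule)
        assert summary.mean_lr_post_cp > summary.mean_lr

    def test_no_change_points_raises(self):
        s = generate_schedule(TaskConfig(hazard=0.0, seed=1))
        s.is_change_point[:] = False
        rec = simulate_agent(s, fixed_lr_params(1.0), seed=0)
        with pytest.raises(ValueError, match="no change points"):
            post_changepoint_learning(rec, s)


class TestUpdateRegression:
    def test_noiseless_delta_rule_exact(self, short_schedule):
        """A pure delta-rule agent recovers beta_PE = 1 and R^2 = 1 exactly."""
        rec = simulate_agent(short_schedule, fixed_lr_params(1.0), seed=0)
        cfg = ObserverConfig(noise_sd=2.3, conditioning="empirical")
        tr = run_observer(rec.outcome, cfg, predictions=rec.prediction,
                          run=rec.run, missing=rec.missing)
        res = fit_update_regression(rec, tr)
        assert res.coef["pe"] == pytest.approx(1.0, abs=1e-10)
        for name in ("pe_x_cpp", "pe_x_ru", "edge"):
            assert res.coef[name] == pytest.approx(0.0, abs=1e-8)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_residual_orthogonality(self, hc_record, hc_trace):
        """OLS residuals are numerically orthogonal to every design column."""
        res = fit_update_regression(hc_record, hc_trace)
        ok = np.isfinite(res.residuals)
        r = res.residuals[ok]
        pe = hc_record.pe[ok]
        for col in (pe, pe * hc_trace.cpp[ok], pe * hc_trace.ru[ok] * (1 - hc_trace.cpp[ok])):
            c = np.corrcoef(r, col)[0, 1]
            assert abs(c) < 1e-8
        assert abs(r.mean()) < 1e-10

    def test_constant_reward_column_dropped(self, short_schedule):
        rec = simulate_agent(short_schedule, fixed_lr_params(0.8), seed=2)
        rec.reward[:] = False  # reward term identically zero
        cfg = ObserverConfig(noise_sd=2.3, conditioning="empirical")
        tr = run_observer(rec.outcome, cfg, predictions=rec.prediction,
                          run=rec.run, missing=rec.missing)
        res = fit_update_regression(rec, tr)
        assert "reward" in res.dropped
        assert np.isnan(res.coef["reward"])

    def test_pure_noise_null_coverage(self):
        """Updates independent of all regressors: 95% CIs cover 0 at ~nominal rate."""
        rng = np.random.default_rng(42)
        cover = {"pe": 0, "pe_x_cpp": 0, "pe_x_ru": 0}
        n_seeds = 100
        s = generate_schedule(TaskConfig(n_runs=1, trials_per_run=120,
                                         noise_sd_by_run=(2.3,), seed=1))
        for _ in range(n_seeds):
            preds = rng.uniform(20, 80, len(s))
            rec = _record_from(preds, s.outcome, run=s.run,
                               reward=s.reward)
            # overwrite updates with pure noise by resampling predictions
            cfg = ObserverConfig(noise_sd=2.3, conditioning="empirical")
            tr = run_observer(rec.outcome, cfg, predictions=rec.prediction,
                              run=rec.run, missing=rec.missing)
            res = fit_update_regression(rec, tr)
            for k in cover:
                cover[k] += res.pvalues[k] >= 0.05
        for k, c in cover.items():
            assert 0.87 <= c / n_seeds <= 1.0, k


class TestExclusionScreen:
    def test_missing_fraction_rule(self, default_schedule):
        pred = default_schedule.mean.copy()
        pred[:71] = np.nan  # 71 of 280 missing (> 25%)
        rec = _record_from(pred, default_schedule.outcome, run=default_schedule.run)
        assert exclusion_screen(rec)["excluded_missing"]
        pred2 = default_schedule.mean.copy()
        pred2[:70] = np.nan  # exactly 25%: not excluded
        rec2 = _record_from(pred2, default_schedule.outcome, run=default_schedule.run)
        assert not exclusion_screen(rec2)["excluded_missing"]

    def test_repetitive_and_random_proxies(self, default_schedule):
        const = _record_from(np.full(280, 50.0), default_schedule.outcome,
                             run=default_schedule.run)
        assert exclusion_screen(const)["flag_repetitive"]
        rng = np.random.default_rng(0)
        rand = _record_from(rng.uniform(0, 100, 280), default_schedule.outcome,
                            run=default_schedule.run)
        assert exclusion_screen(rand)["flag_random"]

    def test_normative_agent_clean(self, default_schedule):
        rec = simulate_normative_agent(default_schedule, seed=0)
        flags = exclusion_screen(rec)
        assert not any(flags[k] for k in ("excluded_missing", "flag_random", "flag_repetitive"))


class TestGroupCompare:
    def test_identical_groups(self, rng):
        x = rng.normal(0, 1, 60)
        res = group_compare(np.concatenate([x, x]), np.repeat([0, 1], 60))
        assert abs(res["t"]) < 1e-10
        assert res["p_t"] > 0.99

    def test_constant_shifted_groups(self):
        metric = np.concatenate([np.full(10, 1.0), np.full(10, 2.0)])
        metric += np.linspace(0, 1e-9, 20)  # break exact ties
        res = group_compare(metric, np.repeat([0, 1], 10))
        assert res["p_t"] < 1e-10

    def test_power_matches_welch_closed_form(self):
        """Rejection rate at a 1-SD shift (n=40 vs 19) matches noncentral-t power."""
        from scipy import stats

        n1, n2, d = 40, 19, 1.0
        se = np.sqrt(1 / n1 + 1 / n2)
        df = n1 + n2 - 2
        nc = d / se
        tcrit = stats.t.ppf(0.975, df)
        power = 1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        rng = np.random.default_rng(7)
        rejections = 0
        n_seeds = 500
        for _ in range(n_seeds):
            m = np.concatenate([rng.normal(0, 1, n1), rng.normal(d, 1, n2)])
            rejections += group_compare(m, np.repeat([0, 1], [n1, n2]))["p_t"] < 0.05
        se_sim = np.sqrt(power * (1 - power) / n_seeds)
        assert abs(rejections / n_seeds - power) < 4 * se_sim + 0.01

    def test_mad_outlier_exclusion(self):
        a = np.concatenate([np.random.default_rng(1).normal(0, 1, 20), [40.0]])
        b = np.random.default_rng(2).normal(0, 1, 20)
        res = group_compare(np.concatenate([a, b]), np.repeat([0, 1], [21, 20]),
                            exclude_outliers=True)
        assert res["n_excluded"] >= 1

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            group_compare(np.arange(5.0), np.array([0, 0, 0, 0, 1]))


class TestGroupLogistic:
    def test_balanced_flipped_labels_symmetry(self, rng):
        """Duplicated subjects with flipped labels: all slopes ~ 0."""
        base = pd.DataFrame(rng.normal(0, 1, (30, 4)),
                            columns=["pe", "pe_x_cpp", "pe_x_ru", "reward"])
        ct = pd.concat([base, base], ignore_index=True)
        labels = np.concatenate([np.zeros(30), np.ones(30)])
        res = fit_group_logistic(ct, labels)
        for name in ("pe", "pe_x_cpp", "pe_x_ru", "reward"):
            assert abs(res.loc[name, "coef"]) < 1e-6

    def test_constant_column_raises(self, rng):
        ct = pd.DataFrame({"pe": np.ones(20), "pe_x_cpp": rng.normal(size=20),
                           "pe_x_ru": rng.normal(size=20), "reward": rng.normal(size=20)})
        with pytest.raises(ValueError, match="constant"):
            fit_group_logistic(ct, np.repeat([0, 1], 10))

    def test_separation_falls_back_to_penalized(self, rng):
        ct = pd.DataFrame({
            "pe": np.concatenate([rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10)]),
            "pe_x_cpp": rng.normal(size=20),
            "pe_x_ru": rng.normal(size=20),
            "reward": rng.normal(size=20),
        })
        res = fit_group_logistic(ct, np.repeat([0, 1], 10))
        assert res.attrs["penalized"]
        assert res.loc["pe", "coef"] > 0


class TestSymptomRegressions:
    def test_zero_noise_exact_recovery(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (40, 2)), columns=["pe_x_cpp", "pe_x_ru"])
        y = 3.0 + 2.5 * X["pe_x_ru"].to_numpy()
        res = fit_symptom_regressions(y, X)
        assert res.loc["pe_x_ru", "coef"] == pytest.approx(2.5, abs=1e-10)
        assert res.loc["pe_x_cpp", "coef"] == pytest.approx(0.0, abs=1e-10)

    def test_sign_recovery_under_noise(self, rng):
        hits = 0
        for _ in range(50):
            X = pd.DataFrame(rng.normal(0, 1, (59, 2)), columns=["pe_x_cpp", "pe_x_ru"])
            y = 5 + 4 * X["pe_x_ru"].to_numpy() + rng.normal(0, 2, 59)
            res = fit_symptom_regressions(y, X)
            hits += res.loc["pe_x_ru", "coef"] > 0 and res.loc["pe_x_ru", "p"] < 0.05
        assert hits >= 48

    def test_too_few_rows_raises(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (3, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            fit_symptom_regressions(np.ones(3), X)


class TestBacsComposite:
    def test_reference_anchoring(self):
        ref = pd.DataFrame({"mean": [50.0, 20.0], "sd": [10.0, 5.0]},
                           index=["verbal_memory", "attention"])
        scores = pd.DataFrame({"verbal_memory": [50.0, 60.0, 40.0],
                               "attention": [20.0, 25.0, 25.0]})
        z = bacs_composite(scores, ref)
        assert z[0] == pytest.approx(0.0)
        assert z[1] == pytest.approx(1.0)
        assert z[2] == pytest.approx(0.0)  # -1 and +1 average to 0

    def test_zero_reference_sd_raises(self):
        ref = pd.DataFrame({"mean": [50.0], "sd": [0.0]}, index=["attention"])
        with pytest.raises(ValueError, match="zero reference SD"):
            bacs_composite(pd.DataFrame({"attention": [50.0]}), ref)
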