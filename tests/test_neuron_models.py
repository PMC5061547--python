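"""Single-neuron statistics: screening, model fits, contests, sliding windows."""

import math

import numpy as np
import pandas as pd
import pytest

from saveseq import neuron_models as nm
from saveseq import session_io as io
from saveseq import synthetic_data as sd
from saveseq.regression import RegressionFit, ols_fit, simple_regression_pvalues

from conftest import make_counts


def _dummy_fit(r2, model_p, model_id="A", slope=1.0, slope_p=0.01):
    return RegressionFit(
        model_id=model_id,
        params=pd.Series({"const": 0.0, "x": slope}),
        pvalues=pd.Series({"const": 1.0, "x": slope_p}),
        standardized=pd.Series({"x": slope}),
        r_squared=r2, residuals=np.zeros(5), n_trials=5,
        model_pvalue=model_p,
    )


class TestOlsAgainstNormalEquations:
    def test_small_instance_matches_oracle(self, rng):
        n = 10
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = 1.5 + 2.0 * X["a"] - 0.5 * X["b"] + rng.normal(0, 0.1, n)
        fit = ols_fit(X, y.to_numpy())
        Xc = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y.to_numpy())
        assert np.allclose(fit.params[["const", "a", "b"]], beta, atol=1e-10)

    def test_vectorized_pvalues_match_ols(self, rng):
        n = 40
        x = rng.normal(size=n)
        Y = np.column_stack([x * 0.5 + rng.normal(0, 1, n) for _ in range(4)])
        p_vec = simple_regression_pvalues(x, Y)
        for j in range(4):
            fit = ols_fit(pd.DataFrame({"x": x}), Y[:, j])
            assert p_vec[j] == pytest.approx(fit.slope_pvalue, rel=1e-8)


class TestTaskRelatedness:
    def _counts(self, ctrl_rate, cue_rate, n=60, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for period, rate in [("pre_fixation", ctrl_rate), ("cue", cue_rate)]:
            counts = rng.poisson(rate, n)
            for i, c in enumerate(counts):
                rows.append({"neuron_id": "n0", "session_id": "S1",
                             "trial_index": i, "period": period,
                             "count": c, "rate": float(c)})
        return pd.DataFrame(rows)

    def test_zero_activity_not_related(self):
        out = nm.select_task_related(self._counts(0, 0))
        assert not out["task_related"].any()

    def test_strong_cue_response_flagged(self):
        out = nm.select_task_related(self._counts(5, 20, seed=1))
        row = out[out["period"] == "cue"].iloc[0]
        assert row["task_related"] and row["pvalue"] < 1e-6

    def test_flag_is_strict_inequality(self):
        out = nm.select_task_related(self._counts(5, 20, seed=1))
        assert (out["task_related"] == (out["pvalue"] < nm.TASK_RELATED_ALPHA)).all()

    def test_min_trials_exclusion(self):
        out = nm.select_task_related(self._counts(5, 20, n=10))
        assert len(out) == 0


class TestFitModel:
    def test_constant_counts(self, clean_trials):
        counts = make_counts(clean_trials, lambda row: 7.0)
        fit = nm.fit_model(counts, clean_trials, "eq2")
        assert fit.slope == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(0.0)

    def test_noiseless_line_recovered(self, clean_trials):
        counts = make_counts(clean_trials, lambda row: 2.0 * row["step"] + 1.0)
        fit = nm.fit_model(counts, clean_trials, "eq2")
        assert fit.params["Sequenceprogress"] == pytest.approx(2.0)
        assert fit.params["const"] == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_adaptive_gain_recovery(self, clean_trials):
        gains = []
        for i in range(12):
            spec = sd.NeuronSpec(f"g{i}", "adaptive_progress", 5.0, 12.0,
                                 target_periods=("cue",))
            spikes = sd.generate_spikes(spec, clean_trials, seed=50 + i)
            counts = io.extract_window_counts(spikes, clean_trials)
            fit = nm.fit_model(counts, clean_trials, "eq3", period="cue")
            gains.append(fit.params["AdaptiveProgress"])
        # eq3 slope estimates the configured gain (Hz at full drive)
        assert np.mean(gains) == pytest.approx(12.0, rel=0.15)

    def test_eq6_indicator_fit_matches_step_means(self, clean_trials):
        counts = make_counts(clean_trials, lambda row: float(row["step"] ** 2))
        fit = nm.fit_model(counts, clean_trials, "eq6")
        for name, val in fit.params.items():
            s = int(name.removeprefix("Step"))
            assert val == pytest.approx(s**2)
        assert fit.r_squared == pytest.approx(1.0)

    def test_eq8_contains_both_progress_regressors(self, clean_trials):
        counts = make_counts(clean_trials, lambda row: row["step"])
        fit = nm.fit_model(counts, clean_trials, "eq8")
        assert set(fit.params.index) == {"const", "Sequenceprogress", "AdaptiveProgress"}


class TestStepwise:
    def test_all_zero_counts_gives_intercept_only(self, clean_trials):
        counts = make_counts(clean_trials, lambda row: 0.0)
        fit = nm.fit_stepwise(counts, clean_trials)
        assert fit.retained == []

    def test_progress_only_neuron_selects_progress(self, clean_trials, rng):
        hits, other_value_hits = 0, 0
        n_rep = 25
        for i in range(n_rep):
            noise = rng.normal(0, 1.0, (~clean_trials["error"]).sum())
            it = iter(noise)
            counts = make_counts(clean_trials,
                                 lambda row: 5.0 + 2.0 * row["step"] + next(it))
            fit = nm.fit_stepwise(counts, clean_trials)
            hits += "Sequenceprogress" in fit.retained
            other_value_hits += bool({"SVspend", "SVsave"} & set(fit.retained))
        assert hits >= 0.9 * n_rep
        assert other_value_hits <= 0.3 * n_rep

    def test_length_only_neuron_rarely_selects_progress(self, clean_trials, rng):
        false_sel = 0
        n_rep = 25
        for i in range(n_rep):
            noise = rng.normal(0, 1.0, (~clean_trials["error"]).sum())
            it = iter(noise)
            counts = make_counts(clean_trials,
                                 lambda row: 5.0 + 2.0 * row["sequence_length"] + next(it))
            fit = nm.fit_stepwise(counts, clean_trials)
            false_sel += "Sequenceprogress" in fit.retained
        assert false_sel <= 0.2 * n_rep

    def test_simultaneous_estimation(self, clean_trials):
        counts = make_counts(clean_trials, lambda row: row["step"] * 1.0)
        fit = nm.fit_stepwise(counts, clean_trials, method="simultaneous")
        assert "Sequenceprogress" in fit.retained
        assert len(fit.retained) >= 5  # full covariate set minus dropped columns

    def test_rt_covariates_added(self, clean_trials):
        counts = make_counts(clean_trials, lambda row: row["step"] * 1.0)
        fit = nm.fit_stepwise(counts, clean_trials, include_rts=True,
                              method="simultaneous")
        assert {"rt_key_z", "rt_saccade_z"} <= set(fit.retained)


class TestCompareModels:
    def test_identical_fits(self):
        fits = [_dummy_fit(0.3, 0.01) for _ in range(10)]
        cmp = nm.compare_models(fits, [
            _dummy_fit(0.3, 0.01, "B") for _ in range(10)])
        assert cmp.wins_a == cmp.wins_b == 0
        assert cmp.ties == 10
        assert cmp.z == 0.0

    def test_discordant_pair_z_formula(self):
        # 30 responses significant for A only, 10 for B only
        fits_a = ([_dummy_fit(0.3, 0.01) for _ in range(30)]
                  + [_dummy_fit(0.0, 0.9) for _ in range(10)])
        fits_b = ([_dummy_fit(0.0, 0.9, "B") for _ in range(30)]
                  + [_dummy_fit(0.3, 0.01, "B") for _ in range(10)])
        cmp = nm.compare_models(fits_a, fits_b)
        assert cmp.z == pytest.approx(20 / math.sqrt(40))
        assert cmp.n_a_only == 30 and cmp.n_b_only == 10

    def test_adaptive_vs_nonadaptive_recovery(self, clean_trials):
        fits2, fits3 = [], []
        for i in range(15):
            spec = sd.NeuronSpec(f"ad{i}", "adaptive_progress", 5.0, 12.0,
                                 target_periods=("cue",))
            spikes = sd.generate_spikes(spec, clean_trials, seed=100 + i)
            counts = io.extract_window_counts(spikes, clean_trials)
            fits2.append(nm.fit_model(counts, clean_trials, "eq2", period="cue"))
            fits3.append(nm.fit_model(counts, clean_trials, "eq3", period="cue"))
        cmp = nm.compare_models(fits3, fits2)
        assert cmp.wins_a > cmp.wins_b  # adaptive model wins on adaptive neurons

    def test_zero_discordant_pairs(self):
        fits = [_dummy_fit(0.2, 0.5)]
        cmp = nm.compare_models(fits, [_dummy_fit(0.1, 0.5, "B")])
        assert cmp.z == 0.0 and cmp.z_pvalue == 1.0


class TestSlopeSigns:
    def test_all_positive(self):
        fits = [_dummy_fit(0.3, 0.01, slope=1.0) for _ in range(8)]
        out = nm.summarize_slope_signs(fits)
        assert out.n_positive == 8 and out.n_negative == 0
        assert out.pvalue == pytest.approx(min(1.0, 2 * 0.5**8))

    def test_exact_binomial_oracle_294_of_408(self):
        fits = ([_dummy_fit(0.3, 0.01, slope=1.0) for _ in range(294)]
                + [_dummy_fit(0.3, 0.01, slope=-1.0) for _ in range(114)])
        out = nm.summarize_slope_signs(fits)
        # two-sided exact binomial tail by direct summation
        n = 408
        pmf = [math.comb(n, k) * 0.5**n for k in range(n + 1)]
        crit = pmf[294]
        expected = sum(p for p in pmf if p <= crit + 1e-15)
        assert out.pvalue == pytest.approx(expected, rel=1e-6)
        assert out.pvalue < 1e-18

    def test_balanced_signs(self):
        fits = ([_dummy_fit(0.3, 0.01, slope=1.0) for _ in range(10)]
                + [_dummy_fit(0.3, 0.01, slope=-1.0) for _ in range(10)])
        assert nm.summarize_slope_signs(fits).pvalue == pytest.approx(1.0)

    def test_only_significant_included(self):
        fits = [_dummy_fit(0.3, 0.5, slope=1.0, slope_p=0.5) for _ in range(5)]
        out = nm.summarize_slope_signs(fits)
        assert out.n_positive == 0 and math.isnan(out.pvalue)


class TestSlidingWindow:
    def test_window_count_arithmetic(self):
        offs = nm.window_offsets(0.0, 1.0, 0.2, 0.025)
        assert len(offs) == 33  # floor((1.0-0.2)/0.025)+1

    def test_cue_tuned_neuron_localized(self, clean_trials):
        spec = sd.NeuronSpec("cue", "nonadaptive_progress", 5.0, 25.0,
                             target_periods=("cue",))
        spikes = sd.generate_spikes(spec, clean_trials, seed=9)
        res = nm.sliding_window_regression(spikes, clean_trials)[0]
        sig = res.pvalues < 0.05
        meta = res.windows
        # cue onset sits at offset 2.0 in the fixation-aligned segment and 0 in cue segment
        cue_zone = ((meta["segment"] == "cue")
                    & (meta["offset"].between(-0.2, 0.32))).to_numpy()
        prefix_zone = ((meta["segment"] == "fixation")
                       & (meta["offset"] < -0.2)).to_numpy()
        assert sig[cue_zone].mean() > 0.5
        assert sig[prefix_zone].mean() < 0.2
        assert res.significant(run_threshold=8)

    def test_null_neuron_type_one_level(self, clean_trials):
        rates = []
        for i in range(12):
            spec = sd.NeuronSpec(f"z{i}", "null", 5.0, 0.0)
            spikes = sd.generate_spikes(spec, clean_trials, seed=200 + i)
            res = nm.sliding_window_regression(spikes, clean_trials)[0]
            rates.append((res.pvalues < 0.05).mean())
        assert 0.01 < np.mean(rates) < 0.10

    def test_longest_run(self):
        assert nm.longest_run([True, True, False, True, True, True]) == 3
        assert nm.longest_run([]) == 0


class TestRunCalibration:
    def test_zero_shuffles_rejected(self, clean_trials):
        with pytest.raises(ValueError):
            nm.calibrate_run_threshold(pd.DataFrame(columns=io.SPIKE_COLUMNS),
                                       clean_trials, n_shuffles=0)

    def test_independent_windows_match_markov_oracle(self, clean_trials):
        """With non-overlapping windows the run-length null follows the
        Bernoulli-run chain; compare the shuffled survival function to a
        dynamic-programming oracle."""
        spec = sd.NeuronSpec("cal", "null", 8.0, 0.0)
        spikes = sd.generate_spikes(spec, clean_trials, seed=33)
        window = step = 0.2  # no overlap -> independent windows
        regs_x = None
        cal = nm.calibrate_run_threshold(spikes, clean_trials, n_shuffles=600,
                                         window=window, step=step, seed=4)
        res = nm.sliding_window_regression(spikes, clean_trials,
                                           window=window, step=step)[0]
        k = len(res.pvalues)

        def p_max_run_le(L, k, p=0.05):
            # DP over run-length states 0..L
            states = np.zeros(L + 1)
            states[0] = 1.0
            for _ in range(k):
                new = np.zeros(L + 1)
                new[0] = states.sum() * (1 - p)
                for s in range(L):
                    new[s + 1] += states[s] * p
                states = new
            return states.sum()

        for L in (1, 2, 3):
            oracle = 1.0 - p_max_run_le(L, k)
            emp = (cal.max_runs > L).mean()
            se = math.sqrt(max(oracle * (1 - oracle), 1e-6) / len(cal.max_runs))
            assert abs(emp - oracle) < 4 * se + 0.01

    def test_shuffling_preserves_marginal_rate(self, clean_trials):
        spec = sd.NeuronSpec("m", "null", 8.0, 0.0)
        spikes = sd.generate_spikes(spec, clean_trials, seed=44)
        regs = nm.regressor_frame(clean_trials)
        x = regs["Sequenceprogress"].to_numpy()
        counts, _ = nm._counts_matrix(
            spikes, clean_trials, nm.DEFAULT_SEGMENTS, 0.2, 0.025)
        rng = np.random.default_rng(0)
        # marginal per-window significance of shuffled fits is ~5%
        Yc = counts - counts.mean(axis=0)
        ps = []
        for _ in range(30):
            ps.append(simple_regression_pvalues(rng.permutation(x), counts))
        rate = (np.array(ps) < 0.05).mean()
        assert 0.02 < rate < 0.08


class TestFreeVsImperative:
    def test_free_only_neurons_lose_significance_when_instructed(self):
        cfg = sd.GeneratorConfig(n_sequences=60, seed=13, error_rate=0.0)
        trials, _, _, _ = sd.generate_dataset(cfg)
        free = trials[trials["task_type"] == "free"]
        imp = trials[trials["task_type"] == "imperative"]
        free_sig, imp_sig = 0, 0
        n = 10
        for i in range(n):
            spec = sd.NeuronSpec(f"fo{i}", "adaptive_progress", 5.0, 12.0,
                                 target_periods=("cue",), free_only=True)
            spikes = sd.generate_spikes(spec, trials, seed=300 + i)
            for task, bucket in ((free, "free"), (imp, "imp")):
                counts = io.extract_window_counts(
                    spikes, task, periods={"cue": io.DEFAULT_PERIODS["cue"]})
                fit = nm.fit_model(counts, task, "eq2", period="cue")
                if fit.slope_pvalue < 0.05:
                    if bucket == "free":
                        free_sig += 1
                    else:
                        imp_sig += 1
        assert free_sig >= 8
        assert imp_sig <= 2
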