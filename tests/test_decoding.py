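"""Pseudo-population construction and decoder behavior."""

import numpy as np
import pandas as pd
import pytest

from saveseq import decoding as dec


def make_activity(rng, n_neurons=10, n_trials=60, signal=1.0, max_step=6):
    """Per-neuron activity with z = signal * progress/max + noise."""
    frames = []
    for i in range(n_neurons):
        progress = rng.integers(1, max_step + 1, n_trials)
        z = signal * progress / max_step + rng.normal(0, 0.3, n_trials)
        frames.append(pd.DataFrame({
            "neuron_id": f"n{i:02d}", "session_id": "S1",
            "trial_index": np.arange(n_trials), "progress": progress, "z": z,
        }))
    return pd.concat(frames, ignore_index=True)


def brute_force_nn_loo(groups):
    """Python-loop leave-one-out nearest neighbor (first-index tie-break)."""
    X = np.vstack(groups)
    y = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    correct = 0
    for i in range(len(y)):
        best_d, best_j = None, None
        for j in range(len(y)):
            if j == i:
                continue
            d = float(np.sqrt(np.sum((X[i] - X[j]) ** 2)))
            if best_d is None or d < best_d - 1e-12:
                best_d, best_j = d, j
        correct += int(y[best_j] == y[i])
    return 100.0 * correct / len(y)


class TestGrouping:
    def test_tercile_arithmetic(self):
        labels = dec.progress_groups(np.array([1, 2, 3, 4, 5, 6]), 3)
        assert list(labels) == [0, 0, 1, 1, 2, 2]

    def test_boundary_goes_to_lower_group(self):
        labels = dec.progress_groups(np.array([1.0, 2.0, 2.0, 3.0]), 2)
        edge = np.quantile([1, 2, 2, 3], 0.5)
        assert all(l == 0 for v, l in zip([1.0, 2.0, 2.0, 3.0], labels) if v <= edge)

    def test_quartile_option(self, rng):
        act = make_activity(rng, n_neurons=6, n_trials=80, max_step=8)
        pop = dec.build_pseudopopulation(act, n_groups=4, n_matchings=3, seed=0)
        assert pop.n_groups == 4
        assert len(pop.matchings[0]) == 4

    def test_sparse_neuron_excluded(self, rng):
        act = make_activity(rng, n_neurons=5, n_trials=60)
        # one neuron with only 4 trials overall -> <5 per group
        extra = pd.DataFrame({
            "neuron_id": "sparse", "session_id": "S1",
            "trial_index": np.arange(4), "progress": [1, 2, 4, 6],
            "z": [0.0, 0.1, 0.2, 0.3],
        })
        pop = dec.build_pseudopopulation(pd.concat([act, extra]), n_matchings=2, seed=0)
        assert "sparse" not in pop.neuron_ids

    def test_too_few_neurons_rejected(self, rng):
        act = make_activity(rng, n_neurons=1)
        with pytest.raises(ValueError):
            dec.build_pseudopopulation(act, n_matchings=2, seed=0)


class TestDecoders:
    def test_separable_population_is_perfect(self):
        # group means far apart, no noise overlap
        groups = [np.full((6, 20), g * 10.0) + np.random.default_rng(g).normal(0, 0.1, (6, 20))
                  for g in range(3)]
        assert dec.nn_loo_accuracy(groups) == 100.0
        assert dec.svm_loo_accuracy(groups) == 100.0

    def test_null_population_at_chance(self, rng):
        accs = []
        for i in range(30):
            groups = [rng.normal(0, 1, (8, 12)) for _ in range(3)]
            accs.append(dec.nn_loo_accuracy(groups))
        mean = np.mean(accs)
        # 24 trials/instance, 30 instances: binomial CI around 33.3%
        se = 100 * np.sqrt((1 / 3) * (2 / 3) / (24 * 30))
        assert abs(mean - 100 / 3) < 4 * se + 2.0

    def test_nn_matches_brute_force_oracle_small_instances(self, rng):
        for trial in range(60):
            sizes = rng.integers(2, 4, size=2)  # ≤8 trials total
            groups = [rng.normal(0, 1, (s, 3)) for s in sizes]
            assert dec.nn_loo_accuracy(groups) == pytest.approx(
                brute_force_nn_loo(groups))

    def test_nn_oracle_with_ties(self):
        # duplicated points force distance ties; both paths use first-index order
        g0 = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        g1 = np.array([[1.0, 1.0], [2.0, 2.0]])
        assert dec.nn_loo_accuracy([g0, g1]) == pytest.approx(
            brute_force_nn_loo([g0, g1]))

    def test_hand_computed_three_neuron_instance(self):
        # 3 neurons, 6 trials; nearest neighbors worked out by hand
        g0 = np.array([[0, 0, 0], [0.1, 0, 0]])
        g1 = np.array([[1, 1, 1], [1.1, 1, 1]])
        g2 = np.array([[5, 5, 5], [5, 5, 5.1]])
        assert dec.nn_loo_accuracy([g0, g1, g2]) == 100.0
        g1_far = np.array([[0.05, 0, 0], [9, 9, 9]])  # each misclassified
        acc = dec.nn_loo_accuracy([g0, g1_far, g2])
        assert acc == pytest.approx(brute_force_nn_loo([g0, g1_far, g2]))

    def test_split_cv_supported(self, rng):
        act = make_activity(rng, n_neurons=12, n_trials=80, signal=3.0)
        pop = dec.build_pseudopopulation(act, n_matchings=5, seed=1)
        r = dec.decode(pop, cv="split")
        assert r.mean > 50.0


class TestShuffleNull:
    def test_null_mean_near_chance_and_significance(self, rng):
        act = make_activity(rng, n_neurons=15, n_trials=90, signal=2.0)
        pop = dec.build_pseudopopulation(act, n_matchings=20, seed=2)
        real = dec.decode(pop)
        out = dec.shuffle_null(pop, real, n_iterations=200, seed=3)
        total = sum(pop.group_sizes)
        expected_chance = 100 * sum((s / total) ** 2 for s in pop.group_sizes)
        assert out.null_mean == pytest.approx(expected_chance, abs=6.0)
        assert out.pvalue < 0.01
        assert real.mean > out.null_mean + 10

    def test_low_iteration_warning(self, rng):
        act = make_activity(rng, n_neurons=5, n_trials=60)
        pop = dec.build_pseudopopulation(act, n_matchings=2, seed=4)
        real = dec.decode(pop)
        with pytest.warns(UserWarning):
            dec.shuffle_null(pop, real, n_iterations=50, seed=5)


class TestNeuronCountCurve:
    def test_full_size_matches_full_decode(self, rng):
        act = make_activity(rng, n_neurons=8, n_trials=70, signal=2.0)
        pop = dec.build_pseudopopulation(act, n_matchings=1, seed=6)
        full = dec.decode(pop)
        curve = dec.neuron_count_curve(pop, [pop.n_neurons], iterations=1, seed=7)
        assert curve["mean"].iloc[0] == pytest.approx(full.mean)

    def test_accuracy_increases_with_size(self, rng):
        from scipy import stats
        act = make_activity(rng, n_neurons=20, n_trials=80, signal=2.0)
        pop = dec.build_pseudopopulation(act, n_matchings=10, seed=8)
        curve = dec.neuron_count_curve(pop, [1, 3, 6, 12, 20], iterations=10, seed=9)
        rho, p = stats.spearmanr(curve["size"], curve["mean"])
        assert rho > 0.9 and p < 0.05

    def test_invalid_size_rejected(self, rng):
        act = make_activity(rng, n_neurons=4)
        pop = dec.build_pseudopopulation(act, n_matchings=1, seed=10)
        with pytest.raises(ValueError):
            dec.neuron_count_curve(pop, [0])


class TestSubsetAnalysis:
    def _mixed_pop(self, rng, n_tuned=25, n_null=35):
        tuned = make_activity(rng, n_neurons=n_tuned, n_trials=80, signal=2.5)
        null = make_activity(rng, n_neurons=n_null, n_trials=80, signal=0.0)
        null["neuron_id"] = null["neuron_id"].str.replace("n", "z")
        act = pd.concat([tuned, null], ignore_index=True)
        roster = pd.DataFrame({
            "neuron_id": sorted(act["neuron_id"].unique()),
        })
        roster["significant"] = roster["neuron_id"].str.startswith("n")
        roster["slope"] = np.where(roster["significant"], 2.5 / 6, 0.0)
        roster["region"] = np.where(
            np.arange(len(roster)) % 2 == 0, "basolateral", "centromedial")
        return dec.build_pseudopopulation(act, n_matchings=10, seed=11,
                                          roster=roster)

    def test_significant_subsets_beat_nonsignificant(self, rng):
        from scipy import stats
        pop = self._mixed_pop(rng)
        out = dec.subset_analysis(pop, subset_size=15, iterations=40, seed=12)
        sig = out.accuracies["significant"]
        nsig = out.accuracies["nonsignificant"]
        assert sig.mean() > nsig.mean()
        assert stats.ranksums(sig, nsig).pvalue < 0.01

    def test_covariate_regression_positive_slope_effect(self, rng):
        pop = self._mixed_pop(rng)
        out = dec.subset_analysis(pop, subset_size=15, iterations=60, seed=13)
        fit = out.covariate_fit
        assert fit is not None
        assert fit.params["mean_abs_slope"] > 0

    def test_undersized_category_skipped(self, rng):
        pop = self._mixed_pop(rng, n_tuned=5, n_null=30)
        out = dec.subset_analysis(pop, subset_size=15, iterations=5, seed=14)
        assert "significant" not in out.accuracies
        assert "random" in out.accuracies

    def test_roster_required(self, rng):
        act = make_activity(rng, n_neurons=6)
        pop = dec.build_pseudopopulation(act, n_matchings=2, seed=15)
        with pytest.raises(ValueError):
            dec.subset_analysis(pop)


class TestMonotoneInformation:
    def test_appending_tuned_neuron_does_not_hurt(self, rng):
        act = make_activity(rng, n_neurons=10, n_trials=80, signal=2.0)
        pop = dec.build_pseudopopulation(act, n_matchings=15, seed=16)
        sub = pop.restrict(np.arange(5))
        acc_small = dec.decode(sub).mean
        acc_full = dec.decode(pop).mean
        assert acc_full >= acc_small - 2.0  # expectation is non-decreasing
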