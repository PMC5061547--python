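"""Pseudo-population decoding of sequence progress.

Neurons recorded in different sessions are aggregated by splitting each
neuron's trials into progress groups (terciles by default: low / medium /
high progress on that neuron's own progress values) and randomly matching
up trials across neurons within each group. Each matching yields one
(trials x neurons) matrix per group; a leave-one-out classifier —
nearest-neighbor by Euclidean distance, or a linear max-margin SVM —
decodes the group label, and accuracy (% correct) is averaged over
matchings. Shuffle nulls permute group labels without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .regression import RegressionFit, ols_fit

CLASSIFIERS = ("nearest_neighbor", "linear_max_margin")


def activity_table(znormalized: pd.DataFrame, trials: pd.DataFrame, period: str) -> pd.DataFrame:
    """Tidy per-neuron trial activity for one task period: neuron_id, z, progress."""
    correct = trials[~trials["error"].astype(bool)]
    sub = znormalized[znormalized["period"] == period]
    merged = sub.merge(correct[["session_id", "trial_index", "step"]],
                       on=["session_id", "trial_index"], how="inner")
    return merged.rename(columns={"step": "progress"})[
        ["neuron_id", "session_id", "trial_index", "progress", "z"]
    ]


def progress_groups(progress: np.ndarray, n_groups: int = 3) -> np.ndarray:
    """Per-neuron quantile grouping of progress values; boundaries go to the lower group."""
    edges = np.quantile(progress, np.arange(1, n_groups) / n_groups)
    return np.array([int(np.sum(v > edges)) for v in progress])


@dataclass
class PseudoPopulation:
    """Matched trial x neuron matrices per progress group, repeated over matchings."""

    matchings: list[list[np.ndarray]]  # [matching][group] -> (m_g, n_neurons)
    neuron_ids: list[str]
    group_sizes: list[int]
    n_groups: int
    seed: int
    roster: pd.DataFrame | None = None  # per-neuron slope / significance / region

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    def restrict(self, neuron_indices: np.ndarray) -> "PseudoPopulation":
        return PseudoPopulation(
            matchings=[[m[:, neuron_indices] for m in groups] for groups in self.matchings],
            neuron_ids=[self.neuron_ids[i] for i in neuron_indices],
            group_sizes=self.group_sizes, n_groups=self.n_groups, seed=self.seed,
            roster=self.roster.iloc[neuron_indices].reset_index(drop=True)
            if self.roster is not None else None,
        )


def build_pseudopopulation(
    activity: pd.DataFrame,
    n_groups: int = 3,
    min_trials: int = 5,
    n_matchings: int = 150,
    seed: int = 0,
    roster: pd.DataFrame | None = None,
) -> PseudoPopulation:
    """Assemble pseudo-population matrices from per-neuron trial activity.

    ``activity`` has columns (neuron_id, progress, z) as from
    :func:`activity_table`; no pre-selection for tuning is applied. Group
    edges are per-neuron progress quantiles; neurons with fewer than
    ``min_trials`` trials in any group are excluded. The per-group trial
    count is the minimum available across included neurons; within-group
    trial matching is repeated ``n_matchings`` times.
    """
    rng = np.random.default_rng(seed)
    per_neuron: dict[str, list[np.ndarray]] = {}
    for neuron, grp in activity.groupby("neuron_id", sort=True):
        labels = progress_groups(grp["progress"].to_numpy(dtype=float), n_groups)
        z = grp["z"].to_numpy(dtype=float)
        groups = [z[labels == g] for g in range(n_groups)]
        if min(len(g) for g in groups) >= min_trials:
            per_neuron[str(neuron)] = groups
    if len(per_neuron) < 2:
        raise ValueError("fewer than two neurons survive the per-group trial minimum")
    neuron_ids = sorted(per_neuron)
    sizes = [min(len(per_neuron[n][g]) for n in neuron_ids) for g in range(n_groups)]
    matchings = []
    for _ in range(n_matchings):
        groups = []
        for g in range(n_groups):
            cols = [rng.choice(per_neuron[n][g], size=sizes[g], replace=False)
                    for n in neuron_ids]
            groups.append(np.column_stack(cols))
        matchings.append(groups)
    if roster is not None:
        roster = (roster.set_index("neuron_id").loc[neuron_ids]
                  .reset_index())
    return PseudoPopulation(
        matchings=matchings, neuron_ids=neuron_ids, group_sizes=sizes,
        n_groups=n_groups, seed=seed, roster=roster,
    )


# ---------------------------------------------------------------------------
# classifiers


def _stack(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack(groups)
    y = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    return X, y


def nn_loo_accuracy(groups: list[np.ndarray]) -> float:
    """Leave-one-out nearest-neighbor accuracy (%): Euclidean distance.

    Each trial is assigned the label of its nearest other trial; distance
    ties resolve to the lowest trial index in stacking order (groups in
    label order, rows in matrix order) — a fixed, documented ordering.
    """
    X, y = _stack(groups)
    d = cdist(X, X, metric="euclidean")
    np.fill_diagonal(d, np.inf)
    nearest = np.argmin(d, axis=1)  # argmin takes the first minimum: stable tie-break
    return 100.0 * float(np.mean(y[nearest] == y))


def svm_loo_accuracy(groups: list[np.ndarray]) -> float:
    """Leave-one-out linear max-margin (SVM) accuracy (%)."""
    X, y = _stack(groups)
    correct = 0
    idx = np.arange(len(y))
    for i in idx:
        train = idx != i
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(X[train], y[train])
        correct += int(clf.predict(X[i:i + 1])[0] == y[i])
    return 100.0 * correct / len(y)


def split_accuracy(groups: list[np.ndarray], classifier: str, rng: np.random.Generator,
                   train_fraction: float = 0.8) -> float:
    """Single random stratified 80/20 split accuracy (%), alternative to LOO."""
    train_groups, test_X, test_y = [], [], []
    for gi, g in enumerate(groups):
        perm = rng.permutation(len(g))
        n_train = max(1, int(round(train_fraction * len(g))))
        n_train = min(n_train, len(g) - 1)
        train_groups.append(g[perm[:n_train]])
        test_X.append(g[perm[n_train:]])
        test_y.append(np.full(len(g) - n_train, gi))
    Xtr, ytr = _stack(train_groups)
    Xte, yte = np.vstack(test_X), np.concatenate(test_y)
    if classifier == "nearest_neighbor":
        d = cdist(Xte, Xtr)
        pred = ytr[np.argmin(d, axis=1)]
    else:
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
    return 100.0 * float(np.mean(pred == yte))


@dataclass
class DecodingResult:
    classifier: str
    accuracies: np.ndarray  # % correct per matching
    mean: float
    sem: float
    null_accuracies: np.ndarray | None = None
    null_mean: float | None = None
    pvalue: float | None = None  # rank-sum real vs shuffled

    @property
    def chance(self) -> float | None:
        return None


def decode(
    pop: PseudoPopulation,
    classifier: str = "nearest_neighbor",
    cv: str = "leave_one_out",
    seed: int = 0,
) -> DecodingResult:
    """Cross-validated decoding accuracy per matching, mean ± sem across matchings."""
    if classifier not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}")
    rng = np.random.default_rng(seed)
    accs = []
    for groups in pop.matchings:
        if cv == "leave_one_out":
            if classifier == "nearest_neighbor":
                accs.append(nn_loo_accuracy(groups))
            else:
                accs.append(svm_loo_accuracy(groups))
        elif cv == "split":
            accs.append(split_accuracy(groups, classifier, rng))
        else:
            raise ValueError(f"unknown cv {cv!r}")
    accs = np.array(accs)
    sem = float(accs.std(ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0
    return DecodingResult(classifier=classifier, accuracies=accs,
                          mean=float(accs.mean()), sem=sem)


def shuffle_null(
    pop: PseudoPopulation,
    result: DecodingResult,
    n_iterations: int = 500,
    seed: int = 1,
) -> DecodingResult:
    """Shuffle-null decoding: group labels permuted without replacement.

    Each iteration shuffles the label vector of one matching (cycled) and
    recomputes the leave-one-out accuracy; the real accuracies are compared
    with the null by a two-sided rank-sum test.
    """
    if n_iterations < 100:
        import warnings
        warnings.warn("fewer than 100 shuffle iterations: null comparison is low-powered")
    rng = np.random.default_rng(seed)
    nulls = []
    n_match = len(pop.matchings)
    for i in range(n_iterations):
        groups = pop.matchings[i % n_match]
        X, y = _stack(groups)
        perm = rng.permutation(len(y))  # label multiset preserved
        y_shuf = y[perm]
        shuffled_groups = [X[y_shuf == g] for g in range(pop.n_groups)]
        if result.classifier == "nearest_neighbor":
            nulls.append(nn_loo_accuracy(shuffled_groups))
        else:
            nulls.append(svm_loo_accuracy(shuffled_groups))
    nulls = np.array(nulls)
    p = float(stats.ranksums(result.accuracies, nulls).pvalue)
    return DecodingResult(
        classifier=result.classifier, accuracies=result.accuracies,
        mean=result.mean, sem=result.sem,
        null_accuracies=nulls, null_mean=float(nulls.mean()), pvalue=p,
    )


def neuron_count_curve(
    pop: PseudoPopulation,
    sizes: list[int],
    iterations: int = 100,
    classifier: str = "nearest_neighbor",
    seed: int = 2,
) -> pd.DataFrame:
    """Decoding accuracy as a function of population size.

    For each size, ``iterations`` random neuron subsets are decoded (one
    matching per iteration, cycled); returns mean ± sem per size.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_match = len(pop.matchings)
    for size in sizes:
        if size < 1 or size > pop.n_neurons:
            raise ValueError(f"size {size} outside 1..{pop.n_neurons}")
        accs = []
        for i in range(iterations):
            cols = rng.choice(pop.n_neurons, size=size, replace=False)
            groups = [m[:, cols] for m in pop.matchings[i % n_match]]
            if classifier == "nearest_neighbor":
                accs.append(nn_loo_accuracy(groups))
            else:
                accs.append(svm_loo_accuracy(groups))
        accs = np.array(accs)
        rows.append({"size": size, "mean": float(accs.mean()),
                     "sem": float(accs.std(ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0})
    return pd.DataFrame(rows)


@dataclass
class SubsetAnalysisResult:
    accuracies: dict[str, np.ndarray]  # per category
    covariate_fit: RegressionFit | None  # accuracy ~ mean |slope| + slope sd (+ CM fraction)


def subset_analysis(
    pop: PseudoPopulation,
    subset_size: int = 20,
    categories: tuple[str, ...] = ("significant", "random", "nonsignificant"),
    iterations: int = 300,
    classifier: str = "nearest_neighbor",
    seed: int = 3,
) -> SubsetAnalysisResult:
    """Decode from fixed-size neuron subsets and explain accuracy by subset makeup.

    Requires ``pop.roster`` with columns ``slope`` (progress slope),
    ``significant`` (progress significance) and optionally ``region``.
    Categories draw subsets from significant, unrestricted, or
    non-significant neurons; a category with too few eligible neurons is
    skipped. For the random category, subset accuracy is regressed on mean
    rectified slope, slope standard deviation and (when regions are
    present) the centromedial fraction.
    """
    if pop.roster is None:
        raise ValueError("subset analysis requires a roster with slopes and significance")
    rng = np.random.default_rng(seed)
    roster = pop.roster
    eligible = {
        "significant": np.flatnonzero(roster["significant"].astype(bool)),
        "random": np.arange(pop.n_neurons),
        "nonsignificant": np.flatnonzero(~roster["significant"].astype(bool)),
    }
    n_match = len(pop.matchings)
    accuracies: dict[str, np.ndarray] = {}
    covariates = []
    for cat in categories:
        idx_pool = eligible[cat]
        if len(idx_pool) < subset_size:
            continue
        accs = []
        for i in range(iterations):
            cols = rng.choice(idx_pool, size=subset_size, replace=False)
            groups = [m[:, cols] for m in pop.matchings[i % n_match]]
            acc = (nn_loo_accuracy(groups) if classifier == "nearest_neighbor"
                   else svm_loo_accuracy(groups))
            accs.append(acc)
            if cat == "random":
                slopes = roster["slope"].to_numpy(dtype=float)[cols]
                row = {"accuracy": acc, "mean_abs_slope": float(np.mean(np.abs(slopes))),
                       "slope_sd": float(np.std(slopes, ddof=1))}
                if "region" in roster.columns:
                    row["cm_fraction"] = float(
                        (roster["region"].to_numpy()[cols] == "centromedial").mean())
                covariates.append(row)
        accuracies[cat] = np.array(accs)
    fit = None
    if covariates:
        cov = pd.DataFrame(covariates)
        X = cov.drop(columns="accuracy")
        X = X.loc[:, X.std() > 0]
        if not X.empty:
            fit = ols_fit(X, cov["accuracy"].to_numpy(dtype=float), model_id="subset_covariates")
    return SubsetAnalysisResult(accuracies=accuracies, covariate_fit=fit)
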