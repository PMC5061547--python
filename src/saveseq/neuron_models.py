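"""Single-neuron statistics for progress coding.

Workflow mirrored by the CLI's ``analyze-neurons`` step:

1. screen (neuron, period) responses for task-relatedness against the
   pre-fixation control period (paired Wilcoxon, Bonferroni p < 0.0083);
2. fit the suite of single-regressor tuning models to trial-by-trial rates
   (non-adaptive progress, length-normalized adaptive progress, reward
   magnitude, elapsed time, step indicators, partial adaptation);
3. contest models pairwise by R² with a dependent-samples z-test on
   discordant significance and a t-test on paired R² differences;
4. optionally fit the stepwise multiple regression with choice, value,
   sequence-length, cue-position, action-side (and reaction-time) covariates;
5. confirm findings free of window/pre-selection choices with the
   sliding-window regression and its shuffle-calibrated run-length detector.

Model identifiers:

=======  ===========================================================
eq2      y ~ Sequenceprogress (cumulative correct trials in sequence)
eq3      y ~ Sequenceprogress / Sequencelength (adaptive)
eq4      y ~ Rewardmagnitude (accumulated ml, geometric rule)
eq5      y ~ Elapsedtime (within-sequence trials including errors)
eq6      y ~ Step1 .. StepN indicators (no intercept)
eq7      stepwise multiple regression with task covariates
eq8      y ~ progress + progress/length (partial adaptation)
=======  ===========================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .regression import RegressionFit, ols_fit, simple_regression_pvalues, standardized_coefficients
from .task_model import accumulate_reward, tables_from_trials, znormalize_rt
from .synthetic_data import elapsed_within_sequence

TASK_RELATED_ALPHA = 0.0083  # Bonferroni-corrected Wilcoxon criterion
SINGLE_MODELS = ("eq2", "eq3", "eq4", "eq5", "eq6", "eq8")


# ---------------------------------------------------------------------------
# regressors


def regressor_frame(trials: pd.DataFrame, sv_tables=None) -> pd.DataFrame:
    """Per-correct-trial regressor values for the full model suite.

    ``sv_tables`` maps interest rate -> SubjectiveValueTable; by default they
    are estimated from the trial table itself (empirical length frequencies
    pooled per interest rate). Elapsed time is computed on the full table
    (error trials advance it) before restriction to correct trials.
    """
    elapsed = elapsed_within_sequence(trials)
    correct = trials[~trials["error"].astype(bool)].copy()
    if sv_tables is None:
        sv_tables = tables_from_trials(trials)
    step = correct["step"].astype(int)
    length = correct["sequence_length"].astype(int)
    out = pd.DataFrame({
        "session_id": correct["session_id"],
        "trial_index": correct["trial_index"],
        "step": step,
        "sequence_length": length,
        "sequence_id": correct["sequence_id"],
        "task_type": correct["task_type"],
        "Sequenceprogress": step.astype(float),
        "AdaptiveProgress": step / length,
        "Elapsedtime": elapsed.loc[correct.index].astype(float),
        "Choice": (correct["choice"] == "spend").astype(float),
        "SeqLength": length.astype(float),
        "Cueposition": (correct["cue_position"] == "save_left").astype(float),
        "LeftRight": (correct["action_side"] == "left").astype(float),
    })
    out["Rewardmagnitude"] = [
        accumulate_reward(int(s), float(b), float(q))
        for s, b, q in zip(step, correct["base_rate"], correct["interest_rate"])
    ]
    sv_spend, sv_save, seq_sv = [], [], []
    for s, L, q in zip(step, length, correct["interest_rate"]):
        table = sv_tables[float(q)]
        sv_spend.append(float(table.sv_spend[int(s) - 1]))
        sv_save.append(float(table.sv_save[int(s) - 1]) if int(s) < table.m else 0.0)
        seq_sv.append(table.seq_sv(int(L)))
    out["SVspend"] = sv_spend
    out["SVsave"] = sv_save
    out["SeqSV"] = seq_sv
    out["rt_key_z"] = znormalize_rt(correct.reset_index(drop=True), "key")
    out["rt_saccade_z"] = znormalize_rt(correct.reset_index(drop=True), "saccade")
    return out.reset_index(drop=True)


def _merge_response(counts, regs, period, neuron_id):
    sub = counts[counts["period"] == period]
    if neuron_id is not None:
        sub = sub[sub["neuron_id"] == neuron_id]
    value_col = "z" if "z" in sub.columns else "rate"
    merged = regs.merge(
        sub[["session_id", "trial_index", value_col]],
        on=["session_id", "trial_index"], how="inner",
    )
    return merged, value_col


# ---------------------------------------------------------------------------
# task-relatedness screening


def select_task_related(
    counts: pd.DataFrame,
    min_trials: int = 20,
    alpha: float = TASK_RELATED_ALPHA,
    control_period: str = "pre_fixation",
) -> pd.DataFrame:
    """Flag (neuron, period) responses whose activity differs from pre-fixation.

    Paired two-sided Wilcoxon signed-rank test on per-trial rates, period vs
    control, strict p < alpha. The control period itself is never screened.
    Returns one row per (neuron_id, period) with pvalue and task_related;
    neurons with fewer than ``min_trials`` trials are excluded entirely.
    """
    rows = []
    for neuron, grp in counts.groupby("neuron_id"):
        pivot = grp.pivot_table(index=["session_id", "trial_index"],
                                columns="period", values="rate")
        if control_period not in pivot.columns or len(pivot) < min_trials:
            continue
        ctrl = pivot[control_period].to_numpy(dtype=float)
        for period in pivot.columns:
            if period == control_period:
                continue
            x = pivot[period].to_numpy(dtype=float)
            diffs = x - ctrl
            if np.allclose(diffs, 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(x, ctrl, zero_method="wilcox").pvalue)
            rows.append({"neuron_id": neuron, "period": period,
                         "pvalue": p, "task_related": bool(p < alpha)})
    out = pd.DataFrame(rows, columns=["neuron_id", "period", "pvalue", "task_related"])
    return out


# ---------------------------------------------------------------------------
# model suite


def _design(regs: pd.DataFrame, model_id: str) -> tuple[pd.DataFrame, bool]:
    """Design matrix for one model; second element: include an intercept."""
    if model_id == "eq2":
        return regs[["Sequenceprogress"]], True
    if model_id == "eq3":
        return regs[["AdaptiveProgress"]], True
    if model_id == "eq4":
        return regs[["Rewardmagnitude"]], True
    if model_id == "eq5":
        return regs[["Elapsedtime"]], True
    if model_id == "eq6":
        steps = sorted(regs["step"].unique())
        X = pd.DataFrame({f"Step{s}": (regs["step"] == s).astype(float) for s in steps})
        return X, False
    if model_id == "eq8":
        return regs[["Sequenceprogress", "AdaptiveProgress"]], True
    raise ValueError(f"unknown model {model_id!r}")


def fit_model(
    counts: pd.DataFrame,
    trials: pd.DataFrame,
    model_id: str,
    period: str = "cue",
    neuron_id: str | None = None,
    sv_tables=None,
    regs: pd.DataFrame | None = None,
) -> RegressionFit:
    """OLS fit of one tuning model to one neuron's rates in one task period.

    ``regs`` may carry a precomputed :func:`regressor_frame` to amortize the
    subjective-value computation over many neurons. Step-indicator fits
    (eq6) drop the intercept (the indicators span it); their R² is centered
    and their model p-value comes from the F-test against the mean.
    """
    if regs is None:
        regs = regressor_frame(trials, sv_tables)
    merged, ycol = _merge_response(counts, regs, period, neuron_id)
    y = merged[ycol].to_numpy(dtype=float)
    X, with_const = _design(merged, model_id)
    if len(y) < X.shape[1] + 2:
        raise ValueError(f"too few trials ({len(y)}) for model {model_id}")
    if with_const:
        return ols_fit(X, y, model_id=model_id, neuron_id=neuron_id, period=period)
    # no-intercept indicator fit
    res = sm.OLS(y, X.astype(float)).fit()
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float((res.resid ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    k, n = X.shape[1], len(y)
    if ss_tot > ss_res and k > 1 and n > k:
        f = ((ss_tot - ss_res) / (k - 1)) / (ss_res / (n - k)) if ss_res > 0 else np.inf
        model_p = float(stats.f.sf(f, k - 1, n - k))
    else:
        model_p = 1.0
    params = pd.Series(res.params, index=X.columns)
    fit = RegressionFit(
        model_id=model_id,
        params=params,
        pvalues=pd.Series(res.pvalues, index=X.columns),
        standardized=standardized_coefficients(params, X, y),
        r_squared=max(0.0, min(1.0, r2)),
        residuals=np.asarray(res.resid),
        n_trials=n,
        neuron_id=neuron_id,
        period=period,
        degenerate=np.linalg.matrix_rank(np.asarray(X, float)) < k,
        n_params=k,  # the indicators span the intercept
    )
    fit.model_pvalue = model_p
    return fit


def best_fit_model(fits: dict[str, RegressionFit],
                   models=("eq2", "eq3", "eq4", "eq5", "eq6")) -> str:
    """Best-fitting model among candidates, by BIC.

    Models of equal size are thereby ranked exactly by R²; the ln(n)
    parsimony penalty makes the contest fair against the step-indicator
    model, which nests any tuning that depends on step alone.
    """
    return min(models, key=lambda m: fits[m].bic)


def fit_all_models(counts, trials, period="cue", neuron_id=None, sv_tables=None,
                   models=SINGLE_MODELS, regs=None) -> dict[str, RegressionFit]:
    if regs is None:
        regs = regressor_frame(trials, sv_tables)
    return {m: fit_model(counts, trials, m, period, neuron_id, regs=regs) for m in models}


# ---------------------------------------------------------------------------
# stepwise multiple regression (eq7)

EQ7_REGRESSORS = ("Choice", "SVspend", "SVsave", "SeqSV", "SeqLength",
                  "Cueposition", "LeftRight", "Sequenceprogress")


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    keep: list[str] = []
    for col in X.columns:
        cand = X[keep + [col]].to_numpy(dtype=float)
        cand = np.column_stack([np.ones(len(cand)), cand])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            keep.append(col)
    return X[keep]


def fit_stepwise(
    counts: pd.DataFrame,
    trials: pd.DataFrame,
    period: str = "cue",
    neuron_id: str | None = None,
    include_rts: bool = False,
    sv_tables=None,
    method: str = "stepwise",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    regs: pd.DataFrame | None = None,
    adaptive_progress: bool = False,
) -> RegressionFit:
    """Multiple regression of trial rates on the task covariates.

    ``method="stepwise"`` runs forward selection (p-to-enter 0.05) with
    backward elimination (p-to-remove 0.10); an all-noise response returns
    the intercept-only model. ``method="simultaneous"`` forces all regressors
    in at once (perfectly collinear columns are dropped in entry order).
    ``adaptive_progress`` swaps the progress regressor for its
    length-normalized version.
    """
    if regs is None:
        regs = regressor_frame(trials, sv_tables)
    merged, ycol = _merge_response(counts, regs, period, neuron_id)
    y = merged[ycol].to_numpy(dtype=float)
    names = list(EQ7_REGRESSORS)
    if adaptive_progress:
        names[names.index("Sequenceprogress")] = "AdaptiveProgress"
    if include_rts:
        names += ["rt_key_z", "rt_saccade_z"]
    X_full = merged[names]
    X_full = X_full.loc[:, X_full.std() > 0]  # constant covariates are uninformative
    if method == "simultaneous":
        X_full = _drop_collinear(X_full)
        fit = ols_fit(X_full, y, model_id="eq7", neuron_id=neuron_id, period=period)
        fit.retained = list(X_full.columns)
        return fit
    if method != "stepwise":
        raise ValueError(f"unknown method {method!r}")

    included: list[str] = []
    while True:
        changed = False
        excluded = [c for c in X_full.columns if c not in included]
        if excluded:
            pvals = {}
            for c in excluded:
                cand = _drop_collinear(X_full[included + [c]])
                if c not in cand.columns:
                    continue
                f = ols_fit(cand, y, model_id="probe")
                pvals[c] = float(f.pvalues[c])
            if pvals:
                best = min(pvals, key=pvals.get)
                if pvals[best] < p_enter:
                    included.append(best)
                    changed = True
        if included:
            f = ols_fit(X_full[included], y, model_id="probe")
            slopes = f.pvalues.drop("const")
            worst = slopes.idxmax()
            if float(slopes[worst]) > p_remove:
                included.remove(worst)
                changed = True
        if not changed:
            break
    if included:
        fit = ols_fit(X_full[included], y, model_id="eq7", neuron_id=neuron_id, period=period)
    else:
        params = pd.Series({"const": float(np.mean(y))})
        fit = RegressionFit(
            model_id="eq7", params=params, pvalues=pd.Series({"const": 1.0}),
            standardized=pd.Series(dtype=float), r_squared=0.0,
            residuals=y - np.mean(y), n_trials=len(y),
            neuron_id=neuron_id, period=period,
        )
    fit.retained = list(included)
    return fit


# ---------------------------------------------------------------------------
# model contests


@dataclass
class ModelComparison:
    """Paired contest of two tuning models over matched responses."""

    model_a: str
    model_b: str
    n_responses: int
    wins_a: int  # higher R² within the paired scope
    wins_b: int
    ties: int
    n_a_only: int  # significant for A but not B
    n_b_only: int
    z: float  # discordant-pair z statistic
    z_pvalue: float
    r2_diff: np.ndarray  # R²(A) - R²(B) within scope
    t_stat: float
    t_pvalue: float
    normality_pvalue: float


def compare_models(
    fits_a: list[RegressionFit],
    fits_b: list[RegressionFit],
    paired_scope: str = "both_significant",
    alpha: float = 0.05,
) -> ModelComparison:
    """Contest models A and B over one-to-one matched responses.

    Win counts (higher R², exact ties counted for neither) are taken within
    ``paired_scope`` ("both_significant" or "all"). The dependent-samples z
    statistic uses responses significant for exactly one model:
    z = (n_A_only - n_B_only) / sqrt(n_A_only + n_B_only). The shift of the
    R² distribution is tested with a one-sample t-test on the differences,
    with a Kolmogorov-Smirnov normality check.
    """
    if len(fits_a) != len(fits_b):
        raise ValueError("fit lists must be matched one-to-one")
    if paired_scope not in ("both_significant", "all"):
        raise ValueError(f"unknown paired_scope {paired_scope!r}")
    r2a = np.array([f.r_squared for f in fits_a])
    r2b = np.array([f.r_squared for f in fits_b])
    siga = np.array([f.model_pvalue < alpha for f in fits_a])
    sigb = np.array([f.model_pvalue < alpha for f in fits_b])
    scope = (siga & sigb) if paired_scope == "both_significant" else np.ones(len(r2a), bool)
    wins_a = int(((r2a > r2b) & scope).sum())
    wins_b = int(((r2b > r2a) & scope).sum())
    ties = int(((r2a == r2b) & scope).sum())
    n_a_only = int((siga & ~sigb).sum())
    n_b_only = int((~siga & sigb).sum())
    disc = n_a_only + n_b_only
    z = (n_a_only - n_b_only) / np.sqrt(disc) if disc > 0 else 0.0
    z_p = 2.0 * stats.norm.sf(abs(z)) if disc > 0 else 1.0
    diffs = (r2a - r2b)[scope]
    if len(diffs) >= 3 and np.std(diffs) > 0:
        t_stat, t_p = stats.ttest_1samp(diffs, 0.0)
        norm_p = float(stats.kstest((diffs - diffs.mean()) / diffs.std(ddof=1), "norm").pvalue)
    else:
        t_stat, t_p, norm_p = 0.0, 1.0, 1.0
    return ModelComparison(
        model_a=fits_a[0].model_id if fits_a else "A",
        model_b=fits_b[0].model_id if fits_b else "B",
        n_responses=int(scope.sum()), wins_a=wins_a, wins_b=wins_b, ties=ties,
        n_a_only=n_a_only, n_b_only=n_b_only, z=float(z), z_pvalue=float(z_p),
        r2_diff=diffs, t_stat=float(t_stat), t_pvalue=float(t_p),
        normality_pvalue=norm_p,
    )


def task_contrast(
    free_a: list[RegressionFit], free_b: list[RegressionFit],
    imp_a: list[RegressionFit], imp_b: list[RegressionFit],
):
    """Paired t-test of the model-A advantage (ΔR²) free-choice vs imperative.

    All four lists are matched response-for-response. Returns (mean free ΔR²,
    mean imperative ΔR², t statistic, p-value).
    """
    d_free = np.array([a.r_squared - b.r_squared for a, b in zip(free_a, free_b)])
    d_imp = np.array([a.r_squared - b.r_squared for a, b in zip(imp_a, imp_b)])
    if len(d_free) != len(d_imp):
        raise ValueError("free and imperative fits must be matched")
    t, p = stats.ttest_rel(d_free, d_imp)
    return float(d_free.mean()), float(d_imp.mean()), float(t), float(p)


@dataclass
class SlopeSignSummary:
    n_positive: int
    n_negative: int
    pvalue: float  # two-sided exact binomial vs 0.5


def summarize_slope_signs(fits: list[RegressionFit], alpha: float = 0.05) -> SlopeSignSummary:
    """Count positive vs negative slopes among significant responses (binomial test)."""
    slopes = [f.slope for f in fits if f.slope_pvalue < alpha and f.slope != 0]
    n_pos = sum(1 for s in slopes if s > 0)
    n_neg = len(slopes) - n_pos
    if not slopes:
        return SlopeSignSummary(0, 0, float("nan"))
    p = stats.binomtest(n_pos, n_pos + n_neg, 0.5, alternative="two-sided").pvalue
    return SlopeSignSummary(n_pos, n_neg, float(p))


# ---------------------------------------------------------------------------
# sliding-window regression and run-length calibration

#: Event-aligned segments tiled by the sliding window, stitched in task
#: order: around fixation (covering the control and fixation periods),
#: around the cues, through the post-choice delay, and around the outcome.
DEFAULT_SEGMENTS = (
    ("fixation", "t_fix_on", -1.000, 1.825),
    ("cue", "t_cue_on", -0.200, 0.520),
    ("choice", "t_choice", 0.000, 1.550),
    ("outcome", "t_outcome", -0.100, 0.650),
)


def window_offsets(start: float, end: float, window: float, step: float) -> np.ndarray:
    """Window start offsets tiling [start, end): floor((span - window)/step) + 1 windows."""
    n = int(np.floor((end - start - window) / step + 1e-9)) + 1
    if n < 1:
        return np.empty(0)
    return start + step * np.arange(n)


@dataclass
class SlidingWindowResult:
    neuron_id: str
    pvalues: np.ndarray  # per window, stitched across segments
    windows: pd.DataFrame  # segment, anchor_event, offset per window
    n_trials: int

    def max_run(self, alpha: float = 0.05) -> int:
        return longest_run(self.pvalues < alpha)

    def significant(self, run_threshold: int = 8, alpha: float = 0.05) -> bool:
        """Detector: more than ``run_threshold`` consecutive significant windows."""
        return self.max_run(alpha) > run_threshold


def longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in np.asarray(mask, bool):
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def _counts_matrix(spikes_one, trials_correct, segments, window, step):
    """(n_trials x n_windows) spike counts for one neuron, plus window metadata."""
    metas = []
    all_offsets = []
    for name, anchor, a, b in segments:
        offs = window_offsets(a, b, window, step)
        all_offsets.append((anchor, offs))
        metas.append(pd.DataFrame({"segment": name, "anchor_event": anchor, "offset": offs}))
    meta = pd.concat(metas, ignore_index=True)
    n_windows = len(meta)
    keys = trials_correct[["session_id", "trial_index"]]
    grouped = {
        k: np.sort(g["t"].to_numpy(dtype=float))
        for k, g in spikes_one.groupby(["session_id", "trial_index"], sort=False)
    }
    counts = np.zeros((len(keys), n_windows), dtype=float)
    anchors = trials_correct[["t_fix_on", "t_cue_on", "t_choice", "t_outcome"]].to_numpy(float)
    anchor_cols = {"t_fix_on": 0, "t_cue_on": 1, "t_choice": 2, "t_outcome": 3}
    for i, (key, row) in enumerate(zip(keys.itertuples(index=False, name=None), anchors)):
        t = grouped.get(key)
        if t is None or len(t) == 0:
            continue
        col = 0
        for anchor, offs in all_offsets:
            if len(offs) == 0:
                continue
            starts = row[anchor_cols[anchor]] + offs
            lo = np.searchsorted(t, starts, side="left")
            hi = np.searchsorted(t, starts + window, side="left")
            counts[i, col:col + len(offs)] = hi - lo
            col += len(offs)
    return counts, meta


def sliding_window_regression(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    regressor: str = "Sequenceprogress",
    window: float = 0.200,
    step: float = 0.025,
    segments=DEFAULT_SEGMENTS,
) -> list[SlidingWindowResult]:
    """Per-window regression p-values for every neuron in ``spikes``.

    A 200 ms window moved in 25 ms steps across event-aligned segments of
    the trial; per window, OLS of spike counts (correct trials) on the
    regressor with a two-sided slope t-test. Windows with zero count
    variance record p = 1.
    """
    regs = regressor_frame(trials)
    x = regs[regressor].to_numpy(dtype=float)
    correct = trials[~trials["error"].astype(bool)].reset_index(drop=True)
    out = []
    for neuron, grp in spikes.groupby("neuron_id"):
        counts, meta = _counts_matrix(grp, correct, segments, window, step)
        p = simple_regression_pvalues(x, counts)
        out.append(SlidingWindowResult(
            neuron_id=neuron, pvalues=p, windows=meta, n_trials=len(correct)))
    return out


def shuffled_max_runs(
    x: np.ndarray, counts: np.ndarray, n_shuffles: int,
    rng: np.random.Generator, alpha: float = 0.05,
) -> np.ndarray:
    """Max significant-run lengths over trial-shuffled sliding-window series.

    Shuffling permutes the regressor over trials (counts fixed), destroying
    any progress relation while preserving the per-window marginal
    significance level and the between-window correlation induced by
    overlapping windows.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    Yc = counts - counts.mean(axis=0)
    sy = np.sqrt((Yc**2).sum(axis=0))
    xc = x - x.mean()
    sx = np.sqrt((xc**2).sum())
    perms = np.stack([rng.permutation(xc) for _ in range(n_shuffles)])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (perms @ Yc) / (sx * sy)
    r = np.clip(np.nan_to_num(r), -0.9999999, 0.9999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[:, sy == 0] = 1.0
    sig = p < alpha
    return np.array([longest_run(row) for row in sig])


@dataclass
class RunCalibration:
    threshold: int  # smallest L with P(max run > L) < 0.05 under shuffling
    max_runs: np.ndarray  # pooled over (neuron, shuffle)
    false_positive_rate: float  # fraction of shuffled series exceeding threshold


def calibrate_run_threshold(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    regressor: str = "Sequenceprogress",
    n_shuffles: int = 1000,
    window: float = 0.200,
    step: float = 0.025,
    segments=DEFAULT_SEGMENTS,
    alpha: float = 0.05,
    seed: int = 0,
) -> RunCalibration:
    """Bootstrap the run-length criterion for the sliding-window detector.

    For each neuron the sliding-window regression is repeated on
    trial-shuffled data; the criterion is the smallest run length L such
    that fewer than 5% of shuffled series show more than L consecutive
    significant windows. The detector then flags neurons whose real series
    exceeds L.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be positive")
    rng = np.random.default_rng(seed)
    regs = regressor_frame(trials)
    x = regs[regressor].to_numpy(dtype=float)
    correct = trials[~trials["error"].astype(bool)].reset_index(drop=True)
    runs = []
    for neuron, grp in spikes.groupby("neuron_id"):
        counts, _ = _counts_matrix(grp, correct, segments, window, step)
        runs.append(shuffled_max_runs(x, counts, n_shuffles, rng, alpha))
    max_runs = np.concatenate(runs)
    threshold = 0
    while (max_runs > threshold).mean() >= 0.05:
        threshold += 1
    return RunCalibration(
        threshold=threshold, max_runs=max_runs,
        false_positive_rate=float((max_runs > threshold).mean()),
    )


# ---------------------------------------------------------------------------
# generator/model identifiability

#: tuning enum -> the analysis model that should best fit it
RECOVERY_CLASSES = {
    "adaptive_progress": "eq3",
    "nonadaptive_progress": "eq2",
    "reward_magnitude": "eq4",
    "elapsed_time": "eq5",
    "step_tuned": "eq6",
}


def model_recovery_confusion(
    trials: pd.DataFrame,
    n_per_class: int = 200,
    baseline: float = 5.0,
    gain: float = 12.0,
    period: str = "cue",
    seed: int = 0,
    classes: dict[str, str] = RECOVERY_CLASSES,
) -> pd.DataFrame:
    """Confusion matrix of best-fitting models over ground-truth tuning classes.

    For each tuning class, ``n_per_class`` synthetic neurons are simulated on
    the given trials and refit with the whole single-regressor model suite;
    the winner is the model with the highest adjusted R². An identifiable
    generator/analysis pair shows a dominant diagonal. Rows: true tuning;
    columns: best-fit model; entries: fractions per class.
    """
    from .session_io import DEFAULT_PERIODS, extract_window_counts
    from .synthetic_data import NeuronSpec, generate_spikes

    regs = regressor_frame(trials)
    rng = np.random.default_rng(seed)
    models = tuple(sorted(set(classes.values())))
    confusion = pd.DataFrame(0.0, index=list(classes), columns=models)
    periods = {period: DEFAULT_PERIODS[period]}
    for tuning in classes:
        for i in range(n_per_class):
            spec = NeuronSpec(
                neuron_id=f"{tuning}_{i:04d}", tuning=tuning,
                baseline_rate=baseline, gain=gain, target_periods=(period,),
                step_centers=(int(rng.integers(2, 5)),) if tuning == "step_tuned" else (),
            )
            spikes = generate_spikes(spec, trials, seed)
            counts = extract_window_counts(spikes, trials, periods=periods)
            fits = fit_all_models(counts, trials, period=period,
                                  neuron_id=spec.neuron_id, regs=regs, models=models)
            confusion.loc[tuning, best_fit_model(fits, models)] += 1
    return confusion / n_per_class
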