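"""Population-level adaptation and error-trial analyses.

All functions take *normalized activity*: a tidy frame with columns
(neuron_id, session_id, trial_index, period, z) as produced by
:func:`saveseq.session_io.znormalize`, typically restricted to responses
significant for sequence progress and sign-corrected so that population
averages aggregate coherently.

The central quantity is the population progress slope: the OLS slope of
normalized activity on sequence progress, computed within a subset of
trials (one sequence length, one sequence, or one error condition). Under
an adaptive code the slope scales with the inverse of the planned sequence
length; under a non-adaptive code it is length-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regression import RegressionFit, ols_fit


def _merge(activity: pd.DataFrame, trials: pd.DataFrame, include_errors=False) -> pd.DataFrame:
    use = trials if include_errors else trials[~trials["error"].astype(bool)]
    cols = ["session_id", "trial_index", "sequence_id", "step",
            "sequence_length", "interest_rate", "task_type", "error"]
    return activity.merge(use[cols], on=["session_id", "trial_index"], how="inner")


def _pooled_slope(df: pd.DataFrame) -> float:
    x = df["step"].to_numpy(dtype=float)
    y = df["z"].to_numpy(dtype=float)
    if len(x) < 2 or np.ptp(x) == 0:
        return np.nan
    return float(np.polyfit(x, y, 1)[0])


@dataclass
class AdaptationResult:
    """Per-length population slopes and their relation to inverse length."""

    slopes: pd.DataFrame  # length, slope, n_sequences, n_trials
    coefficient: float  # slope of slope-vs-1/length regression
    intercept: float
    r_squared: float
    pvalue: float


def adaptation_by_length(
    activity: pd.DataFrame,
    trials: pd.DataFrame,
    min_sequences: int = 10,
    per_neuron: bool = False,
    include_spend: bool = True,
) -> AdaptationResult:
    """Fit population activity against progress separately per sequence length.

    For each final length L with at least ``min_sequences`` sequences, the
    progress slope is fit on pooled trial-level activity (or, with
    ``per_neuron``, averaged over per-neuron slopes); the slopes are then
    regressed on 1/L. A fully adaptive population (activity proportional to
    step/L) gives slope(L) = g/L, hence a perfect slope ~ 1/L line through
    the origin with coefficient g.
    """
    merged = _merge(activity, trials)
    if not include_spend:
        merged = merged[merged["step"] < merged["sequence_length"]]
    rows = []
    correct = trials[~trials["error"].astype(bool)]
    seq_counts = (correct.drop_duplicates(["session_id", "sequence_id"])
                  .groupby("sequence_length").size())
    for L, grp in merged.groupby("sequence_length"):
        if int(seq_counts.get(L, 0)) < min_sequences or grp["step"].nunique() < 2:
            continue
        if per_neuron:
            slopes = [s for _, sub in grp.groupby("neuron_id")
                      if not np.isnan(s := _pooled_slope(sub))]
            slope = float(np.mean(slopes)) if slopes else np.nan
        else:
            slope = _pooled_slope(grp)
        rows.append({"length": int(L), "slope": slope,
                     "n_sequences": int(seq_counts.get(L, 0)), "n_trials": len(grp)})
    slopes = pd.DataFrame(rows).dropna()
    if len(slopes) < 2:
        raise ValueError("need at least two sequence lengths with enough sequences")
    fit = stats.linregress(1.0 / slopes["length"], slopes["slope"])
    return AdaptationResult(
        slopes=slopes, coefficient=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), pvalue=float(fit.pvalue),
    )


def predict_sequence_length(
    activity: pd.DataFrame,
    trials: pd.DataFrame,
    step_k: int = 2,
) -> RegressionFit:
    """Regress final sequence length on population activity at sequence step k.

    Under adaptive coding, activity at a fixed step is lower for longer
    planned sequences (step/L decreases in L), so the prospective length is
    predictable from activity with a negative slope — except at step 1 when
    the generator enforces a common starting level.
    """
    merged = _merge(activity, trials)
    at_k = merged[merged["step"] == step_k]
    if at_k.empty:
        raise ValueError(f"no trials at step {step_k}")
    pop = (at_k.groupby(["session_id", "sequence_id"])
           .agg(z=("z", "mean"), length=("sequence_length", "first"))
           .reset_index())
    if pop["length"].nunique() < 2:
        raise ValueError("need at least two distinct forthcoming lengths")
    return ols_fit(pop[["z"]], pop["length"].to_numpy(dtype=float),
                   model_id=f"length_on_activity_step{step_k}")


@dataclass
class ConsecutiveAdaptationResult:
    pairs: pd.DataFrame  # per consecutive-sequence pair: lengths, slopes, deltas
    coefficient: float  # regression of Δslope on Δ(1/length)
    intercept: float
    r_squared: float
    pvalue: float


def consecutive_adaptation(
    activity: pd.DataFrame,
    trials: pd.DataFrame,
    min_length: int = 2,
) -> ConsecutiveAdaptationResult:
    """Slope re-adaptation between consecutive saving sequences.

    For adjacent sequence pairs (same session, task and interest-rate block,
    both lengths >= ``min_length``) the within-sequence population progress
    slopes are compared: Δslope is regressed on Δ(1/length). Under full
    adaptation with population gain g, Δslope = g Δ(1/L).
    """
    merged = _merge(activity, trials)
    correct = trials[~trials["error"].astype(bool)]
    seq_info = (correct.drop_duplicates(["session_id", "sequence_id"])
                [["session_id", "sequence_id", "sequence_length", "interest_rate", "task_type"]])
    slopes = {}
    for (sess, seq), grp in merged.groupby(["session_id", "sequence_id"]):
        if grp["step"].nunique() >= 2:
            slopes[(sess, seq)] = _pooled_slope(grp)
    rows = []
    for sess, info in seq_info.groupby("session_id"):
        info = info.sort_values("sequence_id").reset_index(drop=True)
        for i in range(len(info) - 1):
            a, b = info.iloc[i], info.iloc[i + 1]
            if b["sequence_id"] != a["sequence_id"] + 1:
                continue
            if a["interest_rate"] != b["interest_rate"] or a["task_type"] != b["task_type"]:
                continue
            if a["sequence_length"] < min_length or b["sequence_length"] < min_length:
                continue
            s1 = slopes.get((sess, a["sequence_id"]))
            s2 = slopes.get((sess, b["sequence_id"]))
            if s1 is None or s2 is None or np.isnan(s1) or np.isnan(s2):
                continue
            rows.append({
                "session_id": sess,
                "first_sequence": int(a["sequence_id"]), "second_sequence": int(b["sequence_id"]),
                "first_length": int(a["sequence_length"]), "second_length": int(b["sequence_length"]),
                "delta_slope": s2 - s1,
                "delta_inv_length": 1.0 / b["sequence_length"] - 1.0 / a["sequence_length"],
            })
    pairs = pd.DataFrame(rows)
    if pairs.empty:
        raise ValueError("no qualifying consecutive sequence pairs")
    if pairs["delta_inv_length"].nunique() < 2:
        raise ValueError("Δ(1/length) has no variance across pairs (equal-length pairs only)")
    fit = stats.linregress(pairs["delta_inv_length"], pairs["delta_slope"])
    return ConsecutiveAdaptationResult(
        pairs=pairs, coefficient=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), pvalue=float(fit.pvalue),
    )


@dataclass
class ErrorCodingResult:
    """Strength of progress coding before, on, and after error trials."""

    slopes: dict  # condition -> pooled raw slope of z on progress
    standardized: dict  # condition -> pooled standardized coefficient
    per_neuron: pd.DataFrame  # neuron_id, pre, on, post raw slopes
    pre_vs_on: tuple  # (t, p) dependent-samples
    post_vs_on: tuple
    on_pre_ratio: float  # attenuation estimate


def error_trial_coding(activity: pd.DataFrame, trials: pd.DataFrame) -> ErrorCodingResult:
    """Compare progress-coding strength on pre-error, error, and post-error trials.

    ``activity`` must retain error trials (window extraction with
    ``include_errors=True``). Raw and standardized progress slopes are fit
    within each condition; dependent-samples t-tests compare per-neuron
    slopes between conditions. The on/pre slope ratio estimates the error
    attenuation of the underlying tuning gain.
    """
    merged = _merge(activity, trials, include_errors=True)
    if not merged["error"].astype(bool).any():
        raise ValueError("no error trials in the dataset")
    by_sess = {s: g.sort_values("trial_index") for s, g in
               trials.groupby("session_id")}
    pre_keys, post_keys = set(), set()
    for sess, g in by_sess.items():
        err = g["error"].astype(bool).to_numpy()
        idx = g["trial_index"].to_numpy()
        for i in range(len(g)):
            if err[i]:
                continue
            if i + 1 < len(g) and err[i + 1]:
                pre_keys.add((sess, int(idx[i])))
            if i - 1 >= 0 and err[i - 1]:
                post_keys.add((sess, int(idx[i])))
    keys = list(zip(merged["session_id"], merged["trial_index"].astype(int)))
    is_err = merged["error"].astype(bool).to_numpy()
    masks = {
        "pre": np.array([k in pre_keys for k in keys]) & ~is_err,
        "on": is_err,
        "post": np.array([k in post_keys for k in keys]) & ~is_err,
    }
    slopes, standardized = {}, {}
    per_neuron_rows = {}
    for cond, mask in masks.items():
        sub = merged[mask]
        if sub.empty or sub["step"].nunique() < 2:
            raise ValueError(f"no usable trials in condition {cond!r}")
        fit = ols_fit(sub[["step"]].astype(float), sub["z"].to_numpy(dtype=float),
                      model_id=f"error_{cond}")
        slopes[cond] = fit.slope
        standardized[cond] = float(fit.standardized.get("step", np.nan))
        for neuron, ngrp in sub.groupby("neuron_id"):
            per_neuron_rows.setdefault(neuron, {})[cond] = _pooled_slope(ngrp)
    per_neuron = (pd.DataFrame.from_dict(per_neuron_rows, orient="index")
                  .rename_axis("neuron_id").reset_index())
    paired = per_neuron.dropna(subset=["pre", "on", "post"])
    if len(paired) >= 3:
        pre_on = stats.ttest_rel(paired["pre"], paired["on"])
        post_on = stats.ttest_rel(paired["post"], paired["on"])
        pre_vs_on = (float(pre_on.statistic), float(pre_on.pvalue))
        post_vs_on = (float(post_on.statistic), float(post_on.pvalue))
    else:
        pre_vs_on = post_vs_on = (np.nan, np.nan)
    ratio = slopes["on"] / slopes["pre"] if slopes["pre"] != 0 else np.nan
    return ErrorCodingResult(
        slopes=slopes, standardized=standardized, per_neuron=per_neuron,
        pre_vs_on=pre_vs_on, post_vs_on=post_vs_on, on_pre_ratio=float(ratio),
    )


def population_progress_slope(activity: pd.DataFrame, trials: pd.DataFrame) -> float:
    """Pooled slope of normalized activity on progress (non-negative after sign correction)."""
    merged = _merge(activity, trials)
    return _pooled_slope(merged)
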