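"""Reward dynamics, subjective values, and behavioral analyses of the saving task.

The task: on each trial the animal chooses to *save* (accumulate liquid
reward, which grows at an interest rate q) or *spend* (consume the amount
accumulated so far). A run of save choices terminated by one spend choice is
a *saving sequence*; its length is self-determined. The cumulative count of
correct trials since sequence start is the *sequence progress* n — the
central behavioral variable of every downstream analysis.

Reward accumulated after n-1 save choices follows a geometric series

    x_n = b * sum_{i=0}^{n-1} q**i

with base rate b (ml) and interest rate q. Subjective values derive from the
animal's own length preferences: the spend value at step i is the
probability of producing a sequence of length i times the objective reward
magnitude there; the save value at step n is the mean spend value over all
future steps of the sequence.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .regression import RegressionFit, ols_fit

#: Column schema for a trials table, one row per trial (error trials included).
TRIAL_COLUMNS = [
    "session_id", "trial_index", "sequence_id", "step", "sequence_length",
    "interest_rate", "base_rate", "choice", "task_type", "cue_position",
    "action_side", "error", "t_fix_on", "t_cue_on", "t_choice", "t_outcome",
    "rt_key", "rt_saccade", "reward_ml",
]

CHOICES = ("save", "spend")
TASK_TYPES = ("free", "imperative")
CUE_POSITIONS = ("save_left", "save_right")
ACTION_SIDES = ("left", "right")


def accumulate_reward(step: int, base_rate: float, interest_rate: float) -> float:
    """Reward magnitude (ml) available at trial ``step`` of a saving sequence.

    Returns b * sum_{i=0}^{n-1} q**i, the amount accumulated after ``step - 1``
    save choices; equals b(q**n - 1)/(q - 1) for q != 1 and b*n for q == 1.

    >>> accumulate_reward(2, 0.11, 1.5)
    0.275
    """
    step_arr = np.asarray(step)
    if not np.issubdtype(step_arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(step_arr, 1), 0)):
            raise ValueError("step must be a positive integer")
        step_arr = step_arr.astype(int)
    if np.any(step_arr < 1):
        raise ValueError("step must be >= 1")
    if base_rate <= 0 or interest_rate <= 0:
        raise ValueError("base_rate and interest_rate must be positive")
    q = float(interest_rate)
    n = step_arr
    if q == 1.0:
        out = base_rate * n.astype(float)
    else:
        # expm1/log1p form of b(q^n - 1)/(q - 1): stable as q -> 1
        d = q - 1.0
        out = base_rate * np.expm1(n.astype(float) * np.log1p(d)) / d
    return float(out) if np.isscalar(step) else out


def round_ml(value: float, ndigits: int = 3) -> float:
    """Round a reward magnitude for display: half-up, three decimals by default."""
    d = decimal.Decimal(repr(float(value))).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


@dataclass
class SubjectiveValueTable:
    """Per-interest-rate subjective values over sequence positions 1..m.

    ``P[i-1]`` is the empirical probability of a sequence of length i,
    ``M[i-1]`` the objective reward there, ``sv_spend = P * M``, and
    ``sv_save[n-1]`` the mean future spend value at position n (defined for
    n = 1..m-1).
    """

    interest_rate: float
    P: np.ndarray
    M: np.ndarray
    sv_spend: np.ndarray
    sv_save: np.ndarray
    m: int

    def seq_sv(self, realized_length: int) -> float:
        """Value of a sequence: the spend value actually realized at its end."""
        if not 1 <= realized_length <= self.m:
            raise ValueError(f"realized length {realized_length} outside 1..{self.m}")
        return float(self.sv_spend[realized_length - 1])


def spend_value_table(
    length_frequencies: Iterable[float] | Mapping[int, float],
    base_rate: float,
    interest_rate: float,
) -> SubjectiveValueTable:
    """Build the subjective-value table from observed sequence-length frequencies.

    ``length_frequencies`` maps length i -> probability (or is a vector over
    i = 1..m); probabilities must be non-negative and sum to one.
    """
    if isinstance(length_frequencies, Mapping):
        m = max(length_frequencies)
        P = np.zeros(m)
        for length, p in length_frequencies.items():
            if length < 1:
                raise ValueError("sequence lengths start at 1")
            P[length - 1] = p
    else:
        P = np.asarray(list(length_frequencies), dtype=float)
        m = len(P)
    if m < 1 or np.all(P == 0):
        raise ValueError("length frequencies must have positive mass")
    if np.any(P < 0):
        raise ValueError("negative frequency")
    if not np.isclose(P.sum(), 1.0, atol=1e-6):
        raise ValueError(f"frequencies sum to {P.sum():.6f}, expected 1")
    steps = np.arange(1, m + 1)
    M = accumulate_reward(steps, base_rate, interest_rate)
    sv_spend = P * M
    # mean future spend value at each position n = 1..m-1
    rev_cumsum = np.cumsum(sv_spend[::-1])[::-1]
    remaining = m - np.arange(1, m)
    sv_save = (rev_cumsum[1:]) / remaining
    return SubjectiveValueTable(
        interest_rate=float(interest_rate), P=P, M=M,
        sv_spend=sv_spend, sv_save=sv_save, m=m,
    )


def save_value(table: SubjectiveValueTable, position: int) -> float:
    """Subjective value of saving at sequence position n: mean of future spend values."""
    if position < 1 or position >= table.m:
        raise ValueError(f"position must satisfy 1 <= n <= m-1 = {table.m - 1}")
    return float(table.sv_save[position - 1])


def tables_from_trials(trials: pd.DataFrame) -> dict[float, SubjectiveValueTable]:
    """Empirical subjective-value tables, one per interest rate, pooled over sessions."""
    correct = trials[~trials["error"].astype(bool)]
    out: dict[float, SubjectiveValueTable] = {}
    for q, grp in correct.groupby("interest_rate"):
        seqs = grp.drop_duplicates(["session_id", "sequence_id"])
        lengths = seqs["sequence_length"].astype(int)
        counts = lengths.value_counts().sort_index()
        freqs = {int(k): v / counts.sum() for k, v in counts.items()}
        b = float(grp["base_rate"].iloc[0])
        out[float(q)] = spend_value_table(freqs, b, float(q))
    return out


def choice_probability_by_progress(trials: pd.DataFrame) -> pd.DataFrame:
    """Spend-choice probability at each sequence step (the discrete hazard).

    For each interest rate and step s: (# spend choices at step s) /
    (# sequences reaching step s), over correct trials. The probability at
    the largest observed step is 1 by construction.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    correct = trials[~trials["error"].astype(bool)]
    if len(correct) == 0:
        raise ValueError("no correct trials")
    rows = []
    for q, grp in correct.groupby("interest_rate"):
        for s, step_grp in grp.groupby("step"):
            n_reached = len(step_grp)
            n_spend = int((step_grp["choice"] == "spend").sum())
            rows.append({
                "interest_rate": float(q), "step": int(s),
                "n_reached": n_reached, "n_spend": n_spend,
                "p_spend": n_spend / n_reached,
            })
    return pd.DataFrame(rows).sort_values(["interest_rate", "step"]).reset_index(drop=True)


#: Reaction-time regressors available to :func:`rt_regression`.
RT_COVARIATES = (
    "progress", "choice", "seq_length", "task",
    "progress_x_task", "progress_x_inv_length",
)


def znormalize_rt(trials: pd.DataFrame, rt_field: str) -> np.ndarray:
    """Z-normalize reaction times within each session (mean 0, sd 1 per session)."""
    col = {"key": "rt_key", "saccade": "rt_saccade"}[rt_field]
    rt = trials[col].astype(float)
    z = np.full(len(trials), np.nan)
    for _, idx in trials.groupby("session_id").groups.items():
        vals = rt.loc[idx]
        sd = vals.std(ddof=1)
        z[trials.index.get_indexer(idx)] = (
            (vals - vals.mean()) / sd if sd > 0 else 0.0
        )
    return z


def rt_regression(
    trials: pd.DataFrame,
    rt_field: str = "key",
    covariates: Iterable[str] = ("progress", "choice", "seq_length"),
) -> RegressionFit:
    """Multiple linear regression of session-normalized reaction times.

    Supported covariates: sequence progress, save/spend choice (spend = 1),
    final sequence length, a free-vs-imperative task dummy (free = 1), the
    progress x task interaction, and the progress x (1/length) interaction
    that captures adaptation of motivation to planned sequence length.
    """
    covariates = list(covariates)
    unknown = set(covariates) - set(RT_COVARIATES)
    if unknown:
        raise ValueError(f"unknown covariates: {sorted(unknown)}")
    correct = trials[~trials["error"].astype(bool)].reset_index(drop=True)
    y = znormalize_rt(correct, rt_field)
    cols: dict[str, np.ndarray] = {}
    progress = correct["step"].to_numpy(dtype=float)
    if "progress" in covariates:
        cols["progress"] = progress
    if "choice" in covariates:
        cols["choice"] = (correct["choice"] == "spend").to_numpy(dtype=float)
    if "seq_length" in covariates:
        cols["seq_length"] = correct["sequence_length"].to_numpy(dtype=float)
    if "task" in covariates:
        cols["task"] = (correct["task_type"] == "free").to_numpy(dtype=float)
    if "progress_x_task" in covariates:
        cols["progress_x_task"] = progress * (correct["task_type"] == "free").to_numpy(dtype=float)
    if "progress_x_inv_length" in covariates:
        cols["progress_x_inv_length"] = progress / correct["sequence_length"].to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    if len(X) < len(covariates) + 2:
        raise ValueError("fewer trials than parameters")
    return ols_fit(X, y, model_id=f"rt_{rt_field}")


def validate_trials(trials: pd.DataFrame) -> list[str]:
    """Check the trial-table invariants; return human-readable violations.

    Checked per sequence (correct trials only): step runs 1..L with exactly
    one spend choice on the final correct trial whose step equals the
    sequence length; spend-trial reward matches the accumulation rule; event
    times increase within every trial.
    """
    problems: list[str] = []
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        return [f"missing columns: {missing}"]
    for col, allowed in [
        ("choice", CHOICES), ("task_type", TASK_TYPES),
        ("cue_position", CUE_POSITIONS), ("action_side", ACTION_SIDES),
    ]:
        bad = ~trials[col].isin(allowed)
        # canceled error trials may carry NA choice/side
        if col in ("choice", "action_side"):
            bad &= ~(trials["error"].astype(bool) & trials[col].isna())
        if bad.any():
            problems.append(f"rows {list(trials.index[bad])[:5]}: invalid {col}")
    ev = trials[["t_fix_on", "t_cue_on", "t_choice", "t_outcome"]].to_numpy(dtype=float)
    nondec = ~(np.diff(ev, axis=1) > 0).all(axis=1)
    nondec &= ~np.isnan(ev).any(axis=1)
    if nondec.any():
        problems.append(f"rows {list(trials.index[nondec])[:5]}: event times not increasing")
    correct = trials[~trials["error"].astype(bool)]
    for (sess, seq), grp in correct.groupby(["session_id", "sequence_id"]):
        grp = grp.sort_values("trial_index")
        steps = grp["step"].to_numpy(dtype=int)
        L = int(grp["sequence_length"].iloc[0])
        label = f"session {sess} sequence {seq}"
        if not np.array_equal(steps, np.arange(1, len(steps) + 1)):
            problems.append(f"{label}: steps {steps.tolist()} not consecutive from 1")
            continue
        spends = grp["choice"] == "spend"
        if spends.sum() != 1 or not bool(spends.iloc[-1]):
            problems.append(f"{label}: expected exactly one spend on the last correct trial")
            continue
        if steps[-1] != L or (grp["sequence_length"] != L).any():
            problems.append(f"{label}: final step {steps[-1]} != sequence_length {L}")
            continue
        spend_row = grp.iloc[-1]
        expected = accumulate_reward(L, float(spend_row["base_rate"]), float(spend_row["interest_rate"]))
        if not np.isclose(float(spend_row["reward_ml"]), expected, atol=1e-9):
            problems.append(
                f"{label}: spend reward {spend_row['reward_ml']} != accumulate_reward = {expected:.6f}"
            )
    return problems
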