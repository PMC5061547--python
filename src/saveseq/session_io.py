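"""Dataset I/O, task-period window extraction, and activity normalization.

On-disk layout of a dataset directory::

    trials.csv    one row per trial (error trials included), TrialRecord schema
    spikes.csv    neuron_id, session_id, trial_index, t  (seconds from trial start)
    neurons.csv   ground-truth tuning table (synthetic datasets)
    manifest.json generator config echo + seed + package version

CSV dialect: comma, UTF-8, "." decimal, booleans as 0/1, missing values "NA".
All analysis windows are half-open [start, start + duration): a spike exactly
at the window start is counted, one exactly at the end is not.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .task_model import TRIAL_COLUMNS, validate_trials
from .regression import simple_regression_pvalues

log = logging.getLogger("saveseq")

SPIKE_COLUMNS = ["neuron_id", "session_id", "trial_index", "t"]

PERIOD_NAMES = ("pre_fixation", "fixation", "cue", "delay", "outcome")


@dataclass(frozen=True)
class PeriodDefinition:
    """A fixed analysis window anchored to a trial event."""

    name: str
    anchor_event: str
    start_offset: float  # s, signed, relative to anchor
    duration: float  # s

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("period duration must be positive")


#: The five fixed task periods: 1000 ms before fixation onset (the control
#: period), 1775 ms of fixation from +25 ms, 300 ms of cue from +20 ms,
#: 1500 ms of post-choice delay from +25 ms, and 500 ms of outcome from
#: +50 ms after the reinforcer.
DEFAULT_PERIODS: dict[str, PeriodDefinition] = {
    "pre_fixation": PeriodDefinition("pre_fixation", "t_fix_on", -1.000, 1.000),
    "fixation": PeriodDefinition("fixation", "t_fix_on", 0.025, 1.775),
    "cue": PeriodDefinition("cue", "t_cue_on", 0.020, 0.300),
    "delay": PeriodDefinition("delay", "t_choice", 0.025, 1.500),
    "outcome": PeriodDefinition("outcome", "t_outcome", 0.050, 0.500),
}

CONTROL_PERIOD = "pre_fixation"


def period_interval(trial_row, period: PeriodDefinition) -> tuple[float, float]:
    """Absolute [start, end) of a period within one trial (seconds from trial start)."""
    anchor = float(trial_row[period.anchor_event])
    start = anchor + period.start_offset
    return start, start + period.duration


# ---------------------------------------------------------------------------
# dataset read/write


def _encode(trials: pd.DataFrame) -> pd.DataFrame:
    out = trials.copy()
    out["error"] = out["error"].astype(bool).astype(int)
    return out


def write_dataset(
    path: str | Path,
    trials: pd.DataFrame,
    spikes: pd.DataFrame,
    neurons: pd.DataFrame | None = None,
    manifest: dict | None = None,
) -> Path:
    """Write a dataset directory; trial invariants are validated before writing."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    problems = validate_trials(trials)
    if problems:
        raise ValueError("trial table violates invariants:\n" + "\n".join(problems))
    _encode(trials)[TRIAL_COLUMNS].to_csv(path / "trials.csv", index=False, na_rep="NA")
    spikes[SPIKE_COLUMNS].to_csv(path / "spikes.csv", index=False, na_rep="NA")
    if neurons is not None:
        if neurons["neuron_id"].duplicated().any():
            raise ValueError("duplicate neuron ids")
        neurons.to_csv(path / "neurons.csv", index=False, na_rep="NA")
    if manifest is not None:
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_dataset(path: str | Path, validate: bool = True):
    """Read a dataset directory back into (trials, spikes, neurons, manifest).

    Raises ``ValueError`` on schema mismatch or, when ``validate``, on
    TrialRecord invariant violations (reported with row identifiers).
    """
    path = Path(path)
    trials = pd.read_csv(path / "trials.csv", na_values=["NA"], keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trials.csv: missing columns {missing}")
    trials["error"] = trials["error"].astype(bool)
    spikes = pd.read_csv(path / "spikes.csv", na_values=["NA"], keep_default_na=False)
    missing = [c for c in SPIKE_COLUMNS if c not in spikes.columns]
    if missing:
        raise ValueError(f"spikes.csv: missing columns {missing}")
    if validate and len(trials):
        problems = validate_trials(trials)
        if problems:
            raise ValueError("trials.csv violates invariants:\n" + "\n".join(problems))
    neurons = None
    if (path / "neurons.csv").exists():
        neurons = pd.read_csv(path / "neurons.csv", na_values=["NA"], keep_default_na=False)
    manifest = None
    if (path / "manifest.json").exists():
        manifest = json.loads((path / "manifest.json").read_text())
    return trials, spikes, neurons, manifest


# ---------------------------------------------------------------------------
# window extraction


def extract_window_counts(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    periods: dict[str, PeriodDefinition] | None = None,
    include_errors: bool = False,
) -> pd.DataFrame:
    """Count spikes of every neuron in the fixed task periods of every trial.

    Returns a tidy frame (neuron_id, session_id, trial_index, period, count,
    rate) over correct trials (error trials only when ``include_errors``,
    e.g. for the error-trial coding analysis). Spikes outside the trial span
    are dropped with a warning.
    """
    periods = periods or DEFAULT_PERIODS
    use = trials if include_errors else trials[~trials["error"].astype(bool)]
    ev = use[["session_id", "trial_index", "t_fix_on", "t_cue_on", "t_choice", "t_outcome"]]

    sp = spikes.merge(ev, on=["session_id", "trial_index"], how="inner")
    t = sp["t"].to_numpy(dtype=float)
    span_end = sp["t_outcome"].to_numpy(dtype=float) + 1.0
    outside = (t < 0) | (t >= span_end)
    if outside.any():
        log.warning("extract_window_counts: dropping %d spikes outside trial span",
                    int(outside.sum()))
        sp = sp[~outside]
        t = sp["t"].to_numpy(dtype=float)

    neuron_ids = spikes["neuron_id"].unique()
    trial_keys = list(ev[["session_id", "trial_index"]].itertuples(index=False, name=None))
    grid = pd.MultiIndex.from_tuples(
        [(n, s, i) for n in neuron_ids for (s, i) in trial_keys],
        names=["neuron_id", "session_id", "trial_index"],
    )
    pieces = []
    for name, per in periods.items():
        start = sp[per.anchor_event].to_numpy(dtype=float) + per.start_offset
        in_window = (t >= start) & (t < start + per.duration)
        counted = (
            sp[in_window]
            .groupby(["neuron_id", "session_id", "trial_index"], sort=False)
            .size()
            .reindex(grid, fill_value=0)
        )
        piece = counted.rename("count").reset_index()
        piece["period"] = name
        piece["rate"] = piece["count"] / per.duration
        pieces.append(piece)
    out = pd.concat(pieces, ignore_index=True)
    return out[["neuron_id", "session_id", "trial_index", "period", "count", "rate"]]


# ---------------------------------------------------------------------------
# normalization


def znormalize(
    counts: pd.DataFrame,
    mode: str = "control_period",
    control_period: str = CONTROL_PERIOD,
    trials: pd.DataFrame | None = None,
    sign_correct: bool = False,
) -> pd.DataFrame:
    """Z-score task-period rates per neuron.

    ``control_period`` mode subtracts each neuron's mean pre-fixation rate
    and divides by its standard deviation — the population-analysis
    normalization. ``session`` mode z-scores each (neuron, period) against
    its own across-trial distribution. Neurons whose normalizing sd is zero
    are excluded and logged.

    With ``sign_correct`` (requires ``trials``), responses whose regression
    slope on sequence progress is negative are flipped so that population
    averages aggregate coherently.
    """
    if mode not in ("control_period", "session"):
        raise ValueError(f"unknown mode {mode!r}")
    out = counts.copy()
    excluded = []
    z = np.full(len(out), np.nan)
    if mode == "control_period":
        ctrl = counts[counts["period"] == control_period]
        stats_ = ctrl.groupby("neuron_id")["rate"].agg(["mean", "std"])
        for neuron, row in stats_.iterrows():
            mask = (out["neuron_id"] == neuron).to_numpy()
            if not row["std"] > 0:
                excluded.append(neuron)
                continue
            z[mask] = (out.loc[mask, "rate"] - row["mean"]) / row["std"]
    else:
        for (neuron, period), idx in out.groupby(["neuron_id", "period"]).groups.items():
            vals = out.loc[idx, "rate"]
            sd = vals.std(ddof=1)
            if not sd > 0:
                excluded.append((neuron, period))
                continue
            z[out.index.get_indexer(idx)] = (vals - vals.mean()) / sd
    out["z"] = z
    if excluded:
        log.info("znormalize: excluded %d neurons/responses with zero sd: %s",
                 len(excluded), excluded[:10])
    out = out[~out["z"].isna()].reset_index(drop=True)
    if sign_correct:
        if trials is None:
            raise ValueError("sign correction requires the trial table")
        out = apply_sign_correction(out, trials)
    return out


def apply_sign_correction(zcounts: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Flip (neuron, period) responses whose progress slope is negative."""
    correct = trials[~trials["error"].astype(bool)][
        ["session_id", "trial_index", "step"]
    ]
    merged = zcounts.merge(correct, on=["session_id", "trial_index"], how="inner")
    out = zcounts.copy()
    for (neuron, period), idx in merged.groupby(["neuron_id", "period"]).groups.items():
        sub = merged.loc[idx]
        x = sub["step"].to_numpy(dtype=float)
        y = sub["z"].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        slope = np.polyfit(x, y, 1)[0]
        if slope < 0:
            flip = (out["neuron_id"] == neuron) & (out["period"] == period)
            out.loc[flip, "z"] = -out.loc[flip, "z"]
    return out


__all__ = [
    "PeriodDefinition", "DEFAULT_PERIODS", "CONTROL_PERIOD", "PERIOD_NAMES",
    "period_interval", "write_dataset", "read_dataset",
    "extract_window_counts", "znormalize", "apply_sign_correction",
    "simple_regression_pvalues",
]
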