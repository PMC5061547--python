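"""Synthetic saving-task experiments: behavior, reaction times, spike trains.

The generator emulates the statistical structure the downstream analyses
assume: self-determined saving sequences drawn from per-interest-rate length
distributions, Bernoulli error trials that do not advance sequence progress,
reaction times following a linear model with a negative progress slope and a
progress x (1/length) adaptation interaction, and inhomogeneous-Poisson
spike trains whose rate is phasically incremented in target task periods
according to one of several ground-truth tuning models:

========================  ====================================================
tuning                    rate drive f (normalized to max 1 over the session)
========================  ====================================================
adaptive_progress         step / sequence_length
nonadaptive_progress      step / max_step
partial_adaptive          w * step/length + (1-w) * step/max_step
reward_magnitude          accumulated reward x_n (geometric rule)
elapsed_time              within-sequence trial count including error trials
step_tuned                indicator of specific sequence steps
reward_expectation        within-trial ramp to outcome, identical across steps
null                      0
========================  ====================================================

The firing rate on a trial is ``baseline + gain * f`` inside the neuron's
target periods and ``baseline`` elsewhere, clipped at zero; the drive is
silenced in imperative trials for free-only neurons and multiplied by
``error_attenuation`` on error trials.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import session_io
from .task_model import TRIAL_COLUMNS, accumulate_reward
from .session_io import DEFAULT_PERIODS, PeriodDefinition

TUNINGS = (
    "adaptive_progress", "nonadaptive_progress", "partial_adaptive",
    "reward_magnitude", "elapsed_time", "step_tuned", "reward_expectation",
    "null",
)


@dataclass
class NeuronSpec:
    """Ground-truth tuning model and parameters for one synthetic neuron."""

    neuron_id: str
    tuning: str = "null"
    baseline_rate: float = 5.0  # Hz
    gain: float = 12.0  # Hz at maximal drive; negative = decreasing response
    adaptation_weight: float = 1.0  # w in [0,1]; partial_adaptive mixing
    target_periods: tuple[str, ...] = ("cue",)
    free_only: bool = False
    error_attenuation: float = 1.0  # gain multiplier on error trials
    region: str = "basolateral"
    step_centers: tuple[int, ...] = ()

    def __post_init__(self):
        if self.tuning not in TUNINGS:
            raise ValueError(f"unknown tuning {self.tuning!r}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if not 0.0 <= self.adaptation_weight <= 1.0:
            raise ValueError("adaptation_weight must lie in [0,1]")
        if not 0.0 <= self.error_attenuation <= 1.0:
            raise ValueError("error_attenuation must lie in [0,1]")
        if self.region not in ("basolateral", "centromedial"):
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class RTModel:
    """Linear reaction-time model (seconds); noise is Gaussian."""

    key_intercept: float = 0.45
    key_progress: float = -0.010  # negative: faster later in the sequence
    key_adaptive: float = -0.050  # coefficient on step/length (adaptation)
    key_choice: float = -0.030  # spend trials faster
    key_sd: float = 0.050
    saccade_intercept: float = 0.200
    saccade_progress: float = 0.002
    saccade_sd: float = 0.030
    floor: float = 0.050


@dataclass
class TaskTiming:
    """Event schedule within a trial (seconds from trial start)."""

    pre_fixation: float = 1.0  # fixation spot appears this long after start
    fixation_to_cue: float = 2.0  # 1500 ms fixation + 500 ms mean extra
    choice_to_go: float = 1.5  # post-choice delay before the go signal
    post_outcome: float = 0.6  # recording continues past the reinforcer


@dataclass
class GeneratorConfig:
    """Full recipe for one synthetic experiment."""

    interest_rates: dict[float, dict[int, float]] = field(
        default_factory=lambda: {1.5: {2: 0.15, 3: 0.25, 4: 0.25, 5: 0.20, 6: 0.10, 7: 0.05}}
    )
    base_rate: float = 0.11  # ml
    n_sequences: int = 200  # per interest rate and session
    error_rate: float = 0.10
    include_imperative: bool = True
    n_sessions: int = 1
    timing: TaskTiming = field(default_factory=TaskTiming)
    rt_model: RTModel = field(default_factory=RTModel)
    neurons: list[NeuronSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for q, dist in self.interest_rates.items():
            total = sum(dist.values())
            if total <= 0:
                raise ValueError(f"length distribution for q={q} has zero mass")
            if any(p < 0 or p > 1 for p in dist.values()):
                raise ValueError("length probabilities must lie in [0,1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0,1)")


def _substream(*keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(keys)))


def _neuron_key(neuron_id: str) -> int:
    return zlib.crc32(neuron_id.encode("utf-8"))


# ---------------------------------------------------------------------------
# behavior


def generate_behavior(
    config: GeneratorConfig,
    task_type: str = "free",
    session_id: str = "S1",
    session_key: int = 0,
) -> pd.DataFrame:
    """One session of trials for one task type.

    Sequence lengths are drawn i.i.d. from the per-interest-rate length
    distribution; the draw depends only on (seed, session, interest rate) so
    an imperative session reuses the free-choice length sequence, matching
    save/spend statistics between tasks. Error trials are injected with the
    configured per-trial probability; they repeat the pending step without
    advancing it, and accumulated reward is retained across them.
    """
    if task_type not in ("free", "imperative"):
        raise ValueError(f"unknown task_type {task_type!r}")
    task_key = 0 if task_type == "free" else 1
    rng = _substream(config.seed, session_key, task_key, 22)

    rows: list[dict] = []
    trial_index = 0
    sequence_id = 0
    for q_index, (q, dist) in enumerate(sorted(config.interest_rates.items())):
        lengths = np.array(sorted(dist))
        probs = np.array([dist[k] for k in lengths], dtype=float)
        probs = probs / probs.sum()
        len_rng = _substream(config.seed, session_key, q_index, 11)
        drawn = len_rng.choice(lengths, size=config.n_sequences, p=probs)
        for L in drawn:
            L = int(L)
            for step in range(1, L + 1):
                consecutive_errors = 0
                while rng.random() < config.error_rate and consecutive_errors < 3:
                    rows.append(_trial_row(
                        config, session_id, trial_index, sequence_id, step, L,
                        q, task_type, error=True, rng=rng,
                    ))
                    trial_index += 1
                    consecutive_errors += 1
                rows.append(_trial_row(
                    config, session_id, trial_index, sequence_id, step, L,
                    q, task_type, error=False, rng=rng,
                ))
                trial_index += 1
            sequence_id += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _trial_row(config, session_id, trial_index, sequence_id, step, length,
               q, task_type, error, rng) -> dict:
    tm, rt = config.timing, config.rt_model
    spend = (step == length) and not error
    cue_position = "save_left" if rng.random() < 0.5 else "save_right"
    if error:
        choice = np.nan
        action_side = np.nan
        rt_key = np.nan
        rt_saccade = np.nan
        # schedule markers for window extraction on canceled trials
        sacc, key = 0.25, 0.35
        reward = 0.0
    else:
        choice = "spend" if spend else "save"
        rt_key = (rt.key_intercept + rt.key_progress * step
                  + rt.key_adaptive * step / length
                  + rt.key_choice * float(spend)
                  + rng.normal(0.0, rt.key_sd))
        rt_saccade = (rt.saccade_intercept + rt.saccade_progress * step
                      + rng.normal(0.0, rt.saccade_sd))
        rt_key = max(rt.floor, rt_key)
        rt_saccade = max(rt.floor, rt_saccade)
        sacc, key = rt_saccade, rt_key
        saves_left = cue_position == "save_left"
        goes_save = choice == "save"
        action_side = "left" if saves_left == goes_save else "right"
        reward = accumulate_reward(step, config.base_rate, q) if spend else 0.0
    t_fix = tm.pre_fixation
    t_cue = t_fix + tm.fixation_to_cue
    t_choice = t_cue + sacc
    t_outcome = t_choice + tm.choice_to_go + key
    return dict(
        session_id=session_id, trial_index=trial_index, sequence_id=sequence_id,
        step=step, sequence_length=length, interest_rate=q,
        base_rate=config.base_rate, choice=choice, task_type=task_type,
        cue_position=cue_position, action_side=action_side, error=error,
        t_fix_on=t_fix, t_cue_on=t_cue, t_choice=t_choice, t_outcome=t_outcome,
        rt_key=rt_key, rt_saccade=rt_saccade, reward_ml=reward,
    )


# ---------------------------------------------------------------------------
# tuning drives


def elapsed_within_sequence(trials: pd.DataFrame) -> pd.Series:
    """Cumulative trial count within each sequence, error trials included."""
    order = trials.sort_values("trial_index")
    ranks = order.groupby(["session_id", "sequence_id"]).cumcount() + 1
    return ranks.reindex(trials.index)


def tuning_drive(spec: NeuronSpec, trials: pd.DataFrame) -> np.ndarray:
    """Per-trial drive f in [0, 1] for the spec's tuning model.

    The drive is normalized by its session maximum so ``gain`` is the rate
    increment (Hz) at maximal drive, comparable across tuning models.
    reward_expectation returns 1 (its within-trial ramp is applied at spike
    generation); null returns 0.
    """
    step = trials["step"].to_numpy(dtype=float)
    length = trials["sequence_length"].to_numpy(dtype=float)
    max_step = float(length.max())
    if spec.tuning == "adaptive_progress":
        f = step / length
    elif spec.tuning == "nonadaptive_progress":
        f = step / max_step
    elif spec.tuning == "partial_adaptive":
        w = spec.adaptation_weight
        f = w * step / length + (1.0 - w) * step / max_step
    elif spec.tuning == "reward_magnitude":
        b = trials["base_rate"].to_numpy(dtype=float)
        q = trials["interest_rate"].to_numpy(dtype=float)
        mags = np.array([
            accumulate_reward(int(s), float(bb), float(qq))
            for s, bb, qq in zip(step, b, q)
        ])
        f = mags / mags.max()
    elif spec.tuning == "elapsed_time":
        el = elapsed_within_sequence(trials).to_numpy(dtype=float)
        f = el / el.max()
    elif spec.tuning == "step_tuned":
        if not spec.step_centers:
            raise ValueError("step_tuned spec requires step_centers")
        f = np.isin(step, np.asarray(spec.step_centers)).astype(float)
    elif spec.tuning == "reward_expectation":
        f = np.ones_like(step)
    else:  # null
        f = np.zeros_like(step)
    # task/error multipliers
    mult = np.ones_like(f)
    if spec.free_only:
        mult *= (trials["task_type"] == "free").to_numpy(dtype=float)
    err = trials["error"].astype(bool).to_numpy()
    mult[err] *= spec.error_attenuation
    return f * mult


# ---------------------------------------------------------------------------
# spikes


def generate_spikes(
    spec: NeuronSpec,
    trials: pd.DataFrame,
    seed: int,
    periods: dict[str, PeriodDefinition] | None = None,
) -> pd.DataFrame:
    """Inhomogeneous-Poisson spike trains for one neuron over all trials.

    The rate is piecewise constant: baseline everywhere in the trial span,
    plus ``gain * drive`` inside each target period (for reward_expectation
    the increment is additionally scaled by the period's fractional time to
    outcome, giving a within-trial ramp identical across steps). Negative
    resulting rates are clipped at zero with a logged warning.
    """
    periods = periods or DEFAULT_PERIODS
    rng = np.random.default_rng(np.random.SeedSequence([seed, _neuron_key(spec.neuron_id)]))
    drive = tuning_drive(spec, trials)
    targets = [periods[p] for p in spec.target_periods]
    clipped = 0
    out_sess, out_idx, out_t = [], [], []
    cols = trials[["session_id", "trial_index", "t_fix_on", "t_cue_on",
                   "t_choice", "t_outcome"]]
    for trial, f in zip(cols.itertuples(index=False), drive):
        span = float(trial.t_outcome) + 1.0
        edges = {0.0, span}
        incs: list[tuple[float, float, float]] = []
        for per in targets:
            start = float(getattr(trial, per.anchor_event)) + per.start_offset
            end = start + per.duration
            start, end = max(0.0, start), min(span, end)
            if end <= start:
                continue
            inc = spec.gain * f
            if spec.tuning == "reward_expectation":
                mid = 0.5 * (start + end)
                inc *= mid / float(trial.t_outcome)
            incs.append((start, end, inc))
            edges.update((start, end))
        bounds = np.array(sorted(edges))
        spikes_t: list[np.ndarray] = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            mid = 0.5 * (a + b)
            rate = spec.baseline_rate + sum(inc for s, e, inc in incs if s <= mid < e)
            if rate < 0:
                clipped += 1
                rate = 0.0
            n = rng.poisson(rate * (b - a))
            if n:
                spikes_t.append(np.sort(rng.uniform(a, b, size=n)))
        t = np.concatenate(spikes_t) if spikes_t else np.empty(0)
        out_sess.append(np.repeat(trial.session_id, len(t)))
        out_idx.append(np.repeat(trial.trial_index, len(t)))
        out_t.append(t)
    if clipped:
        session_io.log.warning("neuron %s: clipped negative rate in %d segments",
                               spec.neuron_id, clipped)
    return pd.DataFrame({
        "neuron_id": spec.neuron_id,
        "session_id": np.concatenate(out_sess) if out_sess else [],
        "trial_index": np.concatenate(out_idx).astype(int) if out_idx else [],
        "t": np.concatenate(out_t) if out_t else [],
    })


# ---------------------------------------------------------------------------
# full datasets


def default_roster(
    n_neurons: int = 60,
    seed: int = 0,
    fractions: dict[str, float] | None = None,
) -> list[NeuronSpec]:
    """A mixed roster of synthetic neurons with field-realistic proportions.

    Defaults: a majority of progress-tuned neurons (mostly adaptive, most
    with positive gain, about half free-choice-specific), smaller fractions
    tracking reward magnitude, elapsed time, specific steps or generic
    reward expectation, and a quarter untuned.
    """
    fractions = fractions or {
        "adaptive_progress": 0.30, "nonadaptive_progress": 0.15,
        "partial_adaptive": 0.05, "reward_magnitude": 0.10,
        "elapsed_time": 0.05, "step_tuned": 0.05,
        "reward_expectation": 0.05, "null": 0.25,
    }
    rng = _substream(seed, 77)
    tunings = list(fractions)
    probs = np.array([fractions[t] for t in tunings], dtype=float)
    probs /= probs.sum()
    roster = []
    period_pool = ("fixation", "cue", "delay", "outcome")
    for i in range(n_neurons):
        tuning = str(rng.choice(tunings, p=probs))
        gain_sign = 1.0 if (tuning == "null" or rng.random() < 0.72) else -1.0
        spec = NeuronSpec(
            neuron_id=f"n{i:03d}",
            tuning=tuning,
            baseline_rate=float(rng.uniform(3.0, 8.0)),
            gain=gain_sign * float(rng.uniform(8.0, 16.0)),
            adaptation_weight=0.5 if tuning == "partial_adaptive" else 1.0,
            target_periods=(str(rng.choice(period_pool)),),
            free_only=bool(tuning != "null" and rng.random() < 0.5),
            error_attenuation=0.3 if tuning.endswith("progress") else 1.0,
            region="basolateral" if rng.random() < 0.55 else "centromedial",
            step_centers=(int(rng.integers(2, 5)),) if tuning == "step_tuned" else (),
        )
        roster.append(spec)
    return roster


def neurons_table(roster: list[NeuronSpec], session_ids: list[str]) -> pd.DataFrame:
    rows = []
    for i, spec in enumerate(roster):
        d = asdict(spec)
        d["target_periods"] = ";".join(spec.target_periods)
        d["step_centers"] = ";".join(str(s) for s in spec.step_centers)
        d["session_id"] = session_ids[i % len(session_ids)]
        rows.append(d)
    return pd.DataFrame(rows)


def roster_from_table(neurons: pd.DataFrame) -> list[NeuronSpec]:
    roster = []
    for _, row in neurons.iterrows():
        tp = row["target_periods"]
        sc = row.get("step_centers", "")
        roster.append(NeuronSpec(
            neuron_id=str(row["neuron_id"]),
            tuning=str(row["tuning"]),
            baseline_rate=float(row["baseline_rate"]),
            gain=float(row["gain"]),
            adaptation_weight=float(row["adaptation_weight"]),
            target_periods=tuple(str(tp).split(";")) if isinstance(tp, str) and tp else (),
            free_only=bool(row["free_only"]),
            error_attenuation=float(row["error_attenuation"]),
            region=str(row["region"]),
            step_centers=tuple(int(s) for s in str(sc).split(";") if s) if not pd.isna(sc) else (),
        ))
    return roster


def generate_dataset(config: GeneratorConfig, path: str | Path | None = None):
    """Generate a complete experiment and optionally write it to disk.

    Each session holds a free-choice block and (if configured) an imperative
    block with the same sequence lengths; neurons are assigned to sessions
    round-robin and their spike trains cover every trial of their session.
    Returns (trials, spikes, neurons, manifest).
    """
    if len({s.neuron_id for s in config.neurons}) != len(config.neurons):
        raise ValueError("duplicate neuron_id in roster")
    session_ids = [f"S{k + 1}" for k in range(config.n_sessions)]
    all_trials = []
    for k, sid in enumerate(session_ids):
        free = generate_behavior(config, "free", session_id=sid, session_key=k)
        blocks = [free]
        if config.include_imperative:
            imp = generate_behavior(config, "imperative", session_id=sid, session_key=k)
            imp["trial_index"] += len(free)
            imp["sequence_id"] += free["sequence_id"].max() + 1
            blocks.append(imp)
        all_trials.append(pd.concat(blocks, ignore_index=True))
    trials = pd.concat(all_trials, ignore_index=True)

    neurons = neurons_table(config.neurons, session_ids) if config.neurons else None
    spike_frames = []
    if neurons is not None:
        for _, row in neurons.iterrows():
            spec = roster_from_table(pd.DataFrame([row]))[0]
            sess_trials = trials[trials["session_id"] == row["session_id"]]
            spike_frames.append(generate_spikes(spec, sess_trials, config.seed))
    spikes = (pd.concat(spike_frames, ignore_index=True) if spike_frames
              else pd.DataFrame(columns=session_io.SPIKE_COLUMNS))

    manifest = {
        "seed": config.seed,
        "n_sequences": config.n_sequences,
        "n_sessions": config.n_sessions,
        "error_rate": config.error_rate,
        "base_rate": config.base_rate,
        "interest_rates": {str(q): {str(k): v for k, v in d.items()}
                           for q, d in config.interest_rates.items()},
        "include_imperative": config.include_imperative,
        "n_neurons": len(config.neurons),
    }
    if path is not None:
        session_io.write_dataset(path, trials, spikes, neurons, manifest)
    return trials, spikes, neurons, manifest
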