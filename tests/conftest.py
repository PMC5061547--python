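"""Shared fixtures: small deterministic synthetic sessions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from saveseq import synthetic_data as sd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> sd.GeneratorConfig:
    return sd.GeneratorConfig(n_sequences=40, seed=123, include_imperative=False)


@pytest.fixture(scope="session")
def small_trials(small_config) -> pd.DataFrame:
    return sd.generate_behavior(small_config, "free")


@pytest.fixture(scope="session")
def clean_trials() -> pd.DataFrame:
    """Error-free session with a spread of sequence lengths."""
    cfg = sd.GeneratorConfig(n_sequences=60, seed=7, error_rate=0.0,
                             include_imperative=False)
    return sd.generate_behavior(cfg, "free")


def make_counts(trials: pd.DataFrame, rate_fn, neuron_id="n0", period="cue",
                extra_periods=("pre_fixation",)) -> pd.DataFrame:
    """Construct a windowed-counts frame with rates given by rate_fn(trial row)."""
    correct = trials[~trials["error"].astype(bool)]
    frames = []
    for per in (period, *extra_periods):
        frames.append(pd.DataFrame({
            "neuron_id": neuron_id,
            "session_id": correct["session_id"].to_numpy(),
            "trial_index": correct["trial_index"].to_numpy(),
            "period": per,
            "count": 0,
            "rate": [float(rate_fn(row)) if per == period else 0.0
                     for _, row in correct.iterrows()],
        }))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
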