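"""Shared fixtures: tiny synthetic datasets and hand-built epochs."""

import numpy as np
import pandas as pd
import pytest

from emgchrono import ContinuousRecording, GeneratorSpec, TrialEpoch, generate_dataset


def make_epoch(left, right, rt_ms, responding="right", correct="right",
               sat="neutral", lexicality="word", pre_ms=500.0, rate=1000.0,
               participant="p01", trial=1):
    """Stimulus-locked epoch from two explicit channel arrays."""
    signal = np.column_stack([np.asarray(left, float), np.asarray(right, float)])
    return TrialEpoch(
        signal=signal, sampling_rate=rate, pre_ms=pre_ms,
        participant=participant, trial=trial, sat=sat, lexicality=lexicality,
        correct_hand=correct, responding_hand=responding, rt_ms=rt_ms,
        channel_hands=("left", "right"),
    )


def noise_epoch(rng, n=3000, sd=1.0, **kwargs):
    return make_epoch(rng.normal(0, sd, n), rng.normal(0, sd, n), **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_recording(rng):
    n = 2000
    signal = rng.normal(0, 2.0, size=(n, 2))
    return ContinuousRecording(
        sampling_rate=1000, signal=signal,
        channel_map={"emg_left": "left", "emg_right": "right"},
    )


@pytest.fixture
def valid_events():
    return pd.DataFrame({
        "participant": ["p01"] * 3,
        "trial": [1, 2, 3],
        "stimulus_onset_ms": [5000.0, 12000.0, 19000.0],
        "rt_ms": [650.0, np.nan, 702.5],
        "responding_hand": ["right", np.nan, "left"],
        "correct_hand": ["right", "left", "right"],
        "sat": ["neutral", "speed", "neutral"],
        "lexicality": ["word", "pseudoword", "word"],
    })


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 participants x 3 SAT x 2 lexicality x 8 trials, fixed seed."""
    spec = GeneratorSpec(n_participants=2, trials_per_cell=8)
    return generate_dataset(spec, seed=7)
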