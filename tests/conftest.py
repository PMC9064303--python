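"""Shared fixtures: synthetic spike trains and one cached simulation run."""

from __future__ import annotations

import numpy as np
import pytest

from infoflow import SimConfig, jitter_spike_times, simulate
from infoflow.spike_data import Recording, SpikeTrain, recording_from_arrays


def poisson_train(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    """Homogeneous Poisson spike times on [0, duration)."""
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))


def poisson_pair(seed: int, rate: float = 1.0, duration: float = 120.0) -> Recording:
    """Two independent Poisson trains, jittered, as a Recording."""
    rng = np.random.default_rng([seed, 1234])
    rec = recording_from_arrays(
        [("a", poisson_train(rng, rate, duration)),
         ("b", poisson_train(rng, rate, duration))],
        0.0, duration,
    )
    return jitter_spike_times(rec, seed=seed)


def relay_pair(seed: int, rate: float = 1.0, duration: float = 600.0,
               delay: float = 0.005) -> Recording:
    """Deterministic relay: target spikes are source spikes shifted by ``delay``."""
    rng = np.random.default_rng([seed, 777])
    src = poisson_train(rng, rate, duration)
    tgt = src + delay
    rec = recording_from_arrays(
        [("src", src), ("tgt", tgt[tgt < duration])], 0.0, duration
    )
    return jitter_spike_times(rec, seed=seed)


@pytest.fixture(scope="session")
def default_sim():
    """One full 550 s development run with the default configuration.

    Session-scoped: the same run backs the simulator unit tests and the
    developmental acceptance checks.
    """
    return simulate(SimConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def simple_recording():
    """Tiny deterministic three-node recording for data-model tests."""
    return recording_from_arrays(
        [("a", np.array([0.5, 1.0, 2.0])),
         ("b", np.array([0.25, 1.5])),
         ("c", np.array([3.0]))],
        0.0, 4.0, culture_id="toy", day=3,
    )
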