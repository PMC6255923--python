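"""Shared fixtures: small synthetic sessions and epoch sets.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from somatacs.preprocess import EpochSet
from somatacs.synthdata import (
    EEGGenParams,
    ObserverModel,
    TacsProtocol,
    TaskConfig,
    run_session,
)


@pytest.fixture(scope="session")
def default_task() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def small_task() -> TaskConfig:
    """A short session: 30/10/30 trials per block."""
    return TaskConfig(n_pre=30, n_during=10, n_post=30)


@pytest.fixture(scope="session")
def observer() -> ObserverModel:
    return ObserverModel()


@pytest.fixture(scope="session")
def eeg_params() -> EEGGenParams:
    return EEGGenParams()


@pytest.fixture(scope="session")
def small_session(small_task, observer, eeg_params):
    """One short alpha-tACS session with epochs (seeded)."""
    trials, epochs = run_session(
        small_task, observer, TacsProtocol(), eeg_params, rng=7
    )
    return trials, epochs


def make_epochs(
    data: np.ndarray,
    fs_hz: float = 250.0,
    t0_ms: float = -1000.0,
    labels: pd.DataFrame | None = None,
) -> EpochSet:
    """Wrap a (trials, samples) array into an EpochSet with dummy labels."""
    data = np.atleast_2d(data)
    n, ns = data.shape
    t_ms = t0_ms + np.arange(ns) * 1000.0 / fs_hz
    if labels is None:
        labels = pd.DataFrame(
            {
                "index": np.arange(n),
                "block": "pre",
                "stim_type": "threshold",
                "intensity_um": 250.0,
                "onset_jitter_s": 1.0,
                "tacs_on": False,
                "group": "sham",
                "outcome": "hit",
                "alpha_amp": 0.0,
            }
        )
    return EpochSet(data=data, fs_hz=fs_hz, t_ms=t_ms, labels=labels)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
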