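"""Shared fixtures: small synthetic sessions and a decoded epoch chain.

Expensive artifacts are session-scoped so several test modules can reuse
them; everything is generated programmatically from fixed seeds.
"""

import numpy as np
import pytest

from postbias import neural
from postbias.synth import (
    EpochGroundTruth,
    ObserverSpec,
    SessionConfig,
    simulate_epochs,
    simulate_session,
    simulate_study,
)


@pytest.fixture(scope="session")
def observer():
    return ObserverSpec()


@pytest.fixture(scope="session")
def session_table(observer):
    """One default behavioural session (2x2 x 90 trials)."""
    return simulate_session(SessionConfig(), observer, seed=11)


@pytest.fixture(scope="session")
def study_table(observer):
    """Four subjects, reduced cells, for hierarchical-model smoke tests."""
    return simulate_study(SessionConfig(n_trials_per_cell=40), observer, 4, seed=5)


@pytest.fixture(scope="session")
def epoch_chain(session_table):
    """Small-geometry epochs plus the full LOO decode chain.

    Returns (epochs, truth, pre, post, ensemble, dv, unsigned_trend).
    """
    trials = session_table.iloc[:80].reset_index(drop=True)
    truth = EpochGroundTruth(
        n_channels=32,
        n_samples=251,
        t_start_ms=-200.0,
        pre_onset_ms=0.0,
        post_onset_ms=1200.0,
        window_ms=850.0,
        spatial_corr_length=4.0,
    )
    epochs, truth = simulate_epochs(trials, truth, seed=3)
    pre = neural.sliding_features(epochs, tmin_ms=0, tmax_ms=850)
    post = neural.sliding_features(epochs, tmin_ms=1200, tmax_ms=2050)
    ens = neural.train_decoders(pre, epochs.labels["initial_choice"], scheme="loo")
    dv = neural.decode_dv(ens, post)
    trend = neural.dv_trend(dv)
    unsigned = neural.unsign(trend, epochs.labels["direction"])
    return epochs, truth, pre, post, ens, dv, unsigned


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
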