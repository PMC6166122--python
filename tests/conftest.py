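"""Shared fixtures: synthetic trips and full-study analysis results.

Heavy simulations are session-scoped so the full-chain properties, the
acceptance-style checks and the detector tests share one generation pass.
"""

from __future__ import annotations

import numpy as np
import pytest

import discomfortlab as dl


@pytest.fixture(scope="session")
def default_trip():
    """One default trip: channels, event streams, kinematics (seed 101)."""
    return dl.simulate_trip(seed=101)


@pytest.fixture(scope="session")
def default_recording(default_trip):
    channels, events, _ = default_trip
    return dl.resample_to_master(channels, channels["handset"], events=events)


@pytest.fixture(scope="session")
def study_result():
    """20 participants x 2 sessions at generator defaults (~100 sequences),
    analyzed end to end."""
    recs = dl.simulate_study(20, 2, seed=515)
    return recs, dl.analyze_recordings(recs)


@pytest.fixture(scope="session")
def zero_effect_result():
    """10 x 2 sessions with every event-locked amplitude zeroed."""
    recs = dl.simulate_study(
        10, 2, response=dl.ResponseConfig.zero_effect(), seed=616
    )
    return recs, dl.analyze_recordings(recs)


@pytest.fixture(scope="session")
def detector_recordings():
    """Six default trips for detection evaluation (seeds disjoint from the
    detector's tuning seeds)."""
    recs = []
    for seed in range(700, 706):
        channels, events, _ = dl.simulate_trip(seed=seed)
        recs.append(dl.resample_to_master(channels, channels["handset"], events=events))
    return recs


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
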