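"""Shared fixtures and construction helpers for the gazesa test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gazesa import (
    GazeRecording,
    ScenarioConfig,
    default_aoi_scheme,
    default_profiles,
    simulate_recording,
)
from gazesa.io import GAZE_COLUMNS


def make_recording(
    t,
    x,
    y,
    valid=None,
    pupil_l=None,
    pupil_r=None,
    rate_hz=None,
    screen=(1920, 1080),
) -> GazeRecording:
    """Build a recording from plain arrays (valid everywhere by default)."""
    t = np.asarray(t, float)
    n = len(t)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    pl = np.full(n, np.nan) if pupil_l is None else np.asarray(pupil_l, float)
    pr = np.full(n, np.nan) if pupil_r is None else np.asarray(pupil_r, float)
    if rate_hz is None:
        rate_hz = 1000.0 / float(np.median(np.diff(t))) if n > 1 else 100.0
    df = pd.DataFrame(
        {
            "t_ms": t,
            "x": x,
            "y": y,
            "pupil_l": pl,
            "pupil_r": pr,
            "valid_l": valid,
            "valid_r": valid.copy(),
        }
    )[GAZE_COLUMNS]
    return GazeRecording(df, rate_hz, screen[0], screen[1])


@pytest.fixture(scope="session")
def small_scenario():
    """A scaled-down scenario for fast unit-level simulation."""
    return ScenarioConfig(
        duration_s=60.0,
        rate_hz=120.0,
        anomaly_s=(20.0, 40.0),
        n_novices=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def scheme():
    return default_aoi_scheme()


@pytest.fixture(scope="session")
def expert_sim(small_scenario):
    expert, _ = default_profiles(small_scenario)
    return simulate_recording(expert, small_scenario, seed=101)


@pytest.fixture(scope="session")
def novice_sim(small_scenario):
    _, novice = default_profiles(small_scenario)
    return simulate_recording(novice, small_scenario, seed=102)
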