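import numpy as np
import pandas as pd
import pytest

from vrneglect.classifier import classify_cohort
from vrneglect.gameplay_data import PlayerSession
from vrneglect.synthetic_cohort import simulate_cohort


def make_session(
    player_id="p1",
    group="patient",
    trials_spec=None,
    orientation=None,
):
    """Hand-build a session from compact specs.

    trials_spec: list of (set_size, lateral_angle, correct, rt).
    orientation: list of (source, set_size, mean_angle).
    """
    trials_spec = trials_spec or []
    rows = []
    for i, (set_size, lat, correct, rt) in enumerate(trials_spec):
        rows.append(
            {
                "player_id": player_id,
                "group": group,
                "level_index": 2,
                "half": 1,
                "set_size": set_size,
                "target_lateral_angle": lat,
                "target_vertical_angle": 0.0,
                "correct": bool(correct),
                "rt_s": rt,
            }
        )
    trials = pd.DataFrame(
        rows,
        columns=[
            "player_id", "group", "level_index", "half", "set_size",
            "target_lateral_angle", "target_vertical_angle", "correct", "rt_s",
        ],
    )
    orows = [
        {
            "player_id": player_id,
            "source": src,
            "set_size": s,
            "mean_lateral_angle_deg": ang,
            "n_frames": 100,
        }
        for src, s, ang in (orientation or [])
    ]
    osum = pd.DataFrame(
        orows,
        columns=["player_id", "source", "set_size", "mean_lateral_angle_deg", "n_frames"],
    )
    return PlayerSession(player_id, group, trials, osum)


@pytest.fixture(scope="session")
def small_cohort():
    """30 controls + 51 patients at the default mix, fixed seed."""
    return simulate_cohort(30, 51, seed=7)


@pytest.fixture(scope="session")
def classified_cohort(small_cohort):
    summaries, cutoffs = classify_cohort(small_cohort)
    return small_cohort, summaries, cutoffs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
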