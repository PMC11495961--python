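from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from peristartle import SimulationConfig, simulate_dataset


def track_from_beak(
    bout_id: str,
    beak: list[tuple[float, float]],
    height: float = 100.0,
    itj_split: float = 0.0,
) -> pd.DataFrame:
    """Keypoint table for one bout with the beak following ``beak`` and
    both ITJs tracking it ``height`` pixels lower (so the per-frame and
    mean body height are exactly ``height``).  ``itj_split`` offsets the
    two ITJ sides by ±itj_split around that height."""
    rows = []
    for frame, (x, y) in enumerate(beak):
        rows.append((bout_id, frame, "beak_tip", x, y))
        rows.append((bout_id, frame, "left_itj", x - 10.0, y + height - itj_split))
        rows.append((bout_id, frame, "right_itj", x + 10.0, y + height + itj_split))
        rows.append((bout_id, frame, "left_foot", x - 8.0, y + height * 1.4))
        rows.append((bout_id, frame, "right_foot", x + 8.0, y + height * 1.4))
    frame = pd.DataFrame(rows, columns=["bout_id", "frame", "keypoint", "x", "y"])
    frame["valid"] = True
    return frame


def metadata_for(bout_ids, male_id="m1", status="owner", date="2018-09-01"):
    return pd.DataFrame(
        {
            "bout_id": list(bout_ids),
            "male_id": male_id,
            "status": status,
            "date": date,
            "fps": 30.0,
        }
    )


def events_frame(rows) -> pd.DataFrame:
    """rows: (bout_id, element_type, intensity_class, kind, start, duration)."""
    return pd.DataFrame(
        rows,
        columns=["bout_id", "element_type", "intensity_class", "kind",
                 "start_frame", "duration_frames"],
    )


def empty_exits() -> pd.DataFrame:
    return pd.DataFrame({"bout_id": pd.Series(dtype=str),
                         "frame": pd.Series(dtype=np.int64)})


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but fully featured simulation: both statuses, startles in
    owners only, exits possible."""
    return SimulationConfig(
        n_owners=3,
        n_subordinates=3,
        bouts_per_male=(2, 3),
        bout_length_frames=(240, 320),
        element_rate=4.0,
        high_fraction=0.5,
        high_duration_frames=(20.0, 10.0),
        startle_magnitude={"owner": 0.3, "subordinate": 0.0},
        startle_probability=0.8,
        exit_probability=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)
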