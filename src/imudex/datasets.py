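"""Packaged reference tables from the glove validation study.

Five small CSVs transcribed from the published study travel with the
package: the video-review metrics of the 14 volunteers and the
per-volunteer dexterity metrics (exercise duration, movement counts,
spatial and angular displacement per sensor). They are the inputs of the
assessment layer and the ground against which its outputs are checked.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# published group memberships (video review / dexterity clustering)
BLUE_GROUP = [1, 4, 5, 9, 12, 13]
GREEN_GROUP = [2, 3, 6, 10]
RED_GROUP = [7, 8, 11, 14]
TYPE1_GROUP = [1, 4, 5, 9, 12, 13]
TYPE2_GROUP = [2, 3, 6, 7, 8, 10, 11, 14]
AMBIGUOUS_VOLUNTEER = 10  # reported as assignable to either green or red


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("imudex").joinpath("data", name)
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def load_video_review() -> pd.DataFrame:
    """Video-review metrics per volunteer: t_span, total_task1, t_ratio,
    errors (pegboard exercise)."""
    return _load("table1_video_review.csv").set_index("volunteer")


def load_durations() -> pd.DataFrame:
    """Automatically measured exercise durations (s) per volunteer."""
    return _load("table3_duration.csv").set_index("volunteer")


def load_movements() -> pd.DataFrame:
    """Automatically detected movement counts per volunteer."""
    return _load("table4_movements.csv").set_index("volunteer")


def load_disp() -> pd.DataFrame:
    """Spatial displacement (m) per volunteer x sensor x exercise."""
    return _load("table5_disp.csv")


def load_disptheta() -> pd.DataFrame:
    """Angular displacement (deg) per volunteer x sensor x exercise."""
    return _load("table6_disptheta.csv")


def exercise_features(exercise: int = 3, sensor: int = 1) -> pd.DataFrame:
    """Subjects x variables table (Duration, Movements, Disp, Disp_theta)
    for one exercise, displacement metrics taken from one sensor."""
    dur = load_durations()[f"exercise{exercise}"]
    mov = load_movements()[f"exercise{exercise}"]
    disp = load_disp()
    disp = disp[disp["sensor"] == sensor].set_index("volunteer")[
        f"e{exercise}"]
    dth = load_disptheta()
    dth = dth[dth["sensor"] == sensor].set_index("volunteer")[
        f"e{exercise}"]
    return pd.DataFrame({
        "duration": dur, "movements": mov.astype(float),
        "disp": disp, "disp_theta": dth.astype(float),
    })
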