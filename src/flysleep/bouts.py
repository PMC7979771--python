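"""Rest-bout extraction from trajectories and circadian phase labelling.

A rest bout is a maximal run of frames whose positions stay within
``tol_px`` of the run's anchor (its first frame), lasting at least
``min_rest_s`` on the frame grid. Anchor-based tolerance deliberately
prevents slow drift from accumulating into a single "rest": a fly creeping
1 px per second would pass a frame-to-frame test forever but breaks an
anchored run as soon as it leaves the tolerance disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tracking import LightSchedule, Trajectory

__all__ = ["extract_rest_bouts", "assign_phase"]

BOUT_COLUMNS = ["onset_s", "duration_s", "x_px", "y_px"]


def extract_rest_bouts(
    traj: Trajectory,
    min_rest_s: float = 1.0,
    tol_px: float = 1.0,
) -> pd.DataFrame:
    """Segment a trajectory into rest bouts.

    Durations are measured between the first and last stationary frame
    (frame span / fps), so a run covering 25 inter-frame intervals at 25 fps
    is a 1.0 s bout. Bouts are disjoint, ordered, and located at their
    anchor position. Returns a table with columns
    ``onset_s, duration_s, x_px, y_px``.
    """
    if np.any(np.diff(traj.times) <= 0):
        raise ValueError("trajectory times must be strictly increasing")
    x, y, t = traj.x, traj.y, traj.times
    n = len(traj)
    bouts: list[tuple[float, float, float, float]] = []
    i = 0
    while i < n:
        ax, ay = x[i], y[i]
        j = i + 1
        while j < n and (x[j] - ax) ** 2 + (y[j] - ay) ** 2 <= tol_px**2:
            j += 1
        duration = t[j - 1] - t[i]
        if duration >= min_rest_s:
            bouts.append((t[i], duration, ax, ay))
            i = j
        else:
            # too short to be a bout: release its frames, so a rest whose
            # first frames fell inside the tolerance disk of a final move
            # step still anchors its own run one frame later
            i += 1
    return pd.DataFrame(bouts, columns=BOUT_COLUMNS)


def assign_phase(bouts: pd.DataFrame, schedule: LightSchedule) -> pd.DataFrame:
    """Label each bout 'day' or 'night' by its onset Zeitgeber time.

    Bouts spanning a light transition are assigned by onset, not split.
    Under constant darkness the labels follow the hypothetical entrained
    light:dark schedule.
    """
    out = bouts.copy()
    light = schedule.is_light(out["onset_s"].to_numpy())
    out["phase"] = np.where(light, "day", "night")
    return out
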