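"""Sensitivity of joint angles at the detected events to event-timing error.

A timing error of a few frames at foot-strike or toe-off propagates into the
sagittal hip/knee/ankle angles read off at those instants — most severely at
toe-off, where the limb extends rapidly. For every cycle, joint and offset
delta in {-5..-1, +1..+5} frames, the analysis computes
``angle(event + delta) - angle(event)`` and aggregates the distribution per
(joint, event, offset) cell. Each cell is banded by its mean absolute error:
below 2 degrees is acceptable, 2–5 degrees reasonable but requiring
consideration, above 5 degrees unacceptable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import StepEvents

__all__ = ["SensitivityGrid", "angle_sensitivity", "classify_band"]

BANDS = ("acceptable", "reasonable", "unacceptable")
_EVENTS = ("foot_strike", "toe_off")


def classify_band(mean_abs_error: float) -> str:
    """Band a mean absolute angle error (degrees): <2 acceptable, 2–5 reasonable,
    >5 unacceptable."""
    if mean_abs_error < 0:
        raise ValueError(f"angle error magnitude cannot be negative: {mean_abs_error}")
    if mean_abs_error < 2.0:
        return "acceptable"
    if mean_abs_error <= 5.0:
        return "reasonable"
    return "unacceptable"


@dataclass
class SensitivityGrid:
    """Per (joint, event, offset) error distributions, means and bands."""

    table: pd.DataFrame  # columns: joint, event, offset, mean_error, mean_abs_error, band, n
    distributions: dict[tuple[str, str, int], np.ndarray]
    excluded: int  # cycle-offset combinations outside the cycle bounds
    rate: float

    def band(self, joint: str, event: str, offset: int) -> str:
        row = self.table[
            (self.table.joint == joint)
            & (self.table.event == event)
            & (self.table.offset == offset)
        ]
        if row.empty:
            raise KeyError((joint, event, offset))
        return row.band.iloc[0]


def angle_sensitivity(
    angles: list[dict[str, np.ndarray]],
    truth_events: list[StepEvents],
    max_offset: int = 5,
    rate: float | None = None,
) -> SensitivityGrid:
    """Build the offset-error grid for hip/knee/ankle angles at both events.

    Parameters
    ----------
    angles : list of dict
        Per cycle, a mapping of joint name to its angle series (degrees, mocap
        rate, same indexing as the cycle's events).
    truth_events : list of StepEvents
        Ground-truth foot-strike/toe-off per cycle (force-derived).
    max_offset : int
        Largest offset in frames either side of the event (default 5; at
        200 Hz that is 25 ms).
    rate : float, optional
        Mocap rate; taken from the first event set when omitted.

    Cycles whose shifted index falls outside the angle series are excluded
    from that offset and counted in ``excluded``, with a warning.
    """
    if len(angles) != len(truth_events):
        raise ValueError("angles and events collections differ in length")
    if not angles:
        raise ValueError("empty collection")
    if rate is None:
        rate = truth_events[0].rate
    joints = sorted(angles[0].keys())
    offsets = [d for d in range(-max_offset, max_offset + 1) if d != 0]
    bucket: dict[tuple[str, str, int], list[float]] = {
        (j, ev, d): [] for j in joints for ev in _EVENTS for d in offsets
    }
    excluded = 0
    for cycle_angles, events in zip(angles, truth_events):
        for ev, idx in (("foot_strike", events.foot_strike_index), ("toe_off", events.toe_off_index)):
            for d in offsets:
                k = idx + d
                for j in joints:
                    series = cycle_angles[j]
                    if k < 0 or k >= len(series):
                        excluded += 1
                        continue
                    bucket[(j, ev, d)].append(float(series[k] - series[idx]))
    if excluded:
        warnings.warn(
            f"{excluded} cycle-offset combinations fell outside the cycle and were excluded"
        )
    rows = []
    dists: dict[tuple[str, str, int], np.ndarray] = {}
    for key, vals in bucket.items():
        arr = np.asarray(vals)
        dists[key] = arr
        mean_err = float(arr.mean()) if arr.size else float("nan")
        mean_abs = float(np.abs(arr).mean()) if arr.size else float("nan")
        rows.append(
            {
                "joint": key[0],
                "event": key[1],
                "offset": key[2],
                "offset_ms": key[2] / rate * 1000.0,
                "mean_error": mean_err,
                "mean_abs_error": mean_abs,
                "band": classify_band(mean_abs) if arr.size else "n/a",
                "n": int(arr.size),
            }
        )
    table = pd.DataFrame(rows).sort_values(["joint", "event", "offset"]).reset_index(drop=True)
    return SensitivityGrid(table=table, distributions=dists, excluded=excluded, rate=rate)
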