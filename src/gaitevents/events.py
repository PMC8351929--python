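"""Discrete step events and their extraction from per-frame contact probabilities.

Foot-strike (FS) is the first frame of the contact phase and toe-off (TO) the
last; contact time is the interval between them. Ground truth uses the 50 N
vertical ground-reaction-force convention; model output is converted to events
by thresholding the predicted contact probability and taking the longest
contiguous supra-threshold run, which is robust to isolated spurious frames
during the swing phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StepEvents",
    "EventErrors",
    "NoContactError",
    "contiguous_runs",
    "extract_events",
    "event_errors",
]


class NoContactError(ValueError):
    """Raised when no contact phase can be identified in a cycle."""

    def __init__(self, message: str, max_probability: float | None = None):
        super().__init__(message)
        self.max_probability = max_probability


@dataclass(frozen=True)
class StepEvents:
    """Foot-strike and toe-off for one gait cycle, at motion-capture resolution.

    Indices are frames from cycle start; times are milliseconds from cycle
    start. ``contact_time_ms`` is exactly
    ``(toe_off_index - foot_strike_index) / rate * 1000``.
    """

    foot_strike_index: int
    toe_off_index: int
    rate: float

    def __post_init__(self) -> None:
        if self.foot_strike_index > self.toe_off_index:
            raise ValueError(
                f"foot-strike frame {self.foot_strike_index} after "
                f"toe-off frame {self.toe_off_index}"
            )

    @property
    def foot_strike_time_ms(self) -> float:
        return self.foot_strike_index / self.rate * 1000.0

    @property
    def toe_off_time_ms(self) -> float:
        return self.toe_off_index / self.rate * 1000.0

    @property
    def contact_time_ms(self) -> float:
        return (self.toe_off_index - self.foot_strike_index) / self.rate * 1000.0


@dataclass(frozen=True)
class EventErrors:
    """Detection errors in ms: predicted minus ground truth.

    Positive foot-strike / toe-off error means late detection; positive
    contact-time error means overestimated contact duration. By construction
    ``contact_time == toe_off - foot_strike``.
    """

    foot_strike_ms: float
    toe_off_ms: float
    contact_time_ms: float


def contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of the True runs in a boolean vector."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def extract_events(
    probabilities: np.ndarray,
    rate: float,
    threshold: float = 0.5,
    mask: np.ndarray | None = None,
) -> StepEvents:
    """Convert a per-frame contact-probability sequence into step events.

    Frames with probability >= ``threshold`` (on unmasked positions) are
    binarised to contact; the longest contiguous contact run defines the
    contact phase, whose first and last frames are foot-strike and toe-off.
    Ties between equally long runs go to the earliest. Indices are reported
    relative to the start of the real (unpadded) part of the cycle.

    Raises
    ------
    NoContactError
        If no unmasked frame reaches the threshold; carries the maximum
        observed probability.
    """
    p = np.asarray(probabilities, dtype=float)
    if mask is None:
        mask = np.ones_like(p, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != p.shape:
            raise ValueError("probability and mask shapes differ")
    real = np.flatnonzero(mask)
    if real.size == 0:
        raise ValueError("cycle has no unmasked frames")
    # padding is prepended, so indexing the unmasked frames re-bases to cycle start
    p_real = p[real]
    contact = p_real >= threshold
    runs = contiguous_runs(contact)
    if not runs:
        raise NoContactError(
            f"no contact detected: max probability {p_real.max():.4f} "
            f"below threshold {threshold}",
            max_probability=float(p_real.max()),
        )
    lengths = [end - start + 1 for start, end in runs]
    start, end = runs[int(np.argmax(lengths))]
    return StepEvents(foot_strike_index=start, toe_off_index=end, rate=rate)


def event_errors(pred: StepEvents, truth: StepEvents, rate: float | None = None) -> EventErrors:
    """Errors (predicted - ground truth) in ms for FS, TO and contact time.

    Both event sets must share the same sampling rate (same cycle).
    """
    if pred.rate != truth.rate:
        raise ValueError(f"rate mismatch: predicted {pred.rate} Hz vs truth {truth.rate} Hz")
    if rate is not None and rate != pred.rate:
        raise ValueError(f"rate mismatch: events at {pred.rate} Hz, expected {rate} Hz")
    fs = pred.foot_strike_time_ms - truth.foot_strike_time_ms
    to = pred.toe_off_time_ms - truth.toe_off_time_ms
    ct = pred.contact_time_ms - truth.contact_time_ms
    return EventErrors(foot_strike_ms=fs, toe_off_ms=to, contact_time_ms=ct)
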