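"""Preprocessing primitives: zero-lag low-pass filtering and differentiation.

Marker-derived position and angle channels are conventionally smoothed with a
zero-phase (forward-backward) Butterworth filter before differentiation, so
that event timing is not biased by filter phase lag. Velocities are obtained
by central differences, which are second-order accurate and phase-neutral,
consistent with the zero-lag filtering philosophy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = ["TimeSeries", "lowpass_zero_lag", "differentiate"]


@dataclass
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values : array-like of float
        Sample values.
    rate : float
        Sampling rate in Hz, strictly positive.
    name : str
        Channel name (used in error messages and CSV headers).
    """

    values: np.ndarray
    rate: float
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError(f"TimeSeries '{self.name}' must be 1-D")
        if not self.rate > 0:
            raise ValueError(f"TimeSeries '{self.name}': rate must be > 0, got {self.rate}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"TimeSeries '{self.name}' contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Signal duration in seconds (n samples at `rate`)."""
        return len(self.values) / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(len(self.values)) / self.rate


def lowpass_zero_lag(x: TimeSeries, cutoff: float = 10.0, order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth low-pass filter (forward-backward application).

    The filter is applied once forward and once backward, cancelling phase
    distortion; the effective attenuation order is therefore twice the design
    ``order``. Edges are handled by reflective (even) padding of length
    ``3 * (order + 1)`` samples.

    Parameters
    ----------
    x : TimeSeries
        Input signal.
    cutoff : float
        Cut-off frequency in Hz; must be below the Nyquist rate. Default 10 Hz,
        the conventional cut-off for running kinematics.
    order : int
        Butterworth design order of each pass. Default 4.

    Returns
    -------
    TimeSeries
        Filtered signal, same length and rate.

    Raises
    ------
    ValueError
        If ``cutoff >= rate / 2`` or the series is too short for stable
        filtering (length must exceed ``3 * (order + 1)``).
    """
    if cutoff >= x.rate / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below Nyquist ({x.rate / 2} Hz) for '{x.name}'"
        )
    padlen = 3 * (order + 1)
    if len(x) <= padlen:
        raise ValueError(
            f"series '{x.name}' too short for zero-lag filtering: "
            f"{len(x)} samples, need > {padlen}"
        )
    b, a = _sig.butter(order, cutoff, btype="low", fs=x.rate)
    y = _sig.filtfilt(b, a, x.values, padtype="even", padlen=padlen)
    return TimeSeries(y, x.rate, x.name)


def differentiate(x: TimeSeries) -> TimeSeries:
    """Numerical time derivative: central differences, one-sided at the ends.

    Parameters
    ----------
    x : TimeSeries
        Signal to differentiate (length >= 3).

    Returns
    -------
    TimeSeries
        Derivative in input units per second, same length and rate.
    """
    if len(x) < 3:
        raise ValueError(f"need >= 3 samples to differentiate '{x.name}', got {len(x)}")
    v = np.gradient(x.values, 1.0 / x.rate)
    name = f"d({x.name})/dt" if x.name else ""
    return TimeSeries(v, x.rate, name)
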