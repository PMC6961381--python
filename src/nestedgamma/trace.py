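"""Uniformly sampled traces and event-time containers.

These two containers are the lingua franca of the package: every simulator
output, synthetic fixture, and analysis input is either a :class:`Trace`
(a uniformly sampled series with an explicit unit and sampling interval)
or a :class:`SpikeTrain` (a strictly increasing list of event times).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_UNITS = ("mV", "pA", "uM", "a.u.")


@dataclass
class Trace:
    """Uniformly sampled time series.

    Parameters
    ----------
    values : array of samples.
    dt : sampling interval in ms (must be > 0).
    t0 : time of the first sample in ms.
    unit : physical unit of the samples ("mV", "pA", "uM" or "a.u.").
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    unit: str = "a.u."

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("trace must be a 1-D array with at least one sample")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        """Span from first to last sample in ms."""
        return self.dt * (self.values.size - 1)

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt

    def __len__(self) -> int:
        return self.values.size

    def crop(self, t_start: float, t_end: float) -> "Trace":
        """Return the sub-trace with t_start <= t <= t_end (ms)."""
        i0 = max(0, int(np.ceil((t_start - self.t0) / self.dt)))
        i1 = min(len(self), int(np.floor((t_end - self.t0) / self.dt)) + 1)
        if i1 <= i0:
            raise ValueError("empty crop window")
        return Trace(self.values[i0:i1], self.dt, self.t0 + i0 * self.dt, self.unit)

    def at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the trace at times ``t`` (ms)."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)


@dataclass
class SpikeTrain:
    """Strictly increasing, non-negative event times in ms."""

    times: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if self.times.size and (np.any(np.diff(self.times) <= 0) or self.times[0] < 0):
            raise ValueError("spike times must be non-negative and strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def rate(self, duration_ms: float) -> float:
        """Mean firing rate in Hz over the given span."""
        return 1000.0 * len(self) / duration_ms
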