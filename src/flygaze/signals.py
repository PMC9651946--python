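"""Uniformly sampled angular time series.

All angles are in degrees, time in seconds, and sample rates in Hz
throughout the package (single unit system).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled angular trajectory.

    Parameters
    ----------
    values : ndarray
        Angular positions in degrees.
    sample_rate : float
        Sampling rate in Hz (> 0).
    t0 : float, optional
        Time of the first sample in seconds.
    """

    values: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("values must be a 1-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if not (self.sample_rate > 0):
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        """Span covered by the samples in seconds (n/fs)."""
        return self.values.size / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.values.size) / self.sample_rate

    def velocity(self) -> np.ndarray:
        """Angular velocity in deg/s by central differences.

        Forward/backward one-sided differences are used at the edges so the
        output has the same length as the input.
        """
        if self.values.size < 3:
            raise ValueError("need at least 3 samples to differentiate")
        return np.gradient(self.values, self.dt)

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        """Copy of this series with new values on the same time base."""
        return replace(self, values=np.asarray(values, dtype=float))

    def crop(self, t_start: float, t_stop: float | None = None) -> "TimeSeries":
        """Samples with t_start <= t < t_stop (times relative to t0)."""
        i0 = int(np.ceil(t_start * self.sample_rate - 1e-9))
        i1 = len(self) if t_stop is None else int(np.floor(t_stop * self.sample_rate + 1e-9))
        if i1 <= i0:
            raise ValueError("empty crop window")
        return TimeSeries(self.values[i0:i1], self.sample_rate, self.t0 + i0 * self.dt)


def check_same_base(*series: TimeSeries) -> None:
    """Raise if the series do not share sample rate and length."""
    fs = series[0].sample_rate
    n = len(series[0])
    for s in series[1:]:
        if s.sample_rate != fs:
            raise ValueError(f"sample-rate mismatch: {s.sample_rate} != {fs}")
        if len(s) != n:
            raise ValueError(f"length mismatch: {len(s)} != {n}")
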