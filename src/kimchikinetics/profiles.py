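"""Piecewise-constant time-temperature histories (logger-style profiles)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TemperatureProfile"]


@dataclass(frozen=True)
class TemperatureProfile:
    """A piecewise-constant temperature history.

    Each temperature holds from its breakpoint (inclusive) to the next
    breakpoint (exclusive); the final temperature holds indefinitely.
    Breakpoints are in days, strictly increasing, starting at 0.
    """

    breakpoints: np.ndarray
    temps: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        tp = np.asarray(self.temps, dtype=float)
        if bp.ndim != 1 or len(bp) == 0 or len(bp) != len(tp):
            raise ValueError("breakpoints and temps must be equal-length non-empty 1-D arrays")
        if bp[0] != 0.0:
            raise ValueError(f"profile must start at time 0, got {bp[0]}")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("profile breakpoints must be strictly increasing")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "temps", tp)

    @classmethod
    def constant(cls, temperature: float) -> "TemperatureProfile":
        return cls(np.array([0.0]), np.array([float(temperature)]))

    @classmethod
    def square_wave(
        cls, low: float, high: float, interval_h: float = 24.0, duration_d: float = 20.0
    ) -> "TemperatureProfile":
        """Alternating low/high profile, starting low.

        ``interval_h`` is the dwell per level in hours (a full cycle is two
        intervals); segments are generated to cover ``duration_d`` days.
        """
        if interval_h <= 0 or duration_d <= 0:
            raise ValueError("interval and duration must be positive")
        dwell = interval_h / 24.0
        n_seg = int(np.ceil(duration_d / dwell))
        bp = np.arange(n_seg) * dwell
        tp = np.where(np.arange(n_seg) % 2 == 0, float(low), float(high))
        return cls(bp, tp)

    @property
    def n_segments(self) -> int:
        return len(self.breakpoints)

    @property
    def tmin(self) -> float:
        return float(self.temps.min())

    @property
    def tmax(self) -> float:
        return float(self.temps.max())

    def temperature_at(self, t):
        """Temperature(s) governing at time(s) ``t`` (days)."""
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.breakpoints, t, side="right") - 1, 0, None)
        out = self.temps[idx]
        return out if out.ndim else float(out)

    def time_average(self, t: float) -> float:
        """Running time-average of the profile temperature over [0, t].

        At ``t == 0`` this is the initial temperature.
        """
        if t < 0:
            raise ValueError("t must be non-negative")
        if t == 0:
            return float(self.temps[0])
        ends = np.append(self.breakpoints[1:], np.inf)
        starts = self.breakpoints
        dur = np.clip(np.minimum(ends, t) - starts, 0.0, None)
        return float(np.sum(dur * self.temps) / t)

    def segment_bounds(self, t_end: float) -> np.ndarray:
        """Breakpoints clipped to [0, t_end], with t_end appended."""
        bp = self.breakpoints[self.breakpoints < t_end]
        return np.append(bp, t_end)
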