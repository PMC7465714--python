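"""Study-like synthetic inputs: temperature profiles and noisy observations.

The generator emulates the calibration study's design: three seasonal
experiments with different initial acidities near 0.24 %, constant-
temperature storage at 0/5/10/20 degC, two square-wave fluctuating profiles
(0-10 degC for 20 d and 5-15 degC for 14 d, switching every 24 h), and
additive Gaussian measurement noise on acidity (sd 0.03 % by default).

Sampling horizons are not fixed by the study design; by default each
constant-temperature series is sampled to the time at which the generating
model reaches 99% of its plateau span, so every series covers lag,
exponential and stationary phases and the secondary models are identifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dynamic import simulate_dynamic_mkt
from .fitting import ObservationSet
from .kinetics import closed_form_constant_temperature, simulate_constant_temperature
from .params import KineticParameters
from .profiles import TemperatureProfile
from .secondary import n_max

__all__ = [
    "SyntheticDesign",
    "generate_temperature_profile",
    "generate_observations",
    "stationary_horizon",
]


def stationary_horizon(
    params: KineticParameters, temperature: float, n0: float = 0.24, frac: float = 0.99
) -> float:
    """Days until the constant-T model covers ``frac`` of the span n0 -> n_max.

    Used to size sampling horizons so a series spans lag to stationary
    phase.  Rounded up to whole days.
    """
    nm = n_max(params, temperature)
    target = n0 + frac * (nm - n0)
    f = lambda t: closed_form_constant_temperature(params, n0, temperature, t) - target
    hi = 1.0
    while f(hi) < 0 and hi < 1e5:
        hi *= 2.0
    return float(math.ceil(brentq(f, 0.0, hi, xtol=1e-3)))


@dataclass
class SyntheticDesign:
    """Design of a simulated storage study.

    ``fluctuating`` entries are (low degC, high degC, interval_h, duration_d)
    square waves; ``horizons`` optionally fixes the constant-temperature
    sampling horizons in days (otherwise computed via
    :func:`stationary_horizon`).
    """

    temperatures: Sequence[float] = (0.0, 5.0, 10.0, 20.0)
    fluctuating: Sequence[tuple[float, float, float, float]] = (
        (0.0, 10.0, 24.0, 20.0),
        (5.0, 15.0, 24.0, 14.0),
    )
    n_experiments: int = 3
    n0_range: tuple[float, float] = (0.20, 0.30)
    n_times: int = 12
    horizons: Optional[dict[float, float]] = None
    noise_sd: float = 0.03
    noise_floor: float = 0.01
    include_fluctuating: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for low, high, interval_h, duration_d in self.fluctuating:
            if interval_h <= 0 or duration_d <= 0:
                raise ValueError("fluctuating profile interval and duration must be positive")


def generate_temperature_profile(kind: str, **settings) -> TemperatureProfile:
    """Build a profile of the given kind.

    ``fixed(temp)`` — single segment; ``square_wave(low, high, interval_h,
    duration_d)`` — alternating dwell segments starting low;
    ``logger_noise(low, high, interval_h, duration_d, jitter_sd, seed)`` —
    square wave re-sampled hourly with Gaussian jitter, emulating a data
    logger.
    """
    if kind == "fixed":
        return TemperatureProfile.constant(settings["temp"])
    if kind == "square_wave":
        return TemperatureProfile.square_wave(
            settings["low"],
            settings["high"],
            interval_h=settings.get("interval_h", 24.0),
            duration_d=settings["duration_d"],
        )
    if kind == "logger_noise":
        base = TemperatureProfile.square_wave(
            settings["low"],
            settings["high"],
            interval_h=settings.get("interval_h", 24.0),
            duration_d=settings["duration_d"],
        )
        rng = np.random.default_rng(settings.get("seed", 0))
        hours = np.arange(0.0, settings["duration_d"], 1.0 / 24.0)
        temps = base.temperature_at(hours) + rng.normal(
            0.0, settings.get("jitter_sd", 0.5), size=len(hours)
        )
        return TemperatureProfile(hours, temps)
    raise ValueError(f"unknown profile kind {kind!r}")


def generate_observations(
    params: KineticParameters, design: SyntheticDesign, seed: Optional[int] = None
) -> ObservationSet:
    """Simulate the design with ``params`` and add measurement noise.

    Constant-temperature conditions use the constant-temperature simulator;
    fluctuating conditions use the MKT dynamic model.  Noise is additive
    Gaussian truncated at ``noise_floor``.  The same seed yields an
    identical ObservationSet.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n0s = rng.uniform(*design.n0_range, size=design.n_experiments)
    horizons = design.horizons or {
        T: stationary_horizon(params, T) for T in design.temperatures
    }
    rows = []
    for e in range(design.n_experiments):
        exp = f"exp{e + 1}"
        n0 = float(n0s[e])
        for T in design.temperatures:
            t_grid = np.linspace(0.0, horizons[T], design.n_times)
            traj = simulate_constant_temperature(params, n0, T, t_grid)
            for t, n in zip(traj.t, traj.n):
                rows.append((exp, f"{T:g}", float(t), float(n)))
        if design.include_fluctuating:
            for low, high, interval_h, duration_d in design.fluctuating:
                profile = TemperatureProfile.square_wave(low, high, interval_h, duration_d)
                t_grid = np.linspace(0.0, duration_d, design.n_times)
                traj = simulate_dynamic_mkt(params, n0, profile, t_grid)
                n_pred = traj.acidity_at(t_grid)
                for t, n in zip(t_grid, n_pred):
                    rows.append((exp, f"{low:g}-{high:g}", float(t), float(n)))
    frame = pd.DataFrame(rows, columns=["experiment", "condition", "time_d", "acidity_pct"])
    if design.noise_sd > 0:
        frame["acidity_pct"] += rng.normal(0.0, design.noise_sd, size=len(frame))
    frame["acidity_pct"] = frame["acidity_pct"].clip(lower=design.noise_floor)
    n0_map = {f"exp{e + 1}": float(n0s[e]) for e in range(design.n_experiments)}
    return ObservationSet(frame, n0=n0_map)
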