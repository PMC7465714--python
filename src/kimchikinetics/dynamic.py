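"""Acidity prediction under fluctuating temperature.

Two dynamic schemes are provided:

* ``simulate_dynamic_instantaneous`` — the naive adaptation: both the growth
  rate and the stationary-phase maximum track the instantaneous temperature,
  ``n_max = n_max(T(t))``.  When the temperature drops after the acidity has
  exceeded the low-temperature maximum, predicted acidity *decreases* — a
  physically wrong artefact this simulator intentionally reproduces.

* ``simulate_dynamic_mkt`` — the mean-kinetic-temperature scheme: the
  stationary-phase maximum is evaluated at the MKT, the constant temperature
  whose model trajectory reproduces the current acidity at the current
  elapsed time.  Because the current acidity always lies below the
  constant-MKT plateau, the trajectory is non-decreasing by construction.

The MKT here is the acidity-matching definition used in fermentation
monitoring, not the pharmaceutical Arrhenius-weighted average.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .kinetics import AcidityTrajectory, integrate_segment
from .params import KineticParameters
from .profiles import TemperatureProfile
from .secondary import mu_max, n_max

__all__ = [
    "MKTRecord",
    "estimate_mkt",
    "simulate_dynamic_instantaneous",
    "simulate_dynamic_mkt",
]

#: Acidity increments below this (% lactic acid) are indistinguishable from
#: the initial value; the MKT inversion is then degenerate.
DEGENERATE_ACIDITY_TOL = 1e-6

#: Default MKT bisection tolerance in degC.
MKT_XTOL = 5e-3

#: Default refresh/step interval of the MKT simulator: one hour, in days.
DEFAULT_MAX_STEP_D = 1.0 / 24.0


@dataclass(frozen=True)
class MKTRecord:
    """One step of an MKT trajectory: time, actual temp, and the MKT."""

    t: float
    temp_actual: float
    t_mkt: float


def _lse0(x: float) -> float:
    """log(1 + e^x) without overflow."""
    return x + math.log1p(math.exp(-x)) if x > 0 else math.log1p(math.exp(x))


def _constant_t_acidity(params: KineticParameters, n0: float, mu: float, nm: float, t: float) -> float:
    """Scalar fast path of the exact constant-temperature solution."""
    lq0 = math.log(params.q0)
    tau = (_lse0(lq0 + mu * t) - _lse0(lq0)) / mu
    return nm / (1.0 + (nm / n0 - 1.0) * math.exp(-mu * tau))


def estimate_mkt(
    params: KineticParameters,
    n0: float,
    t: float,
    n: float,
    bracket: tuple[float, float],
    xtol: float = MKT_XTOL,
    degenerate_temp: float | None = None,
) -> float:
    """Mean kinetic temperature for acidity ``n`` observed at time ``t``.

    Finds the constant temperature T* in ``bracket`` whose
    constant-temperature trajectory from ``n0`` passes through ``(t, n)``,
    by root bracketing on the monotone map T -> N(t; T).  If the target lies
    outside the achievable range it is clamped to the nearer bracket end
    with a warning.

    At ``t == 0``, or while ``n`` is within ``DEGENERATE_ACIDITY_TOL`` of
    ``n0``, the inversion carries no information and ``degenerate_temp``
    (e.g. the running time-average of the profile, which equals the initial
    temperature at t = 0) is returned instead.
    """
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    if n < n0 - DEGENERATE_ACIDITY_TOL:
        raise ValueError(f"acidity {n} below the initial value {n0}; MKT undefined")
    lo, hi = float(bracket[0]), float(bracket[1])
    if lo > hi:
        raise ValueError(f"bracket must be ordered, got {bracket}")
    if t == 0.0 or abs(n - n0) < DEGENERATE_ACIDITY_TOL:
        if degenerate_temp is None:
            raise ValueError(
                "acidity indistinguishable from n0: supply degenerate_temp "
                "(e.g. the profile's running time-average)"
            )
        return float(degenerate_temp)
    if lo == hi:
        return lo

    mus = mu_max(params, np.linspace(lo, hi, 5))
    nms = n_max(params, np.linspace(lo, hi, 5))
    vals = [
        _constant_t_acidity(params, n0, float(m), float(nmv), t) for m, nmv in zip(mus, nms)
    ]
    if np.any(np.diff(vals) < -1e-12):
        raise RuntimeError(
            f"N(t; T) is not monotone in T on [{lo}, {hi}]; MKT inversion is ill-posed"
        )

    def f(temp: float) -> float:
        m = params.a0 + params.a1 * temp + params.a2 * temp * temp
        nmv = params.nmax_intercept + params.nmax_slope * temp
        return _constant_t_acidity(params, n0, m, nmv, t) - n

    f_lo, f_hi = f(lo), f(hi)
    if f_hi < 0:
        warnings.warn(
            f"target acidity {n} at t={t} d exceeds the constant-{hi} degC trajectory; "
            "clamping MKT to the upper bracket",
            stacklevel=2,
        )
        return hi
    if f_lo > 0:
        warnings.warn(
            f"target acidity {n} at t={t} d lies below the constant-{lo} degC trajectory; "
            "clamping MKT to the lower bracket",
            stacklevel=2,
        )
        return lo
    return float(brentq(f, lo, hi, xtol=xtol))


def _refined_grid(t_grid, profile: TemperatureProfile, max_step: float | None) -> np.ndarray:
    """Union of t_grid and breakpoints, optionally subdivided to max_step."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1 or t_grid[0] != 0.0:
        raise ValueError("t_grid must be 1-D, non-empty and start at 0")
    if len(t_grid) > 1 and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    t_end = t_grid[-1]
    base = np.unique(
        np.round(np.concatenate([t_grid, profile.breakpoints[profile.breakpoints <= t_end]]), 12)
    )
    if max_step is None:
        return base
    pieces = []
    for u, v in zip(base[:-1], base[1:]):
        k = max(1, int(math.ceil((v - u) / max_step - 1e-9)))
        pieces.append(np.linspace(u, v, k + 1)[:-1])
    pieces.append(base[-1:])
    return np.concatenate(pieces) if len(base) > 1 else base


def simulate_dynamic_instantaneous(
    params: KineticParameters, n0: float, profile: TemperatureProfile, t_grid
) -> AcidityTrajectory:
    """Integrate the acidity system with mu_max and n_max at T(t).

    The returned trajectory is evaluated on the union of ``t_grid`` and the
    profile breakpoints.  May produce decreasing acidity when the
    temperature drops after N has exceeded the low-temperature plateau;
    this failure mode is intentional.
    """
    if n0 <= 0:
        raise ValueError(f"initial acidity must be positive, got {n0}")
    grid = _refined_grid(t_grid, profile, max_step=None)
    t_end = grid[-1]
    n_out = [n0]
    lq_out = [math.log(params.q0)]
    n_cur, lq_cur = n0, math.log(params.q0)
    bounds = profile.segment_bounds(t_end)
    for s0, s1 in zip(bounds[:-1], bounds[1:]):
        temp = profile.temperature_at(s0)
        mu = mu_max(params, temp)
        nm = n_max(params, temp)
        pts = grid[(grid > s0) & (grid <= s1)]
        nn, lq, n_cur, lq_cur = integrate_segment(n_cur, lq_cur, mu, nm, s0, s1, pts)
        n_out.extend(nn)
        lq_out.extend(lq)
    with np.errstate(over="ignore"):
        q = np.exp(np.array(lq_out))
    return AcidityTrajectory(
        t=grid,
        n=np.array(n_out),
        q=q,
        temperature=profile.temperature_at(grid),
    )


def simulate_dynamic_mkt(
    params: KineticParameters,
    n0: float,
    profile: TemperatureProfile,
    t_grid,
    mu_source: str = "instantaneous",
    max_step_d: float = DEFAULT_MAX_STEP_D,
    mkt_bracket: tuple[float, float] | None = None,
) -> AcidityTrajectory:
    """Integrate the acidity system with n_max evaluated at the MKT.

    At every step the MKT is re-estimated from the elapsed time and current
    acidity, and the system is advanced over the step with ``n_max =
    n_max(T_MKT)`` held fixed.  ``mu_source`` selects where the growth rate
    is evaluated: ``"instantaneous"`` (default) uses the actual temperature
    T(t); ``"mkt"`` uses the MKT as well.

    The grid is the union of ``t_grid`` and the profile breakpoints,
    subdivided so no step exceeds ``max_step_d`` (default one hour).  Within
    a step the update is the exact constant-coefficient solution (Q advances
    analytically; N is logistic in the transformed time), so the only
    discretisation is the MKT refresh interval.
    """
    if n0 <= 0:
        raise ValueError(f"initial acidity must be positive, got {n0}")
    if mu_source not in ("instantaneous", "mkt"):
        raise ValueError(f"mu_source must be 'instantaneous' or 'mkt', got {mu_source!r}")
    grid = _refined_grid(t_grid, profile, max_step=max_step_d)
    bracket = mkt_bracket if mkt_bracket is not None else (profile.tmin, profile.tmax)

    n_arr = np.empty_like(grid)
    lq_arr = np.empty_like(grid)
    mkt_arr = np.empty_like(grid)
    n_cur = n0
    lq_cur = math.log(params.q0)
    for i, t_i in enumerate(grid):
        t_mkt = estimate_mkt(
            params,
            n0,
            float(t_i),
            n_cur,
            bracket=bracket,
            degenerate_temp=profile.time_average(float(t_i)),
        )
        n_arr[i] = n_cur
        lq_arr[i] = lq_cur
        mkt_arr[i] = t_mkt
        if i == len(grid) - 1:
            break
        dt = grid[i + 1] - t_i
        t_src = float(profile.temperature_at(float(t_i))) if mu_source == "instantaneous" else t_mkt
        mu = params.a0 + params.a1 * t_src + params.a2 * t_src * t_src
        nm = params.nmax_intercept + params.nmax_slope * t_mkt
        # exact constant-coefficient step
        dtau = (_lse0(lq_cur + mu * dt) - _lse0(lq_cur)) / mu
        n_cur = nm / (1.0 + (nm / n_cur - 1.0) * math.exp(-mu * dtau))
        lq_cur += mu * dt
    with np.errstate(over="ignore"):
        q_arr = np.exp(lq_arr)
    return AcidityTrajectory(
        t=grid,
        n=n_arr,
        q=q_arr,
        temperature=profile.temperature_at(grid),
        mkt=mkt_arr,
    )


def mkt_records(trajectory: AcidityTrajectory) -> list[MKTRecord]:
    """The MKT series of a trajectory as explicit records."""
    if trajectory.mkt is None:
        raise ValueError("trajectory carries no MKT series")
    return [
        MKTRecord(float(t), float(temp), float(m))
        for t, temp, m in zip(trajectory.t, trajectory.temperature, trajectory.mkt)
    ]
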