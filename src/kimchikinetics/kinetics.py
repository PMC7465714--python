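"""Primary kinetic model of kimchi acidification.

Titratable acidity N (% lactic acid) follows a Baranyi-Roberts system with
a physiological-state variable Q controlling the lag phase:

    dN/dt = Q/(1+Q) * mu_max(T) * (1 - N/n_max(T)) * N
    dQ/dt = mu_max(T) * Q

with N(0) = n0 and Q(0) = q0.  At constant temperature the system has an
exact solution (logistic growth in the transformed time tau(t)), which this
module provides both as the production oracle and for fast evaluation.

Units: times in days, rates per day, temperatures in degC, acidity in
% lactic acid (w/w).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .params import KineticParameters
from .secondary import mu_max, n_max

__all__ = [
    "MILLIEQUIVALENT_WEIGHT_LACTIC",
    "IntegrationError",
    "AcidityState",
    "AcidityTrajectory",
    "titratable_acidity",
    "closed_form_constant_temperature",
    "simulate_constant_temperature",
]

#: Milliequivalent weight of lactic acid for a 0.1 N titrant (g/meq); the
#: conversion constant of the standard NaOH titration assay.
MILLIEQUIVALENT_WEIGHT_LACTIC = 0.009

# Below this rtol/atol the closed-form comparison bound of 1e-6 % would be
# dominated by integrator error rather than model differences.
_RTOL = 1e-8
_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """ODE solver failed to converge; carries the solver diagnostics."""


@dataclass(frozen=True)
class AcidityState:
    """Model state at one instant: time (d), acidity (%), physiological Q."""

    t: float
    n: float
    q: float


@dataclass
class AcidityTrajectory:
    """Time-ordered model states with their governing temperature.

    Attributes
    ----------
    t : ndarray
        Strictly increasing times in days.
    n : ndarray
        Acidity in % lactic acid.
    q : ndarray
        Physiological state (dimensionless).
    temperature : ndarray
        Governing (actual) temperature in degC at each time.
    mkt : ndarray or None
        Mean kinetic temperature in degC at each time, when produced by the
        MKT dynamic model.
    """

    t: np.ndarray
    n: np.ndarray
    q: np.ndarray
    temperature: np.ndarray
    mkt: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.mkt is not None:
            self.mkt = np.asarray(self.mkt, dtype=float)
        if not (len(self.t) == len(self.n) == len(self.q) == len(self.temperature)):
            raise ValueError("trajectory arrays must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def states(self) -> Iterator[AcidityState]:
        for i in range(len(self)):
            yield AcidityState(float(self.t[i]), float(self.n[i]), float(self.q[i]))

    def acidity_at(self, times) -> np.ndarray:
        """Linearly interpolate acidity onto ``times`` (days)."""
        return np.interp(np.asarray(times, dtype=float), self.t, self.n)

    def to_frame(self):
        """Tabular form with the canonical column order."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_d": self.t,
                "temp_C": self.temperature,
                "acidity_pct": self.n,
                "q": self.q,
                "mkt_C": self.mkt if self.mkt is not None else np.full(len(self), np.nan),
            }
        )


def titratable_acidity(naoh_volume_ml: float, naoh_factor: float, sample_weight_g: float) -> float:
    """Convert an NaOH titration to titratable acidity in % lactic acid.

    ``0.009 * V_NaOH(mL) * factor / sample_weight(g) * 100`` for a 0.1 N
    titrant, where 0.009 is the milliequivalent weight of lactic acid.
    """
    if sample_weight_g <= 0:
        raise ValueError(f"sample weight must be positive, got {sample_weight_g} g")
    if naoh_volume_ml < 0:
        raise ValueError(f"titrant volume cannot be negative, got {naoh_volume_ml} mL")
    if naoh_factor <= 0:
        raise ValueError(f"titrant factor must be positive, got {naoh_factor}")
    return MILLIEQUIVALENT_WEIGHT_LACTIC * naoh_volume_ml * naoh_factor / sample_weight_g * 100.0


def transformed_time(q0: float, mu: float, t):
    """Baranyi transformed time tau(t) = ln((1 + q0*e^(mu t)) / (1 + q0)) / mu.

    Computed in log space (``logaddexp``) so that ``e^(mu t)`` never
    overflows; for mu*t >> 1 this reduces to the asymptote
    ``t - ln((1+q0)/q0)/mu`` exactly.
    """
    t = np.asarray(t, dtype=float)
    return (np.logaddexp(0.0, mu * t + np.log(q0)) - np.log1p(q0)) / mu


def closed_form_constant_temperature(params: KineticParameters, n0: float, temperature: float, t):
    """Exact constant-temperature solution of the acidity system.

    Logistic growth in the transformed time: ``n(t) = n_max / (1 +
    (n_max/n0 - 1) * exp(-mu * tau(t)))`` with ``mu = mu_max(T)`` and
    ``n_max = n_max(T)``.  Vectorised over ``t``; valid for any positive
    ``n0`` (values above ``n_max`` decay toward it).
    """
    if n0 <= 0:
        raise ValueError(f"initial acidity must be positive, got {n0}")
    mu = mu_max(params, temperature)
    nm = n_max(params, temperature)
    tau = transformed_time(params.q0, mu, t)
    out = nm / (1.0 + (nm / n0 - 1.0) * np.exp(-mu * tau))
    return out if np.ndim(out) else float(out)


def _validate_grid(t_grid: np.ndarray) -> np.ndarray:
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1:
        raise ValueError("t_grid must be a non-empty 1-D array of times")
    if t_grid[0] != 0.0:
        raise ValueError(f"t_grid must start at 0, got {t_grid[0]}")
    if len(t_grid) > 1 and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    return t_grid


def integrate_segment(n, logq, mu: float, nm: float, t0: float, t1: float, t_eval: np.ndarray):
    """Integrate the system over [t0, t1] at fixed mu and n_max.

    State is (N, log Q); Q is propagated in log scale so it cannot
    overflow.  Returns (N(t_eval), logQ(t_eval), N(t1), logQ(t1)).
    """

    def rhs(_t, y):
        nn, lq = y
        alpha = 1.0 / (1.0 + np.exp(-lq))  # Q/(1+Q)
        return [alpha * mu * (1.0 - nn / nm) * nn, mu]

    want = np.unique(np.append(t_eval, t1))
    sol = solve_ivp(
        rhs,
        (t0, t1),
        [n, logq],
        method="RK45",
        t_eval=want,
        rtol=_RTOL,
        atol=_ATOL,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed on [{t0}, {t1}] at mu={mu}, n_max={nm}: {sol.message}"
        )
    keep = np.isin(sol.t, t_eval)
    return sol.y[0][keep], sol.y[1][keep], sol.y[0][-1], sol.y[1][-1]


def simulate_constant_temperature(
    params: KineticParameters, n0: float, temperature: float, t_grid
) -> AcidityTrajectory:
    """Numerically integrate the acidity system at a fixed temperature.

    ``t_grid`` must start at 0 and be strictly increasing.  ``n0`` must lie
    in (0, n_max(T)]; ``n0 == n_max(T)`` is the already-stationary limit and
    yields a constant trajectory.
    """
    t_grid = _validate_grid(t_grid)
    mu = mu_max(params, temperature)
    nm = n_max(params, temperature)
    if n0 <= 0:
        raise ValueError(f"initial acidity must be positive, got {n0}")
    if n0 > nm:
        raise ValueError(
            f"initial acidity {n0} exceeds the stationary maximum n_max({temperature}) = {nm}"
        )
    logq = np.log(params.q0) + mu * t_grid  # exact in Q
    if n0 == nm or len(t_grid) == 1:
        n = np.full_like(t_grid, n0)
    else:
        n, _, _, _ = integrate_segment(n0, np.log(params.q0), mu, nm, 0.0, t_grid[-1], t_grid)
        n[0] = n0
    temp = np.full_like(t_grid, float(temperature))
    # Q grows without bound once the lag ends; inf is its honest limit here
    with np.errstate(over="ignore"):
        q = np.exp(logq)
    return AcidityTrajectory(t=t_grid, n=n, q=q, temperature=temp)
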