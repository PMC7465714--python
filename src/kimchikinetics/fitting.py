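"""Global calibration of the kinetic constants against acidity observations.

All six constants (a0, a1, a2, q0, nmax_intercept, nmax_slope) plus one
initial acidity per experiment are estimated jointly by minimising the
plain sum of squared residuals between observed acidities and the
constant-temperature model, pooled over every temperature and experiment.
q0 is optimised in log10 space because its likelihood surface spans orders
of magnitude.

The optimiser is two-stage: a seeded differential-evolution global search
over box bounds, followed by local trust-region least-squares refinement
started from the best few population members (a single start occasionally
polishes into a local minimum).  Identical data and seed give bit-identical
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import differential_evolution, least_squares

from .params import KineticParameters

__all__ = [
    "ObservationSet",
    "FitConfig",
    "FitResult",
    "IdentifiabilityError",
    "fit_parameters",
    "confidence_intervals",
]

_CONSTANT_NAMES = ("a0", "a1", "a2", "log10_q0", "nmax_intercept", "nmax_slope")


class IdentifiabilityError(ValueError):
    """The observation design cannot identify the secondary models."""


@dataclass
class ObservationSet:
    """Measured acidity records across experiments and storage conditions.

    Wraps a table with columns ``experiment`` (str), ``condition`` (str;
    numeric strings such as ``"10"`` denote constant temperature in degC,
    labels such as ``"0-10"`` denote fluctuating profiles), ``time_d``
    (days) and ``acidity_pct`` (% lactic acid).  ``n0`` optionally annotates
    the known initial acidity per experiment.
    """

    frame: pd.DataFrame
    n0: dict[str, float] = field(default_factory=dict)

    REQUIRED = ("experiment", "condition", "time_d", "acidity_pct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"observation table is missing columns: {missing}")
        f = self.frame
        if len(f) == 0:
            raise ValueError("observation table is empty")
        if (f["acidity_pct"] <= 0).any():
            bad = f.index[f["acidity_pct"] <= 0][0]
            raise ValueError(f"non-positive acidity at row {bad}")
        if (f["time_d"] < 0).any():
            bad = f.index[f["time_d"] < 0][0]
            raise ValueError(f"negative time at row {bad}")
        self.frame = f.assign(
            experiment=f["experiment"].astype(str), condition=f["condition"].astype(str)
        )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def experiments(self) -> list[str]:
        return sorted(self.frame["experiment"].unique())

    def constant_temperature_records(self) -> pd.DataFrame:
        """Rows whose condition parses as a constant temperature, with temp_C."""
        f = self.frame
        temp = pd.to_numeric(f["condition"], errors="coerce")
        out = f[temp.notna()].copy()
        out["temp_C"] = temp[temp.notna()].astype(float)
        return out

    @property
    def temperatures(self) -> list[float]:
        return sorted(self.constant_temperature_records()["temp_C"].unique())


@dataclass(frozen=True)
class FitConfig:
    """Settings of the two-stage optimiser.

    Bounds reflect physical positivity and the observed acidity range:
    polynomial coefficients in [0, 5], log10(q0) in [-10, -2], plateau
    intercept in [0.1, 3] %, slope in [0, 0.2] %/degC, initial acidities in
    [0.05, 0.6] %.
    """

    population: int = 60
    generations: int = 200
    tol: float = 1e-8
    polish_starts: int = 5
    coeff_bounds: tuple[float, float] = (0.0, 5.0)
    log10_q0_bounds: tuple[float, float] = (-10.0, -2.0)
    nmax_intercept_bounds: tuple[float, float] = (0.1, 3.0)
    nmax_slope_bounds: tuple[float, float] = (0.0, 0.2)
    n0_bounds: tuple[float, float] = (0.05, 0.6)


@dataclass
class FitResult:
    """Point estimates, uncertainty and diagnostics of a calibration."""

    params: KineticParameters
    n0: dict[str, float]
    rss: float
    seed: int
    theta: np.ndarray
    param_names: tuple[str, ...]
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def estimates(self) -> dict[str, float]:
        out = {
            "a0": self.params.a0,
            "a1": self.params.a1,
            "a2": self.params.a2,
            "q0": self.params.q0,
            "nmax_intercept": self.params.nmax_intercept,
            "nmax_slope": self.params.nmax_slope,
        }
        out.update({f"n0[{k}]": v for k, v in self.n0.items()})
        return out

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates(),
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "rss": self.rss,
            "seed": self.seed,
            "diagnostics": self.diagnostics,
        }


def _design_arrays(obs: ObservationSet):
    rec = obs.constant_temperature_records()
    temps = np.sort(rec["temp_C"].unique())
    if len(temps) < 2:
        raise IdentifiabilityError(
            f"at least two constant temperatures are required to identify the "
            f"secondary models; got {list(temps)}"
        )
    exps = obs.experiments
    e_idx = rec["experiment"].map({e: i for i, e in enumerate(exps)}).to_numpy()
    return (
        rec["temp_C"].to_numpy(),
        rec["time_d"].to_numpy(),
        rec["acidity_pct"].to_numpy(),
        e_idx.astype(int),
        exps,
    )


def _predict(theta: np.ndarray, T: np.ndarray, t: np.ndarray, e_idx: np.ndarray) -> np.ndarray:
    """Vectorised constant-temperature model over the observation design."""
    a0, a1, a2, lq0, ni, ns = theta[:6]
    n0s = np.asarray(theta[6:])
    q0 = 10.0**lq0
    mu = np.maximum(a0 + a1 * T + a2 * T**2, 1e-12)
    nm = ni + ns * T
    n0 = n0s[e_idx]
    tau = (np.logaddexp(0.0, mu * t + np.log(q0)) - np.log1p(q0)) / mu
    return nm / (1.0 + (nm / n0 - 1.0) * np.exp(-mu * tau))


def _bounds(config: FitConfig, n_exp: int) -> list[tuple[float, float]]:
    return (
        [config.coeff_bounds] * 3
        + [config.log10_q0_bounds]
        + [config.nmax_intercept_bounds, config.nmax_slope_bounds]
        + [config.n0_bounds] * n_exp
    )


def fit_parameters(
    observations: ObservationSet, config: Optional[FitConfig] = None, seed: int = 0
) -> FitResult:
    """Two-stage global least-squares calibration.

    Raises :class:`IdentifiabilityError` if the observations span fewer than
    two constant temperatures.  With the same observations and ``seed`` the
    result is bit-identical across runs.
    """
    config = config or FitConfig()
    T, t, y, e_idx, exps = _design_arrays(observations)
    bounds = _bounds(config, len(exps))
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(theta):
        r = _predict(theta, T, t, e_idx) - y
        return float(r @ r)

    rng = np.random.default_rng(seed)
    init = rng.uniform(lo, hi, size=(config.population, len(bounds)))
    de = differential_evolution(
        objective,
        bounds,
        init=init,
        maxiter=config.generations,
        tol=config.tol,
        seed=seed,
        polish=False,
        updating="immediate",
    )

    order = np.argsort(de.population_energies)[: config.polish_starts]
    best = None
    for k in order:
        ls = least_squares(
            lambda th: _predict(th, T, t, e_idx) - y,
            de.population[k],
            bounds=(lo, hi),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        rss = float(ls.fun @ ls.fun)
        if best is None or rss < best[0]:
            best = (rss, ls)
    rss, ls = best
    if not (de.success or de.message.startswith("Maximum number")) and not ls.success:
        raise RuntimeError(
            f"optimiser did not converge (global: {de.message}; local status {ls.status}); "
            f"best RSS so far {rss:.6g}"
        )

    theta = ls.x
    params = KineticParameters(
        a0=float(theta[0]),
        a1=float(theta[1]),
        a2=float(theta[2]),
        q0=float(10.0 ** theta[3]),
        nmax_intercept=float(theta[4]),
        nmax_slope=float(theta[5]),
    )
    n0_map = {e: float(v) for e, v in zip(exps, theta[6:])}
    names = _CONSTANT_NAMES + tuple(f"n0[{e}]" for e in exps)
    return FitResult(
        params=params.with_n0(n0_map),
        n0=n0_map,
        rss=rss,
        seed=seed,
        theta=theta,
        param_names=names,
        diagnostics={
            "n_obs": int(len(y)),
            "n_params": int(len(theta)),
            "de_message": de.message,
            "de_nit": int(de.nit),
            "ls_status": int(ls.status),
            "ls_nfev": int(ls.nfev),
        },
    )


def residual_sum_of_squares(fit: FitResult, observations: ObservationSet) -> float:
    """Recompute the objective at the fitted estimates (consistency check)."""
    T, t, y, e_idx, _ = _design_arrays(observations)
    r = _predict(fit.theta, T, t, e_idx) - y
    return float(r @ r)


def confidence_intervals(
    fit: FitResult,
    observations: ObservationSet,
    method: str = "linearized",
    n_boot: int = 200,
    seed: Optional[int] = None,
) -> FitResult:
    """Populate 95% confidence intervals on a converged fit.

    ``"linearized"`` (default) uses the Jacobian at the solution:
    ``cov = s^2 (J'J)^-1`` with ``s^2 = RSS/(n-p)`` and Student-t quantiles.
    ``"bootstrap"`` resamples residuals with replacement, refits locally and
    takes percentile intervals; it is also the automatic fallback when J'J
    is singular.  q0 intervals are formed in log10 space and transformed
    back, so they can span orders of magnitude.
    """
    if method not in ("linearized", "bootstrap"):
        raise ValueError(f"unknown CI method {method!r}")
    T, t, y, e_idx, _ = _design_arrays(observations)
    config = FitConfig()
    bounds = _bounds(config, len(fit.n0))
    lo_b = np.array([b[0] for b in bounds])
    hi_b = np.array([b[1] for b in bounds])

    def resid(th):
        return _predict(th, T, t, e_idx) - y

    if method == "linearized":
        ls = least_squares(
            resid, fit.theta, bounds=(lo_b, hi_b), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12
        )
        J = ls.jac
        n, p = len(y), len(fit.theta)
        if n <= p:
            raise ValueError("more parameters than observations; no degrees of freedom for CIs")
        jtj = J.T @ J
        cond = np.linalg.cond(jtj)
        if not np.isfinite(cond) or cond > 1e14:
            import warnings

            warnings.warn(
                "singular Jacobian in linearized CIs; falling back to bootstrap", stacklevel=2
            )
            return confidence_intervals(fit, observations, "bootstrap", n_boot=n_boot, seed=seed)
        s2 = float(ls.fun @ ls.fun) / (n - p)
        cov = np.linalg.inv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        tq = stats.t.ppf(0.975, n - p)
        lo_th = fit.theta - tq * se
        hi_th = fit.theta + tq * se
    else:
        if n_boot <= 0:
            raise ValueError(f"bootstrap requires a positive replicate count, got {n_boot}")
        rng = np.random.default_rng(fit.seed if seed is None else seed)
        yhat = _predict(fit.theta, T, t, e_idx)
        r0 = y - yhat
        draws = np.empty((n_boot, len(fit.theta)))
        for b in range(n_boot):
            y_b = yhat + rng.choice(r0, size=len(r0), replace=True)
            ls_b = least_squares(
                lambda th: _predict(th, T, t, e_idx) - y_b,
                fit.theta,
                bounds=(lo_b, hi_b),
                method="trf",
                xtol=1e-10,
                ftol=1e-10,
            )
            draws[b] = ls_b.x
        lo_th = np.percentile(draws, 2.5, axis=0)
        hi_th = np.percentile(draws, 97.5, axis=0)

    ci_low, ci_high = {}, {}
    for i, name in enumerate(fit.param_names):
        if name == "log10_q0":
            ci_low["q0"], ci_high["q0"] = 10.0 ** lo_th[i], 10.0 ** hi_th[i]
        else:
            ci_low[name], ci_high[name] = float(lo_th[i]), float(hi_th[i])
    out = replace(fit)
    out.ci_low = ci_low
    out.ci_high = ci_high
    out.diagnostics = {**fit.diagnostics, "ci_method": method}
    return out
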