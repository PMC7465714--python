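"""Kinetic parameter container for the kimchi acidity model.

The model is parameterised by six constants: three polynomial coefficients
for the temperature dependence of the maximum acidity growth rate
``mu_max(T) = a0 + a1*T + a2*T**2`` (per day), the dimensionless initial
physiological state ``q0`` that sets the lag phase, and the intercept/slope
of the linear stationary-phase maximum ``n_max(T) = nmax_intercept +
nmax_slope*T`` (% lactic acid).

All rates are per **day** and all times are in **days**; temperatures are in
degrees Celsius.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = ["KineticParameters", "reference_parameters"]


@dataclass(frozen=True)
class KineticParameters:
    """The six fitted constants of the acidity model, plus metadata.

    Parameters
    ----------
    a0, a1, a2
        Polynomial coefficients of the maximum acidity growth rate
        ``mu_max(T)`` in 1/day, 1/(day*degC) and 1/(day*degC**2).
    q0
        Dimensionless initial physiological state ``Q(0)``.  Small values
        produce a long lag phase; ``q0 -> inf`` recovers plain logistic
        growth.
    nmax_intercept, nmax_slope
        Linear stationary-phase maximum acidity ``n_max(T)`` in % lactic
        acid and % lactic acid per degC.
    calibration_range
        Temperature interval (degC) over which the secondary models were
        calibrated.  Evaluation outside it is permitted with a warning.
    n0
        Optional per-experiment initial acidities (% lactic acid), keyed by
        experiment id.
    """

    a0: float
    a1: float
    a2: float
    q0: float
    nmax_intercept: float
    nmax_slope: float
    calibration_range: tuple[float, float] = (0.0, 20.0)
    n0: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.calibration_range
        if not lo < hi:
            raise ValueError(f"calibration_range must be increasing, got {self.calibration_range}")
        if not self.q0 > 0:
            raise ValueError(f"q0 must be positive, got {self.q0}")
        # mu_max and n_max must be positive everywhere on the calibration
        # range; a quadratic/linear is checked on a dense grid including the
        # vertex, which is sufficient at float precision.
        grid = np.linspace(lo, hi, 201)
        if self.a2 != 0.0:
            vertex = -self.a1 / (2.0 * self.a2)
            if lo < vertex < hi:
                grid = np.append(grid, vertex)
        mu = self.a0 + self.a1 * grid + self.a2 * grid**2
        if np.any(mu <= 0):
            raise ValueError("mu_max(T) must be positive on the calibration range")
        nmax = self.nmax_intercept + self.nmax_slope * grid
        if np.any(nmax <= 0):
            raise ValueError("n_max(T) must be positive on the calibration range")
        for key, val in self.n0.items():
            if not val > 0:
                raise ValueError(f"initial acidity for experiment {key!r} must be positive, got {val}")

    # Convenience evaluators; the canonical functions live in
    # :mod:`kimchikinetics.secondary`.
    def mu_max(self, temperature):
        from .secondary import mu_max

        return mu_max(self, temperature)

    def n_max(self, temperature):
        from .secondary import n_max

        return n_max(self, temperature)

    def with_n0(self, n0: Mapping[str, float]) -> "KineticParameters":
        return replace(self, n0=dict(n0))

    def to_dict(self) -> dict:
        return {
            "a0": self.a0,
            "a1": self.a1,
            "a2": self.a2,
            "q0": self.q0,
            "nmax_intercept": self.nmax_intercept,
            "nmax_slope": self.nmax_slope,
            "calibration_range": list(self.calibration_range),
            "n0": dict(self.n0),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticParameters":
        return cls(
            a0=float(d["a0"]),
            a1=float(d["a1"]),
            a2=float(d["a2"]),
            q0=float(d["q0"]),
            nmax_intercept=float(d["nmax_intercept"]),
            nmax_slope=float(d["nmax_slope"]),
            calibration_range=tuple(d.get("calibration_range", (0.0, 20.0))),  # type: ignore[arg-type]
            n0={str(k): float(v) for k, v in d.get("n0", {}).items()},
        )


def reference_parameters() -> KineticParameters:
    """Constants calibrated for commercial napa-cabbage kimchi, 0-20 degC.

    These are the published global-fit values for titratable acidity of
    refrigerated kimchi; they serve as the package default and as the
    generating truth of the synthetic-data module.
    """
    return KineticParameters(
        a0=7.09e-2,
        a1=1.52e-2,
        a2=2.33e-3,
        q0=3.70e-7,
        nmax_intercept=8.78e-1,
        nmax_slope=1.60e-2,
        calibration_range=(0.0, 20.0),
    )
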