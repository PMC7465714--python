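"""Secondary models: temperature dependence of the primary-model parameters.

The maximum acidity growth rate follows a quadratic polynomial in storage
temperature, and the stationary-phase maximum acidity increases linearly
with temperature — the distinctive feature of kimchi ripening compared to
classical growth systems whose plateau is temperature independent.
"""

from __future__ import annotations

import warnings

import numpy as np

from .params import KineticParameters

__all__ = ["mu_max", "n_max", "CalibrationRangeWarning"]


class CalibrationRangeWarning(UserWarning):
    """Temperature outside the range the secondary models were fitted on."""


def _check_range(params: KineticParameters, temperature, what: str) -> None:
    lo, hi = params.calibration_range
    t = np.asarray(temperature, dtype=float)
    if np.any(t < lo) or np.any(t > hi):
        warnings.warn(
            f"{what} evaluated outside the calibration range [{lo}, {hi}] degC; "
            "extrapolating the fitted polynomial/linear form",
            CalibrationRangeWarning,
            stacklevel=3,
        )


def mu_max(params: KineticParameters, temperature):
    """Maximum acidity growth rate (1/day) at ``temperature`` (degC).

    ``mu_max(T) = a0 + a1*T + a2*T**2``.  Accepts scalars or arrays.
    """
    _check_range(params, temperature, "mu_max")
    t = np.asarray(temperature, dtype=float)
    out = params.a0 + params.a1 * t + params.a2 * t**2
    return out if out.ndim else float(out)


def n_max(params: KineticParameters, temperature):
    """Stationary-phase maximum acidity (% lactic acid) at ``temperature``.

    ``n_max(T) = nmax_intercept + nmax_slope*T``.  Accepts scalars or arrays.
    """
    _check_range(params, temperature, "n_max")
    t = np.asarray(temperature, dtype=float)
    out = params.nmax_intercept + params.nmax_slope * t
    return out if out.ndim else float(out)
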