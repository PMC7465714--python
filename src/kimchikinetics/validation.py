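"""Accuracy and bias factors for prediction-observation comparison.

Af = 10^(mean |log10(pred/obs)|) measures spread; Bf = 10^(mean
log10(pred/obs)) measures systematic over/under-prediction.  Both equal 1
exactly when every prediction matches its observation; Af >= max(Bf, 1/Bf)
always.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import ObservationSet
from .kinetics import AcidityTrajectory

__all__ = ["accuracy_bias_factors", "ValidationReport", "validate_trajectories"]


def accuracy_bias_factors(predicted, observed) -> tuple[float, float]:
    """Return (Af, Bf) for paired positive series, base-10 logs."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError(f"predicted and observed must be equal-length 1-D, got {p.shape} vs {o.shape}")
    if len(p) < 1:
        raise ValueError("at least one prediction/observation pair is required")
    if np.any(p <= 0) or np.any(o <= 0):
        raise ValueError("all values must be strictly positive (log-ratio undefined otherwise)")
    logr = np.log10(p / o)
    af = float(10.0 ** np.mean(np.abs(logr)))
    bf = float(10.0 ** np.mean(logr))
    return af, bf


@dataclass
class ValidationReport:
    """Per-condition Af/Bf table, mirroring how validation results are
    reported per experiment and temperature condition."""

    records: list[dict] = field(default_factory=list)

    def add(self, experiment: str, condition: str, af: float, bf: float, n_points: int) -> None:
        self.records.append(
            {
                "experiment": experiment,
                "condition": condition,
                "af": af,
                "bf": bf,
                "n_points": n_points,
            }
        )

    @property
    def rows(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["experiment", "condition", "af", "bf", "n_points"]
        )

    def to_dict(self) -> dict:
        out: dict = {}
        for _, r in self.rows.iterrows():
            out.setdefault(str(r["experiment"]), {})[str(r["condition"])] = {
                "af": float(r["af"]),
                "bf": float(r["bf"]),
                "n_points": int(r["n_points"]),
            }
        return out


def validate_trajectories(
    trajectories: dict[tuple[str, str], AcidityTrajectory] | AcidityTrajectory,
    observations: ObservationSet,
) -> ValidationReport:
    """Compare predicted trajectories with observations, grouped by
    (experiment, condition).

    Predictions are interpolated linearly from the trajectory's own grid
    onto the observation times.  Pass a single trajectory to apply it to
    every group, or a mapping keyed by (experiment, condition).
    """
    report = ValidationReport()
    for (exp, cond), grp in observations.frame.groupby(["experiment", "condition"], sort=True):
        if isinstance(trajectories, AcidityTrajectory):
            traj = trajectories
        else:
            if (exp, cond) not in trajectories:
                continue
            traj = trajectories[(exp, cond)]
        pred = traj.acidity_at(grp["time_d"].to_numpy())
        af, bf = accuracy_bias_factors(pred, grp["acidity_pct"].to_numpy())
        report.add(exp, cond, af, bf, len(grp))
    return report
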