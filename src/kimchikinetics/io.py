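"""File formats: parameter JSON, observation/profile/trajectory CSV.

All CSV files are comma-separated UTF-8 with a header row and dot decimals.
The canonical time unit on disk is days (column ``time_d``); hour-based
logger files use ``time_h`` and are converted on read.  Numeric fields are
written with full float precision (17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult, ObservationSet
from .kinetics import AcidityTrajectory
from .params import KineticParameters
from .profiles import TemperatureProfile
from .synthetic import SyntheticDesign

__all__ = [
    "read_params",
    "write_params",
    "read_observations",
    "write_observations",
    "read_temperature_log",
    "write_temperature_profile",
    "read_trajectory",
    "write_trajectory",
    "write_fit_result",
    "read_design",
]

PathLike = Union[str, Path]

TRAJECTORY_COLUMNS = ["time_d", "temp_C", "acidity_pct", "q", "mkt_C"]


class ParseError(ValueError):
    """A file violated the expected schema."""


def read_params(path: PathLike) -> KineticParameters:
    with open(path, encoding="utf-8") as fh:
        return KineticParameters.from_dict(json.load(fh))


def write_params(path: PathLike, params: KineticParameters) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(params.to_dict(), fh, indent=2)
        fh.write("\n")


def read_observations(path: PathLike) -> ObservationSet:
    frame = pd.read_csv(path)
    try:
        return ObservationSet(frame)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_observations(path: PathLike, obs: ObservationSet) -> None:
    obs.frame.to_csv(path, index=False, float_format="%.17g")


def read_temperature_log(path: PathLike, time_unit: str | None = None) -> TemperatureProfile:
    """Read a logger-style CSV with columns ``time_d`` (or ``time_h``) and
    ``temp_C``; each sample holds until the next."""
    frame = pd.read_csv(path)
    if "temp_C" not in frame.columns:
        raise ParseError(f"{path}: missing required column 'temp_C'")
    if time_unit is None:
        if "time_d" in frame.columns:
            time_col, scale = "time_d", 1.0
        elif "time_h" in frame.columns:
            time_col, scale = "time_h", 1.0 / 24.0
        else:
            raise ParseError(f"{path}: missing time column ('time_d' or 'time_h')")
    else:
        if time_unit not in ("d", "h"):
            raise ParseError(f"time_unit must be 'd' or 'h', got {time_unit!r}")
        time_col = f"time_{time_unit}"
        scale = 1.0 if time_unit == "d" else 1.0 / 24.0
        if time_col not in frame.columns:
            raise ParseError(f"{path}: missing time column {time_col!r}")
    times = frame[time_col].to_numpy(dtype=float) * scale
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        line = int(np.argmax(diffs <= 0)) + 3  # +1 header, +1 one-based, +1 offending row
        raise ParseError(f"{path}: times not strictly increasing at line {line}")
    try:
        return TemperatureProfile(times, frame["temp_C"].to_numpy(dtype=float))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_temperature_profile(path: PathLike, profile: TemperatureProfile) -> None:
    pd.DataFrame({"time_d": profile.breakpoints, "temp_C": profile.temps}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_trajectory(path: PathLike) -> AcidityTrajectory:
    frame = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS[:4] if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing trajectory columns {missing}")
    mkt = None
    if "mkt_C" in frame.columns and frame["mkt_C"].notna().any():
        mkt = frame["mkt_C"].to_numpy(dtype=float)
    return AcidityTrajectory(
        t=frame["time_d"].to_numpy(dtype=float),
        n=frame["acidity_pct"].to_numpy(dtype=float),
        q=frame["q"].to_numpy(dtype=float),
        temperature=frame["temp_C"].to_numpy(dtype=float),
        mkt=mkt,
    )


def write_trajectory(path: PathLike, trajectory: AcidityTrajectory) -> None:
    trajectory.to_frame()[TRAJECTORY_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def write_fit_result(path: PathLike, fit: FitResult) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"params": fit.params.to_dict(), **fit.to_dict()}, fh, indent=2)
        fh.write("\n")


def read_design(path: PathLike) -> SyntheticDesign:
    """Read a synthetic-study design from YAML or JSON."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: design file must contain a mapping")
    if "fluctuating" in data:
        data["fluctuating"] = [tuple(x) for x in data["fluctuating"]]
    if "horizons" in data and data["horizons"] is not None:
        data["horizons"] = {float(k): float(v) for k, v in data["horizons"].items()}
    if "n0_range" in data:
        data["n0_range"] = tuple(data["n0_range"])
    if "temperatures" in data:
        data["temperatures"] = tuple(data["temperatures"])
    try:
        return SyntheticDesign(**data)
    except TypeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
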