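"""Readers/writers for course JSON, trajectory CSV, metrics CSV and config YAML.

File formats
------------
* Course JSON: ``{"slope_angle_deg", "start": {x, y, v0, heading_deg},
  "finish_x", "gates": [{id, x, y, side, capture_radius}]}``.
* Trajectory CSV: header ``t_s,x_m,y_m,v_mps,heading_deg,lean_deg``
  (the last three optional), comma separator, ``.`` decimal, UTF-8.
* Config YAML: ``athlete:``, ``environment:``, ``slope:`` blocks with
  the physical field names, plus ``solver:`` and ``paths:`` blocks; a
  JSON schema is published at ``docs/config_schema.json``.

Round-trip ``save -> load`` is the identity up to float formatting
(12 significant digits).  Unknown keys warn; invalid values raise
:class:`ConfigError` naming the file and field.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .analysis import Trajectory
from .model import AthleteSystem, Environment, SlopeFrame
from .simulate import CourseGeometry

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_course",
    "save_course",
    "load_trajectory",
    "save_trajectory",
    "load_config",
    "save_metrics",
    "save_summary",
    "load_validation_csv",
]

_TRAJ_COLUMNS = ["t_s", "x_m", "y_m", "v_mps", "heading_deg", "lean_deg"]


class ConfigError(ValueError):
    """A configuration or input file violates the schema or an invariant."""


@dataclass(frozen=True)
class SolverConfig:
    n_knots: int = 12
    dt: float = 0.005
    seed: int = 0
    time_cap: float = 60.0


@dataclass(frozen=True)
class RunConfig:
    athlete: AthleteSystem
    environment: Environment
    slope: SlopeFrame
    solver: SolverConfig = field(default_factory=SolverConfig)
    paths: dict = field(default_factory=dict)


def save_course(course: CourseGeometry, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(course.to_dict(), fh, indent=2)
        fh.write("\n")


def load_course(path) -> CourseGeometry:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"{path}: cannot read course JSON: {exc}") from exc
    for key in ("slope_angle_deg", "start", "finish_x"):
        if key not in data:
            raise ConfigError(f"{path}: course JSON missing required field {key!r}")
    try:
        return CourseGeometry.from_dict(data)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: invalid course definition: {exc}") from exc


def save_trajectory(traj: Trajectory, path) -> None:
    df = traj.to_dataframe()
    df.to_csv(path, index=False, float_format="%.12g")


def load_trajectory(path, frame: SlopeFrame | None = None) -> Trajectory:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise ConfigError(f"{path}: cannot read trajectory CSV: {exc}") from exc
    missing = [c for c in ("t_s", "x_m", "y_m") if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: trajectory CSV missing columns {missing}")
    unknown = [c for c in df.columns if c not in _TRAJ_COLUMNS]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown trajectory columns {unknown}")
        df = df[[c for c in df.columns if c in _TRAJ_COLUMNS]]
    try:
        return Trajectory.from_dataframe(df, frame=frame)
    except ValueError as exc:
        raise ConfigError(f"{path}: invalid trajectory: {exc}") from exc


_CONFIG_BLOCKS = {
    "athlete": ("mass_total", "drag_area", "lean_max", "com_height"),
    "environment": ("gravity", "air_density", "friction_coeff", "altitude", "temperature"),
    "slope": ("slope_angle",),
    "solver": ("n_knots", "dt", "seed", "time_cap"),
    "paths": None,  # free-form
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Physical values are validated by constructing the model-layer types,
    so every invariant (positive mass, friction in [0, 1), ...) applies
    at load time.  Paths named under ``paths:`` with a ``*_in`` suffix
    must exist.
    """
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: cannot read config YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping of blocks")

    for block in raw:
        if block not in _CONFIG_BLOCKS:
            warnings.warn(f"{path}: ignoring unknown config block {block!r}")
    for block, fields in _CONFIG_BLOCKS.items():
        sub = raw.get(block)
        if sub is None or fields is None:
            continue
        for key in sub:
            if key not in fields:
                warnings.warn(f"{path}: ignoring unknown key {block}.{key}")

    def pick(block: str, fields) -> dict:
        sub = raw.get(block) or {}
        return {k: sub[k] for k in fields if k in sub}

    try:
        athlete = AthleteSystem(**pick("athlete", _CONFIG_BLOCKS["athlete"]))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: athlete block: {exc}") from exc
    try:
        environment = Environment(**pick("environment", _CONFIG_BLOCKS["environment"]))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: environment block: {exc}") from exc
    try:
        slope = SlopeFrame(**pick("slope", _CONFIG_BLOCKS["slope"]))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: slope block: {exc}") from exc
    try:
        solver = SolverConfig(**pick("solver", _CONFIG_BLOCKS["solver"]))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: solver block: {exc}") from exc

    paths = dict(raw.get("paths") or {})
    for key, p in paths.items():
        if key.endswith("_in") and not Path(p).exists():
            raise ConfigError(f"{path}: paths.{key}: file not found: {p}")
    return RunConfig(athlete=athlete, environment=environment, slope=slope,
                     solver=solver, paths=paths)


def save_metrics(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, index=False, float_format="%.12g")


def save_summary(summary: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")


def load_validation_csv(path) -> tuple[list, list]:
    """Measured/analyzed distance columns from a validation CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise ConfigError(f"{path}: cannot read validation CSV: {exc}") from exc
    for col in ("measured_m", "analyzed_m"):
        if col not in df.columns:
            raise ConfigError(f"{path}: validation CSV missing column {col!r}")
    return df["measured_m"].tolist(), df["analyzed_m"].tolist()
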