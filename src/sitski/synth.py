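"""Synthetic courses, schedules, noisy COM tracks and metric datasets.

Everything here has known ground truth, so the simulator, the analysis
metrics and the statistical layer are testable without any field data.
The defaults emulate the giant-slalom study section this toolkit was
built around: three gates over a 69.7 m slope length on a 24 deg
incline, drone-video sampling at 60 Hz with ~0.03 m isotropic spatial
noise, and gate-turn metrics with Table-like means/SDs
(t_s 0.88 +/- 0.19 s, L_s 13.61 +/- 2.87 m, d_min 1.31 +/- 0.47 m,
d_lev 1.34 +/- 0.49 m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import Trajectory
from .model import AthleteSystem, Environment
from .simulate import (
    ControlSchedule,
    CourseGeometry,
    Gate,
    StartSpec,
    simulate_run,
    tracking_schedule,
)

__all__ = [
    "SynthSpec",
    "METRIC_MEANS",
    "METRIC_SDS",
    "make_course",
    "heuristic_schedule",
    "make_trajectory",
    "make_metric_dataset",
]

#: gate-turn metric moments used to locate/scale generated datasets
METRIC_MEANS = {"t_s": 0.88, "L_s": 13.61, "d_min": 1.31, "d_lev": 1.34}
METRIC_SDS = {"t_s": 0.19, "L_s": 2.87, "d_min": 0.47, "d_lev": 0.49}

#: section-entry speed of the generated courses, m/s
START_SPEED = 12.0


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic course/trajectory generator."""

    n_gates: int = 3
    gate_spacing_x: float = 69.7 / 3.0
    gate_offset_y: float = 4.0
    slope_angle: float = 24.0
    noise_sd: float = 0.03
    sample_rate: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gates < 1:
            raise ValueError("n_gates must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_course(spec: SynthSpec) -> CourseGeometry:
    """A gated course with alternating lateral gate offsets.

    Gates sit at ``x = spacing, 2*spacing, ...`` with ``y`` alternating
    ``+offset, -offset, ...``; the COM passes each gate on the
    centreline side (left of a right-offset gate and vice versa).  The
    start is at ``x = 0`` and the finish line 1 m beyond the last gate,
    so the default three-gate spec spans the 69.7 m study section (last
    gate at ``n_gates * spacing = 69.7 m``).  Construction is
    deterministic; the spec seed only drives the noise and metric
    generators.
    """
    gates = tuple(
        Gate(
            id=f"g{i + 1}",
            x=(i + 1) * spec.gate_spacing_x,
            y=spec.gate_offset_y * (1 if i % 2 == 0 else -1),
            side="left" if i % 2 == 0 else "right",
            capture_radius=1.5,
        )
        for i in range(spec.n_gates)
    )
    return CourseGeometry(
        slope_angle_deg=spec.slope_angle,
        start=StartSpec(x=0.0, y=0.0, v0=START_SPEED, heading_deg=0.0),
        finish_x=spec.n_gates * spec.gate_spacing_x + 1.0,
        gates=gates,
    )


def heuristic_schedule(
    course: CourseGeometry,
    sys: AthleteSystem,
    env: Environment,
    waypoint_margin: float = 0.6,
    dt: float = 0.005,
) -> ControlSchedule:
    """A plausible (not optimal) gate-to-gate lean schedule for a course.

    Wraps the pure-pursuit tracking run along a spline racing line
    threaded ``waypoint_margin`` metres inside each gate; the recorded
    lean series is the schedule.  Synthetic runs generated with it swing
    around the gates the way a controlled athlete would.
    """
    schedule, _ = tracking_schedule(
        sys, env, course.frame, course, waypoint_margin=waypoint_margin, dt=dt
    )
    return schedule


def make_trajectory(
    course: CourseGeometry,
    sys: AthleteSystem,
    env: Environment,
    schedule: ControlSchedule,
    spec: SynthSpec,
    dt: float = 0.005,
) -> tuple[Trajectory, Trajectory]:
    """(clean, noisy) COM tracks from a simulated run.

    The clean track is the simulator output resampled at
    ``spec.sample_rate``; the noisy track adds i.i.d. Gaussian noise of
    SD ``spec.noise_sd`` to x and y (seeded).  The lean channel is
    carried through unchanged.
    """
    result = simulate_run(sys, env, course.frame, course, schedule, dt=dt)
    clean = Trajectory.from_sim(result, frame=course.frame).resample(spec.sample_rate)
    rng = np.random.default_rng(spec.seed)
    noisy = Trajectory(
        t=clean.t.copy(),
        x=clean.x + rng.normal(0.0, spec.noise_sd, clean.x.size),
        y=clean.y + rng.normal(0.0, spec.noise_sd, clean.y.size),
        v=None if clean.v is None else clean.v.copy(),
        heading=None if clean.heading is None else clean.heading.copy(),
        lean=None if clean.lean is None else clean.lean.copy(),
        frame=clean.frame,
    )
    return clean, noisy


def make_metric_dataset(
    n_turns: int = 33,
    target_corr: float = 0.8,
    seed: int = 0,
    means: dict | None = None,
    sds: dict | None = None,
) -> pd.DataFrame:
    """Gate-turn metric table with a prescribed correlation structure.

    ``t_s`` acts as a common factor: each of ``L_s``, ``d_min`` and
    ``d_lev`` correlates with it at ``target_corr`` (cross-correlations
    are ``target_corr**2``, the single-factor structure).  Draws are
    shifted/scaled to the configured means and SDs and truncated at zero
    by redrawing, preserving physical non-negativity.
    """
    if n_turns < 10:
        raise ValueError("n_turns must be >= 10")
    if not abs(target_corr) < 1:
        raise ValueError("|target_corr| must be < 1")
    means = dict(METRIC_MEANS if means is None else means)
    sds = dict(METRIC_SDS if sds is None else sds)
    cols = ["t_s", "L_s", "d_min", "d_lev"]
    rho = target_corr
    corr = np.full((4, 4), rho * rho)
    corr[0, :] = corr[:, 0] = rho
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - factor form is PSD
        raise ValueError("requested correlation matrix is not positive definite") from exc

    rng = np.random.default_rng(seed)
    out = np.empty((n_turns, 4))
    filled = 0
    while filled < n_turns:
        z = rng.standard_normal((n_turns, 4)) @ chol.T
        draw = z * np.array([sds[c] for c in cols]) + np.array([means[c] for c in cols])
        ok = draw[(draw > 0).all(axis=1)]
        take = min(len(ok), n_turns - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return pd.DataFrame(out, columns=cols)
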