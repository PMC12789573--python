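"""Gate-turn descriptors of a COM trajectory.

Given a time-stamped slope-plane COM track and the gate positions, this
module segments the run into turns at the zero-crossings of the lean
angle, computes the per-gate spatial metrics

* ``L_s``  — skiing distance over the turn segment,
* ``t_s``  — skiing time over the turn segment,
* ``d_min`` — continuous minimum COM-gate distance,
* ``d_lev`` — cross-slope COM-gate distance at the instant the COM
  reaches the gate's downslope level,

classifies where the closest approach falls relative to the gate-level
instant (turn completed *before*, *at* or *after* the gate), and
estimates the local turn radius by sliding-window quadratic fits of the
coordinates against arc length (``R = 1/|kappa|``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SlopeFrame
from .simulate import Gate, SimResult

__all__ = [
    "Trajectory",
    "TurnSegment",
    "GateTurnMetrics",
    "CurvatureProfile",
    "segment_turns",
    "gate_metrics",
    "curvature_profile",
    "analyze_run",
    "PATTERN_BEFORE",
    "PATTERN_AT",
    "PATTERN_AFTER",
]

logger = logging.getLogger(__name__)

PATTERN_BEFORE = "before"
PATTERN_AT = "at"
PATTERN_AFTER = "after"

#: curvatures below this are reported as straight running (R = inf)
KAPPA_FLOOR = 1e-6


@dataclass
class Trajectory:
    """Time-ordered COM samples in the slope plane.

    ``v``, ``heading`` and ``lean`` are optional channels (``None`` when
    the source did not record them).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    v: np.ndarray | None = None
    heading: np.ndarray | None = None
    lean: np.ndarray | None = None
    frame: SlopeFrame | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        for name in ("v", "heading", "lean"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, np.asarray(val, dtype=float))
        n = self.t.size
        if self.x.size != n or self.y.size != n:
            raise ValueError("t, x, y must have equal length")
        if n >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    def path_length(self) -> float:
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @classmethod
    def from_sim(cls, result: SimResult, frame: SlopeFrame | None = None) -> "Trajectory":
        a = result.arrays()
        return cls(
            t=a["t"], x=a["x"], y=a["y"], v=a["v"],
            heading=a["heading"], lean=a["lean"], frame=frame,
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {"t_s": self.t, "x_m": self.x, "y_m": self.y}
        if self.v is not None:
            data["v_mps"] = self.v
        if self.heading is not None:
            data["heading_deg"] = self.heading
        if self.lean is not None:
            data["lean_deg"] = self.lean
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame: SlopeFrame | None = None) -> "Trajectory":
        for col in ("t_s", "x_m", "y_m"):
            if col not in df.columns:
                raise ValueError(f"trajectory table missing required column {col!r}")
        return cls(
            t=df["t_s"].to_numpy(),
            x=df["x_m"].to_numpy(),
            y=df["y_m"].to_numpy(),
            v=df["v_mps"].to_numpy() if "v_mps" in df else None,
            heading=df["heading_deg"].to_numpy() if "heading_deg" in df else None,
            lean=df["lean_deg"].to_numpy() if "lean_deg" in df else None,
            frame=frame,
        )

    def resample(self, sample_rate: float) -> "Trajectory":
        """Linear-interpolation resampling onto a uniform time grid."""
        if sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        tq = np.arange(self.t[0], self.t[-1] + 1e-12, 1.0 / sample_rate)

        def interp(ch):
            return None if ch is None else np.interp(tq, self.t, ch)

        return Trajectory(
            t=tq, x=np.interp(tq, self.t, self.x), y=np.interp(tq, self.t, self.y),
            v=interp(self.v), heading=interp(self.heading), lean=interp(self.lean),
            frame=self.frame,
        )

    def reversed(self) -> "Trajectory":
        """The same geometric path traversed backward in time."""
        tr = self.t[-1] - self.t[::-1]

        def rev(ch):
            return None if ch is None else ch[::-1]

        return Trajectory(
            t=tr, x=self.x[::-1], y=self.y[::-1],
            v=rev(self.v), heading=rev(self.heading), lean=rev(self.lean),
            frame=self.frame,
        )


@dataclass(frozen=True)
class TurnSegment:
    """One inter-zero-crossing turn segment assigned to a gate.

    ``start``/``stop`` delimit the samples strictly inside
    ``[t_start, t_end]`` (``stop`` exclusive, usable as a slice).
    """

    gate_id: str
    start: int
    stop: int
    t_start: float
    t_end: float


@dataclass(frozen=True)
class GateTurnMetrics:
    gate_id: str
    L_s: float
    t_s: float
    d_min: float
    d_lev: float
    pattern: str
    mean_radius: float


@dataclass
class CurvatureProfile:
    """Per-sample curvature ``kappa`` (1/m) and radius ``R = 1/|kappa|`` (m)."""

    kappa: np.ndarray
    radius: np.ndarray
    window: int
    arc_length: np.ndarray = field(default=None)  # type: ignore[assignment]


def _lean_zero_crossings(t: np.ndarray, lean: np.ndarray) -> list[float]:
    """Interpolated times where the lean series changes sign."""
    crossings: list[float] = []
    sign = np.sign(lean)
    for i in range(len(lean) - 1):
        a, b = lean[i], lean[i + 1]
        if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]:
            f = a / (a - b)
            crossings.append(float(t[i] + f * (t[i + 1] - t[i])))
        elif sign[i] != 0 and sign[i + 1] == 0:
            crossings.append(float(t[i + 1]))
    return crossings


def _gate_level_time(t: np.ndarray, x: np.ndarray, gate_x: float) -> float | None:
    """Interpolated instant the downslope coordinate first equals ``gate_x``."""
    lev = x - gate_x
    for i in range(len(lev) - 1):
        if lev[i] == 0.0:
            return float(t[i])
        if lev[i] * lev[i + 1] < 0:
            f = lev[i] / (lev[i] - lev[i + 1])
            return float(t[i] + f * (t[i + 1] - t[i]))
    if lev[-1] == 0.0:
        return float(t[-1])
    return None


def segment_turns(
    traj: Trajectory,
    lean_series: np.ndarray | None = None,
    gates: list[Gate] | tuple[Gate, ...] = (),
) -> list[TurnSegment]:
    """Partition a run at the lean-angle zero-crossings and assign gates.

    Each gate is assigned the inter-crossing segment containing the
    instant its downslope level is crossed.  Gates whose level is never
    reached are logged and skipped (not fatal).
    """
    lean = traj.lean if lean_series is None else np.asarray(lean_series, dtype=float)
    if lean is None:
        raise ValueError("trajectory has no lean channel and no lean_series given")
    if lean.size != len(traj):
        raise ValueError("lean series must align with trajectory samples")

    bounds = [float(traj.t[0])] + _lean_zero_crossings(traj.t, lean) + [float(traj.t[-1])]
    bounds = sorted(set(bounds))
    segments: list[TurnSegment] = []
    for gate in gates:
        t_gate = _gate_level_time(traj.t, traj.x, gate.x)
        if t_gate is None:
            logger.warning("gate %s: downslope level never crossed; unassigned", gate.id)
            continue
        j = int(np.searchsorted(bounds, t_gate, side="right")) - 1
        j = min(max(j, 0), len(bounds) - 2)
        t0, t1 = bounds[j], bounds[j + 1]
        i0 = int(np.searchsorted(traj.t, t0, side="left"))
        i1 = int(np.searchsorted(traj.t, t1, side="right"))
        segments.append(TurnSegment(gate.id, i0, i1, t0, t1))
    return segments


def _segment_polyline(
    traj: Trajectory, seg: TurnSegment
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(t, x, y) over the segment with endpoints interpolated onto its bounds."""
    ts = [seg.t_start]
    xs = [float(np.interp(seg.t_start, traj.t, traj.x))]
    ys = [float(np.interp(seg.t_start, traj.t, traj.y))]
    for i in range(seg.start, seg.stop):
        if seg.t_start < traj.t[i] < seg.t_end:
            ts.append(float(traj.t[i]))
            xs.append(float(traj.x[i]))
            ys.append(float(traj.y[i]))
    ts.append(seg.t_end)
    xs.append(float(np.interp(seg.t_end, traj.t, traj.x)))
    ys.append(float(np.interp(seg.t_end, traj.t, traj.y)))
    return np.array(ts), np.array(xs), np.array(ys)


def gate_metrics(
    traj: Trajectory,
    gate: Gate,
    segment: TurnSegment,
    eps_t: float | None = None,
) -> GateTurnMetrics:
    """Per-gate spatial metrics over one turn segment.

    ``d_min`` is the continuous minimum over the segment polyline (point
    to line-segment distance), not the sample-only minimum, so it is
    stable under resampling.  ``eps_t`` is the tolerance of the "at the
    gate" pattern class; it defaults to half the median sampling
    interval.
    """
    ts, xs, ys = _segment_polyline(traj, segment)
    if ts.size < 2:
        raise ValueError(f"segment for gate {gate.id} is empty")
    if eps_t is None:
        eps_t = 0.5 * float(np.median(np.diff(traj.t)))

    t_gate = _gate_level_time(ts, xs, gate.x)
    if t_gate is None:
        raise ValueError(
            f"gate {gate.id}: downslope level x={gate.x} never crossed in its segment"
        )
    y_gate = float(np.interp(t_gate, ts, ys))
    d_lev = abs(y_gate - gate.y)

    # continuous minimum distance and its time
    px, py = xs - gate.x, ys - gate.y
    d_min = math.hypot(px[0], py[0])
    t_min = float(ts[0])
    for i in range(len(px) - 1):
        dx, dy = px[i + 1] - px[i], py[i + 1] - py[i]
        seg2 = dx * dx + dy * dy
        tpar = 0.0 if seg2 == 0 else min(max(-(px[i] * dx + py[i] * dy) / seg2, 0.0), 1.0)
        d = math.hypot(px[i] + tpar * dx, py[i] + tpar * dy)
        if d < d_min:
            d_min = d
            t_min = float(ts[i] + tpar * (ts[i + 1] - ts[i]))

    if t_min > t_gate + eps_t:
        pattern = PATTERN_AFTER
    elif t_min < t_gate - eps_t:
        pattern = PATTERN_BEFORE
    else:
        pattern = PATTERN_AT

    L_s = float(np.hypot(np.diff(xs), np.diff(ys)).sum())
    t_s = float(segment.t_end - segment.t_start)

    # mean turn radius over the segment samples (finite radii only)
    if xs.size >= 3:
        prof = curvature_profile(Trajectory(t=ts, x=xs, y=ys), window=3)
        finite = np.isfinite(prof.radius)
        mean_radius = float(prof.radius[finite].mean()) if finite.any() else math.inf
    else:
        mean_radius = math.inf

    return GateTurnMetrics(
        gate_id=gate.id,
        L_s=L_s,
        t_s=t_s,
        d_min=d_min,
        d_lev=d_lev,
        pattern=pattern,
        mean_radius=mean_radius,
    )


def curvature_profile(traj: Trajectory, window: int = 3) -> CurvatureProfile:
    """Sliding-window quadratic-fit curvature along the path.

    Within each centred window of ``window`` samples, ``x(s)`` and
    ``y(s)`` are fitted by least-squares quadratics in the cumulative
    chord arc length ``s``; the curvature at the window centre is

        kappa = |x' y'' - y' x''| / (x'^2 + y'^2)^(3/2)

    Endpoints reuse the nearest full window.  Consecutive duplicate
    points are dropped with a warning.  Radii with ``|kappa|`` below
    ``KAPPA_FLOOR`` are reported as infinite (straight running).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    x, y = traj.x, traj.y
    keep = np.ones(len(x), dtype=bool)
    keep[1:] = (np.diff(x) != 0) | (np.diff(y) != 0)
    if not keep.all():
        logger.warning("curvature_profile: dropped %d duplicate points", (~keep).sum())
        x, y = x[keep], y[keep]
    n = len(x)
    if n < window:
        raise ValueError(f"need at least window={window} distinct points, got {n}")

    s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
    half = window // 2
    kappa = np.empty(n)
    for i in range(n):
        lo = min(max(i - half, 0), n - window)
        sl = slice(lo, lo + window)
        sw = s[sl] - s[i]
        cx = np.polyfit(sw, x[sl], 2)
        cy = np.polyfit(sw, y[sl], 2)
        xp, xpp = cx[1], 2.0 * cx[0]
        yp, ypp = cy[1], 2.0 * cy[0]
        denom = (xp * xp + yp * yp) ** 1.5
        kappa[i] = abs(xp * ypp - yp * xpp) / denom if denom > 0 else 0.0

    with np.errstate(divide="ignore"):
        radius = np.where(np.abs(kappa) < KAPPA_FLOOR, np.inf, 1.0 / np.abs(kappa))
    return CurvatureProfile(kappa=kappa, radius=radius, window=window, arc_length=s)


def analyze_run(
    traj: Trajectory,
    gates: list[Gate] | tuple[Gate, ...],
    lean_series: np.ndarray | None = None,
    eps_t: float | None = None,
) -> pd.DataFrame:
    """Segment a run and tabulate per-gate metrics (Table-style columns)."""
    segments = segment_turns(traj, lean_series, gates)
    by_id = {g.id: g for g in gates}
    rows = []
    for seg in segments:
        m = gate_metrics(traj, by_id[seg.gate_id], seg, eps_t)
        rows.append(
            {
                "gate_id": m.gate_id,
                "L_s_m": m.L_s,
                "t_s_s": m.t_s,
                "d_min_m": m.d_min,
                "d_lev_m": m.d_lev,
                "pattern": m.pattern,
                "mean_radius_m": m.mean_radius,
            }
        )
    return pd.DataFrame(rows)
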