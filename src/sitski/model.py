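"""Physical parameters and pointwise carving-turn mechanics.

The athlete, the sit-ski bucket and the skis are treated as a single rigid
body whose centre of mass (COM) moves in the plane of a uniform incline.
During a carving turn the body leans toward the turn centre like an
inverted pendulum; the lean angle is the single control variable that,
together with speed, fixes the turn radius through the ideal-carving
constraint

    tan(phi1) = v**2 / (g * R_c * cos(alpha)) - tan(alpha) * cos(beta)

where ``phi1`` is the angle between the COM-to-inner-ski-edge line and the
slope normal, ``alpha`` the slope inclination and ``beta`` the trunk
inclination (0 when the trunk is not tracked separately).

All angles are degrees at the public interfaces and radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AthleteSystem",
    "Environment",
    "SlopeFrame",
    "ForceBreakdown",
    "air_density_from_site",
    "force_breakdown",
    "carving_lean_angle",
    "carving_radius",
    "classify_turn_regime",
    "REGIME_SIDE_SLIP",
    "REGIME_IDEAL",
    "REGIME_OVER_EDGED",
]

# ISA troposphere constants (barometric pressure profile + ideal gas law)
_P0 = 101325.0          # sea-level pressure, Pa
_T0 = 288.15            # sea-level temperature, K
_LAPSE = 0.0065         # temperature lapse rate, K/m
_G_ISA = 9.80665        # standard gravity, m/s^2
_R_DRY = 287.05         # specific gas constant of dry air, J/(kg K)
_ISA_EXPONENT = _G_ISA / (_R_DRY * _LAPSE)   # ~5.2559

REGIME_SIDE_SLIP = "side_slip"
REGIME_IDEAL = "ideal"
REGIME_OVER_EDGED = "over_edged"


@dataclass(frozen=True)
class AthleteSystem:
    """The unified rigid body: athlete + sit-ski + skis.

    Parameters
    ----------
    mass_total : float
        Combined mass of athlete, bucket and skis, kg.
    drag_area : float
        Drag-coefficient times frontal-area product ``C_d * s``, m^2,
        for the seated posture.
    lean_max : float
        Largest admissible lean angle, degrees.  Sit-ski frames limit
        edging well below the standing-skier range.
    com_height : float
        Distance from the ski edge to the COM along the trunk axis, m.
        Used only for reporting/plotting, not by the planar dynamics.
    """

    mass_total: float = 85.0
    drag_area: float = 0.30
    lean_max: float = 55.0
    com_height: float = 0.60

    def __post_init__(self) -> None:
        if self.mass_total <= 0:
            raise ValueError(f"mass_total must be positive, got {self.mass_total}")
        if self.drag_area < 0:
            raise ValueError(f"drag_area must be non-negative, got {self.drag_area}")
        if not 0 < self.lean_max < 90:
            raise ValueError(f"lean_max must be in (0, 90) deg, got {self.lean_max}")


@dataclass(frozen=True)
class Environment:
    """Ambient conditions on the course.

    Defaults are a mid-altitude winter race site: air density for
    ~1800 m at -10 degC and the hard-packed-snow friction coefficient
    0.2 from the alpine-skiing literature.
    """

    gravity: float = 9.8
    air_density: float = 1.0525
    friction_coeff: float = 0.2
    altitude: float | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        if self.gravity <= 0:
            raise ValueError(f"gravity must be positive, got {self.gravity}")
        if self.air_density <= 0:
            raise ValueError(f"air_density must be positive, got {self.air_density}")
        if not 0 <= self.friction_coeff < 1:
            raise ValueError(
                f"friction_coeff must be in [0, 1), got {self.friction_coeff}"
            )

    @classmethod
    def from_site(
        cls,
        altitude: float,
        temperature: float,
        gravity: float = 9.8,
        friction_coeff: float = 0.2,
    ) -> "Environment":
        """Build an environment with air density computed from the site."""
        rho = air_density_from_site(altitude, temperature)
        return cls(
            gravity=gravity,
            air_density=rho,
            friction_coeff=friction_coeff,
            altitude=altitude,
            temperature=temperature,
        )


@dataclass(frozen=True)
class SlopeFrame:
    """A uniform planar incline; ``slope_angle`` is its inclination in degrees."""

    slope_angle: float = 24.0

    def __post_init__(self) -> None:
        if not 0 <= self.slope_angle < 90:
            raise ValueError(
                f"slope_angle must be in [0, 90) deg, got {self.slope_angle}"
            )

    @property
    def slope_angle_rad(self) -> float:
        return math.radians(self.slope_angle)


@dataclass(frozen=True)
class ForceBreakdown:
    """Pointwise force magnitudes acting on the COM, all in newtons.

    ``equiv_gravity`` is the magnitude of the vector sum of the downslope
    gravity component and the centripetal force — the effective load the
    ski edge must support during the turn.
    """

    gravity_downslope: float
    drag: float
    friction: float
    centripetal: float
    normal: float
    equiv_gravity: float


def air_density_from_site(altitude: float, temperature: float) -> float:
    """Air density (kg/m^3) from site altitude (m) and temperature (degC).

    Pressure follows the ISA troposphere barometric formula; density then
    comes from the ideal gas law at the supplied local temperature.
    """
    if not 0 <= altitude <= 6000:
        raise ValueError(f"altitude must be in [0, 6000] m, got {altitude}")
    if not -90 <= temperature <= 60:
        raise ValueError(f"temperature must be in [-90, 60] degC, got {temperature}")
    pressure = _P0 * (1.0 - _LAPSE * altitude / _T0) ** _ISA_EXPONENT
    return pressure / (_R_DRY * (temperature + 273.15))


def force_breakdown(
    sys: AthleteSystem,
    env: Environment,
    frame: SlopeFrame,
    speed: float,
    turn_radius: float = math.inf,
    loaded_friction: bool = False,
) -> ForceBreakdown:
    """Evaluate every force term at one instant of a carving turn.

    Parameters
    ----------
    speed : float
        COM speed, m/s.
    turn_radius : float
        Carving radius, m; ``math.inf`` for straight running.
    loaded_friction : bool
        When True, friction uses the turn-loaded normal force
        ``mu * m * sqrt((g cos a)^2 + (v^2/R)^2)`` instead of the
        unloaded ``mu * m * g * cos a`` of the planar equations.
    """
    if speed < 0:
        raise ValueError(f"speed must be non-negative, got {speed}")
    if turn_radius <= 0:
        raise ValueError(f"turn_radius must be positive (or inf), got {turn_radius}")

    m = sys.mass_total
    g = env.gravity
    alpha = frame.slope_angle_rad
    g_down = m * g * math.sin(alpha)
    drag = 0.5 * sys.drag_area * env.air_density * speed**2
    normal = m * g * math.cos(alpha)
    centripetal = 0.0 if math.isinf(turn_radius) else m * speed**2 / turn_radius
    if loaded_friction:
        a_lat = 0.0 if math.isinf(turn_radius) else speed**2 / turn_radius
        friction = env.friction_coeff * m * math.hypot(g * math.cos(alpha), a_lat)
    else:
        friction = env.friction_coeff * normal
    equiv_gravity = math.hypot(g_down, centripetal)
    return ForceBreakdown(
        gravity_downslope=g_down,
        drag=drag,
        friction=friction,
        centripetal=centripetal,
        normal=normal,
        equiv_gravity=equiv_gravity,
    )


def carving_lean_angle(
    speed: float,
    turn_radius: float,
    slope_angle: float,
    body_incl: float = 0.0,
    gravity: float = 9.8,
) -> float:
    """Lean angle (deg) demanded by the ideal-carving constraint.

    A negative result means the balance point lies on the other side of
    the slope normal (lean toward the opposite side).
    """
    if turn_radius <= 0:
        raise ValueError(f"turn_radius must be positive, got {turn_radius}")
    if speed < 0:
        raise ValueError(f"speed must be non-negative, got {speed}")
    alpha = math.radians(slope_angle)
    beta = math.radians(body_incl)
    cos_a = math.cos(alpha)
    if abs(cos_a) < 1e-12:
        raise ValueError("slope_angle of 90 deg has no carving solution")
    tan_phi = speed**2 / (gravity * turn_radius * cos_a) - math.tan(alpha) * math.cos(beta)
    return math.degrees(math.atan(tan_phi))


def carving_radius(
    speed: float,
    lean_angle: float,
    slope_angle: float,
    body_incl: float = 0.0,
    gravity: float = 9.8,
) -> float:
    """Carving radius (m) from lean angle: the inverse constraint.

    Returns ``math.inf`` when no finite carving radius exists at this
    lean/slope combination (the caller treats this as straight running).
    """
    alpha = math.radians(slope_angle)
    beta = math.radians(body_incl)
    denom = math.tan(math.radians(lean_angle)) + math.tan(alpha) * math.cos(beta)
    if denom <= 0:
        return math.inf
    return speed**2 / (gravity * math.cos(alpha) * denom)


def classify_turn_regime(psi1: float, phi1: float, tol: float = 0.5) -> str:
    """Classify the edging regime from edge angle ``psi1`` vs lean ``phi1`` (deg).

    Under-edged skis slide sideways (no carve); over-edged skis carve but
    scrub speed through excess friction; the ideal turn has the edge
    matched to the lean and loses no speed.
    """
    for name, val in (("psi1", psi1), ("phi1", phi1)):
        if not -90 < val < 90:
            raise ValueError(f"{name} must be in (-90, 90) deg, got {val}")
    if psi1 < phi1 - tol:
        return REGIME_SIDE_SLIP
    if psi1 > phi1 + tol:
        return REGIME_OVER_EDGED
    return REGIME_IDEAL
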