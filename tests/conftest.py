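"""Shared fixtures: reference athlete/environment/course setups."""

from pathlib import Path

import pytest

import sitski as sk
from sitski import synth

FIXTURES = Path(__file__).resolve().parent.parent / "fixtures"


@pytest.fixture(scope="session")
def athlete() -> sk.AthleteSystem:
    return sk.AthleteSystem(mass_total=85.0, drag_area=0.30, lean_max=55.0)


@pytest.fixture(scope="session")
def environment() -> sk.Environment:
    return sk.Environment()  # rho 1.0525, mu 0.2, g 9.8


@pytest.fixture(scope="session")
def frame24() -> sk.SlopeFrame:
    return sk.SlopeFrame(24.0)


@pytest.fixture(scope="session")
def course3() -> sk.CourseGeometry:
    """Default synthetic three-gate course over the 69.7 m section."""
    return synth.make_course(synth.SynthSpec(seed=0))


@pytest.fixture(scope="session")
def straight_course() -> sk.CourseGeometry:
    """Gateless 69.7 m straight course from rest."""
    return sk.CourseGeometry(24.0, sk.StartSpec(0.0, 0.0, 0.0, 0.0), 69.7, ())


@pytest.fixture(scope="session")
def frictionless() -> tuple[sk.AthleteSystem, sk.Environment]:
    """Drag-free athlete and friction-free snow for closed-form oracles."""
    return sk.AthleteSystem(drag_area=0.0), sk.Environment(friction_coeff=0.0)


@pytest.fixture(scope="session")
def drone_csv() -> Path:
    return FIXTURES / "drone_validation.csv"
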