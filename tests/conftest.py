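"""Shared fixtures: baseline configuration and expensive session-scope runs."""

import numpy as np
import pytest

from vesseladapt.cli_io import RunConfig, StudySpec, run_study
from vesseladapt.vessel_model import (
    build_section,
    calibrate_fiber_angle,
    homeostasis_solve,
)


@pytest.fixture(scope="session")
def baseline() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def vessel_inputs(baseline):
    """(geom, materials, composition, remodeling) tuple from the baseline."""
    return (
        baseline.geometry,
        {lay: baseline.materials(lay) for lay in ("media", "adventitia")},
        {lay: baseline.composition(lay) for lay in ("media", "adventitia")},
        baseline.remodeling,
    )


@pytest.fixture(scope="session")
def gamma_cal(vessel_inputs) -> float:
    """Fiber angle calibrated to the 23 mm homeostatic inner diameter."""
    geom, mats, comp, rem = vessel_inputs
    return calibrate_fiber_angle(geom, mats, comp, rem, target_diameter=23.0)


@pytest.fixture(scope="session")
def homeostatic_section(vessel_inputs, gamma_cal):
    geom, mats, comp, rem = vessel_inputs
    sec = build_section(geom, mats, comp, 4, gamma_deg=gamma_cal)
    homeostasis_solve(sec, geom, rem)
    return sec


@pytest.fixture(scope="session")
def study1_results(baseline, gamma_cal):
    """Full collagen net-growth study at the calibrated fiber angle.

    Twelve quasi-1D runs (4 kinematics x 3 beta); the heavyweight fixture
    behind the whole-run acceptance checks.
    """
    cfg = baseline.replace(fibers={"gamma_deg": gamma_cal})
    records, summary = run_study(StudySpec(study="study1"), cfg)
    return records, summary


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
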