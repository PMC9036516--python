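"""Shared fixtures: solved bulk water (session-scoped, it is the expensive
common dependency) and coarse 3D solutions reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from ecrism.closures import ClosureSpec
from ecrism.driver import ECRISMConfig, solvate_once
from ecrism.fixtures import make_fixture
from ecrism.forcefield import ThermoState, get_water_model
from ecrism.rism1d import RadialGrid, solve_drism, susceptibility


@pytest.fixture(scope="session")
def thermo():
    return ThermoState()


@pytest.fixture(scope="session")
def water_cspce():
    return get_water_model("cSPC/E")


@pytest.fixture(scope="session")
def bulk_kh(water_cspce, thermo):
    return solve_drism(water_cspce, thermo, RadialGrid(), ClosureSpec("KH"))


@pytest.fixture(scope="session")
def bulk_pse3(water_cspce, thermo):
    return solve_drism(water_cspce, thermo, RadialGrid(), ClosureSpec("PSE", 3))


@pytest.fixture(scope="session")
def sus_kh(bulk_kh):
    return susceptibility(bulk_kh)


@pytest.fixture(scope="session")
def sus_pse3(bulk_pse3):
    return susceptibility(bulk_pse3)


@pytest.fixture(scope="session")
def lj_fixture():
    return make_fixture("lj_sphere")


@pytest.fixture(scope="session")
def dipolar_fixture():
    return make_fixture("dipolar_diatomic")


@pytest.fixture(scope="session")
def coarse_config():
    """Cheap but converged 3D settings reused across the suite."""
    return ECRISMConfig(
        buffer=8.0, spacing=0.5, closure="PSE-3", water_model="cSPC/E", rism_tol=1e-7
    )


@pytest.fixture(scope="session")
def lj_solution(lj_fixture, coarse_config, sus_pse3):
    return solvate_once(lj_fixture.solute, coarse_config, sus_pse3)


@pytest.fixture(scope="session")
def dipolar_solution(dipolar_fixture, coarse_config, sus_pse3):
    return solvate_once(dipolar_fixture.solute, coarse_config, sus_pse3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
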