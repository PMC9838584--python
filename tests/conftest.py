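"""Shared fixtures: default parameter sets and coarse FEM solutions.

The finite-element solves are expensive, so the baseline (no-closure)
and half-closed scenarios are computed once per session on the coarsest
mesh and shared across test modules.
"""

import pytest
from hypothesis import settings, HealthCheck

from ahflow.fem_solver import (BoundaryConditions, NumericsConfig,
                               solve_flow_temperature)
from ahflow.geometry_mesh import GeometryParams, build_geometry, generate_mesh
from ahflow.materials import (ClosureScenario, FluidProperties,
                              default_cb_params, default_tm_params)

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geometry():
    return GeometryParams()


@pytest.fixture(scope="session")
def geo_spec(geometry):
    return build_geometry(geometry)


@pytest.fixture(scope="session")
def coarse_mesh(geo_spec):
    """Coarsest test mesh (resolution level 0)."""
    return generate_mesh(geo_spec, 0)


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def porous():
    return {"TM": default_tm_params(), "CB": default_cb_params()}


@pytest.fixture(scope="session")
def bcs():
    return BoundaryConditions()


@pytest.fixture(scope="session")
def numerics():
    return NumericsConfig()


@pytest.fixture(scope="session")
def baseline_solution(coarse_mesh, fluid, porous, bcs, numerics):
    """Converged no-closure solution on the coarse mesh."""
    sol = solve_flow_temperature(coarse_mesh, fluid, porous,
                                 ClosureScenario(), bcs, numerics)
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def isothermal_solution(coarse_mesh, fluid, porous, numerics):
    """Gravity on but no temperature gradient: hydrostatics without
    buoyancy, isolating the convective contribution by difference."""
    bcs_iso = BoundaryConditions(T_cornea=310.15, T_interior=310.15)
    sol = solve_flow_temperature(coarse_mesh, fluid, porous,
                                 ClosureScenario(), bcs_iso, numerics)
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def half_closed_scenario():
    return ClosureScenario(extent_deg=45.0, reduction_factor=10.0)


@pytest.fixture(scope="session")
def half_closed_solution(coarse_mesh, fluid, porous, bcs, numerics,
                         half_closed_scenario):
    """Half the circumference closed with a tenfold facility reduction."""
    sol = solve_flow_temperature(coarse_mesh, fluid, porous,
                                 half_closed_scenario, bcs, numerics)
    assert sol.converged
    return sol
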