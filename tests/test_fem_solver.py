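"""Coupled Stokes--Brinkman/temperature solver: physics and invariants.

The expensive converged solutions (open angle; half circumference
closed at tenfold facility reduction) come from session fixtures on the
coarsest mesh; the tests here probe conservation, symmetry, the
buoyancy vortex, and the insensitivity checks that justify the
numerical regularizations.
"""

import numpy as np
import pytest
from dataclasses import replace

from ahflow.fem_solver import (extract_iop, outflow_partition,
                               region_peak_speeds, reynolds_number,
                               sector_velocity_stats, solve_flow_temperature)
from ahflow.geometry_mesh import (REGION_AC, REGION_TM, TAG_CB_OUTLET,
                                  TAG_CC_OUTLET, TAG_WALL)
from ahflow.materials import ClosureScenario


def upper_dome_peak_speed(sol, mesh):
    """Peak speed in the upper half of the chamber, away from the
    inflow floor: nonzero essentially only when convection stirs it."""
    ac_nodes = np.unique(mesh.cells[mesh.region_tags == REGION_AC])
    z = mesh.nodes[ac_nodes, 2]
    sel = ac_nodes[z > 0.5 * mesh.spec.params.ac_depth]
    return float(np.linalg.norm(sol.velocity[sel], axis=1).max())


class TestBaselineSolution:
    def test_converged_with_closed_mass_balance(self, baseline_solution):
        sol = baseline_solution
        assert sol.converged
        assert sol.mass_residual < 0.01
        assert sol.outflow_tm_fraction + sol.outflow_cb_fraction == \
            pytest.approx(1.0, abs=max(sol.mass_residual, 1e-6) * 2)

    def test_iop_above_outlet_pressure(self, baseline_solution, bcs):
        assert baseline_solution.iop > bcs.outlet_pressure

    def test_both_outflow_pathways_carry_flow(self, baseline_solution,
                                              coarse_mesh):
        tm, cb = outflow_partition(baseline_solution, coarse_mesh)
        assert tm > 0.1 and cb > 0.1

    def test_buoyancy_vortex_dominates_chamber_flow(self, baseline_solution,
                                                    coarse_mesh, bcs):
        """With the 35/37 C gradient a convective vortex stirs the whole
        chamber; its speed far exceeds the mean pumping speed."""
        peaks = region_peak_speeds(baseline_solution, coarse_mesh)
        # mean pumping speed: inflow rate over the mid-chamber cross-section
        area = np.pi * (coarse_mesh.spec.r_angle ** 2) / 4.0
        pumping = (bcs.inflow_rate / 4.0) / area
        assert peaks["AC"] > 50.0 * pumping
        assert upper_dome_peak_speed(baseline_solution, coarse_mesh) > \
            10.0 * pumping

    def test_region_speeds_are_ordered_like_the_physics(
            self, baseline_solution, coarse_mesh):
        peaks = region_peak_speeds(baseline_solution, coarse_mesh)
        # conduits fastest, then the vortex, then the porous tissues
        assert peaks["CC"] > peaks["AC"] > peaks["TM"] > peaks["CB"]

    def test_axisymmetry_of_tm_face_speed_at_zero_closure(
            self, baseline_solution, coarse_mesh):
        """Azimuthal coefficient of variation of the outward TM-face
        speed < 5% away from the collector channels."""
        from ahflow.geometry_mesh import REGION_TM
        mesh = coarse_mesh
        faces, owners = mesh.interface_faces(REGION_AC, REGION_TM)
        x = mesh.nodes[faces]
        cr = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
        areas = 0.5 * np.linalg.norm(cr, axis=1)
        normals = cr / (2 * areas)[:, None]
        cents = x.mean(axis=1)
        away = cents - mesh.cell_centroids()[owners]
        normals[np.einsum("fd,fd->f", normals, away) < 0] *= -1
        un = np.einsum("fnd,fd->f",
                       baseline_solution.velocity[faces], normals) / 3.0
        az = np.degrees(np.arctan2(cents[:, 1], cents[:, 0]))
        cc_az = np.degrees(mesh.spec.cc_centers_rad)
        far = np.min(np.abs(az[:, None] - cc_az[None, :]), axis=1) > 2.0
        # area-weighted speeds per azimuthal bin
        bins = np.linspace(0.0, 90.0, 13)
        means = []
        for lo, hi in zip(bins[:-1], bins[1:]):
            sel = far & (az >= lo) & (az < hi)
            if np.any(sel):
                means.append((un[sel] * areas[sel]).sum() / areas[sel].sum())
        means = np.asarray(means)
        assert means.std() / means.mean() < 0.05

    def test_inflow_iop_agrees_with_chamber_average(self, baseline_solution,
                                                    coarse_mesh):
        """Darcy resistance dominates, so the chamber is nearly
        isobaric: the volume-averaged AC pressure matches the
        inflow-face average within 1%."""
        sel = coarse_mesh.region_tags == REGION_AC
        vols = coarse_mesh.cell_volumes()[sel]
        p_cell = baseline_solution.pressure[
            coarse_mesh.cells[sel]].mean(axis=1)
        vol_avg = float((p_cell * vols).sum() / vols.sum())
        assert vol_avg == pytest.approx(baseline_solution.iop, rel=0.01)

    def test_reynolds_number_is_creeping_flow(self, baseline_solution,
                                              coarse_mesh, fluid):
        re = reynolds_number(baseline_solution, fluid, coarse_mesh)
        assert 0.0 < re < 1.0


class TestExtractIop:
    def test_uniform_pressure_field_returns_constant(self, coarse_mesh):
        c = 1234.5
        assert extract_iop(np.full(coarse_mesh.n_nodes, c), coarse_mesh) \
            == pytest.approx(c, rel=1e-12)


class TestClosureResponse:
    def test_closure_raises_iop(self, baseline_solution,
                                half_closed_solution):
        assert half_closed_solution.iop > baseline_solution.iop

    def test_sector_speed_ratio_tracks_reduction_factor(
            self, half_closed_solution, coarse_mesh, half_closed_scenario):
        stats = sector_velocity_stats(half_closed_solution, coarse_mesh,
                                      half_closed_scenario)
        ratio = stats["open"] / stats["closed"]
        assert ratio == pytest.approx(10.0, rel=0.15)

    def test_sector_stats_degenerate_arcs(self, baseline_solution,
                                          coarse_mesh):
        # zero extent: no closed arc to report
        s0 = sector_velocity_stats(baseline_solution, coarse_mesh,
                                   ClosureScenario())
        assert s0["closed"] is None and s0["open"] > 0.0
        # full closure grouping: no open arc; closed arc equals the
        # whole-circumference mean
        s90 = sector_velocity_stats(
            baseline_solution, coarse_mesh,
            ClosureScenario(extent_deg=90.0, reduction_factor=2.0))
        assert s90["open"] is None
        assert s90["closed"] == pytest.approx(s0["open"], rel=1e-9)


class TestModelingChoicesAreInert:
    """Regularizations and auxiliary physics must not drive the IOP."""

    def test_isothermal_flow_has_no_vortex(self, coarse_mesh,
                                           isothermal_solution,
                                           baseline_solution):
        stirred = upper_dome_peak_speed(baseline_solution, coarse_mesh)
        quiet = upper_dome_peak_speed(isothermal_solution, coarse_mesh)
        assert quiet < 0.2 * stirred

    def test_buoyancy_decouples_from_iop(self, isothermal_solution,
                                         baseline_solution):
        """Switching the 35/37 C gradient on changes the chamber flow
        pattern completely but the IOP by far less than 1%: buoyancy
        stresses are ~1e-2 Pa against ~1e3 Pa Darcy drops.  (Toggling
        gravity altogether would additionally shift the hydrostatic
        datum between the measurement plane and the outlets, which is a
        convention, not outflow physics.)"""
        assert abs(isothermal_solution.iop - baseline_solution.iop) \
            / baseline_solution.iop < 0.01

    def test_porous_viscosity_epsilon_is_inert(self, coarse_mesh, fluid,
                                               porous, bcs, baseline_solution,
                                               numerics):
        half_eps = replace(numerics,
                           porous_viscosity_epsilon=numerics
                           .porous_viscosity_epsilon / 2.0)
        sol = solve_flow_temperature(coarse_mesh, fluid, porous,
                                     ClosureScenario(), bcs, half_eps)
        assert sol.converged
        assert sol.mass_residual < 0.01
        assert abs(sol.iop - baseline_solution.iop) \
            / baseline_solution.iop < 0.01


class TestHardErrors:
    def test_mesh_without_outlets_is_rejected(self, coarse_mesh, fluid,
                                              porous, bcs, numerics):
        from ahflow.geometry_mesh import MeshModel
        tags = coarse_mesh.boundary_tags.copy()
        tags[np.isin(tags, (TAG_CC_OUTLET, TAG_CB_OUTLET))] = TAG_WALL
        sealed = MeshModel(coarse_mesh.nodes, coarse_mesh.cells,
                           coarse_mesh.region_tags,
                           coarse_mesh.boundary_faces, tags,
                           coarse_mesh.boundary_owner,
                           coarse_mesh.resolution_level, coarse_mesh.spec)
        with pytest.raises(ValueError, match="outlet"):
            solve_flow_temperature(sealed, fluid, porous,
                                   ClosureScenario(), bcs, numerics)
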