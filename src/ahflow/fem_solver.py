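"""Unified Stokes--Brinkman flow with buoyancy and temperature transport.

A single momentum/continuity system covers the whole tagged mesh:

    -div(2 mu_K eps(u)) + k_K u + grad p = f_K,     div u = 0,

with cellwise coefficients switching between the open (Stokes) regions
(AC, SC, CC: ``mu_K = mu``, ``k_K = 0``, Boussinesq body force
``f = rho0 g (1 - gamma (T - T_ref))``) and the porous (Darcy) regions
(TM, CB: drag ``k_K = 1/mobility(p) = (1 + beta p)/alpha_eff``, body
force off).  A vanishing viscosity is ill-posed in an H1-conforming
velocity space, so the porous viscosity is retained at
``epsilon * mu`` (Brinkman regularization, epsilon = 1e-3 by default);
its influence on IOP is negligible and checked in the test suite.
Velocity is continuous across the Stokes--Darcy interfaces because a
single continuous velocity space is used; pressure continuity is the
natural interface condition of the weak form.

Discretization: equal-order P1/P1 on tetrahedra with PSPG pressure
stabilization.  The stabilization term is residual-based
(``tau (k u + grad p - f) . grad q`` elementwise; the P1 viscous residual
vanishes), so it is consistent in both the Stokes and the Darcy limit
and introduces no artificial porous transmissivity.  Summing the
continuity rows shows the discrete boundary flux balance
``int_bdry u.n = 0`` holds exactly, so global mass conservation is
limited only by the linear-solver tolerance.

Temperature obeys steady convection--diffusion
``rho cp u . grad T = k lap T`` with Dirichlet values on the cornea
(cooled) and all other exterior surfaces (body temperature); at the
grid Peclet numbers of these flows (<< 1) no upwinding is required.

The nonlinearity (pressure-dependent drag, buoyancy <-> advection) is
resolved by Picard iteration (optionally under-relaxed), initialized
from the lumped 0D model and converged on the IOP and the peak chamber
speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ahflow import lumped_model
from ahflow.geometry_mesh import (
    MeshModel, REGION_AC, REGION_TM, REGION_CB,
    TAG_INFLOW, TAG_CORNEA, TAG_IRIS, TAG_LENS, TAG_CC_OUTLET,
    TAG_CB_OUTLET, TAG_SYMMETRY_X, TAG_SYMMETRY_Y, TAG_WALL,
)
from ahflow.materials import ClosureScenario, FluidProperties, PorousRegionParams


@dataclass
class BoundaryConditions:
    """Flow and temperature boundary data (SI).

    ``inflow_rate`` is the full-eye aqueous production; one quarter of
    it enters the quarter model through the iris--lens slit as a uniform
    normal velocity.  Outlets (collector channels and ciliary body face)
    carry the episcleral venous pressure as a normal traction.
    """

    inflow_rate: float = 3.0e-9 / 60.0    # m^3/s, full eye (3 uL/min)
    outlet_pressure: float = 933.254      # Pa (7 mmHg)
    T_cornea: float = 308.15              # K (35 C)
    T_interior: float = 310.15            # K (37 C)

    def __post_init__(self):
        if self.inflow_rate <= 0:
            raise ValueError("inflow_rate must be positive")
        if self.outlet_pressure <= 0:
            raise ValueError("outlet_pressure must be positive")
        if self.T_interior < self.T_cornea:
            raise ValueError("T_interior must be >= T_cornea")


@dataclass
class NumericsConfig:
    """Iteration and stabilization knobs of the nonlinear solver."""

    picard_tol: float = 0.1               # Pa, on successive IOP change
    max_picard_iters: int = 50
    under_relaxation: float = 1.0
    porous_viscosity_epsilon: float = 1e-3
    stab_delta: float = 0.1               # PSPG coefficient
    speed_rtol: float = 0.02              # relative tol on peak AC speed
    verbose: bool = False

    def __post_init__(self):
        if self.picard_tol <= 0:
            raise ValueError("picard_tol must be positive")
        if not (0.0 < self.under_relaxation <= 1.0):
            raise ValueError("under_relaxation must be in (0, 1]")


@dataclass
class FlowSolution:
    """Converged fields and scalar diagnostics of one scenario."""

    velocity: np.ndarray       # (N, 3), m/s
    pressure: np.ndarray       # (N,), Pa
    temperature: np.ndarray    # (N,), K
    iop: float                 # Pa
    outflow_tm_fraction: float
    outflow_cb_fraction: float
    mass_residual: float       # |in - out| / in
    converged: bool
    iterations: int
    history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# precomputed FEM workspace
# ---------------------------------------------------------------------------

class _Workspace:
    """Element geometry, index maps and constant matrix blocks."""

    def __init__(self, mesh: MeshModel):
        self.mesh = mesh
        cells = mesh.cells
        x = mesh.nodes[cells]                          # (M, 4, 3)
        e = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0],
                      x[:, 3] - x[:, 0]], axis=1)      # (M, 3, 3)
        vol = np.abs(np.linalg.det(e)) / 6.0
        inv = np.linalg.inv(e)                         # rows: d(xi)/dx
        g = np.empty((cells.shape[0], 4, 3))
        g[:, 1:, :] = np.transpose(inv, (0, 2, 1))
        g[:, 0, :] = -g[:, 1:, :].sum(axis=1)          # sum of gradients = 0
        self.vol = vol
        self.grad = g                                  # (M, 4, 3)
        self.gg = np.einsum("mad,mbd->mab", g, g)      # (M, 4, 4)
        self.h2 = (6.0 * np.sqrt(2.0) * vol) ** (2.0 / 3.0)
        n = mesh.n_nodes
        self.n_nodes = n
        self.nu = 3 * n                                # velocity dofs
        self.ndof = 4 * n

        # ---- index arrays ------------------------------------------------
        M = cells.shape[0]
        # velocity-velocity block (a,b,i,j)
        rows = (3 * cells[:, :, None, None, None]
                + np.zeros((1, 1, 4, 3, 3), dtype=np.int64)
                + np.arange(3)[None, None, None, :, None])
        cols = (3 * cells[:, None, :, None, None]
                + np.zeros((1, 4, 1, 3, 3), dtype=np.int64)
                + np.arange(3)[None, None, None, None, :])
        self.vv_rows = rows.ravel()
        self.vv_cols = cols.ravel()
        # velocity-pressure block: momentum row (a,i), pressure col b
        r_up = (3 * cells[:, :, None, None] + np.arange(3)[None, None, None, :]
                + np.zeros((1, 1, 4, 1), dtype=np.int64))
        c_up = (self.nu + cells[:, None, :, None]
                + np.zeros((1, 4, 1, 3), dtype=np.int64))
        self.up_rows = np.transpose(r_up, (0, 1, 3, 2)).ravel()
        self.up_cols = np.transpose(c_up, (0, 1, 3, 2)).ravel()
        # continuity row a, velocity col (b,j)
        r_pu = (cells[:, :, None, None] + np.zeros((1, 1, 4, 3), dtype=np.int64))
        c_pu = (3 * cells[:, None, :, None]
                + np.arange(3)[None, None, None, :]
                + np.zeros((1, 4, 1, 1), dtype=np.int64))
        self.pu_rows = r_pu.ravel()
        self.pu_cols = c_pu.ravel()
        # pressure-pressure block
        self.pp_rows = (cells[:, :, None]
                        + np.zeros((1, 1, 4), dtype=np.int64)).ravel()
        self.pp_cols = (cells[:, None, :]
                        + np.zeros((1, 4, 1), dtype=np.int64)).ravel()

        # ---- constant element data ----------------------------------------
        # viscous: mu (gg delta_ij + g_aj g_bi) V  -> mu factored per cell
        eye = np.eye(3)
        self.visc_data = (self.gg[:, :, :, None, None] * eye[None, None, None]
                          + np.einsum("maj,mbi->mabij", g, g)
                          ) * vol[:, None, None, None, None]
        m4 = (np.ones((4, 4)) + np.eye(4)) / 20.0      # P1 tet mass
        self.mass_data = (m4[None, :, :, None, None] * eye[None, None, None]
                          * vol[:, None, None, None, None])
        # -int p div v : -(g_a)_i V/4 at (row (a,i), col b)
        d = -(g[:, :, None, :] * (vol[:, None, None, None] / 4.0)
              + np.zeros((1, 1, 4, 1)))
        self.up_data = np.transpose(d, (0, 1, 3, 2)).ravel()
        # int q div u : (g_b)_j V/4 at (row a, col (b,j))
        self.pu_div_data = (np.zeros((M, 4, 1, 1)) +
                            g[:, None, :, :] * (vol[:, None, None, None] / 4.0)
                            ).ravel()
        # PSPG drag coupling pattern: (g_a)_j V/4 at (row a, col (b,j))
        self.pu_pspg_geom = (g[:, :, None, :] * (vol[:, None, None, None] / 4.0)
                             + np.zeros((1, 1, 4, 1)))

        self.region = mesh.region_tags
        self.stokes_cell = ~mesh.porous_cell_mask()

        # ---- boundary facet data ------------------------------------------
        areas, normals, cents = mesh.boundary_face_geometry()
        self.b_areas, self.b_normals = areas, normals
        self.tags = mesh.boundary_tags

    def facet_flux(self, u: np.ndarray, tag: int) -> float:
        """Outward volumetric flux of a P1 field through tagged facets."""
        sel = self.tags == tag
        faces = self.mesh.boundary_faces[sel]
        un = np.einsum("fnd,fd->f", u[faces], self.b_normals[sel]) / 3.0
        return float((un * self.b_areas[sel]).sum())


def _dirichlet_sets(ws: _Workspace, bcs: BoundaryConditions):
    """Velocity/temperature Dirichlet dof lists and values.

    Solid surfaces of the open (Stokes) regions are no-slip.  Exterior
    surfaces of the porous tissues are impermeable but not no-slip: a
    Darcy medium admits tangential slip at its boundary, so only the
    normal velocity component is constrained there (those walls are
    horizontal by construction, so the constraint is on u_z).
    """
    mesh = ws.mesh
    wall_sel = ws.tags == TAG_WALL
    porous_owner = ~ws.stokes_cell[mesh.boundary_owner]
    horizontal = np.abs(ws.b_normals[:, 2]) > 0.99
    porous_wall = wall_sel & porous_owner & horizontal
    stokes_wall = wall_sel & ~porous_wall
    noslip = np.unique(np.concatenate(
        [mesh.boundary_nodes(t) for t in (TAG_IRIS, TAG_LENS, TAG_CORNEA)]
        + [np.unique(mesh.boundary_faces[stokes_wall])]))
    impermeable = np.setdiff1d(
        np.unique(mesh.boundary_faces[porous_wall]), noslip)
    inflow_all = mesh.boundary_nodes(TAG_INFLOW)
    inflow = np.setdiff1d(inflow_all, noslip)
    if inflow.size == 0:
        # slit one cell wide: fall back to driving every slit node
        inflow = inflow_all
        noslip = np.setdiff1d(noslip, inflow_all)
    sym_x = np.setdiff1d(mesh.boundary_nodes(TAG_SYMMETRY_X), noslip)
    sym_y = np.setdiff1d(mesh.boundary_nodes(TAG_SYMMETRY_Y), noslip)

    # scale the inflow plateau so the discrete flux equals Q/4 exactly
    probe = np.zeros((ws.n_nodes, 3))
    probe[inflow, 2] = 1.0
    f1 = ws.facet_flux(probe, TAG_INFLOW)
    v_in = -(bcs.inflow_rate / 4.0) / f1     # f1 is negative: inward flow

    vdofs, vvals = [], []
    for n_ in noslip:
        vdofs += [3 * n_, 3 * n_ + 1, 3 * n_ + 2]
        vvals += [0.0, 0.0, 0.0]
    for n_ in inflow:
        vdofs += [3 * n_, 3 * n_ + 1, 3 * n_ + 2]
        vvals += [0.0, 0.0, v_in]
    fixed = set(vdofs)
    for n_ in impermeable:
        if 3 * n_ + 2 not in fixed:
            vdofs.append(3 * n_ + 2)
            vvals.append(0.0)
            fixed.add(3 * n_ + 2)
    for n_ in sym_x:
        if 3 * n_ not in fixed:
            vdofs.append(3 * n_)
            vvals.append(0.0)
    for n_ in sym_y:
        if 3 * n_ + 1 not in fixed:
            vdofs.append(3 * n_ + 1)
            vvals.append(0.0)
    vdofs = np.asarray(vdofs, dtype=np.int64)
    vvals = np.asarray(vvals)

    # temperature: interior surfaces at body temperature, cornea cooled
    t_nodes = {}
    for t in (TAG_INFLOW, TAG_IRIS, TAG_LENS, TAG_WALL,
              TAG_CC_OUTLET, TAG_CB_OUTLET):
        for n_ in ws.mesh.boundary_nodes(t):
            t_nodes[n_] = bcs.T_interior
    for n_ in ws.mesh.boundary_nodes(TAG_CORNEA):
        t_nodes[n_] = bcs.T_cornea
    t_idx = np.fromiter(t_nodes.keys(), dtype=np.int64)
    t_val = np.fromiter(t_nodes.values(), dtype=float)
    return vdofs, vvals, t_idx, t_val, v_in


def _apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, dofs, vals):
    """Replace rows of A by identity rows at Dirichlet dofs."""
    A = A.tocsr()
    row_is_dir = np.zeros(A.shape[0], dtype=bool)
    row_is_dir[dofs] = True
    A.data[np.repeat(row_is_dir, np.diff(A.indptr))] = 0.0
    diag = sp.coo_matrix((np.ones(len(dofs)), (dofs, dofs)), shape=A.shape)
    A = (A + diag.tocsr()).tocsc()
    b = b.copy()
    b[dofs] = vals
    return A, b


def _solve_temperature(ws: _Workspace, fluid: FluidProperties, u,
                       t_idx, t_val):
    mesh = ws.mesh
    cells = mesh.cells
    vol, g = ws.vol, ws.grad
    # diffusion
    diff = (fluid.k_thermal * ws.gg * vol[:, None, None]).ravel()
    # advection with cell-mean velocity
    u_cell = u[cells].mean(axis=1)                     # (M, 3)
    ug = np.einsum("md,mbd->mb", u_cell, g)            # (M, 4)
    adv = (fluid.rho0 * fluid.cp * ug[:, None, :]
           * (vol[:, None, None] / 4.0)
           + np.zeros((1, 4, 1))).ravel()
    A = sp.coo_matrix((diff + adv, (ws.pp_rows, ws.pp_cols)),
                      shape=(ws.n_nodes, ws.n_nodes)).tocsr()
    b = np.zeros(ws.n_nodes)
    A, b = _apply_dirichlet(A, b, t_idx, t_val)
    return spla.spsolve(A, b)


def _assemble_flow_matrix(ws: _Workspace, mu_cell, k_cell, tau):
    """Flow system matrix for a frozen drag field (CSR)."""
    vol = ws.vol
    vv = (ws.visc_data * mu_cell[:, None, None, None, None]
          + ws.mass_data * k_cell[:, None, None, None, None]).ravel()
    pu = (ws.pu_div_data
          + (ws.pu_pspg_geom * (tau * k_cell)[:, None, None, None]).ravel())
    ppdata = (ws.gg * (tau * vol)[:, None, None]).ravel()
    return sp.coo_matrix(
        (np.concatenate([vv, ws.up_data, pu, ppdata]),
         (np.concatenate([ws.vv_rows, ws.up_rows, ws.pu_rows + ws.nu,
                          ws.pp_rows + ws.nu]),
          np.concatenate([ws.vv_cols, ws.up_cols, ws.pu_cols,
                          ws.pp_cols + ws.nu]))),
        shape=(ws.ndof, ws.ndof)).tocsr()


def _assemble_flow_rhs(ws: _Workspace, f_cell, tau,
                       bcs: BoundaryConditions):
    """Load vector: body force, its PSPG image, outlet tractions."""
    vol, g = ws.vol, ws.grad
    rhs = np.zeros(ws.ndof)
    mom = (f_cell[:, None, :] * (vol[:, None, None] / 4.0)
           + np.zeros((1, 4, 1)))
    np.add.at(rhs, (3 * ws.mesh.cells[:, :, None]
                    + np.arange(3)[None, None, :]).ravel(), mom.ravel())
    pspg_rhs = np.einsum("md,mad->ma", f_cell, g) * (tau * vol)[:, None]
    np.add.at(rhs, ws.nu + ws.mesh.cells.ravel(), pspg_rhs.ravel())
    for tag in (TAG_CC_OUTLET, TAG_CB_OUTLET):
        sel = ws.tags == tag
        faces = ws.mesh.boundary_faces[sel]
        load = (-bcs.outlet_pressure * ws.b_areas[sel] / 3.0)[:, None] \
            * ws.b_normals[sel]
        idx = (3 * faces[:, :, None] + np.arange(3)[None, None, :]).ravel()
        np.add.at(rhs, idx, np.repeat(load[:, None, :], 3, axis=1).ravel())
    return rhs


def extract_iop(sol_or_p, mesh: MeshModel) -> float:
    """Area-averaged pressure over the inflow boundary, Pa."""
    p = sol_or_p.pressure if isinstance(sol_or_p, FlowSolution) else sol_or_p
    sel = mesh.boundary_tags == TAG_INFLOW
    areas, _, _ = mesh.boundary_face_geometry()
    a = areas[sel]
    pf = p[mesh.boundary_faces[sel]].mean(axis=1)
    return float((pf * a).sum() / a.sum())


def solve_flow_temperature(mesh: MeshModel, fluid: FluidProperties,
                           porous: dict, scenario: ClosureScenario,
                           bcs: BoundaryConditions,
                           num: NumericsConfig | None = None,
                           initial: FlowSolution | None = None,
                           p_init: float | None = None) -> FlowSolution:
    """Solve the coupled flow/temperature problem on a tagged mesh.

    ``porous`` maps region names ("TM", "CB") to
    :class:`~ahflow.materials.PorousRegionParams`.  ``initial`` warm
    starts the Picard iteration from a previously converged solution on
    the same mesh, and ``p_init`` overrides the initial uniform pressure
    guess for the drag field (both useful in scenario sweeps).  Returns
    a :class:`FlowSolution`; non-convergence is flagged, not raised.
    """
    num = num or NumericsConfig()
    ws = _Workspace(mesh)
    if not (np.any(ws.tags == TAG_CC_OUTLET) or np.any(ws.tags == TAG_CB_OUTLET)):
        raise ValueError("mesh has no outlet boundary; system is singular")
    vdofs, vvals, t_idx, t_val, v_in = _dirichlet_sets(ws, bcs)

    region = ws.region
    tm_p: PorousRegionParams = porous["TM"]
    cb_p: PorousRegionParams = porous["CB"]
    # effective alpha with the closure mask
    alpha = np.zeros(mesh.n_cells)
    beta = np.zeros(mesh.n_cells)
    alpha[region == REGION_TM] = tm_p.alpha
    beta[region == REGION_TM] = tm_p.beta
    alpha[region == REGION_CB] = cb_p.alpha
    beta[region == REGION_CB] = cb_p.beta
    porous_mask = ~ws.stokes_cell
    closed = scenario.is_closed(mesh.cell_azimuth_deg())
    alpha[porous_mask & closed] /= scenario.reduction_factor

    mu_cell = np.where(ws.stokes_cell, fluid.mu,
                       num.porous_viscosity_epsilon * fluid.mu)

    # initialize pressure from the lumped 0D balance
    lcfg = lumped_model.LumpedConfig.from_geometry(
        mesh.spec.params, tm=tm_p, cb=cb_p, q_total=bcs.inflow_rate,
        p_out=bcs.outlet_pressure, scenario=scenario)
    if initial is not None:
        p_cell = initial.pressure[mesh.cells].mean(axis=1)
        T = initial.temperature.copy()
        u = initial.velocity.copy()
    else:
        p0 = p_init if p_init is not None else lumped_model.solve_iop(lcfg)
        p_cell = np.full(mesh.n_cells, p0)
        T = np.full(ws.n_nodes, bcs.T_interior)
        u = np.zeros((ws.n_nodes, 3))
    g_vec = np.asarray(fluid.g_vector)
    free = np.ones(ws.ndof, dtype=bool)
    free[vdofs] = False
    fidx = np.nonzero(free)[0]

    ac_nodes = np.unique(mesh.cells[region == REGION_AC])
    history = []
    converged = False
    n_solves = 0
    iop = np.nan
    p = np.full(ws.n_nodes, bcs.outlet_pressure)
    iop_outer_prev = np.inf
    # Outer loop: refactorize for the current (pressure-dependent) drag.
    # Inner loop: reuse the LU factors while the temperature/buoyancy
    # coupling converges (the matrix does not depend on T).
    for outer in range(1, num.max_picard_iters + 1):
        k_cell = np.zeros(mesh.n_cells)
        k_cell[porous_mask] = (1.0 + beta[porous_mask]
                               * np.maximum(p_cell[porous_mask], 0.0)) \
            / alpha[porous_mask]
        tau = num.stab_delta * ws.h2 / (mu_cell + k_cell * ws.h2)
        A = _assemble_flow_matrix(ws, mu_cell, k_cell, tau)
        # eliminate Dirichlet dofs before factorizing
        lu = spla.splu(A[fidx][:, fidx].tocsc())
        rhs_bc = A[fidx][:, vdofs] @ vvals

        iop_prev = umax_prev = np.inf
        inner_converged = False
        for inner in range(1, 9):
            T = _solve_temperature(ws, fluid, u, t_idx, t_val)
            T_cell = T[mesh.cells].mean(axis=1)
            f_cell = np.where(
                ws.stokes_cell[:, None],
                fluid.rho0 * g_vec[None, :]
                * (1.0 - fluid.gamma * (T_cell - fluid.T_ref))[:, None],
                0.0)
            rhs = _assemble_flow_rhs(ws, f_cell, tau, bcs)
            sol = np.empty(ws.ndof)
            sol[vdofs] = vvals
            sol[fidx] = lu.solve(rhs[fidx] - rhs_bc)
            u = sol[:ws.nu].reshape(-1, 3)
            p = sol[ws.nu:]
            n_solves += 1

            iop = extract_iop(p, mesh)
            umax = float(np.linalg.norm(u[ac_nodes], axis=1).max())
            history.append({"outer": outer, "inner": inner,
                            "iop_pa": iop, "umax_ac": umax})
            if num.verbose:
                print(f"  picard {outer}.{inner}: IOP = {iop:.3f} Pa, "
                      f"max|u|_AC = {umax:.3e}")
            if (abs(iop - iop_prev) < 0.5 * num.picard_tol
                    and abs(umax - umax_prev)
                    <= 0.5 * num.speed_rtol * max(umax, 1e-30)):
                inner_converged = True
                break
            iop_prev, umax_prev = iop, umax

        # under-relaxed mobility update
        p_new = p[mesh.cells].mean(axis=1)
        p_cell = (num.under_relaxation * p_new
                  + (1.0 - num.under_relaxation) * p_cell)
        if (outer >= 2 and inner_converged
                and abs(iop - iop_outer_prev) < num.picard_tol):
            converged = True
            break
        iop_outer_prev = iop
    it = n_solves

    # diagnostics
    q_in = -ws.facet_flux(u, TAG_INFLOW)
    q_cc = ws.facet_flux(u, TAG_CC_OUTLET)
    q_cb = ws.facet_flux(u, TAG_CB_OUTLET)
    mass_residual = abs(q_in - q_cc - q_cb) / q_in if q_in else np.inf
    return FlowSolution(
        velocity=u, pressure=p, temperature=T, iop=iop,
        outflow_tm_fraction=q_cc / q_in, outflow_cb_fraction=q_cb / q_in,
        mass_residual=mass_residual, converged=converged, iterations=it,
        history=history)


# ---------------------------------------------------------------------------
# diagnostics on a solution
# ---------------------------------------------------------------------------

def region_peak_speeds(sol: FlowSolution, mesh: MeshModel) -> dict:
    """Peak velocity magnitude per region, m/s.

    The maximum is taken over region-interior nodes, i.e. nodes all of
    whose adjacent cells belong to the region: interface rings between
    regions would otherwise be attributed ambiguously (a trabecular
    velocity counted as a ciliary-body one, and so on).  The AC peak
    additionally excludes nodes of the prescribed-inflow surface (their
    speed is boundary data, not a flow prediction).
    """
    from ahflow.geometry_mesh import REGION_NAMES
    speed = np.linalg.norm(sol.velocity, axis=1)
    # regions touching each node
    touches = np.zeros((mesh.n_nodes, 6), dtype=bool)
    for tag in REGION_NAMES:
        np.put(touches[:, tag],
               np.unique(mesh.cells[mesh.region_tags == tag]), True)
    n_regions = touches.sum(axis=1)
    inflow_nodes = mesh.boundary_nodes(TAG_INFLOW)
    out = {}
    for tag, name in REGION_NAMES.items():
        nodes = np.nonzero(touches[:, tag] & (n_regions == 1))[0]
        if name == "AC":
            nodes = np.setdiff1d(nodes, inflow_nodes)
        out[name] = float(speed[nodes].max()) if nodes.size else 0.0
    return out


def reynolds_number(sol: FlowSolution, fluid: FluidProperties,
                    mesh: MeshModel, L_char: float | None = None) -> float:
    """Re = rho U L / mu with U the peak AC speed (CC conduits excluded)."""
    if L_char is None:
        L_char = mesh.spec.params.ac_depth
    U = region_peak_speeds(sol, mesh)["AC"]
    return fluid.rho0 * U * L_char / fluid.mu


def outflow_partition(sol: FlowSolution, mesh: MeshModel):
    """(tm_fraction, cb_fraction): outlet fluxes normalized by inflow."""
    return sol.outflow_tm_fraction, sol.outflow_cb_fraction


def sector_velocity_stats(sol: FlowSolution, mesh: MeshModel,
                          scenario: ClosureScenario) -> dict:
    """Mean outward normal speed over the TM inner face, by arc.

    Returns ``{"open": v, "closed": v}`` (m/s); an arc of zero extent is
    reported as ``None``.  The TM inner face is the interior AC--TM
    interface; normals point out of the chamber.
    """
    faces, owners_ac = mesh.interface_faces(REGION_AC, REGION_TM)
    if faces.shape[0] == 0:
        raise ValueError("mesh has no AC-TM interface")
    x = mesh.nodes[faces]
    cr = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
    areas = 0.5 * np.linalg.norm(cr, axis=1)
    normals = cr / (2.0 * areas)[:, None]
    cents = x.mean(axis=1)
    away = cents - mesh.cell_centroids()[owners_ac]
    flip = np.einsum("fd,fd->f", normals, away) < 0
    normals[flip] *= -1.0
    un = np.einsum("fnd,fd->f", sol.velocity[faces], normals) / 3.0
    az = np.degrees(np.arctan2(cents[:, 1], cents[:, 0]))
    closed = scenario.is_closed(az)
    out = {}
    for name, sel in (("open", ~closed), ("closed", closed)):
        if not np.any(sel):
            out[name] = None
        else:
            out[name] = float((un[sel] * areas[sel]).sum() / areas[sel].sum())
    return out
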