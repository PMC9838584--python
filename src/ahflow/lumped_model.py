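"""Closed-form lumped (0D) model of aqueous humor outflow.

The two outflow tissues are treated as plane Darcy slabs in parallel:
the trabecular meshwork (conventional pathway) and the ciliary body
face (unconventional pathway).  Steady 1D Darcy flow with the
pressure-dependent mobility ``K/mu = alpha/(1 + beta p)`` integrates
exactly across a slab of thickness L:

    v(p_in, p_out) = alpha / (beta L) * ln[(1 + beta p_in) / (1 + beta p_out)]

(superficial velocity, m/s), reducing to the linear Darcy value
``alpha (p_in - p_out) / L`` as beta -> 0.  Intraocular pressure is the
unique root of the mass balance

    Q_total = sum over pathways of  A_open v(IOP; alpha)
                                  + A_closed v(IOP; alpha / R)

where a closed arc of the circumference divides alpha by the outflow
facility reduction factor R and splits each pathway area into open and
closed parts.  The flux is strictly increasing in IOP, so the root is
bracketed and unique.

This model deliberately neglects the hydraulic resistance of the
anterior chamber, Schlemm's canal and the collector channels (the slabs
carry essentially all of the resistance), which is what makes it an
independent analytic oracle for the finite-element model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from ahflow.materials import (
    ClosureScenario,
    PorousRegionParams,
    default_cb_params,
    default_tm_params,
)

#: Default full-eye inflow, m^3/s (3 uL/min).
DEFAULT_INFLOW_M3S = 3.0e-9 / 60.0


@dataclass
class PathwayConfig:
    """One outflow slab: mobility parameters, thickness and face area."""

    params: PorousRegionParams
    thickness: float       # slab thickness along the flow, m
    area: float            # full-eye face area, m^2

    def __post_init__(self):
        if self.thickness <= 0 or self.area <= 0:
            raise ValueError("thickness and area must be positive")


@dataclass
class LumpedConfig:
    """Inputs of the 0D mass balance.

    Default areas correspond to the default geometry: face circumference
    at the angle (2 pi R, R = 5.65 mm) times the axial face height
    (TM 275 um, CB face 1.9 mm).
    """

    tm: PathwayConfig = field(default_factory=lambda: PathwayConfig(
        default_tm_params(), thickness=100e-6,
        area=2.0 * np.pi * 5.65e-3 * 275e-6))
    cb: PathwayConfig = field(default_factory=lambda: PathwayConfig(
        default_cb_params(), thickness=300e-6,
        area=2.0 * np.pi * 5.65e-3 * 1.9e-3))
    q_total: float = DEFAULT_INFLOW_M3S   # full-eye inflow, m^3/s
    p_out: float = 933.254                # episcleral venous pressure, Pa
    scenario: ClosureScenario = field(default_factory=ClosureScenario)

    def __post_init__(self):
        if self.q_total < 0:
            raise ValueError("q_total must be >= 0")
        if self.p_out < 0:
            raise ValueError("p_out must be >= 0")

    @classmethod
    def from_geometry(cls, geometry, tm=None, cb=None, **kw) -> "LumpedConfig":
        """Build a config whose areas/thicknesses match a GeometryParams."""
        r = geometry.ac_diameter / 2.0
        circ = 2.0 * np.pi * r
        tm_p = tm or default_tm_params()
        cb_p = cb or default_cb_params()
        return cls(
            tm=PathwayConfig(tm_p, geometry.tm_thickness_radial,
                             circ * geometry.tm_height_axial),
            cb=PathwayConfig(cb_p, geometry.cb_thickness_radial,
                             circ * geometry.cb_face_height),
            **kw,
        )


def slab_flux(p_in, p_out, alpha, beta, thickness):
    """Superficial Darcy velocity (m/s) through a pressure-softening slab.

    Exact integral of ``u = -(alpha/(1+beta p)) dp/dx`` across thickness
    L with boundary pressures ``p_in >= p_out``.  Vectorized in the
    pressures.
    """
    p_in = np.asarray(p_in, dtype=float)
    if beta == 0.0:
        return alpha * (p_in - p_out) / thickness
    return (alpha / (beta * thickness)) * np.log1p(
        beta * (p_in - p_out) / (1.0 + beta * p_out))


def _total_outflow(iop, cfg: LumpedConfig):
    """Full-eye volumetric outflow (m^3/s) at a candidate IOP."""
    c = cfg.scenario.closed_fraction
    r = cfg.scenario.reduction_factor
    q = 0.0
    for path in (cfg.tm, cfg.cb):
        a, b, L = path.params.alpha, path.params.beta, path.thickness
        v_open = slab_flux(iop, cfg.p_out, a, b, L)
        v_closed = slab_flux(iop, cfg.p_out, a / r, b, L)
        q += path.area * ((1.0 - c) * v_open + c * v_closed)
    return q


def solve_iop(cfg: LumpedConfig, tol: float = 1e-6) -> float:
    """IOP (Pa) balancing inflow against the two slab pathways.

    Monotone bracketed root find to ``tol`` Pa.  ``q_total == 0`` returns
    ``p_out`` exactly (no flow, no pressure drop).
    """
    if cfg.q_total == 0.0:
        return cfg.p_out
    f = lambda p: _total_outflow(p, cfg) - cfg.q_total
    lo = cfg.p_out
    hi = cfg.p_out + 100.0
    while f(hi) < 0.0:
        hi = cfg.p_out + 2.0 * (hi - cfg.p_out)
        # Extreme scenarios (large R near full closure) push the root to
        # enormous pressures because the residual flux is logarithmic in
        # IOP; the bracket must accommodate them.
        if hi - cfg.p_out > 1e14:  # pragma: no cover - unreachable
            raise RuntimeError("failed to bracket the IOP root")
    return brentq(f, lo, hi, xtol=tol)


def pathway_split(cfg: LumpedConfig, iop: float | None = None):
    """(tm_fraction, cb_fraction) of total outflow at the balanced IOP."""
    if iop is None:
        iop = solve_iop(cfg)
    c = cfg.scenario.closed_fraction
    r = cfg.scenario.reduction_factor
    q = []
    for path in (cfg.tm, cfg.cb):
        a, b, L = path.params.alpha, path.params.beta, path.thickness
        q.append(path.area * (
            (1.0 - c) * slab_flux(iop, cfg.p_out, a, b, L)
            + c * slab_flux(iop, cfg.p_out, a / r, b, L)))
    total = q[0] + q[1]
    return q[0] / total, q[1] / total


def iop_curve(cfg: LumpedConfig, extents_deg, reduction_factor: float):
    """IOP (Pa) for each quarter-model closure extent at a fixed R.

    ``extents_deg`` must be sorted, within [0, 90].  Strictly increasing
    in extent for R > 1.
    """
    extents = np.asarray(extents_deg, dtype=float)
    if np.any(np.diff(extents) < 0):
        raise ValueError("extents must be sorted ascending")
    if extents.size and (extents[0] < 0 or extents[-1] > 90):
        raise ValueError("extents must lie in [0, 90]")
    out = np.empty(extents.shape)
    for i, e in enumerate(extents):
        scen = ClosureScenario(extent_deg=float(e),
                               reduction_factor=reduction_factor)
        out[i] = solve_iop(replace(cfg, scenario=scen))
    return out
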