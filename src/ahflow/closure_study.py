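"""IOP versus circumferential extent of angle closure.

Sweeps closure scenarios over a grid of extents and outflow facility
reduction factors with either the lumped (0D) or the finite-element
engine, and quantifies the nonlinearity of the resulting IOP curves:

* each curve is normalized by the tangent line at zero closure, so a
  perfectly linear IOP rise maps to a constant 1.0;
* the *nonlinearity onset* is the smallest extent at which the
  normalized IOP exceeds ``1 + threshold`` (5% by default), located by
  linear interpolation between grid points.

Extents are tracked in quarter-model degrees (0..90); the equivalent
full-eye extent is four times larger.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ahflow import lumped_model
from ahflow.materials import ClosureScenario, FluidProperties, pa_to_mmhg

#: Default reduction factors for sweeps; 1.6 is singled out because it
#: best matches binned clinical IOP data, 1 is the open-angle reference.
DEFAULT_FACTORS = (1.0, 1.6, 2.0, 5.0, 10.0, 100.0)

#: Default quarter-model extent grid, degrees (7.5-degree steps resolve
#: the zero-closure tangent).
DEFAULT_EXTENTS = tuple(np.arange(0.0, 90.1, 7.5))


@dataclass
class IOPCurve:
    """Model IOP versus closure extent for one reduction factor."""

    extents_deg_quarter: np.ndarray
    reduction_factor: float
    iop_pa: np.ndarray
    engine: str                                  # "lumped" | "fem"
    converged: np.ndarray = None                 # per-point flag
    normalized_iop: np.ndarray | None = None

    def __post_init__(self):
        self.extents_deg_quarter = np.asarray(self.extents_deg_quarter,
                                              dtype=float)
        self.iop_pa = np.asarray(self.iop_pa, dtype=float)
        if self.iop_pa.shape != self.extents_deg_quarter.shape:
            raise ValueError("extents and IOP lists must have equal length")
        if self.converged is None:
            self.converged = np.ones(self.iop_pa.shape, dtype=bool)

    @property
    def extents_deg_full_eye(self) -> np.ndarray:
        return 4.0 * self.extents_deg_quarter

    @property
    def iop_mmhg(self) -> np.ndarray:
        return pa_to_mmhg(self.iop_pa)


class LumpedEngine:
    """Curve engine backed by the closed-form 0D outflow balance."""

    name = "lumped"

    def __init__(self, cfg: lumped_model.LumpedConfig | None = None):
        self.cfg = cfg or lumped_model.LumpedConfig()

    def iop(self, scenario: ClosureScenario) -> float:
        return lumped_model.solve_iop(replace(self.cfg, scenario=scenario))

    def solve_point(self, scenario):
        return self.iop(scenario), True


class FemEngine:
    """Curve engine running the finite-element solver on a fixed mesh.

    The mesh is built once; only the closure coefficient field changes
    between scenarios.  Each solve seeds the porous drag from the lumped
    prediction scaled by the running FEM/lumped IOP ratio, which keeps
    the Picard iteration short during sweeps.
    """

    name = "fem"

    def __init__(self, mesh, fluid: FluidProperties, porous: dict,
                 bcs, num=None):
        self.mesh = mesh
        self.fluid = fluid
        self.porous = porous
        self.bcs = bcs
        self.num = num
        self._ratio = 1.0
        self._lcfg = lumped_model.LumpedConfig.from_geometry(
            mesh.spec.params, tm=porous["TM"], cb=porous["CB"],
            q_total=bcs.inflow_rate, p_out=bcs.outlet_pressure)

    def solve_point(self, scenario: ClosureScenario):
        from ahflow.fem_solver import solve_flow_temperature
        l_iop = lumped_model.solve_iop(
            replace(self._lcfg, scenario=scenario))
        sol = solve_flow_temperature(
            self.mesh, self.fluid, self.porous, scenario, self.bcs,
            self.num, p_init=l_iop * self._ratio)
        if sol.converged:
            self._ratio = sol.iop / l_iop
        return sol.iop, sol.converged


def sweep(engine, extents_deg=DEFAULT_EXTENTS, factors=DEFAULT_FACTORS):
    """One IOP curve per reduction factor over a common extent grid.

    Non-converged FEM points are flagged in ``curve.converged`` and
    carry NaN IOP; they are excluded from downstream normalization, not
    interpolated.
    """
    extents = np.asarray(extents_deg, dtype=float)
    curves = []
    for R in factors:
        iops = np.empty(extents.shape)
        conv = np.ones(extents.shape, dtype=bool)
        for i, e in enumerate(extents):
            scen = ClosureScenario(extent_deg=float(e), reduction_factor=R)
            iop, ok = engine.solve_point(scen)
            iops[i] = iop if ok else np.nan
            conv[i] = ok
        curves.append(IOPCurve(extents, R, iops, engine.name, conv))
    return curves


def normalize_tangent(curve: IOPCurve) -> IOPCurve:
    """Normalize a curve by its tangent line at zero closure.

    The tangent slope is the forward difference over the two smallest
    extents (the grid must start at 0 and hold at least 3 points).  A
    flat curve (R = 1) normalizes to identically 1.
    """
    e = curve.extents_deg_quarter
    iop = curve.iop_pa
    if e.size < 3 or e[0] != 0.0:
        raise ValueError("normalization needs >= 3 extents starting at 0")
    if not (curve.converged[0] and curve.converged[1]):
        raise ValueError("cannot normalize: tangent points not converged")
    slope = (iop[1] - iop[0]) / (e[1] - e[0])
    if slope <= 0.0:
        norm = np.ones_like(iop)
    else:
        norm = iop / (iop[0] + slope * e)
    norm = np.where(curve.converged, norm, np.nan)
    return replace(curve, normalized_iop=norm)


def nonlinearity_onset(curve: IOPCurve, threshold: float = 0.05):
    """Smallest extent (quarter-model deg) with normalized IOP > 1+threshold.

    Linear interpolation between grid points; returns ``None`` when the
    curve never deviates by more than the threshold ("no onset").
    """
    if curve.normalized_iop is None:
        curve = normalize_tangent(curve)
    e = curve.extents_deg_quarter[curve.converged]
    n = curve.normalized_iop[curve.converged]
    above = np.nonzero(n > 1.0 + threshold)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        return float(e[0])
    f = (1.0 + threshold - n[i - 1]) / (n[i] - n[i - 1])
    return float(e[i - 1] + f * (e[i] - e[i - 1]))


def curves_to_frame(curves):
    """Tidy pandas DataFrame of a family of curves (one row per point)."""
    import pandas as pd
    rows = []
    for c in curves:
        for i, e in enumerate(c.extents_deg_quarter):
            rows.append({
                "engine": c.engine,
                "reduction_factor": c.reduction_factor,
                "extent_deg_quarter": e,
                "extent_deg_full_eye": 4.0 * e,
                "iop_pa": c.iop_pa[i],
                "iop_mmhg": pa_to_mmhg(c.iop_pa[i]),
                "normalized_iop": (np.nan if c.normalized_iop is None
                                   else c.normalized_iop[i]),
                "converged": bool(c.converged[i]),
            })
    return pd.DataFrame(rows)
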