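"""Fluid and porous-tissue constitutive models.

Aqueous humor is treated as water-like at body temperature.  The two
porous outflow tissues (trabecular meshwork, TM; ciliary body face, CB)
follow a Darcy law whose mobility (permeability over viscosity) falls
with increasing gauge pressure,

    K/mu = alpha / (1 + beta * p),

so outflow facility decreases as the eye pressurizes.  ``beta`` is small
for the TM (mild facility loss over the clinical pressure range) and
large for the CB, which makes the unconventional pathway flux nearly
logarithmic in pressure, i.e. only weakly pressure dependent.

Pressure convention: ``p`` is gauge pressure relative to atmosphere, the
same scale on which the episcleral venous pressure is 933.254 Pa
(7 mmHg).  The mmHg conversion constant is fixed from that pair
(933.254 / 7 = 133.322 Pa/mmHg) so tabulated values reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Pa per mmHg, fixed from the EVP pair 7 mmHg == 933.254 Pa.
MMHG_TO_PA = 933.254 / 7.0  # = 133.322 exactly

#: m^3/s per uL/min.
ULMIN_TO_M3S = 1.0e-9 / 60.0

#: Episcleral venous pressure, Pa (7 mmHg): default outlet pressure.
EVP_PA = 933.254


def mmhg_to_pa(p_mmhg):
    """Convert pressure from mmHg to Pa (133.322 Pa/mmHg)."""
    return np.multiply(p_mmhg, MMHG_TO_PA)


def pa_to_mmhg(p_pa):
    """Convert pressure from Pa to mmHg."""
    return np.divide(p_pa, MMHG_TO_PA)


@dataclass
class FluidProperties:
    """Aqueous humor fluid constants (SI).

    ``gamma`` is the volumetric thermal-expansion coefficient entering
    the Boussinesq body force ``rho0 * g * (1 - gamma*(T - T_ref))``;
    ``T_ref`` defaults to the interior temperature (37 C) so the force
    is exactly hydrostatic in an isothermal-at-37C eye.
    ``g_vector`` is the gravity vector for a supine posture: the optical
    axis (+z, anterior) points up, so gravity is along -z.
    """

    mu: float = 1.0e-3            # dynamic viscosity, kg m^-1 s^-1
    rho0: float = 1000.0          # reference density, kg m^-3
    k_thermal: float = 0.6        # thermal conductivity, W m^-1 K^-1
    cp: float = 4182.0            # specific heat, J kg^-1 K^-1
    gamma: float = 3.0e-4         # volume expansion coefficient, K^-1
    T_ref: float = 310.15         # reference temperature, K (37 C)
    g_vector: tuple = (0.0, 0.0, -9.81)  # m s^-2, supine

    def __post_init__(self):
        for name in ("mu", "rho0", "k_thermal", "cp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")

    @property
    def thermal_diffusivity(self) -> float:
        """k / (rho0 * cp), m^2/s."""
        return self.k_thermal / (self.rho0 * self.cp)


@dataclass
class PorousRegionParams:
    """Pressure-dependent Darcy mobility parameters for one tissue.

    ``alpha`` is the zero-pressure mobility K/mu (m^3 s kg^-1) and
    ``beta`` (Pa^-1) its decay rate with gauge pressure.
    """

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


def default_tm_params() -> PorousRegionParams:
    """Trabecular meshwork mobility defaults."""
    return PorousRegionParams(alpha=4.5e-13, beta=1.125e-4)


def default_cb_params() -> PorousRegionParams:
    """Ciliary body face mobility defaults."""
    return PorousRegionParams(alpha=1.0e-12, beta=3.75e-3)


def mobility(p, params: PorousRegionParams):
    """Darcy mobility K/mu = alpha / (1 + beta*p) at gauge pressure p.

    Strictly decreasing in ``p`` for ``beta > 0``; constant (linear
    Darcy) for ``beta == 0``.  Accepts scalars or arrays.
    """
    return params.alpha / (1.0 + params.beta * np.asarray(p, dtype=float))


@dataclass
class ClosureScenario:
    """Sector-wise angle-closure description on the quarter model.

    ``extent_deg`` is the closed arc within the quarter model (degrees
    in [0, 90]; full-eye extent is four times that).  ``reduction_factor``
    R >= 1 divides the mobility parameter alpha of TM and CB cells inside
    the closed arc ("outflow facility reduction factor"); R = 1 is an
    open angle.  ``sector_mask``, if given, is an 8-element boolean mask
    of equal 45-degree full-eye sectors (clinical convention) and
    overrides ``extent_deg``: the quarter model represents the full
    circumference, so a mask with ``m`` closed sectors closes an arc of
    ``m/8`` of the quarter azimuth.
    """

    extent_deg: float = 0.0
    reduction_factor: float = 1.0
    sector_mask: tuple | None = None

    def __post_init__(self):
        if self.sector_mask is not None:
            mask = tuple(bool(b) for b in self.sector_mask)
            if len(mask) != 8:
                raise ValueError("sector_mask must have 8 entries")
            object.__setattr__(self, "sector_mask", mask)
            self.extent_deg = 90.0 * sum(mask) / 8.0
        if not (0.0 <= self.extent_deg <= 90.0):
            raise ValueError("extent_deg must lie in [0, 90]")
        if self.reduction_factor < 1.0:
            raise ValueError("reduction_factor must be >= 1")

    @property
    def extent_deg_full_eye(self) -> float:
        return 4.0 * self.extent_deg

    @property
    def closed_fraction(self) -> float:
        """Closed fraction of the circumference."""
        return self.extent_deg / 90.0

    def is_closed(self, theta_deg):
        """Vectorized: is quarter-model azimuth theta (deg) in the closed arc?

        The closed arc is contiguous and starts at theta = 0.
        """
        theta = np.asarray(theta_deg, dtype=float)
        return theta < self.extent_deg - 1e-12


def closure_mask(mesh, scenario: ClosureScenario) -> np.ndarray:
    """Per-cell alpha reduction factor field for a closure scenario.

    Returns an array of length ``mesh.n_cells`` equal to
    ``scenario.reduction_factor`` on porous (TM, CB) cells whose centroid
    azimuth lies in the closed arc and 1.0 everywhere else.  The
    effective mobility parameter of a closed cell is ``alpha / factor``.
    """
    factor = np.ones(mesh.n_cells)
    porous = mesh.porous_cell_mask()
    closed = scenario.is_closed(mesh.cell_azimuth_deg())
    factor[porous & closed] = scenario.reduction_factor
    return factor
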