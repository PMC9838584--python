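# Methods

`ahflow` is a mechanistic model of steady aqueous humor (AH) circulation
in the anterior segment of the human eye, built to study how the
circumferential extent and severity of anterior chamber angle closure
raise intraocular pressure (IOP). This note records the model, its
numerical treatment, the calibration and design choices that were
genuinely open, and the known limitations.

## Model

### Domain

The computational domain is one quarter (azimuth 0–90°) of an idealized
anterior segment for a supine subject, exploiting the two vertical
symmetry planes:

| region | type | description |
|---|---|---|
| AC | open (Stokes) | anterior chamber: dome with a spherical-cap cornea (depth 3.5 mm at the axis, diameter 11.3 mm) over the iris/lens plane |
| TM | porous (Darcy) | trabecular meshwork: annular band, 275 µm axial × 100 µm radial |
| SC | open | Schlemm's canal: annular band, 275 µm × 30 µm, outside the TM |
| CC | open | collector channels: 7 radial conduits per quarter on the outer SC wall, cross-section area-matched to a 50 µm diameter |
| CB | porous | ciliary body face: annular slab under the TM at the angle, 300 µm thick along the (radial) flow |

AH enters through an annular iris–lens slit in the chamber floor and
leaves through the conventional pathway (TM → SC → CC) and the
unconventional pathway (CB face), both of which discharge at episcleral
venous pressure (EVP).

### Governing equations

A single unified Stokes–Brinkman system covers all regions:

    −∇·(2 μ_K ε(u)) + k_K u + ∇p = f_K,      ∇·u = 0,

with cellwise coefficients: in open regions μ_K = μ, k_K = 0 and the
Boussinesq body force f = ρ₀ g (1 − γ(T − T_ref)); in porous regions
the Darcy drag k_K = 1/mobility(p) acts, gravity is switched off
(following the convention that the homogenized tissue force balance
carries no buoyancy), and the viscosity is reduced to ε·μ (see
*Numerics*). Velocity is continuous across the open–porous interfaces
because a single continuous velocity space is used; continuity of
pressure is the natural interface condition of the weak form.

The porous mobility softens with gauge pressure,

    K/μ = α / (1 + β p),

so outflow facility falls as the eye pressurizes: mildly for the TM
(β_TM = 1.125×10⁻⁴ Pa⁻¹; ≈15.5 % mobility loss from 15 to 30 mmHg) and
strongly for the CB (β_CB = 3.75×10⁻³ Pa⁻¹), which makes the
unconventional flux nearly logarithmic in pressure. `p` is gauge
pressure relative to atmosphere — the same scale on which EVP is
933.254 Pa (7 mmHg). The mmHg conversion constant is fixed from that
pair (933.254/7 = 133.322 Pa/mmHg) so tabulated values reproduce
exactly.

Temperature obeys steady convection–diffusion
ρ C_p u·∇T = k ∇²T with the cornea at 35 °C, every other exterior
surface at 37 °C, and insulated symmetry planes. T_ref is set to the
interior temperature (37 °C) so the buoyancy force is exactly
hydrostatic in an isothermal eye — the "no gradient → no vortex" limit
is then exact rather than approximate.

Angle closure over a circumferential arc is modeled by dividing α of
the TM and CB cells inside the arc by an *outflow facility reduction
factor* R ≥ 1 (R = 1: open angle). The closed arc is contiguous and
starts at azimuth 0; an 8-sector boolean mask (clinical convention) is
also accepted. A quarter-model extent of e degrees represents 4e
degrees of a full eye.

### Boundary conditions

* inflow: uniform normal velocity over the iris–lens slit whose
  discrete surface integral equals one quarter of the full-eye
  production rate (3 µL/min default);
* outlets (CC ends, CB outer face): normal traction −EVP·n;
* cornea, iris, lens, and all solid surfaces of open regions: no-slip;
* exterior surfaces of porous tissues: impermeable (u·n = 0) but not
  no-slip — a homogenized Darcy medium admits tangential slip at its
  boundary, and full no-slip would spuriously pinch the CB outlet at
  coarse resolution;
* symmetry planes: zero normal velocity and temperature gradient.

IOP is reported as the area-averaged pressure over the inflow surface.
Because essentially the whole resistance lies in the porous slabs, the
chamber is nearly isobaric and the volume-averaged AC pressure agrees
within 1 % (asserted in tests). Note that the pressure field includes
the ~20 Pa hydrostatic variation between the chamber floor and the
outlet datum whenever gravity is on; this is a datum convention, not
outflow physics, which is why the buoyancy-decoupling check compares a
thermal with an isothermal run at *identical* gravity.

## Geometry calibration

Published biometry fixes most dimensions; two are genuinely open and
were fixed once, via the lumped model, before any finite-element
result was inspected:

* **CB face height** (axial extent of the ciliary body face exposed to
  the chamber). This sets the unconventional outflow area and thereby
  the pathway split and both face velocities. It is calibrated by
  minimizing the joint log-error of the lumped model's TM and CB face
  speeds against the reference magnitudes (2.5×10⁻⁶ and 5×10⁻⁷ m/s).
  The optimum, 1.9 mm, reproduces the TM speed exactly, puts the CB
  speed within 1.3×, yields a physiologic open-angle IOP of 11.8 mmHg,
  and splits outflow ≈50/50 between the pathways — consistent with the
  reported unconventional fraction in young healthy eyes. 1.9 mm is
  anatomically plausible for the pars plicata.
* **Inflow slit width**: 250 µm (at pupil-margin radius 2.5 mm). The
  slit is a model inflow surface, not an anatomical channel; it is
  sized so the imposed inflow speed (~1.2×10⁻⁵ m/s) stays below the
  buoyant vortex scale (~4×10⁻⁵ m/s) and cannot masquerade as a flow
  feature in chamber velocity diagnostics.

The CB slab thickness along the flow (300 µm) makes the lumped CB face
velocity coefficient α_CB/(β_CB·L) consistent with the reference CB
speed magnitude.

## Numerics

* **Meshing.** A structured cylindrical hexahedral grid — graded radial
  lines, azimuthal lines refined around the collector-channel slots,
  vertical levels that follow the corneal dome — is split into
  tetrahedra with the Freudenthal/Kuhn 6-tet pattern, which is
  face-conforming when applied uniformly. Cells touching the optical
  axis collapse to wedges; their degenerate tetrahedra are dropped.
  Conformity, tag partitioning and the meshed-versus-analytic chamber
  volume (within 2 %) are asserted in tests. Resolution levels scale
  all subdivision counts geometrically (level 0: ≈29 k cells, level 1:
  ≈60 k cells); level 1 is the default study resolution. Much higher
  levels approach the elements counts used in reference simulations of
  this system but are not required by any invariant.
* **Discretization.** Equal-order P1/P1 velocity–pressure elements with
  PSPG stabilization, τ_K = δ h_K²/(μ_K + k_K h_K²) with δ = 0.1. The
  stabilization is residual-based (for P1 the viscous residual vanishes
  elementwise, leaving τ (k u + ∇p − f)·∇q), hence consistent in both
  the Stokes and the Darcy limit: it adds no artificial porous
  transmissivity. Summing the discrete continuity rows annihilates the
  stabilization term, so the boundary flux balance of the discrete
  velocity holds exactly; measured mass residuals are ~10⁻⁶ of the
  inflow, limited by the linear solver.
* **Porous viscosity.** A pure Darcy block (μ = 0) inside an
  H¹-conforming velocity space is ill-posed, so porous cells retain
  ε·μ with ε = 10⁻³ (Brinkman regularization). Halving ε moves IOP by
  far less than 1 % (asserted in tests).
* **Temperature.** P1 Galerkin convection–diffusion with cell-mean
  advection velocity. The grid Péclet number of these flows is ≪ 1
  (ρC_p U h/k ≈ 0.06 at U = 4×10⁻⁵ m/s, h = 200 µm), so no upwinding
  is applied.
* **Nonlinear iteration.** Picard: an outer loop refreshes the
  pressure-dependent drag (and refactorizes the flow matrix once per
  outer pass — the matrix does not depend on temperature); an inner
  loop reuses the LU factors while the temperature/buoyancy coupling
  converges. The drag update contracts at ~0.07–0.2 per outer pass, so
  no under-relaxation is applied by default (the knob exists).
  Convergence requires successive-IOP change below `picard_tol`
  (0.1 Pa default; 1 Pa — 0.05 % of IOP — for sweep-scale runs) and a
  2 % stationary peak chamber speed. The drag field is initialized
  from the lumped model's IOP. Dirichlet rows are eliminated before
  factorization (SuperLU/COLAMD).
* **Tie-breaks and conventions.** Closure detection on the sector mask
  uses the cell-centroid azimuth with strict inequality; a node shared
  by several regions belongs to none of their interiors, so the
  region-wise peak-speed diagnostics maximize over region-interior
  nodes only (otherwise the TM/CB junction ring would be attributed
  ambiguously); the inflow-surface nodes are excluded from the chamber
  peak because their velocity is boundary data.

## Lumped (0D) model and its role

Steady 1D Darcy flow with the softening mobility integrates exactly
across a slab of thickness L:

    v(p_in, p_out) = α/(β L) · ln[(1 + β p_in)/(1 + β p_out)],

and IOP is the unique root of Q = Σ_pathway A_open v(IOP; α) +
A_closed v(IOP; α/R), with the areas computed from the geometry (face
circumference × face height) and split by the closure extent. The
closed form is verified against adaptive quadrature of the underlying
ODE to 10⁻¹⁰ relative error.

The lumped model deliberately ignores the AC/SC/CC conduit resistances
and all three-dimensional redistribution, which is what makes it an
*independent* oracle for the finite-element model. The FEM IOP runs
3–6 % below the lumped prediction across the scenario grid: the
resolved model contains parallel leak paths the slab picture lacks
(e.g. pressure communication from the CB slab into Schlemm's canal
through their shared interface) and slightly lower cylindrical-slab
resistance than the planar formula. The 10 % agreement band used in
the oracle-equivalence tests absorbs these physical differences.

## Closure study conventions

Curves of IOP versus extent are normalized by the tangent line at zero
closure; the tangent slope is the forward difference over the two
smallest grid extents (0 and 7.5° by default). The *nonlinearity
onset* is the smallest extent where the normalized IOP exceeds 1.05,
linearly interpolated. Both the 5 % threshold and the tangent
estimator are conventions, and the onset location is sensitive to
them: with the defaults, the lumped curves place the onset at ≈30° of
quarter-model extent for R = 10 and ≈53° for R = 2 (run `ahflow lumped`
for the full table). The expected band of 30–45° for deviation from
linearity is met at moderate-to-high severity but not for mild closure
(R ≈ 2), whose curve stays within 5 % of its tangent until well past
half closure. The maximum normalized IOP grows monotonically with R
(asserted by brute force over an R grid).

## Synthetic cohort

The generator emulates the *structure* of a population AS-OCT study:
2395 eyes; per-eye AOD500 in eight 45° sectors; closure detected as
AOD500 < 0.04 mm (strict inequality; the boundary value counts as
open; 0.02/0.06 mm sensitivity thresholds re-run the pipeline); a
closed-sector count distribution heavily massed at zero (80 % fully
open, ~1 % with 7–8 closed sectors); a per-eye baseline mobility
multiplier K₀ (log-normal, log-SD 0.30) scaling both pathways; a
per-eye severity R (default: point mass at 1.6); Gaussian tonometry
noise (SD 2 mmHg). K₀ and R are drawn independently of the extent by
construction — under that independence the conditional mean of IOP
given extent reproduces the generating single-eye curve's shape, which
the tests verify within 3 Monte-Carlo standard errors against a
dispersion-aware reference mean.

Because per-eye IOP is drawn from the calibrated mechanistic model,
the cohort's absolute pressure levels follow that model: group means
sit near the 12 mmHg open-angle baseline for few closed sectors and
rise to ~15 mmHg in the merged 7–8 group at the default severity 1.6.
Population studies report higher absolute levels (roughly 15 mmHg
baseline rising toward 20 mmHg with extensive closure); the offset
reflects baseline outflow-facility variation that the geometry
calibration does not target, while the *shape* — flat below about
half closure, accelerating beyond — is the structural prediction the
pipeline tests.

What the generator does **not** emulate: real AS-OCT measurement error
structure, intra-eye sector correlation, iris mechanics or pupillary
block, clinical category labels (carried only as annotations), or any
claim of reproducing the actual study's values. Passing tests
therefore demonstrate the *pipeline* (detection, binning with the
merged 7–8 group, Tukey boxplot statistics with linearly interpolated
quartiles, least-squares selection of R from binned means), not
clinical validity.

One estimator property worth knowing: with realistic K₀ dispersion the
single-curve fit of R is biased upward (the dispersion adds convexity
to the conditional means, which the fit absorbs as severity ≈1.8 when
the generating value is 1.6). The parameter-recovery test therefore
uses the well-specified design — generation from the model curve with
small noise and no dispersion — where recovery is exact for every
seed tried.

## Problem sizes

Tests run the coarsest mesh (level 0, ≈29 k tetrahedra, ≈24 k flow
unknowns); the acceptance script runs the default level 1 (≈60 k
tetrahedra). Each nonlinear solve takes a handful of outer passes with
one sparse LU factorization per pass.

## Limitations

* Rigid tissues; no poroelasticity, no Schlemm's canal collapse (all
  conventional resistance is lumped into the TM slab).
* The iris is impermeable; full geometric closure is therefore modeled
  as finite permeability reduction, never as R → ∞.
* Steady state only: no ocular pulse, no transient mixing.
* The quarter model enforces two symmetry planes, so gravity must be
  axial (supine posture); other postures would break the symmetry the
  mesh exploits.
* P1/P1 with PSPG at coarse resolution under-resolves the collector
  channel entrance and the corneal boundary layer; region speed
  diagnostics are reliable at the factor-of-2 level, IOP at the
  percent level (it is slab-resistance dominated).
* The two counter-rotating vortex states reported in the literature are
  both physical; tests assert vortex existence and magnitude, never
  rotation sense.
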