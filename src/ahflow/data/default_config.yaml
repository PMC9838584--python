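# Default study configuration: fluid and tissue constants, geometry,
# boundary conditions and pipeline settings. All values SI unless the
# key carries a unit suffix. Loading this file reproduces RunConfig().
seed: 0
resolution_level: 1

geometry:
  ac_depth: 3.5e-3            # anterior chamber depth at the axis, m
  ac_diameter: 11.3e-3        # chamber diameter, m
  tm_height_axial: 275.0e-6   # trabecular meshwork axial height, m
  tm_thickness_radial: 100.0e-6
  sc_height_axial: 275.0e-6   # Schlemm's canal (equals TM height)
  sc_thickness_radial: 30.0e-6
  n_collector_channels: 7     # per quarter model
  cc_diameter: 50.0e-6        # nominal circular diameter, m
  cc_length: 200.0e-6
  cb_thickness_radial: 300.0e-6   # ciliary body slab thickness, m
  cb_face_height: 1.9e-3      # CB face axial height (see docs/methods.md)
  inflow_gap: 250.0e-6        # iris-lens slit width, m
  lens_radius: 2.5e-3         # pupil-margin radius, m
  cc_azimuth_offset_deg: 0.0

fluid:
  mu: 1.0e-3                  # viscosity, kg/(m s)
  rho0: 1000.0                # density, kg/m^3
  k_thermal: 0.6              # W/(m K)
  cp: 4182.0                  # J/(kg K)
  gamma: 3.0e-4               # volume expansion, 1/K
  T_ref: 310.15               # Boussinesq reference, K (37 C)

porous:
  tm: {alpha: 4.5e-13, beta: 1.125e-4}   # m^3 s/kg, 1/Pa
  cb: {alpha: 1.0e-12, beta: 3.75e-3}

boundary:
  inflow_ul_min: 3.0          # full-eye production
  outlet_pressure_mmhg: 7.0   # episcleral venous pressure
  t_cornea_c: 35.0
  t_interior_c: 37.0

numerics:
  picard_tol: 0.1             # Pa, successive-IOP change
  max_picard_iters: 50
  under_relaxation: 1.0
  porous_viscosity_epsilon: 1.0e-3
  stab_delta: 0.1

scenario:
  extent_deg: 0.0             # quarter-model degrees
  reduction_factor: 1.0

sweep:
  extents_deg: [0.0, 7.5, 15.0, 22.5, 30.0, 37.5, 45.0, 52.5, 60.0,
                67.5, 75.0, 82.5, 90.0]
  factors: [1.0, 1.6, 2.0, 5.0, 10.0, 100.0]
  engine: lumped

cohort:
  n_eyes: 2395
  baseline_mobility_dispersion: 0.30
  severity_mean: 1.6
  iop_measurement_noise_sd: 2.0
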