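# Reference material parameter set used before calibration.
# Unit convention: rho g/cm^3, E GPa, yield stress MPa, QLV A MPa,
# spring stiffness k N/mm (bone-literature standard; the source tables
# print bare numbers).
# The ligament force-displacement curve is a surrogate (no published
# breakpoints); tau for the QLV relaxation is a module default (1 ms).
trabecular_bone:
  model: linear_elastic
  rho: 1.1
  E: 0.3
  nu: 0.3
cortical_bone:
  model: piecewise_linear_plasticity
  rho: 2.0
  E_quasistatic: 17.5
  E_dynamic: 19.0
  nu: 0.3
  yield_stress: 165.0
  tangent_modulus: 0.0
  rate_threshold: 1.0
cartilage:
  model: linear_elastic
  rho: 1.0
  E: 0.3
  nu: 0.3
ligament:
  model: nonlinear_spring
  tension_only: true
  points: [[0.0, 0.0], [2.0, 140.0], [10.0, 1500.0]]
heel_fat_pad:
  model: qlv
  rho: 0.97
  A: 0.1
  B: 1.258
  nu: 0.495
  Q: 1.6
  tau: 1.0e-3
mild_steel:
  model: linear_elastic
  rho: 7.89
  E: 205.0
  nu: 0.29
plantar_fascia_initial:
  model: nonlinear_spring
  tension_only: true
  k: 240.0
plantar_tissue_initial:
  model: mooney_rivlin
  C01: 0.1
  C10: 1.258
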