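# Hardware catalogue of the simulated femoro-femoral VA ECMO circuit.
# Swap this file to model a different cannula family or circuit layout.
fluid:
  viscosity_cp: 3.6        # 60/40 w/w water-glycerol blood analogue
  density_kg_m3: 1099.0

cannulae:
  - {role: arterial, size_fr: 13, wall_mm: 0.5, stages: single}
  - {role: arterial, size_fr: 15, wall_mm: 0.5, stages: single}
  - {role: arterial, size_fr: 17, wall_mm: 0.5, stages: single}
  - {role: arterial, size_fr: 19, wall_mm: 0.5, stages: single}
  - {role: arterial, size_fr: 21, wall_mm: 0.5, stages: single}
  - {role: drainage, size_fr: 21, wall_mm: 0.5, stages: multi}
  - {role: drainage, size_fr: 23, wall_mm: 0.5, stages: multi}
  - {role: drainage, size_fr: 25, wall_mm: 0.5, stages: multi}

# hydraulic length bounds (m) used by calibration; the physical rig's exact
# inserted + external lengths are undocumented
length_bounds:
  arterial: [0.10, 0.40]
  drainage: [0.30, 0.70]

tubing:
  inner_diameter_m: 0.009525   # 3/8 inch
  segments_m: [2.0, 0.75, 2.0] # drainage->pump, pump->oxygenator, oxygenator->arterial

oxygenator:
  # adult hollow-fibre oxygenator, lumped; k1 calibrated within these bounds
  k1_bounds: [1.0, 25.0]

pump:
  omega_max_rpm: 4500.0
  # head-surface coefficient bounds (H in mmHg, omega in krpm, Q in L/min)
  a2_bounds: [15.0, 40.0]
  a1_bounds: [-15.0, 0.0]
  a0_bounds: [-8.0, 0.0]
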