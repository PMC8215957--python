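# Combat-boot sole stack: compression-only force-deflection curves per
# layer, breakpoints (deflection mm, force N).  The fitted curves of the
# boot characterization study are not published; these bilinear stiffening
# curves (initial stiffness then densification) are surrogate values
# representative of a rubber outsole, PU foam midsole and foam insole.
junction_mass: 0.02
layers:
  outsole:
    points: [[0.0, 0.0], [2.0, 3000.0], [20.0, 111000.0]]
  midsole:
    points: [[0.0, 0.0], [6.0, 2400.0], [30.0, 74400.0]]
  insole:
    points: [[0.0, 0.0], [3.0, 900.0], [20.0, 34900.0]]
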