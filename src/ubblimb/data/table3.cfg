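# Calibrated material parameter set (optimal combination selected by the
# grid-search calibration of the original model).  Units as in table1.cfg.
# Q and tau are carried over from the pre-calibration heel-pad values.
plantar_tissue:
  model: qlv
  rho: 0.97
  A: 0.8
  B: 2.15
  nu: 0.49
  Q: 1.6
  tau: 1.0e-3
plantar_fascia:
  model: nonlinear_spring
  tension_only: true
  k: 234.6
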