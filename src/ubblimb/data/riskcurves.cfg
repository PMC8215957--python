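# Calcaneal injury-risk curves per severity (minor = Sanders-I,
# major = Sanders-II), mapping peak axial proximal tibia force (N) to
# injury probability.  The original curves come from a companion survival
# analysis that is not reproduced here: these SYNTHETIC PLACEHOLDER
# logistic curves are constructed to pass exactly through the two published
# worked examples (12100 N -> 82% minor / 47% major; 7540 N -> 23% minor /
# 3% major).  Placeholder status is logged at load.
minor:
  form: logistic
  location: 9562.2346
  scale: 1673.6041
  placeholder: true
major:
  form: logistic
  location: 12263.2496
  scale: 1358.7789
  placeholder: true
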