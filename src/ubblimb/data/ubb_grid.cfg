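# Canonical 25-point under-body-blast loading sweep:
# peak plate velocities (m/s) x times to peak (s).
peak_velocities: [5.0, 11.25, 17.5, 23.75, 30.0]
times_to_peak: [1.5e-3, 3.5e-3, 5.0e-3, 7.0e-3, 9.0e-3]
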