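# Pendulum validation test modalities: impactor velocity (m/s), pendulum
# mass (kg) and the proximal ballast mass (kg) per test series.
modalities:
  - {impact_velocity: 3.3, pendulum_mass: 23.0, ballast_mass: 16.0}
  - {impact_velocity: 4.5, pendulum_mass: 23.0, ballast_mass: 16.0}
  - {impact_velocity: 6.7, pendulum_mass: 23.0, ballast_mass: 16.0}
  - {impact_velocity: 7.6, pendulum_mass: 23.0, ballast_mass: 16.0}
  - {impact_velocity: 5.0, pendulum_mass: 3.3, ballast_mass: 14.0}
  - {impact_velocity: 5.0, pendulum_mass: 5.7, ballast_mass: 14.0}
  - {impact_velocity: 5.0, pendulum_mass: 12.32, ballast_mass: 14.0}
  - {impact_velocity: 6.0, pendulum_mass: 3.3, ballast_mass: 14.0}
  - {impact_velocity: 6.0, pendulum_mass: 5.7, ballast_mass: 14.0}
  - {impact_velocity: 6.0, pendulum_mass: 12.32, ballast_mass: 14.0}
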