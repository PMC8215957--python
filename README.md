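# ubblimb

A desk-scale toolkit for computational injury biomechanics of the lower limb
under **under-body blast (UBB)** loading — the rapid upward floor motion an
occupant's feet experience when an explosive detonates beneath a vehicle —
and for quantifying the protection offered by combat boots.

The package is aimed at injury-biomechanics researchers and protection
engineers who want a fast, fully transparent, reduced-order stand-in for
expensive 3-D explicit finite-element models of the leg: quick parameter
studies, calibration-procedure prototyping, objective-rating experiments and
mitigation-technology screening, all in pure Python.

## What it implements

* **Signals** — uniformly sampled force/acceleration/velocity series with
  impact-test conditioning: SAE J211 channel-frequency-class (CFC)
  phaseless filtering, Butterworth low-pass filtering, trapezoidal
  integration of plate accelerometer records to velocity, resampling, peak
  extraction, and two-column CSV / HDF5 I/O.
* **Materials** — one-dimensional constitutive laws with the standard
  bone-literature unit convention (ρ in g/cm³, E in GPa, σ_y in MPa):
  linear elasticity, piecewise linear plasticity with a rate-switched
  modulus, quasi-linear viscoelasticity (QLV) with an exponential backbone
  σ_e(ε) = A(e^{Bε} − 1) and one-term reduced relaxation function
  G(t) = (1 + Q e^{−t/τ})/(1 + Q), the incompressible two-constant
  Mooney–Rivlin law σ = 2(λ² − 1/λ)(C₁₀ + C₀₁/λ), and tension-only
  piecewise-linear springs for ligaments and the plantar fascia.
* **Limb model** — a lumped-parameter chain
  plate → (boot layers) → plantar tissue → foot → arch ∥ plantar fascia →
  ankle → tibia+fibula → proximal mass, advanced by explicit
  central-difference integration (numba-compiled) with compression-only
  contact, per-step stability checks and a closing energy ledger.  Two
  boundary modes: a prescribed-plate traumatic-injury-simulator rig (40 kg
  hip-attachment mass) and an initial-velocity pendulum impactor with a
  14/16 kg proximal ballast.
* **Loading** — triangular plate-velocity pulses parameterized by peak
  velocity and time to peak, the canonical 5 × 5 factorial UBB sweep
  (5–30 m/s × 1.5–9 ms), and pendulum test modalities.
* **Rating** — ISO 18571 / CORA-style objective comparison of two time
  histories: corridor, magnitude (1 − ∫|c − r|/∫|r|), phase
  (cross-correlation lag) and slope sub-ratings, weighted overall score and
  Excellent/Good/Fair/Poor grading bands (≥ 0.94 / 0.80 / 0.58).
* **Calibration** — concurrent 5%-increment factorial grid search (6 × 6 =
  36 candidates) over plantar-fascia stiffness and plantar-tissue
  constitutive constants, rating each candidate simulation against a
  reference hindfoot-force signal and selecting the best.
* **Protection** — severity-specific injury-risk curves (minor =
  Sanders-I, major = Sanders-II calcaneal fracture) mapping peak proximal
  tibia force to injury probability, booted-vs-unbooted paired sweeps,
  percent-force-difference and risk-reduction tables, normal-fit summaries
  and a two-sample t-test.
* **Synthgen** — seeded synthetic rig records (25 kHz, Gaussian sensor
  noise) and constructed signal pairs with closed-form expected ratings,
  for testing and parameter-recovery studies.

## Worked example

Run one mid-severity UBB pulse (11.25 m/s peak plate velocity, 3.5 ms time
to peak) through the calibrated chain with and without the boot:

```python
from ubblimb import config as cfg
from ubblimb.limb_model import build_limb_chain, run, attach_boot
from ubblimb.loading import PulseSpec
from ubblimb.protection import load_risk_curves, risk_probability

lib = cfg.calibrated_materials()
model = build_limb_chain(lib["plantar_tissue"], lib["plantar_fascia"])
booted = attach_boot(model, cfg.default_boot_config())

spec = PulseSpec(11.25, 3.5e-3)
f_u = run(model, spec).proximal_force.values.max()
f_b = run(booted, spec).proximal_force.values.max()

curves = load_risk_curves(cfg.data_path("riskcurves.cfg"))
print(f"unbooted peak proximal tibia force: {f_u:8.1f} N")
print(f"booted   peak proximal tibia force: {f_b:8.1f} N")
print(f"force change: {100*(f_b-f_u)/f_u:+.1f} %")
print(f"minor calcaneal injury risk: "
      f"{100*risk_probability(f_u, curves['minor']):.1f} % -> "
      f"{100*risk_probability(f_b, curves['minor']):.1f} %")
```

```
unbooted peak proximal tibia force:   9949.6 N
booted   peak proximal tibia force:   5378.8 N
force change: -45.9 %
minor calcaneal injury risk: 55.8 % -> 7.6 %
```

The boot's compliant sole stack lengthens the load path and absorbs early
pulse energy, cutting the peak axial force transmitted to the proximal
tibia and, through the risk curve, the probability of a minor (Sanders-I)
calcaneal fracture.  The same machinery is exposed on the command line
(`ubblimb simulate`, `ubblimb rate`, `ubblimb calibrate`,
`ubblimb protect`, …).

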