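# Methods

## Scope and intent

`ubblimb` is a reduced-order (one-dimensional, lumped-parameter) re-creation
of an experimentally calibrated lower-limb model for under-body blast (UBB)
loading, together with the full assessment machinery that surrounds such a
model in practice: signal conditioning, objective curve rating, factorial
calibration, and injury-risk-based protection quantification.  It is not a
3-D finite-element model; it trades spatial fidelity for speed and
transparency, and its numerical outputs (peak forces, percent reductions)
should be read as those of a surrogate, not as predictions for a specific
specimen.

## The chain model

The limb is a vertical chain of point masses connected by 1-D elements,
positive displacement upward (the direction of plate motion):

```
plate(0) -[plantar QLV]- foot -[arch ∥ fascia]- ankle -[cartilage]- tibia -[shaft]- proximal
```

With a boot, three compression-only sole layers (outsole, midsole, insole)
are inserted in series between the plate and the plantar block, each with a
small lumped junction mass.

**Masses.** Segment masses are scaled to a 50th-percentile 72.6 kg adult:
foot node 0.75 kg, ankle/talus node 0.60 kg, tibia+fibula node 3.38 kg
(foot ≈ 1.45% and shank ≈ 4.65% of body mass, with the foot split across
two nodes).  The proximal mass is 40 kg in the rig configuration
(mechanical hip attachment) or the 14/16 kg ballast in pendulum mode.
Boot junction masses are 0.02 kg each — the compliant part of a sole stack
weighs on the order of tens of grams, and over-lumping mass here is not
benign: mass moving at plate velocity injects momentum into the chain and
can spuriously *raise* the transmitted force for short pulses.

**Elements.**

* *Plantar block* (heel pad + plantar soft tissue): quasi-linear
  viscoelastic, instantaneous backbone σ_e(ε) = A(e^{Bε} − 1) with the
  calibrated constants A = 0.8 MPa, B = 2.15, relaxation amplitude
  Q = 1.6, relaxation time τ = 1 ms (single-term Prony form; the published
  table gives only Q, so the form and τ are module defaults).  Geometric
  scale: contact area 1600 mm², stack thickness 20 mm.  Compression-only —
  this is also the plate contact, so the limb can separate from the plate.
* *Arch*: linear spring, 300 N/mm, representing arch-flattening
  compliance.
* *Plantar fascia*: tension-only spring (calibrated k = 234.6 N/mm,
  initial 240 N/mm) coupled to the arch segment.  A strictly tension-only
  element in a purely compressive 1-D chain would never engage, so the
  arch mechanism is modeled explicitly: compressing the foot segment by δ
  stretches the fascia by c·δ (arch-flattening leverage, default c = 1),
  which resists the compression with force c·F_fascia(c·δ).  This is what
  makes the hindfoot force sensitive to fascia stiffness — without it the
  calibration's fascia factor would be unobservable.
* *Ankle*: linear spring, 5000 N/mm (≈ cartilage E = 0.3 GPa over
  500 mm² / 30 mm).
* *Tibial shaft*: linear spring, 20 000 N/mm (≈ cortical E = 17.5 GPa over
  400 mm² / 350 mm); its force history is the proximal tibia force.
  Cortical bone stays far below its 165 MPa yield at the simulated forces,
  so the chain uses the elastic branch; the full rate-switched bilinear
  plasticity law is available in `materials`.
* *Boot layers*: bilinear stiffening force-deflection curves
  (initial stiffness, then densification) — outsole 1500 → 6000 N/mm at
  2 mm, midsole 400 → 3000 N/mm at 6 mm, insole 300 → 2000 N/mm at 3 mm.
  The fitted curves of the original boot characterization are not
  published; these are surrogate values (so labeled in `boot.cfg`),
  representative of a rubber outsole and PU foam midsole/insole.

All geometric scales, stiffnesses and masses are constructor arguments.

## Time integration

Explicit central difference: a = F/m, v half-step staggered, x updated with
the new half-step velocity.  The default step is Δt = 1e-7 s (the
linearized stability limit 2/ω_max of the default chain is ≈ 6e-4 s, so the
margin is large even after exponential stiffening of the plantar block);
the calibration scenario uses 2e-7 s and several tests 1e-6 s, all deeply
inside the stable region.  Stability is enforced twice: Δt is rejected
up-front against the initial tangent stiffness, and the tangent stiffness
of every element is re-estimated every step with an abort (diagnostic
`SimulationError`) if Δt²ω² > 4 or the state diverges.

The QLV hereditary convolution uses the exact one-term recursive update
h_{n} = e^{−Δt/τ} h_{n−1} + e^{−Δt/2τ}(σ_e,n − σ_e,n−1), which is
unconditionally stable and first-order accurate, and reproduces the step
response analytically: force σ_e·area at t = 0⁺ relaxing to
σ_e·area/(1+Q).  Note the quasi-static limit of this normalization is the
*long-time* response σ_e/(1+Q), not the instantaneous backbone.

Energies are accumulated every step — kinetic (synchronized half-step
velocities), internal (trapezoidal ∫f dδ per element, which includes
viscous dissipation), external work (trapezoidal plate-force × plate
displacement) — so the ledger KE + internal − external closes to
discretization error (< 1e-9 relative in practice for elastic
configurations; the test bound is 1%).  In impactor mode the reference is
the initial kinetic energy, and the accumulated contact impulse matches the
impactor momentum change to machine precision by construction of the
update.

Outputs are recorded at 1e-5 s (100 kHz) by default; the synthetic
experiment fixtures resample to the 25 kHz experimental rate.

## Signal conditioning

CFC filtering implements the SAE J211 two-pole digital Butterworth
coefficient formula (design frequency 2.0775 × channel class) applied
forward and backward — the standard 4-pole phaseless response — with
reflective padding of three filter lengths to suppress start-up transients
on short impact records.  The force-channel Butterworth low-pass defaults
to 1000 Hz, second order (the cutoff is not published; it is configurable),
also applied forward-backward.  Accelerometer-to-velocity integration is
cumulative trapezoidal.

## Rating

Sub-ratings follow the simple area-discrepancy forms: magnitude and slope
are 1 − ∫|c − r|/∫|r| on the phase-aligned signals and their central
derivatives; phase is linear in the cross-correlation lag, zero at
δ_max = 20% of the evaluation window; the corridor score averages a
per-sample piecewise-linear score between inner (5% of peak) and outer
(50% of peak) corridors.  The evaluation window runs from the first to the
last sample exceeding 5% of the reference peak.  The reference CORA
tooling's exact parameter values are not standardized in print; these are
module defaults, all in `RatingSettings`.  The ISO-style overall weights
corridor 0.4 and the other three 0.2 each; "paper mode" instead reports
the unweighted mean of (magnitude, phase, slope), the averaging used when
a single figure of merit is quoted for a calibrated model.  Grades:
Excellent ≥ 0.94, Good ≥ 0.80, Fair ≥ 0.58, else Poor — bands consistent
with every published (metric, grade) pair shipped in
`data/cora_reference.csv`.

## Calibration

The design ladders both factors geometrically, value·(1+increment)^i, 5%
increment, 6 × 6 = 36 candidates by default; the increment may be negative
(the published calibrated stiffness, 234.6 N/mm, lies *below* the stated
initial 240 N/mm, so the direction of the original sweep is ambiguous —
the machinery supports both).  The tissue factor multiplies (A, B)
jointly, reading "concurrently" as one shared multiplier per level.  The
search simulates every candidate under the rig scenario (5.2 m/s target
plate velocity; the rise time is not published — 2 ms chosen as typical of
such rigs), rates it in paper mode against the reference and returns the
argmax, ties to the lowest index, aborted candidates scored 0.  On a
noiseless self-generated reference the true grid point rates exactly 1.0
and is recovered exactly; with 2% amplitude noise, recovery is within one
grid step in ≥ 18/20 seeds (the fascia axis is the weakly identified one —
its rating sensitivity across one 5% step is a few parts in 10⁻³).

## Risk curves and protection

Minor (Sanders-I) and major (Sanders-II) calcaneal injury risks are
logistic in peak proximal tibia force.  The original curves come from a
survival analysis that is not published with the model; the shipped
parameters (minor: location 9562.2 N, scale 1673.6 N; major: 12263.2 N,
1358.8 N) are **placeholders** solved exactly from the two published
worked examples (12100 N → 82%/47%, 7540 N → 23%/3%), and a warning is
logged at load.  The protection sweep runs each of the 25 grid pulses
through both configurations, reports signed percent force differences
(negative = boot reduces force) and probability changes in percentage
points, fits normal densities to the two force populations and applies a
pooled two-sample t-test at 5%.

## Synthetic data

The fixture generator emulates rig records: the simulator's plate-contact
(hindfoot) force at known parameters, resampled to 25 kHz, plus the plate
acceleration implied by the prescribed pulse, each with seeded zero-mean
Gaussian noise scaled to a fraction of the peak (default conditions: 5.2
m/s pulse, 2% noise).  It reproduces bit-identically from its recorded
seed.  It does **not** emulate piezoelectric drift, offset, anti-aliasing
hardware or 3-D kinematics, so passing recovery tests show the procedure
works under well-behaved additive noise, not that it is robust to every
laboratory artifact.

## Problem sizes

Default runs integrate 15–35 ms of response at Δt = 1e-7 s (≈ 2–3.5 × 10⁵
steps, milliseconds of wall time via the compiled kernel).  The calibration
scenario and recovery studies use Δt = 1e-6 s over 15 ms so that a 36-
candidate search completes in under a second and the 20-seed noisy-recovery
study in a few seconds; the full 25-pulse booted+unbooted sweep runs at the
default Δt = 1e-7 s.

## Known limitations

* One-dimensional: no sagittal-plane rotation, no intra-articular stress
  fields, no shear; ligaments other than the plantar fascia are absorbed
  into the ankle element.
* Peak proximal force grows super-linearly with peak plate velocity (the
  exponentially stiffening plantar block has no 3-D compliance, bottoming
  redistribution or fracture), so at the 23.75–30 m/s end of the sweep the
  chain transmits substantially larger forces than a 3-D model would, the
  force-population SD is inflated, and the booted-vs-unbooted t-test on
  the full sweep does not reject at 5% even though every single
  combination shows a force reduction.  Restricting attention to the
  ≤ 17.5 m/s subset (where the risk curves are informative) is the
  intended reading.
* Boot layer curves and risk-curve parameters are surrogates/placeholders
  (see above); absolute percent reductions (≈ −29% to −47% across the
  sweep) characterize this surrogate boot, not any specific product.
* The energy ledger reports combined stored+dissipated element work as
  "internal"; it does not decompose viscous dissipation.
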