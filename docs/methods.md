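# Methods

`wearlab` re-implements a fully wearable gait-analysis chain: five IMUs
(pelvis, impaired thigh, impaired shank, both feet) and a 64-channel EMG
grid on the impaired shank are turned into gait events, left/right ground
reaction forces (GRFs), centre-of-pressure (CoP) trajectories, sagittal
knee/ankle angles, inverse-dynamics (ID) ankle torque, and an EMG-driven
Hill-type estimate of ankle dorsi-plantar flexion torque.  Because the
package targets desk-scale verification rather than a specific recording
hall, every stage is validated against a bundled synthetic gait generator
whose ground truth is known in closed form.

## Frames and conventions

Model frame: x anterior, y up, z to the participant's right; quaternions
scalar-first.  IMU orientations are reported in a z-up "global" frame; the
fixed −90° rotation about x maps global (x, y, z) → model (x, z, −y).
Accelerometers follow the specific-force convention (at rest they read
+9.81 m/s² along the local up axis); `kinetics.to_model_frame` keeps that
convention and `kinetics.remove_gravity` converts to true acceleration, so
the gravity term enters the Newton summation exactly once.  Sagittal
angles are twists about +z: knee flexion and ankle dorsiflexion positive,
plantar-flexion torque negative.

## Signal conditioning

All kinematic/kinetic streams pass through a zero-lag (forward–backward)
2nd-order Butterworth filter: 6 Hz for lab-style streams, 3 Hz for
IMU-derived velocities and accelerations (the lower corner suppresses
soft-tissue artefact), 20 Hz high-pass for EMG.  The design cutoff is
corrected for the double pass by the standard factor (√2 − 1)^¼ ≈ 0.802 so
the cascade's −3 dB point equals the nominal cutoff; without the
correction the dual pass attenuates even the step-frequency fundamental of
walking by ~9 %, which systematically biases the GRF and torque estimates.
The correction is a flag (`correct_cutoff=True` by default).  Edge
handling is reflective padding.

## EMG chain

Channels with large voltage fluctuations are flagged by a robust amplitude
statistic — the 95th percentile of |x − median(x)| per channel, thresholded
at 5× the across-channel median (both configurable) — and zeroed.  The MAD
is deliberately not used as the per-channel statistic: for phase-locked,
mostly-silent EMG bursts the MAD of a clean active channel is near zero,
which collapses the across-channel reference and false-flags active
channels.  Re-referencing reconstructs the clean common average: with
average-referenced recordings r_i = s_i − mean(s), the output
r_i − mean_clean(r) = s_i − mean_clean(s) removes the noisy channels'
contribution exactly.  Envelopes are 20 Hz high-passed, fully rectified
and smoothed by a centred moving median of round(0.16 s × rate) samples
forced odd (321 at 2000 Hz) — equivalent in bandwidth to a ~6 Hz low-pass
but robust to residual artifact spikes — then normalized per channel by
the maximum across all supplied tasks and averaged into seven
muscle-specific envelopes (tibialis anterior, extensor hallucis longus,
medial/lateral gastrocnemius, soleus, peroneus brevis and longus).  The
channel→muscle assignment is an input; on synthetic data it comes from the
generator's channel map.

## Gait events

Foot-flat (FF) is detected where all three foot angular-velocity
components simultaneously stay within k·SD of their trial mean (k = 0.5
by default; the criterion can be switched to linear velocity — the source
description is ambiguous between the two), with runs shorter than 50 ms
discarded.  IC is the nearest strict local maximum of the angular-velocity
signal-vector magnitude before the FF run; TC the nearest one after it;
the search is bounded by the neighbouring FF runs, runs touching the
series boundary emit no event, and a small prominence floor (5 % of the
SVM range) suppresses numerical ripple left by the zero-lag filter.
Phases per impaired cycle: double stance 1 (impaired IC → contralateral
TC), single stance (→ contralateral IC), double stance 2 (→ impaired TC),
swing (→ next impaired IC).  Strict IC/TC alternation is enforced on the
impaired (cycle-defining) side; contralateral gaps only drop the affected
cycles.

## Kinetics

The body model is the generic 1.68 m model scaled by s = height/1.68
(lengths, foot landmark offsets) with segment masses as generic fractions
of total mass; the pelvis "lump" carries the remainder (whole body minus
impaired thigh, shank, foot and the contralateral foot), so masses sum
exactly.  The foot landmark offsets relative to the calcaneus CoM are the
generic-model values (heel [0.00363314, 0.00830251, −0.00715492] m, toe
[0.231826, −0.0107138, −0.0071549] m).  Segment mass fractions, lengths,
the ankle joint-centre offset and the foot inertia are shipped as a
plausible planar generic asset in `wearlab.anthropometry`; every value can
be overridden.

Total GRF: F = Σᵢ mᵢ(aᵢ − g) over the five tracked segments, with IMUs
assumed at segment CoMs.  The left/right split follows the smooth
transition assumption: exclusive support in single stance, zero in swing,
and during double support the trailing foot's share follows an injectable
transition function of the elapsed double-support fraction — default
s(τ) = (1 + cos πτ)/2, continuous at onset and exactly zero at TC —
applied per component with the leading foot taking the exact remainder.
Conservation F_L + F_R = F_total is enforced bitwise by re-deriving the
trailing share from the floating-point remainder.  The CoP progresses
linearly heel → calcaneus CoM over [IC, contralateral TC] and calcaneus
CoM → toe over [contralateral TC, TC], on landmark trajectories
p + R(q)·offset; the vertical component is set to zero and swing samples
are absent (NaN).

## Joint mechanics

Sensor-to-segment registration uses the mean orientation over a ≥2 s
static trial (rejected if gyro RMS exceeds 0.2 rad/s): the registration
rotation maps each sensor's static orientation onto the segment's
default-pose orientation.  If the participant cannot hold the neutral
pose, the resulting joint-angle bias propagates downstream by
construction — a known limitation of static-pose registration in
post-stroke use.  Joint angles are the sagittal twists of the thigh→shank
and shank→foot relative rotations; for a planar chain with one sensor per
segment this is exactly equivalent to a weighted least-squares orientation
IK, without a generalized-coordinate solver.

Ankle torque (planar foot free body):

τ = I_f·α_f + [r_{com−ankle} × m_f(a_com − g)]_z − [(p_cop − p_ankle) × F]_z

with α_f from twice-differentiating the 3 Hz-filtered sagittal foot angle
and F = 0 during swing.  Cycle curves are resampled to 101 points
(0–100 % of the cycle, the field convention).  Agreement metrics: R² is
the squared Pearson correlation (a pure shape measure — an SSE-based R²
would mix shape and amplitude; that variant is available behind
`r2_variant="sse"`), RMSE measures amplitude, optionally per kg.

## EMG-driven MTU model

Seven rigid-tendon Hill-type MTUs actuate the ankle.  Excitation →
activation: a = (e^{Au} − 1)/(e^A − 1) with shape factor A ∈ [−3, 0).
MTU length is a per-muscle polynomial in the ankle angle (plus a linear
knee term for the bi-articular gastrocnemii); the moment arm is the
negative analytic derivative.  The shipped polynomial coefficients are a
plausible sagittal asset (dorsiflexor arms ≈ +3–4 cm, plantar-flexor arms
≈ −1 to −5 cm, lengths anchored so the fiber sits at optimal length in the
neutral pose); users may replace them.  Fiber force:

F = F_max[a·f_l(l̃)·f_v(ṽ) + f_p(l̃)]·cos φ

with Gaussian active force–length (width 0.45), a hyperbolic
force–velocity curve anchored at f_v(0) = 1 (Hill curvature 0.25,
eccentric plateau 1.5, v_max = 10 optimal lengths/s), exponential passive
curve with f_p(1) = 0 and f_p(1.5) = 1, and pennation from the
constant-thickness relation.  The tendon is rigid (fiber length along the
tendon = L_mt − l_st); MTUs slacker than the tendon produce zero active
force and are flagged.  No activation-dynamics filter precedes the
nonlinearity by default (envelopes are already ~6 Hz-equivalent smoothed);
an optional 2nd-order zero-lag filter sits behind
`activation_lowpass_hz`, and electromechanical delay is fixed at zero.

Pre-calibration scales optimal fiber length and tendon slack length so the
normalized fiber-length curve over an ankle-angle grid matches the generic
model's (linear least squares; exact for uniformly scaled geometry).
Calibration then minimizes J = MSE(τ_model, τ_ref)/Var(τ_ref) over one
calibration gait cycle, with per-muscle l_om and l_st bounded within ±5 %
of their pre-calibrated values, the strength coefficient in [0.5, 2.0] and
A in [−3, −0.01] (the ±5 % bound is the protocol's; the remaining ranges
follow the modelling literature and are configurable).  The optimizer is
seeded differential evolution (`updating="deferred"`, Sobol
initialization, the supplied start injected as x0) followed by an L-BFGS-B
polish; the returned objective never exceeds the start's, and fixed seeds
reproduce results bitwise.  Calibrated parameters are then used unchanged
on novel trials and walking speeds.

## Synthetic gait generator

The generator is the package's ground-truth surface.  One closed-form
planar description produces segment kinematics, IMU signals, EMG and
external loads that are mutually consistent:

- Cycle structure: stance = duty factor d of the cycle (default 0.6),
  contralateral foot shifted half a cycle, so each double support lasts
  d − 0.5.  Default conditions: cadence 100 steps/min, 1.1 m/s, 10 cycles
  (the protocol's minimum), 100 Hz IMU, 2000 Hz EMG, participant
  1.775 m / 94.2 kg (the study cohort's means).
- Foot trajectories are C⁴ piecewise polynomials: the pose is frozen
  exactly on the foot-flat interval [ρ, d − ρ] (ρ = 0.06); heel-strike and
  push-off rotations are 9th-order smoothsteps whose angular-rate peaks
  sit exactly at the prescribed IC and TC — the features the detector is
  designed to find.  Swing advance uses a step whose acceleration is a
  single sinusoid period and the foot lift a two-harmonic bump, keeping
  the load-bearing spectrum below the 3 Hz analysis band.  Small
  quadrature "wiggle" rotations keep all three gyro axes busy during the
  motion interval so the simultaneous-quiet FF criterion cannot fire
  mid-swing; their envelope goes exactly to zero on foot-flat.
- The pelvis advances at the set speed with a double-frequency vertical
  bob (±2 cm), which yields the classic double-peaked per-foot vertical
  GRF (~0.75–1.2 BW) once Newton's summation is applied.  Thigh/shank
  angles are smooth two-wave profiles; the chain is consistent in
  orientation space (knee and ankle angles are exact differences of
  segment angles) but is not a closed-loop forward-kinematic skeleton —
  positions are prescribed, not solved.
- Ground truth: total GRF by an independent numerical Newton summation
  over the pose series; left/right split by the cosine load-sharing rule
  with exclusive single support; CoP by the prescribed heel→calc→toe
  roll-over; ankle torque by the planar free-body closed form; per-muscle
  activations from gait-phase-locked profiles (dorsiflexors at heel
  strike/swing, triceps surae and peroneals at push-off).
- EMG: each clean channel is its muscle's envelope modulating an
  independent 20–450 Hz band-limited noise carrier; noisy-labelled
  channels add large sub-3 Hz drift.  IMU noise defaults (0.02 m/s²,
  0.005 rad/s) are testability choices — the source recordings do not
  characterize sensor noise.  Everything is seeded and bitwise
  reproducible.

What the generator does *not* emulate — and therefore what green tests do
not show about real recordings: soft-tissue artefact and sensor-mount
wobble, out-of-plane gait components beyond small smooth signals,
pathological asymmetry (duty factors are symmetric by default),
non-heel-first initial contact, EMG crosstalk between muscles, and
force-plate-grade GRF texture above the 3 Hz band.  Real-data headline
accuracies (e.g. ankle-torque R² ≈ 0.65 against a lab reference) depend on
those effects and on a marker-based reference system; the synthetic suite
verifies the machinery (equations, conventions, conservation, recovery),
not field accuracy.

## Numerical choices and problem sizes

Differentiation is central-difference (`np.gradient`, 2nd-order edges) at
the sampling rate; the trial-edge transients are excluded from
comparisons.  The IC/TC peak search uses a prominence floor of 5 % of the
SVM range.  Bitwise-exact load conservation uses a remainder-correction
loop (≤3 iterations).  Test and acceptance runs use 3–6 gait cycles per
trial and a differential-evolution budget of up to 60 generations ×
popsize 12 on 28 parameters — sizes chosen so the whole suite verifies the
contracts in a couple of minutes on one CPU; all are configuration values,
and larger studies only change runtime.

## Known limitations

File-driven (non-simulated) pipeline runs require externally supplied foot
pose series for the CoP landmarks (a real deployment would add strapdown
integration or a point-kinematics tool); the CLI therefore chains the
simulated path end-to-end, and stage-level APIs accept real streams
individually.  The CoP model assumes heel-first contact and monotone
roll-over; the ID torque inherits CoP error during single stance; static
registration inherits the neutral-pose assumption.  The tendon is rigid;
muscles beyond the seven shank muscles and joints beyond the ankle are out
of scope.
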