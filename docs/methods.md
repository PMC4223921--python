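# Methods

`gaitmanifold` simulates a planar heel–toe biped and analyses the
stability and intermittent stabilizability of its walking limit cycle.
This note records the model, the numerical choices, and what the packaged
synthetic gait does and does not establish.

## The walker

Seven rigid links move in the sagittal plane: a heavy head–arms–trunk
(HAT) element, and a thigh, shank and heel–toe foot per leg.  The posture
is the generalized coordinate vector

    q = (θ, x, y, q4, q5, q6, q7, q8, q9)

with HAT tilt θ, HAT-CoM position (x, y), and ankle/knee/hip angles of
the left (q4..q6) and right (q7..q9) legs; the state is the 18-vector
(q, q̇).  Segment angles accumulate additively along each chain (thigh
absolute angle θ + q_hip, shank + q_knee, foot + q_ankle, all CCW
positive with the walker advancing in +x), so knee flexion is a negative
angle.  The equation of motion is

    J(q) q̈ + B(q, q̇) + K(q) = G(q, q̇) + U_ff(t) + U_fb(x, t)

with inertia matrix J, Coriolis/centrifugal vector B, gravity K, ground
reaction G and controller torques U.  J, B, K are assembled analytically
from point-mass kinematics: every body point is a sum of rotated constant
vectors, whose Jacobian columns are perpendiculars of partial sums.  The
assembly is validated in the test suite against an independent
trigonometric-expression oracle differentiated by complex step and exact
quadratic-form polarization (agreement ≲ 1e-10 relative).

Body parameters (masses 0.682/3.162/6.882/40.548 kg, segment lengths,
CoM offsets and inertias, g = 9.8 m s⁻²) follow the standard
anthropometric set of this model family; total mass is 62.0 kg.

## Ground contact

Each foot carries a heel and a toe contact point (heel 0.06 m behind the
ankle, toe L1 = 0.122 m ahead, both 0.04 m below it).  A penetrating
point (depth d, rate ḋ) feels

    F_v = k_v d² (1 + c_v ḋ)      clamped at F_v ≥ 0,
    F_h = −c_h s(d) v_x,          s = smoothstep(d / 0.005 m),

with defaults k_v = 2·10⁶ N m⁻², c_v = 0.5 s m⁻¹, c_h = 1500 N s m⁻¹.
Two properties of this law are deliberate:

* It is **C1 in the state**, including at touchdown.  A compliance
  exponent of 3/2 (Hertzian) has unbounded curvature as d → 0 and a
  piecewise-linear friction ramp has derivative kinks; both leave a
  finite-difference Jacobian of the vector field with O(1%) column
  errors near contact events, which propagates into the monodromy
  matrix.  With the quadratic law and smoothstep ramp the variational
  monodromy agrees with a brute-force derivative of the nonlinear period
  map to better than 1e-3 column-wise.
* It is **memoryless**: the horizontal force is a penetration-gated
  viscous drag rather than a spring to an anchor planted at touchdown.
  Anchors are hidden discrete states; they would make the vector field
  history-dependent, break the exact unity (translation) multiplier, and
  require saltation corrections in the variational equation.  The price
  is a slow millimetre-scale slip of the stance foot under load, which
  the steady gait tolerates.  An anchored spring
  (`ContactParams.horizontal_stiffness > 0`, with optional slip
  threshold) remains available for plain nonlinear simulation; the
  Floquet routines refuse it.

Damping magnitudes are capped by explicit-Euler stability of the tiny
foot inertia (I₁ = 1.4·10⁻⁴ kg m²): the fastest contact/viscous rates
must stay below ≈ 2/dt.  This is the main reason the package integrates
at the reference step dt = 10⁻⁵ s everywhere (a 10⁻⁴ step distorts the
stiff-gain stability map and forbids joint viscosities above
≈ 20 N m s rad⁻¹).

## Desired trajectory and the synthetic fixture

The desired gait is a 6-joint trajectory of 8th-order Fourier series
with period T = 1.135 s, phase origin at left heel contact, and exact
left–right half-period symmetry (the right-limb series is the left one
advanced by T/2).  Because the motion-capture coefficients this model
family was originally driven by are not redistributable, the package
synthesizes its own fixture:

1. a task-space design — hip joint translating at 0.9 m s⁻¹ at height
   0.80 m with a small double bob; an ankle path with heel-strike
   (toe-up 0.15 rad), flat-foot, toe-pivot push-off (0.32 rad) and swing
   segments built from C1 Hermite splines; toe-off at 60% of the cycle;
2. two-link inverse kinematics to hip/knee angles plus a pitch-matching
   ankle angle;
3. projection on 8 Fourier harmonics.

The *constraint model* — the walker with all six joints kinematically
prescribed, leaving only the 3 HAT degrees of freedom — walks passively
and stably on this trajectory: from the packaged initial HAT state it
converges stroboscopically at ≈ 0.5–0.7 contraction per cycle down to a
≈ 1e-11 residual.  Its steady cycle is the reference gait x_r(t):
stride 1.001 m, speed 0.88 m s⁻¹, double-support episodes of 17% of the
cycle each (the design aimed at ~10%, but every attempt to shorten the
trailing double support destabilized the passive gait, so 17% is the
fixture's condition).  The zero-moment point computed from the reference
accelerations stays within the span of the loaded contact points at all
phases, confirming dynamic realizability.

`calibrate_fixture` re-runs this pipeline deterministically (a fixed
candidate list of template tweaks, no randomness; the seed argument is
accepted for interface uniformity).

### Exact discrete closure

The reference is stored at every Euler step of one period, with joint
positions obtained by *discretely* integrating the analytic Fourier
velocities (a left Riemann sum of a trigonometric polynomial over a full
period closes exactly) and joint accelerations defined as forward
differences of the velocities.  The feed-forward torque is the inverse
dynamics along these samples; its three HAT rows vanish to rounding.
Consequently x_r is an *exact orbit of the discrete dynamics*: the full
model simulated from x_r(0) with U_ff + PD feedback reproduces the
reference to ≈ 1e-13 after a cycle for any gain set (the open-loop case
sits on a larger, ~1e-4, floor because non-normal contact transients
amplify rounding).  All stability analysis is defined with respect to
this discrete system.

## Floquet analysis

Perturbations x̃ = x − x_r obey x̃' = DF(t) x̃.  The monodromy matrix is
the one-period product of per-step flow Jacobians I + dt·DF(t_k), the
exact chain-rule derivative of the discrete period map; a brute-force
central difference of the nonlinear flow is kept as an independent
oracle.  DF splits into an open-loop part, sampled once per reference by
central differences (step 3e-8·max(1, |x_i|), chosen where truncation
and rounding balance for the quadratic contact law), plus the analytic
feedback part −J⁻¹P̃ / −J⁻¹D̃ — so gain-space scans reuse the cached
blocks and cost one matrix-product sweep per gain set.  The total joint
impedance along the cycle is read off the same blocks
(K_total = −J·A21, B_total = −J·A22), which makes the identity
ΔK_total = ΔP, ΔB_total = ΔD exact.

The model is invariant under horizontal translation, so one multiplier
is exactly unity with eigenvector along q2; it is identified by that
dominant component and excluded from stability verdicts.  Eigenvalues
are ordered by descending modulus; conjugate pairs become 2×2 blocks
[[a, b], [−b, a]] on (Re v, Im v) column pairs of a real Jordan basis.

Under the heavy contact/joint damping many multipliers contract below
numerical resolution within one period (|λ| ≲ 1e-6 or outright
underflow), so the raw eigenvector matrix is numerically singular.  The
phase basis therefore keeps real Jordan columns only for resolved modes
and completes them with an orthonormal basis of the complementary
invariant subspace (the annihilator of the resolved left eigenvectors).
The dual rows for resolved modes are then their exact left eigenvectors,
and zeroing unstable coefficients performs the exact spectral
projection; the unresolved directions are classified stable.

## Stability map of the fixture

With joint viscosity D = 50 N m s rad⁻¹ and equal P-gains the cycle is
stable for P ≈ 1800–2300 N m rad⁻¹ (max non-unity multiplier ≈ 0.90 at
P = 2200); lowering P, a complex-conjugate pair crosses the unit circle
near P ≈ 1750 (a Neimark–Sacker-type signature), remains the only
unstable pair down to P ≈ 500, collides into two real multipliers around
P ≈ 300 where a small secondary stability island appears, and no more
than two non-unity multipliers leave the unit circle anywhere down to
P ≈ 100.  The saddle is extreme: below the unstable pair the next
modulus is ≈ 0.02–0.26, i.e. the stable manifold is 15-dimensional and
strongly attracting.  At the original model family's viscosity
(D = 10 N m s rad⁻¹) this fixture has no stable P region at all — the
synthetic trajectory plus the memoryless contact law demand more joint
damping — which is why the package's default gain set is (2000, 50).

A peculiarity of this fixture is a coexisting *distorted attractor* near
the limit cycle: weakly unstable gaits (e.g. P = 1500, D = 30, unstable
pair modulus 1.215) do not fall but settle into a bounded, visibly
distorted walk.  Strongly unstable settings (P = 500, D = 30, modulus
1.54) do fall, within ≈ 9–14 cycles of a 1e-3–1e-2 rad tilt
perturbation.

## Intermittent control (SMC / LCC)

During two clock-driven windows per cycle (onset phase φ_on and
φ_on + 0.5, duration w) an extra PD torque drives the joints toward a
nominal point: the projection of the current state onto the local stable
manifold in the onset-phase basis (SMC), or the reference state itself
(LCC).  The projection is re-evaluated every step; the basis is held
fixed through the window.  All intermittent torques vanish on the HAT
coordinates.

Two findings shaped the default intermittent gains (P⁺ = 30 N m rad⁻¹,
D⁺ = 100 N m s rad⁻¹):

* The oblique projector onto the unstable plane has norm 10–60 (the
  stable and unstable subspaces are far from orthogonal), so the SMC
  error term arrives pre-amplified; stiff on-period gains overdrive the
  loop and destabilize it.  This was established with an exact
  switched-system monodromy (the product of per-step Jacobians with the
  window term included), which matches the measured nonlinear growth.
* The fixture's unstable pair lives mainly in hip/trunk velocities, so
  viscosity-dominant on-period feedback is what removes it.

Study conditions for the controller comparison: the mild saddle
(P = 1500, D = 30), a 1e-3 rad tilt perturbation, 20-cycle horizons, and
a 5×5 grid over φ_on ∈ {0.10 … 0.40} and w ∈ {0.04 … 0.18} s.  Because
of the coexisting distorted attractor, survival alone saturates; a cell
counts as *stabilized* only if the walker survives **and** the final
cycle stays within dist < 0.05 of the limit cycle.  Under these
conditions:

* SMC stabilizes 13 of 25 cells, including the whole double-support
  onset row (φ_on = 0.10) and short windows elsewhere; LCC stabilizes 3
  cells, all at the double-support onset — a strict subset of SMC's.
* Sweeping the P-gains at D = 30 with the window fixed at
  (φ_on, w) = (0.10, 0.145 s), SMC rescues every unstable point
  P ∈ {500 … 1500} while LCC fails at P = 700; points adjacent to the
  stability boundary return close to the cycle (dist < 0.05), distant
  ones walk with large distortion — rescued but reshaped.
* At the double-support onset the minimum stabilizing duration is
  ≈ 0.03 s (≈ 2.6% of the cycle) for SMC versus ≈ 0.07–0.08 s (≈ 7%)
  for LCC; both fit inside the 0.195 s double-support episode.

The `dist` metric is the RMS over the final recorded cycle of the
component-wise error, each of the 17 non-advancing state components
normalized by its reference peak-to-peak range, with the horizontal
position replaced by the relative per-cycle stride-advance error.  A
uniform offset of 1% of every component's range evaluates to
√(17/18)·0.01 (a constant offset does not change the stride advance).

Fall detection (the model family never defines it operationally): a fall
is recorded in the first cycle in which the HAT-CoM height reaches 60%
of its reference mean or |θ| reaches 1 rad; thresholds are closed.

## Problem sizes and determinism

One period is N = 113 500 Euler steps.  Reference extraction runs 120
cycles of the 3-DOF constraint model; the open-loop Jacobian blocks are
sampled once per reference (36 vector-field evaluations per step) and
cached; each monodromy afterwards is a single product sweep.  Scans use
20-cycle horizons and 5×5 grids.  Everything is deterministic: identical
configurations produce bit-identical trajectories, and the only RNG in
the package (acceptance-script gain-set ordering, test perturbation
draws) is explicitly seeded.

## Limitations

* The fixture emulates the *shape* of physiological joint trajectories
  but is not motion-capture data; quantitative boundaries (the
  instability gain, optimal-impedance location, exact w_min values)
  are properties of this fixture and its contact calibration, not of
  the original subject's gait.  Qualitative structure — unity
  translation multiplier, low-dimensional saddle-type instability via a
  complex pair, a stiff stable region plus a small flexible island,
  SMC's wider stabilizing envelope and shorter minimum burst — is what
  the tests assert.
* Joint viscosities (D = 30–50) are above the quasi-stiffness range
  reported for human gait; the memoryless friction model and the
  explicit integrator both push in that direction.
* The local stable-manifold projection is linear; no global manifold
  continuation or basin mapping is attempted, and large perturbations
  (≳ 3e-3 rad at stable gains) leave the linear regime quickly through
  strong non-normal transients.
* Feedback delay, phase resetting, torque saturation and
  state-triggered (rather than clock-triggered) window onsets are out
  of scope.
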