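# Methods

## Walking model

The plant is a planar biped with two rigid legs of length *l*, curved feet
of radius *R* = 0.3 *l*, a point-mass pelvis (68% of body mass) at the hip,
and 16% of body mass in each leg (COM at *c* = 0.645 *l* from the foot end,
radius of gyration 0.326 *l* about the leg COM).  All quantities are
normalized: *g* = *l* = total mass = 1, time in (l/g)^0.5, speed in
(g l)^0.5, torque in M g l.

**Sign convention.**  Leg angles are measured from vertical, positive when
the foot is forward of the hip.  The stance angle runs from +α to −α over a
step; the swing angle from −α to +α; touchdown geometry is θ_sw = −θ_st.
With this convention the constant stance extensor torque is negative and
performs positive work, and the swing torque −k_sw·θ stiffens the swing
pendulum.

**Continuous dynamics.**  During single support the stance leg is an
inverted pendulum rolling on its curved foot and the swing leg hangs from
the hip.  The equations of motion M(θ)θ̈ + C(θ,θ̇)θ̇ + G(θ) = T were derived
once symbolically from the Lagrangian of this three-body system under the
rolling constraint (contact-point abscissa −Rθ_st) and frozen as closed
forms; with the shorthand K = m_l(c+l) + m_p l − R(2m_l+m_p),
b₁ = l − R, b₂ = l − c:

    M11 = J1 − 2RK(1 − cos θ1)          J1 = m_l(r² + c²) + (m_l+m_p) l²
    M12 = −m_l b2 (R cos θ2 + b1 cos(θ1−θ2))
    M22 = J2 = m_l(r² + b2²)
    C11 = −RK sin θ1 · θ̇1
    C12 = m_l b2 (R sin θ2 − b1 sin(θ1−θ2)) · θ̇2
    C21 = m_l b1 b2 sin(θ1−θ2) · θ̇1,   C22 = 0
    G1  = −K sin θ1,   G2 = m_l b2 sin θ2

(indices: 1 = stance role, 2 = swing role).  The tests verify these against
an independently coded oracle: finite differences of energy functions built
directly from the point kinematics, so an error in the closed forms cannot
hide.

**Heelstrike.**  The step-to-step transition is a perfectly inelastic
collision.  It is computed as a momentum projection in floating-base
coordinates (hip position + two leg angles): the pre-impact velocity under
the old rolling constraint is projected, in the kinetic-energy metric, onto
the rolling constraint of the new contact foot, with the impulse acting
through the new contact point only.  This construction guarantees kinetic
energy never increases and conserves angular momentum about the new
contact (both verified to machine precision).  Ground-contact roles swap
atomically; double support is instantaneous.

**Events.**  Touchdown is a downward zero crossing of the swing-foot
clearance cos θ_st − cos θ_sw, accepted only when the stance leg has
rotated past 10% of the nominal heelstrike angle (the scuffing exemption:
earlier grazes of the rigid swing leg are ignored entirely).  A fall is
|θ_st| reaching π/2 and takes precedence on ties.  Hip torques act about
the hip with reaction on an implicitly inertially anchored torso, so the
actuator power is Σ T_i θ̇_i; this choice (the torso is not modeled)
slightly affects the absolute cost of transport.

## Motor command and speed regulation

    T_i = −(k_st + μ_st s)·GC_i − k_sw θ_i ·(1 − GC_i)

evaluated at the *estimated* angles and contacts.  The tonic drive *s* is
updated once per stride (between same-leg heelstrikes) by discrete integral
control on the stride speed Δ(forward position)/Δt, with an anti-windup
clamp at ±5 nominal.  Stride bookkeeping deliberately continues across
falls, so the time lost falling lowers the measured speed and the drive
compensates by walking faster between falls; this is what "maintaining
average walking speed despite noise" means here.  The integral gain is set
from the measured speed-vs-torque sensitivity of the limit-cycle family so
that the correction factor is ~0.95 per stride (≈10-stride time constant).

**Calibration.**  For a given swing gain k_sw, the stance torque is solved
(Brent bracketing) so the limit cycle walks at 0.4 (g l)^0.5; the limit
cycle itself is a fixed point of the post-heelstrike Poincaré section
(unknowns α, θ̇_st, θ̇_sw; residual < 1e−11).  The calibrated k_sw is the
bounded scalar minimizer of positive work per distance along that
speed-constrained family.  Outcome with the default parameters: step
length 0.5510 l, step time 1.3775, mCOT 0.0532, stride-map eigenvalue
magnitudes {0.13, 0.13, 0.74}.  Only the sum k_st + μ_st·s matters
nominally; it is split evenly with s = 1.

## Noise model

Process noise (additive angular acceleration, SD 0.015 stance role / 0.16
swing role) and sensor noise (additive on the measured leg angles, SD 0.1
each) are band-limited: i.i.d. zero-mean Gaussians drawn at frequency 16,
clipped at ±3 SD, interpolated by a cubic spline (clipping changes the SD
by <1%).  One child RNG stream per channel derives from a master seed, so
process and sensor noise are independent and every trial is bit
reproducible.  Process-noise channels are attached to the stance/swing
*roles* (they swap legs at heelstrike), matching the role-ordered equations
of motion and the role-ordered LQE design.  The generator emulates
unpredictable torque-like disturbances and proprioceptive error; it does
not emulate terrain geometry, sensor bias or delay, or signal-dependent
motor noise.

## Estimator design

The internal model integrates the full nonlinear equations of motion with
the efference copy of the motor command, plus the correction L(y − θ̂).
L is the steady-state Kalman gain of the continuous-time Riccati equation
for the dynamics linearized at legs-vertical with a fixed role assignment,
process covariance ρ·N_x entering the acceleration rows and sensor
covariance N_y on the angle measurements.

Two design choices deserve note:

* **Open-loop linearization.**  Because the plant and the internal model
  receive the *same* command T(θ̂), the estimation-error dynamics obey the
  open-loop Jacobian; A therefore excludes the swing-torque feedback (a
  flag retains the folded variant).  The open-loop design also spans
  normalized gains 0.820–1.452 over ρ ∈ [10⁻⁴, 10⁰·⁸], with a finite floor
  because the inverted-pendulum mode is unstable: as ρ → 0 the Riccati
  solution approaches the smallest stabilizing gain rather than zero.
* **Contact channel.**  Ground contact is a separate boolean input.  With
  non-zero L, any sensed contact change overrides the estimated contact and
  the estimated velocities are transformed by the collision map evaluated
  at the estimated state.  With L = 0 (pure feedforward) and in fictive
  modes, the estimator keeps its own contact bookkeeping: its believed
  contact flips whenever its internal geometry indicates touchdown in the
  right phase (including the case where the phase condition is met with the
  estimated foot already at the ground, which is what sustains the
  small-amplitude fictive rhythm).

The ρ family is evaluated on 13 log-spaced points over [10⁻⁴, 10⁰·⁸]
(exponent step 0.4, which places ρ = 1 exactly on the grid).

## Half-center oscillator form

The estimator is re-written exactly as two mutually inhibiting half-center
oscillators with states u ≙ θ̂̇ and v ≙ θ̂, output q = u, ground-contact
neuron c ≙ ĜC and motoneuron α ≙ T.  The synaptic weights are defined
from the internal model at the *current* estimated state (they are state
dependent): [[a₁,w₁₂],[w₂₁,a₂]] = M⁻¹C, r = M⁻¹, [h′; h] = L, a′ = 0.  The
adaptation gain b_i is fixed to the slope of (M⁻¹G)_i in θ̂_i at the
legs-vertical reference; the higher-order functions f_i carry the exact
residual b_iθ̂_i − (M⁻¹G)_i, so the neural form is the same vector field
traversed through different algebra.  The equivalence check integrates both
forms in closed loop with the walker (a pure-python integrator, independent
of the fast trial engine) and observes agreement at round-off level
(~1e−15 over 10 strides).  Omitting f gives a reduced-order CPG whose gait
persists with a bounded discrepancy.  Motor commands can be rendered as
motoneuron spike trains by an inhomogeneous Poisson process with rate
proportional to |T| (default 500 spikes per unit time per unit torque,
1 ms bins); a single motoneuron per leg carries both torque signs.

## Metrics

* **mCOT** = positive actuator work / (body weight × distance).  Including
  falls: all work over all forward progression (a fall wastes its work and
  time; the reset advances one nominal step length free of work).
  Excluding falls: completed steps only.  On noisy ensembles the including
  variant is the larger; the headline noisy cost is the including-falls
  value.
* **Step-length variability** = RMS deviation of completed step lengths
  about the ensemble mean (fall-interrupted steps excluded).
* **MTBF** = total simulated time / fall count (also reported per step);
  censored at the total observed time when no fall occurs.
* **Estimation RMSE** pools the four state-error components (angles and
  angular velocities, normalized units) over time and trials:
  sqrt(∫Σe²dt / 4T).

## Simulation engine and numerics

Plant, estimator and work/error integrals form one 11-state ODE integrated
by fixed-step classical RK4 (numba kernels): h = 1e−3 for deterministic
runs (global error ≪ 1e−9 per stride; passive energy drift ≈ 1e−16),
h = 2e−3 for noisy trials (the noise floor dominates).  Events are located
by bisection on the step size to ~1e−12 in time; fall beats heelstrike on
ties.  Trials integrate segment-to-segment with collisions, contact
overrides, fall resets (plant and estimator both reset to the nominal
initial condition, advanced one nominal step length) and tonic-drive
updates applied between segments, with a hard time cap guaranteeing
termination and divergence reported as an error rather than dropped.
Sweeps use common random numbers: trial k sees the same noise realization
for every gain, so gain effects are not confounded with sampling noise.

**Problem sizes.**  The standard stochastic protocol is 20 trials × 100
steps per gain; the reference gain sweep uses all 13 ρ values and the
noise-level sweep repeats it for process-covariance multipliers 0.36 /
1.15 / 2.06 with sensor covariance at 1.15.  The impulse demonstration is
a rectangular swing-leg acceleration pulse (amplitude 5 g/l at 15% of the
stride; width one noise-sample interval by default, configurable since the
outcome is somewhat sensitive to the realization).  Fictive runs integrate
the estimator + command loop alone for ≥ 50 nominal stride periods.

## Behavior of the noisy sweeps (what passes and what does not)

At the reference condition the walking-performance optima (mCOT, MTBF,
step variability) sit at or adjacent to normalized gain 1, with roughly
10% mean worsening at the extremes (0.82 / 1.45).  The *estimation-RMSE*
minimum, however, is shallow and reproducibly sits 2–3 grid points below
ρ = 1 (normalized gain ≈ 0.87–0.90).  Diagnosis: in the pure linear error
dynamics driven by the same band-limited noise the empirical minimum is
adjacent to ρ = 1, but in the full hybrid loop the sensed-contact override
and the estimated collision act as discrete corrections that the
continuous-time LQE design does not model, and they disproportionately
rescue low-gain estimators.  The same ~5–10% downward shift appears in all
three noise-level conditions, whose simulated minima otherwise track the
theoretically optimal gains in rank order and magnitude.

In fictive mode with the error signal cut, the internal model reproduces
the nominal rhythm exactly (period and amplitude to 1e−11).  With the
afferent cut and the gain halved, the estimate is drawn toward zero and a
sustained limit cycle of roughly half the nominal amplitude emerges — but
with a *shorter* period (~0.78 vs 1.38 per half-cycle): the small-amplitude
internal gait traverses its reduced angle range faster, and this holds
robustly for gain-reduction factors 0.3–0.7.  A slower-than-nominal fictive
rhythm would require the internal collisions to become rarer, which this
contact model does not produce.

## Known limitations

* No torso, knees, ankles, 3D motion, ground compliance or slipping; the
  hip torque reacts against an idealized inertial frame.
* The estimator gain is constant (no gain scheduling along the cycle, no
  extended/unscented variants); the linearization point is legs-vertical,
  and L is moderately sensitive to that choice.
* Band-limited (spline-interpolated) noise is not white; the LQE design
  treats its covariance as a white-noise intensity, which is part of why
  the simulated RMSE optimum shifts slightly below the theoretical gain.
* Passing tests demonstrate correctness of the mechanics, the estimator
  algebra and the closed-loop trends under the synthetic noise model; they
  do not certify behavior under real terrain, sensor bias/delay, or
  signal-dependent noise.
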