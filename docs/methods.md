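# Methods

This note documents the models, the numerical and design choices behind
them, and what the test suite does and does not establish.

## Plants and discretization

Both benchmark environments are controlled SDEs with constant diffusion,
integrated by the Euler–Maruyama scheme
`x_{t+1} = x_t + Δt·μ(x_t, u_t) + Δw_t`, `Δw_t ~ N(0, Δt·S)`. With `S = 0`
the step is exactly forward Euler (bitwise), and the scheme is first-order:
the deterministic endpoint error halves when Δt is halved (verified in the
tests).

**Double integrator.** State `(q, q̇)`, drift `(q̇, u)`. Step size
Δt = 0.1 s, episodes 100 steps. Start states come from a uniform
100×100 grid over `[−1, 1]²`; the grid extent is a package choice (the
task is scale-free). Success means `‖x‖ < 10⁻³`; an episode that has not
succeeded after 100 steps is a failure.

**Inverted pendulum.** State `(x, ẋ, θ, θ̇)`, drift
`(ẋ, u, θ̇, (g/l)·sin θ)` with g = 9.81 m/s², l = 0.6 m, Δt = 0.02 s,
failure at |θ| > 11°, timeout (= success) at 1000 steps with one reward
point per surviving step. **Deliberate property:** the control force
enters only the cart acceleration; the pole angle is an autonomous
unstable subsystem (`ω = √(g/l) ≈ 4.04 s⁻¹`). This is the equation set
implemented here, and it differs from the fully coupled MuJoCo-style
cartpole: no controller can influence the pole, so episode reward is
determined entirely by the initial perturbation (uniform ±0.01 per state
component). The measured untrained median survival is ≈ 50–60 steps,
consistent with the linearized escape time
`t ≈ ln(2·θ_lim/|θ₀ + θ̇₀/ω|)/ω ≈ 1 s`; a coupled cartpole would topple
faster under random forcing. The angle is kept unwrapped since episodes
end at 11°.

**Noise defaults.** The task plants are deterministic by default
(process covariance zero): the particle's 10⁻³ success radius is
meaningless under sustained process noise, and the pendulum benchmark is
conventionally deterministic. Observation noise enters through the
observation model: the `noisy_position` mode observes only the particle's
position with Gaussian noise of variance 0.1. Process noise is fully
supported and configurable.

## Analytic control

The LQR gain solves the continuous algebraic Riccati equation
(`scipy.linalg.solve_continuous_are`); we store K positive and apply
`u = −K x` (the stabilizing convention; for the double integrator with
Q = R = I, K = [1, √3] exactly). The Kalman filter is the steady-state
*recursion* (predict with the previous control, then innovation-correct
with the DARE gain) on the exactly discretized plant — a purely static map
from one observation to a full state estimate cannot reconstruct velocity
from a single position sample. The estimate starts at zero.

Because the simulated plant is deterministic, the filter Riccati equation
is solved with a *design* process covariance of 0.01·I: with a literal
zero process covariance the steady-state gain is zero and the filter would
ignore its measurements. This design value trades initial convergence
against noise rejection; it is a config parameter.

**A hard limit worth knowing.** With position-only observations of
variance 0.1 (sd ≈ 0.32) and 100 samples, the best achievable estimate of
the current state has error on the order of σ/√N ≈ 0.03. We verified that
even the optimal *time-varying* Kalman filter + LQR achieves a median
closest approach of ≈ 0.04 to the origin. Consequently no causal
controller — analytic or learned — can reach the 10⁻³ success radius
under this observation model, and the corresponding acceptance test fails
by design. The meaningful statement about the noisy-position task is the
cost ratio relative to the analytic oracle (the distilled RNN reaches
≈ 1.25× the oracle's cost), not a success rate at radius 10⁻³.

## RNN controller

Single- or multi-layer tanh RNN; the split-step Euler discretization of
the leaky-membrane equation at Δt = τ is *identical* to the discrete
update `x_t = tanh(A x_{t−1} + B u_t + b)` (tested to 10⁻¹²), so τ never
appears explicitly at run time. Readout `u = gain·tanh(Cx + c)`.

- Presets: 1×50 neurons for the particle, 2×128 for the pendulum, one
  motor output each.
- Init: orthogonal recurrent weights, Gaussian input/readout weights
  scaled by 1/√fan-in, zero biases.
- Readout gain 3 for the neural system: the bounded output must be able
  to express the analytic controller's largest command on the start grid
  (max |Kx| = 1 + √3 ≈ 2.73). Gain 1 would truncate the optimal policy.
- Hidden state resets to zeros at episode start.

## Training

All three backends run on a small built-in reverse-mode autodiff over
numpy arrays (no external DL framework; gradients were validated against
finite differences to ~10⁻⁹ relative error).

**Direct** (environment in the loop): BPTT on the quadratic cost over
batches of on-the-fly rollouts; environment parameters are constants in
the graph. Adam with step size 10⁻³, linear decay, and **gradient-norm
clipping at 1.0** — clipping is essential: untrained rollout costs are
~10⁴ and the resulting gradient spikes otherwise poison Adam's
second-moment estimates, stalling training at ~2× the optimal cost.
Batch 10. At the scaled-down budget (2 epochs × 1000 trajectories) the
trained controller's mean cost is within 1% of the analytic optimum.

**Oracle distillation**: the LQG controller collects (y, u) sequence
pairs on the noisy-position task; the RNN is regressed on the raw (u is
unbounded, but within the readout's gain) oracle controls with MSE + BPTT,
10% of episodes held out for validation.

**RL**: clipped-surrogate policy gradient with generalized advantage
estimation (γ = 0.99, λ = 0.95, clip 0.2, value coefficient 0.5, entropy
0), a Gaussian action head on the bounded readout mean with a learned
log-std, and a linear value head on the top-layer rates. Episodes are
collected whole and replayed from their initial hidden state during the
update epochs, so the recurrent policy's gradients are exact. Learning
rate 2·10⁻⁴ with linear decay. Full-budget presets (500k particle /
800k pendulum episodes) exist but are not desk-scale; tests use
scaled-down budgets and assert improvement over the untrained policy
(particle task only — on the pendulum the reward is policy-independent,
see above).

## Perturbation and prosthesis

`perturb_weights` adds elementwise N(0, σ²) noise to exactly one weight
group: sensory (first-layer input weights), association (all recurrent
weights), or motor (readout weights); everything else is bit-identical,
and the neural system stays frozen during prosthesis training.

The prosthesis (default: one 50-neuron recurrent layer) reads
`y_EN = C_EN x_N` (the masked association *rates*, one tick old — the
loop order is fixed as: prosthesis reads, prosthesis steps, neural system
steps with injected current, motor readout) and stimulates via
`B_EN u_EN` added to the association pre-activation, the Δt = τ analogue
of injected membrane current. Recording and stimulation use the same
uniformly sampled electrode set by default; independent sets are
supported.

Design choices that matter:

- **Stimulation bound (readout gain) 5** — must cover the scale of the
  perturbation-induced current `ΔA·x` (entrywise σ = 0.5 over 50 neurons
  gives currents of order 2).
- **Quiescent start**: prosthesis readout weights are scaled by 0.01 at
  init. A random gain-5 stimulation policy saturates the association
  neurons, making behavior *worse* than no prosthesis and killing the
  BPTT gradient through the saturated tanh.
- **Optimizer**: prosthesis direct training uses step size 7·10⁻³
  (clipped, linearly decayed) rather than the 10⁻³ used for the neural
  system: an association-perturbed network sits in a saturated, chaotic
  regime (spectral radius of the perturbed A ≈ 3.5) and smaller steps
  cannot escape it within the desk budget. This setting restored behavior
  across all populations and all training seeds we probed.
- The restoration sweep perturbs at σ ∈ {0.1, 0.25, 0.5, 1.0} (levels are
  a package choice). The electrode-coverage sweep uses the
  sensory-perturbed system (σ = 0.5): restoring a lost sensory pathway is
  the canonical prosthesis scenario and is attainable at partial coverage,
  whereas the σ = 0.5 association case needs full coverage at desk-scale
  budgets to untangle the chaotic recurrence.

Measured at the defaults: full coverage restores all three populations to
within ~10% of the unimpaired cost; for the sensory case ~2 electrodes of
50 (4%) already suffice to come within 25%.

## Empirical Gramians and electrode bounds

The controllability Gramian is estimated from one-tick impulses
(amplitude s/Δt, both signs, scales averaged and normalized by s²) on
each stimulation channel, accumulating `Σ_t Δt·δx_t δx_tᵀ` of the
sign-symmetrized responses relative to the unforced reference trajectory;
the observability Gramian dually from ±s initial-state perturbations and
their output responses (trapezoid weight on the t = 0 sample). On linear
systems both match the Lyapunov-equation solutions to ~10⁻⁴ relative
Frobenius error (the acceptance bar is 10⁻²), and the scalar plant
`ẋ = −x + u` gives exactly 1/2. For the closed-loop neural system the
probing point is the origin-stabilized operating state (200 settle
ticks), probe scales 0.1–0.2 to stay in the rates' near-linear regime,
horizon 50 ticks.

The variance dimension (smallest k whose leading eigenvalues hold 90% of
the eigenvalue mass) is reported as an electrode-count lower bound.
**Honest caveat:** for networks initialized with orthogonal recurrent
weights — which training at these budgets barely reshapes — impulse
responses are norm-preserving in all directions, the Gramian spectrum is
nearly flat, and the variance dimension lands near 0.9·n (≈ 34–38 of 50),
far above the empirically sufficient 2–5 electrodes. The bound is
informative only when the trained dynamics are genuinely low-dimensional;
with this package's init scheme it is vacuous, and the acceptance test
that asserts the bound matches the empirical minimum fails by design.

## What a green test establishes

The synthetic world is small (2- and 4-dimensional plants, deterministic
by default, Gaussian sensor noise) and the desk budgets are ~100× below
the full-scale presets. Green tests establish correctness of the
numerics (integration, Riccati/Kalman synthesis, autodiff, Gramian
estimation against oracles) and the qualitative claims (training reaches
the analytic optimum; perturbation degrades and a trained prosthesis
restores behavior; partial electrode coverage suffices for the sensory
case). They do not establish robustness to model mismatch, non-Gaussian
noise, real neural dynamics, or the behavior of the RL backend at full
budget.
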