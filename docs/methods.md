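# Methods

## Problem and scope

`solband` studies how different neural strategies — different relative
penalties on individual muscles — change the joint contact forces (JCFs)
predicted for the stance phase of walking. It covers the simulation chain
from per-frame torque equilibrium to band-level statistics. Upstream motion
processing (marker tracking, inverse kinematics, inverse dynamics, model
scaling from markers) and musculotendon dynamics (activation dynamics,
force–length–velocity, tendon compliance) are out of scope: torques, moment
arms, lines of action and intersegmental loads are *inputs*, supplied per
frame, either from files or from the synthetic generator.

## Weighted static optimization

Per frame, activations solve

minimize Σᵢ wᵢ aᵢ²  subject to  G a (+ r) = τ, 0 ≤ a ≤ 1,

with gains `G[d,i] = R[d,i]·F_max,i`. Assumptions:

* **Ideal force generators.** Muscle force is `a·F_max` with rigid tendon
  and no passive component. This keeps the problem a strictly convex QP
  with a unique global optimum and matches common static-optimization
  practice; force–length–velocity scaling of the bounds would be a drop-in
  generalization but is deliberately not modelled.
* **Quasi-static equilibrium.** Segment inertial effects are folded into
  the supplied intersegmental forces.
* **Closed bounds.** Activations may be exactly 0 or 1.

**Numerics.** Because the Hessian is diagonal, the box-constrained
Lagrangian minimizer is separable: `aᵢ(λ) = clip(gᵢᵀλ/(2wᵢ), lbᵢ, ubᵢ)` for
torque multipliers λ (one per DOF). The concave, piecewise-quadratic, C¹
dual is maximized by a damped semismooth Newton iteration with Armijo
backtracking on the dual value; convergence certifies the KKT conditions,
so the returned point is the exact optimum up to the residual tolerance.
The iteration is warm-started across frames (both primal and dual). If it
stalls (rare, near degenerate kinks), the frame falls back to SciPy SLSQP,
whose result is accepted only after an explicit KKT verification —
solver exit flags are never trusted on their own. Torque residuals must
satisfy `|res_d| ≤ 1e-6·max(1, |τ_d|)` for a frame to count as converged.

**Reserve actuators.** A per-DOF torque slack `r`, penalized by
`1000·r²` per (N·m)², can rescue frames where the muscles alone cannot
balance the torque (possible when EMG boxes conflict with equilibrium
under noise). Reserves are off by default, engaged only as a rescue when
`reserve_enabled` is set, and logged at WARNING; their penalty is included
in the reported cost.

**EMG constraint form.** For measured muscles the bounds become
`[max(0, e−δ), min(1, e+δ)]` around the envelope `e`; δ defaults to 0.05
activation units and is configurable. A box was chosen over an equality or
a soft penalty because it preserves the QP structure, degrades gracefully
with envelope noise, and nests the unconstrained problem (δ ≥ 1 recovers
it exactly); the feasible-set inclusion also yields a testable invariant —
the constrained optimal cost can never undercut the unconstrained one.

## Strategy sampling

Weight vectors live on `{1, 10, 100}^m` — three orders of magnitude of
per-muscle penalty. The chain starts at all-ones (the standard static
optimization) and at each step re-draws one uniformly chosen muscle's
weight uniformly from the levels. The proposal is symmetric and always
accepted, so the stationary distribution is uniform over the lattice;
repeats are retained to preserve "n combinations = n simulations"
semantics (a dedupe report is emitted). Burn-in and deduplication are
available but off by default. The default chain length is 10,000; tests
and the acceptance script use 500–1,000 to keep runtimes in minutes on one
CPU, which is ample for the band statistics on a 12-muscle model
(`{1,10,100}^12` has ~5×10⁵ states but the band geometry saturates much
earlier).

## Joint reaction and normalization

Per joint and frame, the contact force is the intersegmental load plus
`Σ fᵢ·dᵢ` over crossing muscles, with unit pull directions `dᵢ` oriented so
positive force adds compressive load. The analyzed scalar is the resultant
(vector norm), divided by bodyweight and linearly resampled onto 101 points
spanning the stance window (frames where vertical GRF > 2 % bodyweight —
the threshold is configurable since no standard value exists).

## Band statistics

* Bandwidth: pointwise max − min across strategies; summarized as mean ± sd
  (population sd) over the 101 points and reported at the two vertical-GRF
  peaks together with the band's [min, max] envelope there (both readings
  are reported since either convention appears in the literature).
* Percentiles: pointwise linear-interpolation quantiles (numpy's default),
  10th–90th by default.
* Impulse/AUC: trapezoidal rule on the 101-point grid, units BW·%stance.
* Bandwidth ratio: mean constrained bandwidth / mean unconstrained
  bandwidth over a shared window; RAD: 100·(AUC_c − AUC_u)/AUC_u. The
  unconstrained run is the reference denominator for both.
* EMG-vs-unconstrained comparisons default to the inter-peak window
  (envelope artifacts concentrate in early stance); full stance optional.
* Extremes: argmin/argmax of impulse, ties to the lowest sample index.
* Wilcoxon signed-rank: exact null by dynamic programming over doubled
  midranks (handles ties) for n ≤ 25, tie-corrected normal approximation
  (no continuity correction) beyond; zero differences dropped; α = 0.05;
  no multiple-testing correction is applied.

## Synthetic data generator

The generator emulates one stance phase of instrumented overground walking
for a reduced 12-muscle, 3-DOF (hip/knee/ankle flexion) lower limb:

| parameter | default | rationale |
|---|---|---|
| frames | 151 over 0.75 s | typical stance duration at ~200 Hz |
| GRF peaks | 1.1 / 1.05 BW at 25 / 75 %stance | double-bump vertical GRF of level walking |
| GRF bump width | σ = 12 %stance | yields a realistic mid-stance valley |
| moment arms | 3–6 cm, smooth, sign-fixed | physiological lower-limb range |
| F_max | 250–3550 N per muscle | order of published lower-limb values |
| truth activations | smooth bumps ≤ 0.8 | headroom so EMG boxes never clip at 1 |
| EMG noise | sd 0.03 (activation units) | mild envelope noise after max-normalization |
| subject mass | 75 kg (template 75 kg) | strength scales linearly with mass ratio |

The key construction choice: ground-truth activations are drawn first and
torques are *computed* as `τ = R(a∘F_max)`, so the truth is exactly
feasible and parameter-recovery experiments are well posed. Smooth curves
are sums of Gaussians/sinusoids, keeping peak locations closed-form; the
config validator requires the GRF peak separation to be ≥ 3.2 × the bump
width so the summed bumps keep their maxima at the configured centers.
Intersegmental loads are proportional to the GRF with joint-specific gains,
and EMG envelopes are the measured channels' true activations plus clipped
Gaussian noise.

What the generator does **not** emulate: biofidelic muscle geometry or
wrapping, moment-arm coupling to joint angles, soft-tissue artifact,
envelope-extraction distortion (synthetic EMG is already an envelope),
inter-subject anthropometric structure beyond a mass range. Tests passing
on synthetic data therefore validate the *pipeline's* correctness and the
qualitative physics (band narrowing under EMG constraints, cross-joint
trade-offs), not population-level claims about real gait.

## Design choices on open points

* Geometry is supplied per frame rather than derived from joint angles —
  it keeps the solver model-agnostic and the upstream muscle analysis out
  of scope.
* Positive moment arm ⇒ positive DOF torque; gravity 9.81 m/s² unless
  overridden; both recorded in the model config.
* Representative-trial selection minimizes the sum over hip/knee/ankle of
  RMS deviation from the across-trial mean curve (ties to lowest index) —
  the intent ("closest to the subject's average") admits several metrics;
  RMS is the least surprising.
* GRF peak detection uses a discrete prominence filter (5 % bodyweight) to
  reject jitter before picking the two tallest local maxima.
* The CLI (`synth`/`solve`/`mcmc`/`analyze`/`report`) is a thin layer over
  the library; every stage writes a checksummed manifest so end-to-end
  determinism is verifiable byte for byte.

## Known limitations

* Ideal force generators overestimate the feasible activation space at
  extreme fiber lengths/velocities; bands are correspondingly wider than a
  musculotendon-dynamics pipeline would produce.
* The EMG constraint assumes envelope amplitude ≈ activation after
  max-normalization; calibration error between the two is not modelled.
* Reserve-rescued frames mix a torque-slack penalty into the reported
  cost; heavy reserve use (logged) signals an inconsistent trial.
* Single-site chains mix slowly per muscle (a weight persists ~m steps);
  statistics that assume independent strategies should thin the chain.
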