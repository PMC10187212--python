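# Methods

## Task and plant

The Critical Stability Task couples the lateral hand position `p(t)` to a
cursor through the unstable first-order law `ẋ = λ(x + p)`; a trial fails when
`|x| > c` (workspace half-width `c = 10 cm`) at any time inside the analyzed
window (6 s of an 8 s simulated horizon).  The hand is a point mass
(`M = 1 kg`) driven by a muscle-like first-order actuator (`τḞ = −F + u`,
`τ = 60 ms`).  Differentiating the cursor law once brings the cursor velocity
into the state (its acceleration obeys `ẍ = λ²x + λ²p + λṗ`), giving the
five-state linear system `[x, ẋ, p, ṗ, F]` used throughout.  Some published
descriptions of this task include hand and cursor accelerations as two further
states; the five-state form is the one that is fully determined by the
dynamics above and is what this package implements.

**Units.** The plant is integrated in SI units (m, m/s, N).  This is a
substantive choice, not a convention: the noise magnitudes below are only
meaningful on a scale, and on the SI scale (workspace ±0.1 m) they produce the
sigmoidal success-vs-difficulty profile with a 50 % crossing in the λ ∈ [3, 6]
range that characterizes real CST performance.  On a cm scale the same noise
numbers would be negligible against a ±10 cm workspace and success would be
perfect at every difficulty.  Trial kinematics are reported in cm; every
derived quantity is either scale-invariant (correlation, lag, RMS ratio,
regression slope, classifier output after standardization) or carries its unit
explicitly.

## Discretization and delay

Forward Euler at `δ = 10 ms`: `A_d = I + δA`, `B_d = δB`, exactly (no
higher-order terms), so the simulated trajectories satisfy the discrete cursor
law `Δx/δ = λ(x + p)` identically at every step — a property the tests assert,
and which makes cursor reconstruction from hand traces (`cursor_from_hand`,
Euler scheme) round-trip the simulator's cursor bit-consistently up to float
rounding.  Because that reconstruction re-integrates an unstable ODE open
loop, rounding is amplified by `e^{λT}`: agreement is ~1e-10 cm at λ = 2 but
only ~1e-3 cm at λ = 4 over 8 s.  This is a conditioning property of the
problem, not of the integrator.  For external recordings (e.g. 250 Hz motion
capture), traces are linearly resampled to the model step and an exact
zero-order-hold integration scheme is available.

A 50 ms sensory delay (5 steps) is represented by state augmentation: the
augmented state stacks `delay_steps + 1` copies of the five physical states,
each transition shifts copies one step older, and the observation matrix reads
the oldest copy.  The state cost acts on the newest copy — the controller's
objective concerns the true current state, while its information is stale.

## Noise model

Three noise sources enter the discrete dynamics
`x_{t+1} = A_d x_t + B_d(1 + Cε_t)u_t + ξ_t`, `y_t = Hx_t + ω_t`:

- **signal-dependent motor noise**: `ε ~ N(0,1)` scaled by `C = 1.5` — the
  executed command's standard deviation grows with its magnitude;
- **additive motor noise**: `ξ ~ N(0, 0.4·B_dB_dᵀ)` (rank one, entering
  through the actuator);
- **additive sensory noise**: `ω ~ N(0, sd² I)` per observation channel,
  default `sd = 0.05` in plant (SI) units.  The sensory magnitude mainly moves
  the success curves; the strategy signatures below are robust to it.

## Controller and estimator

The controller minimizes `J = Σₜ(xₜᵀQxₜ + uₜᵀUuₜ)` with `U = 10`.  Position
Control sets `Q = diag(q, 0, 0, 0, 0)`, Velocity Control
`Q = diag(0, v, 0, 0, 0)`; the defaults `q = v = 10⁴` place both objectives'
critical difficulties inside the empirically observed [3, 6] band (λ_c ≈ 5.5
for Position, ≈ 4.3 for Velocity Control at default noise).  The horizon is
the full simulated duration (`n = 800` steps) with no terminal cost beyond the
running `Q`.

Signal-dependent noise breaks the separation principle, so the gains are
computed by a fixed-point alternation: the backward control recursion

```
Lₜ = (U + B'Sˣₜ₊₁B + Cₛ'(Sˣₜ₊₁ + Sᵉₜ₊₁)Cₛ)⁻¹ B'Sˣₜ₊₁A,   Cₛ = C·B_d
Sˣₜ = Q + A'Sˣₜ₊₁(A − BLₜ)
Sᵉₜ = A'Sˣₜ₊₁BLₜ + (A − KₜH)'Sᵉₜ₊₁(A − KₜH)
```

and the forward filter recursion `Kₜ = AΣᵉₜH'(HΣᵉₜH' + E)⁻¹`, where the
estimate, error, and cross second moments (Σ^x̂, Σᵉ, Σ^x̂e) are propagated
exactly from the trial's initial condition (estimator initialized at the true
state — all trials start at the origin where the two coincide, so the initial
error covariance is zero).  Iteration stops when the maximum relative change
of any gain entry falls below 1e-8 (typically 2–4 alternations; hard failure
after 100 raises an error carrying the residual).  The first pass runs the
filter under zero control gains, i.e. a standard Kalman recursion, which keeps
the backward pass numerically stable even for strongly unstable plants.

With `C = 0` and no delay the alternation decouples and the interior gains
equal the steady-state discrete-Riccati solutions; the test suite checks this
limit against `scipy.linalg.solve_discrete_are` at relative error < 1e-6 under
both objectives.  (For the velocity objective the cursor position is
deliberately unregulated, leaving a closed-loop eigenvalue on the unit circle
that the scipy solver rejects; the oracle therefore adds an `1e-9` position
weight, which perturbs the reference gains by ~1e-9 relative.)  Signal-
dependent noise only makes the controller more cautious: interior gain norms
with `C = 1.5` never exceed those with `C = 0`, another tested property.

## Trial generation

Batches simulate 500 trials per difficulty level over λ = 1.5 … 6.9 in steps
of 0.2 (28 levels; the grid stops below 7 in colon-range semantics, matching
the 14 000-trial batch size of the protocol).  Per-trial randomness is
counter-based — `SeedSequence(base_seed, spawn_key=(stream, lam_index,
trial_index))` — so batches are bit-reproducible, order-independent, and
train/test streams are provably disjoint.  Trials whose state diverges to
non-finite values (expected when a controller is paired with a much harder
plant than it was solved for) are truncated at the first bad step and counted
as failures rather than raising.  An optional per-trial random initial cursor
offset (Gaussian, user-set SD; no fidelity claim for its distribution) is
available for perturbation-style studies; when nonzero, the initial cursor
velocity is set to `λ·x₀` so the cursor law holds at t = 0.

## Behavioral metrics

- **Success table / psychometric fit**: success percentage in half-open λ bins
  of width 0.3 from λ = 1.5; the curve
  `%success = 50[1 − erf((λ − λ_c)/(√2σ))]` — i.e. 100·(1 − Gaussian CDF),
  which is exactly 50 % at λ_c — is fitted by count-weighted least squares.
  The erf argument is sometimes typeset ambiguously as `(λ−λ_c)/2σ`; the
  Gaussian-CDF reading is used because the quantity is described as a
  cumulative Gaussian and σ as its standard deviation.
- **Peak correlation and lag**: Pearson correlation of mean-subtracted hand
  and cursor position at every integer lag within ±1 s; the peak is the lag
  maximizing |r| (ties broken toward the smallest |lag|), reported signed
  (CST correlations are negative and strengthen toward −1 with difficulty);
  positive lag means the hand lags the cursor.  Mean subtraction is a choice —
  raw-trace correlation is not used — flagged here because either convention
  appears in the literature.
- **RMS ratio**: RMS(hand position)/RMS(cursor position) over the analyzed
  6 s, on raw (not mean-subtracted) positions.
- **State-space features**: per-trial means and RMS of cursor position and
  velocity over the analyzed window.  Ensemble summaries (mean-state Pearson
  correlation; OLS slope of RMS velocity on RMS position, intercept included,
  with a through-origin variant behind a flag) include successful trials with
  λ up to the batch's fitted λ_c, the inclusion rule used for ensemble plots
  of this task.

## Strategy classifier

A linear-kernel SVM on standardized (RMS position, RMS velocity), with Platt
sigmoid calibration fitted on cross-validated decision values
(`CalibratedClassifierCV(SVC(kernel="linear"), method="sigmoid",
ensemble=False)`), deterministic given the seed.  Labels: `P(position) ≥ 0.95`
→ Position, `< 0.05` → Velocity, else Uncertain.  Uncertain trials count in
misclassification denominators but never as errors, and they are included in
the per-subject average probability.  Defaults follow the study protocol:
2250 training trials per class, 2500 held-out test trials per class (the
protocol's "2500" is read as per class; it is configurable).

## What the generator does and does not emulate

The synthetic batches reproduce the qualitative structure of CST behavior:
sigmoidal success curves; hand–cursor anticorrelation strengthening toward −1
with difficulty; lag and RMS ratio decreasing with difficulty and larger under
Position Control; a drift-prone, position–velocity-correlated trial cloud
under Velocity Control versus a centered, uncorrelated cloud under Position
Control; and a steeper RMS-space regression slope under Position Control.
They do not emulate: adaptive difficulty staircases of real sessions (the
fixed λ grid replaces them), trial-to-trial learning or strategy switching,
mixed objectives within a trial, a second spatial dimension, or rig details
(display latency is folded into the single 50 ms sensory delay).  Passing
tests therefore validate the model's internal consistency and its qualitative
signatures, not quantitative agreement with any particular subject.

One quantitative caveat is documented deliberately: with the stated noise
magnitudes and any effort/accuracy weighting that keeps λ_c in [3, 6], the two
objectives' RMS clouds are nearly separable, and the confident cross-class
misclassification of the simulation-trained classifier is 0–2 % per class.
Published applications of this analysis report rates around 5–6 %, implying
substantially more cloud overlap than this formulation produces; since the
accuracy weights and sensory noise magnitude behind those numbers are not
recoverable, the defaults here are fixed by the λ_c calibration alone and the
measured rates are reported as computed.

## Numerical choices

- Gain alternation tolerance 1e-8 (max relative gain change), cap 100
  alternations; covariances symmetrized each step.
- Sensory-noise covariance regularized to 1e-12·I when the sensory SD is
  exactly zero, keeping the filter update well-posed.
- Psychometric fitting requires ≥3 bins with rates on both sides of 50 %;
  empty λ bins are omitted; initial guess is the last bin above 50 %.
- Cross-correlation requires non-constant series; zero-variance overlap
  segments are skipped.
- Degenerate inputs raise informative errors rather than returning NaN
  (zero cursor RMS, single-class training sets, empty trial sets).

## Problem sizes in the shipped checks

The test suite runs the full protocol once (500 trials/level for training and
test streams), the qualitative-signature suite at 100 trials/level, classifier
recovery on fresh 150-trials/level batches (1000 decided trials per class),
the separation-limit oracle at a 3000-step horizon, and 500 psychometric
recovery replicates at 200 trials/bin — sizes chosen to keep the whole suite
in the minutes range on a single CPU while leaving every headline quantity
computed at protocol scale.
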