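# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic cohorts do and do not emulate.

## Behavioral model

One model per mouse. Choices are Bernoulli with
p(right)\_{t,d} = logistic(x_{t,d} · β_d), where session *d* has its own
weight vector β_d = [β_bias, β_right, β_left, β_hist] and the regressors
are x = [1, x_R, −x_L, c_t]:

- **Stimulus.** The presented contrast S ∈ (0, 1] enters through
  x_side = tanh(αS)/tanh(α), which equals 1 at full contrast for every
  α > 0 and saturates below full contrast as α grows. The saturation
  absorbs the flattening of psychometric curves at high contrast that
  would otherwise require lapse parameters. Only the presented side's
  regressor is nonzero; the left regressor enters negated so that a
  positive β_left means greater sensitivity toward left choices and both
  stimulus weights grow positive during learning.
- **Choice history.** c_t = c_{t−1} + π(y_{t−1} − c_{t−1}) with choices
  coded ±1. c₁ = 0 at the start of *every* session: trials on different
  days are not temporally adjacent, so the filter does not carry state
  across session boundaries, and no pre-session history is fabricated.
  |c_t| ≤ 1 and c_t uses strictly previous choices only.

Across sessions the weights follow a multivariate Student-t random walk,
β_d ~ StudentT(ν, β_{d−1}, Σ), β₁ ~ StudentT(ν, μ, Σ). The shared scale
matrix Σ = D Ω D combines half-Normal(0,1) diagonal scales with an
LKJ(η)-distributed correlation Ω (η itself half-Normal(0,10)); small ν
lets a mouse make sudden session-to-session changes, large ν enforces
smooth trajectories. Priors on the shared scalars: ν ~ Gamma(2, 0.2),
λ ~ Normal(0,1) with π = Φ(λ), l ~ Normal(−2, 0.5) with α = softplus(l),
μ ~ StudentT(ν, 0, 5) elementwise. The transition distribution is taken as
the *multivariate* Student-t with scale Σ (an elementwise-t would never use
Ω), and the single ν is shared between the μ prior and all transitions.

### Inference

Posterior sampling is by a No-U-Turn sampler (dynamic Hamiltonian Monte
Carlo with slice sampling over the trajectory, dual-averaging step-size
adaptation targeting 0.9 acceptance, and windowed diagonal-metric
adaptation) over a fully unconstrained parameterization:

- log transforms for ν, η, σ;
- canonical partial correlations, tanh-mapped, for the Cholesky factor of
  Ω. The LKJ(η) prior is expressed directly in this space: the partial
  correlations are independent with symmetric Beta densities on (−1, 1),
  shape η + (K−2−j)/2 for column j — the exact pushforward of
  LKJCholesky(η), verified in the tests against the known Beta marginals
  of LKJ correlations;
- a **non-centered** random walk for the weights: β_d = β_{d−1} + A ε_d
  with A = diag(σ)·L the Cholesky factor of Σ and ε_d i.i.d. *spherical*
  multivariate Student-t(ν) innovations. Because the Student-t family is
  elliptical this reproduces the multivariate-t transitions exactly, and
  it removes the scale–weight funnel that makes the centered form
  unsamplable in prior-dominated regimes (in prior-only runs the centered
  version collapsed to step sizes ~2·10⁻³ and effective sample sizes of
  ~3; the non-centered version recovers the analytic prior exactly).

Gradients of the joint log density are computed analytically (verified
against central finite differences to ~10⁻⁹ and against an independently
coded naive-density oracle to 10⁻⁸). Chains are initialized from a coarse
data-driven profile: per-session ridge-logistic MAP weights on a grid of
(α, π), keeping the penalized-likelihood maximizer. This matters because
the posterior of α can sit many prior SDs from the prior mode; chains
started at the prior need most of the warmup just to travel there.
Divergent-transition fractions above 10% raise an explicit warning in the
fit diagnostics; split-R̂ and bulk ESS for the shared scalars come from
arviz.

### What recovery experiments show

The reference recovery experiment simulates one mouse for 20 sessions ×
300 trials with α = 2.5 and π = 0.52 and weight trajectories calibrated to
the psychometric performance of a well-trained animal (≈ 99% accuracy at
100% contrast, ≈ 65% at 6.25%, implying late stimulus weights ≈ 5, history weight 1.2 reflecting strong early
perseveration). With 2 chains × (500 + 500) draws the fit converges
cleanly (R̂ ≈ 1.00, no divergence warnings), per-session weights are
recovered with credible-interval coverage above 80% (typically ~95%), and
π is recovered within ±0.1. The posterior mean of α lands around 1.7–2.0
rather than 2.5: the Normal(−2, 0.5) prior on l places α = 2.5
about nine prior SDs from its mode (a ~39 nat penalty), while the
likelihood information about α at this trial count is capped at a
curvature of roughly 30 per unit α² — logistic saturation prevents larger
stimulus weights from sharpening it further — so the exact posterior mean
is prior-shrunk by ≈ 0.5. This is a property of the model at this data
scale, not of the sampler; profile-likelihood analysis reproduces the same
number.

## Synthetic cohorts

The generator emulates the task's statistical structure: uniform side and
contrast, quiescent durations drawn by rejection from an exponential of
mean 0.55 s truncated to [0.4, 0.7] s, reward (3 µl) iff the choice matches
the stimulus side. Ground-truth weight trajectories are parametric:
saturating-exponential stimulus weights A(1 − e^{−r d}) per side,
exponentially decaying initial bias, constant history weight. The default
cohort couples initial bias to side-specific learning rates so that early
bias predicts late stimulus-weight asymmetry. Two contrast sets are
supported: the 5-level training-task set (100/50/25/12.5/6.25%), used for
behavioral recovery, and a 4-level set (without 50%) matching the encoding
model's one-kernel-per-contrast layout; the generator default is the
4-level set.

Timing conventions the data do not pin down are simulator choices: first
movement uniform 0.2–0.8 s after stimulus onset, feedback 0.1 s later, a
fixed 1.5 s post-feedback period, 0.5 s inter-trial interval. Passive
pre-exposure sessions have 250–272 stimulus presentations, 10 s apart,
uniform over the 8 (side × contrast) conditions, and no choice or reward
events.

Photometry is synthesized as a sum of event-triggered 1 s kernels (smooth
gamma-like bumps, contralateral stimulus gain rising linearly with
contrast as 0.3 + 0.7·contrast, weaker flat ipsilateral responses, fixed
action kernels, positive reward / negative timeout outcome kernels), plus
white noise and a slow drift built from low-frequency sinusoids with
random phases. What the simulation does *not* emulate: hemodynamic and
motion artifacts, photobleaching trends beyond the sinusoidal drift,
indicator (GCaMP) onset/decay dynamics convolved with spiking, or any
nonlinearity between events and fluorescence. Passing tests therefore
certify the estimators under the model's own assumptions, not robustness
to those artifacts.

## Photometry preprocessing

dF/F uses a centered ±30 s rolling mean as F₀ with shrinking windows at
the session edges (no samples dropped, no NaNs); nonpositive baselines
abort with an error since they indicate corrupt input. z-scoring uses the
whole-session mean and SD. The QC criterion partitions the recording into
consecutive 10-minute blocks from session start; a transient is a
*maximal contiguous run* of samples jointly ≥ 1% dF/F and > 3 session SDs
(counted once however long, no gap tolerance), and the recording passes iff
every block contains one. A trailing partial block ≥ 5 min is evaluated;
shorter tails are ignored; recordings shorter than one block are evaluated
as a single short block and flagged. The 3-SD threshold uses the
dF/F-stage session SD (before z-scoring; after z-scoring the two scales
are equivalent). Stage tags (raw → dff → z) are enforced so stages cannot
be applied out of order. Resampling to 50 Hz is linear interpolation on a
uniform grid inside the original support.

## Encoding model

Kernels are 50 lags (1 s at 50 Hz), strictly causal. The raised-cosine
basis uses bumps ½(1 + cos(π(t − c_j)/w)) with centers linearly spaced
over [0, 49] and width w = 2× the center spacing, so neighbors cross at
half height and the columns sum to a constant away from the edges. The
default is 7 basis functions per kernel (a ~7× column reduction;
configurable). Events are aligned to the nearest sample.

The ridge fit treats the basis weights as Gaussian with precision γ and
the noise as Gaussian with variance σ_f². Both hyperparameters maximize
the log marginal likelihood. The intercept is excluded from the penalty,
implemented exactly by partitioned regression: the evidence is computed on
the column-centered problem (one eigendecomposition of X_c′X_c, then each
(γ, σ_f²) evaluation is O(p)), maximized over (log γ, log σ_f²) by
Nelder-Mead from three starts; the final β and Σ use the closed forms with
penalty matrix diag(0, γ, …, γ), so β = σ_f⁻² Σ X′f holds exactly at the
reported hyperparameters. With only two hyperparameters this joint search
is simpler and more robust than coordinate ascent and passes the same
local-maximum checks. Degenerate designs (non-finite evidence, p ≥ n) are
rejected.

Contrast dependence of the stimulus response is summarized per side as
L2(100% kernel) − L2(6.25% kernel) by default; the alternative
L2(100% − 6.25% kernel) is available via `metric="norm-of-diff"`. Both
are reported because descriptions of this quantity differ; the default is
the difference of norms. Model fit is summarized as R² over in-epoch
samples only (stimulus onset to 1 s after feedback, per trial).

## Learning correlates

Robust fits use Huber IRLS with tuning constant 1.345 (95% Gaussian
efficiency), an initial residual scale of 10, and MAD scale re-estimation
each iteration. Deviance is Σρ(rᵢ/s)·s² at convergence (the scale factors
cancel in the quadratic regime, so with c → ∞ pseudoR² reduces to the
classical R², tested to 10⁻⁶ against OLS). The null deviance comes from an
intercept-only robust fit. pseudoR² can be negative for pathological fits;
r is then NaN with a warning rather than an imaginary number. Median
splits assign the median element (odd n, or ties) to the weak group,
making the split deterministic; group inference on per-mouse r values is a
two-sided one-sample t test. Session bins are early 1–7, middle 8–14,
late 15–20, with out-of-range sessions rejected. Mixed-model inference
itself is out of scope: the module emits the coded long-format table
(session bin, mean-subtracted region metric, weight values) for external
statistical tools.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical configuration and seed give
bit-identical simulator output and identical MCMC draws. The shipped test
suite and the acceptance script use one full-scale recovery fit (20
sessions × 300 trials, 2 × (500+500) draws, a few minutes on one CPU);
unit and property tests use smaller fixtures (tens of trials, reduced
chains) chosen to keep the whole suite fast while still exercising every
code path at meaningful sizes.

## Known limitations

- The behavioral model is per-mouse; there is no cross-mouse hierarchy,
  no trial-to-trial weight dynamics, and no discrete-state (engaged /
  disengaged) structure.
- α is weakly identified at small data scales and its posterior mean is
  prior-shrunk even at the reference scale (see above); comparisons of α
  across datasets should use matched trial counts.
- The evidence optimization assumes a single shared γ for all kernel
  columns (no per-kernel relevance determination).
- QC block anchoring at session start is a convention; other partitions
  of "every 10 minutes" are defensible and would change marginal cases.
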