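# Methods

This note documents the model, the synthetic study conditions, and the
numerical and design choices behind `flexcontrol`, in enough detail to
re-derive or deliberately change any of them.

## The generative belief model

The agent believes that the probability `f` of encountering an incongruent
trial can change over time, at a rate governed by a volatility state that we
represent directly as a flexible learning rate `α`. Both live on a discrete
grid: by default 50 × 50 midpoint nodes of (0,1) × (0,1), uniform prior.
Grid size is a pure discretization choice; doubling it changes the filtered
conflict trace by < 0.02 RMS (tested), and 50 × 50 keeps a 768-trial filter
pass around a tenth of a second.

Per trial, in order:

1. **Learning-rate transition.** With probability `k_stay` (default 0.95)
   the learning rate keeps its value; otherwise it jumps uniformly to any
   node. Applied per f-slice, so the conflict marginal is untouched. The
   sticky-or-jump form encodes that control demands usually stay put; the
   uniform jump avoids assuming any knowledge of the task's block structure.
   With much higher stickiness (0.99) the learning-rate belief becomes so
   slow that volatility credit earned in one run leaks into the next and the
   run-type contrast degrades; 0.95 (memory of ~20 trials, one block) is the
   default.
2. **Conflict propagation.** The belief over `f` is spread through a beta
   kernel conditional on each `(α, f_old)` node, with parameter sum
   `s(α) = s_min + c/α` (defaults `s_min = 2`, `c = 2`), rows renormalized
   on the grid. Larger `α` ⇒ smaller sum ⇒ wider kernel ⇒ faster effective
   learning. The kernel is **mean-parameterized** (`a = f·s`,
   `b = (1−f)·s`): centring by the mode instead (available as
   `kernel_param="mode"`) introduces a per-trial drift of the belief mean
   toward 0.5 of order `(2f−1)/s` that a single Bernoulli observation per
   trial cannot cancel, and in our experiments it caps stationary tracking
   of an 80% stream at ~0.65 regardless of `s`. Mean-centring removes the
   drift; residual shrinkage (tracking ~0.78 rather than 0.80) comes from
   boundary truncation on the grid. The width scale `c = 2` was calibrated
   once, before the test suite was frozen, to jointly satisfy the model's
   qualitative signatures (stationary tracking, delta-rule slope near 1,
   volatile-vs-stable learning-rate separation); it is a config hook.
3. **Congruency update.** Multiply by `f^o (1−f)^{1−o}` and renormalize.
4. **Reaction-speed update** (flexible control variant only). Multiply by
   `N(RS; a_c + b_c f, σ_c)` for the trial's congruency `c`; computed in
   log space with a max-shift before exponentiation so extreme observations
   (e.g., injected outliers) cannot underflow the whole grid. Trials without
   a response skip only this step — the congruency observation is still
   processed, so the belief sequence covers every trial.

Pre-stimulus summaries are recorded after steps 1–2 and before 3–4: the
posterior means `α̂`, `f̂`, the estimation uncertainty (s.d. of the conflict
marginal), and the control prediction error `|o − f̂|`. With congruency-only
updating, the filter reduces empirically to a delta rule
`f̂_{i+1} ≈ f̂_i + α̂_i(o_i − f̂_i)`: the update moves toward the observation
on every trial and the regression slope of the increment on `α̂(o − f̂)` is
~0.56 over a full experiment.

## Hyperparameter fitting (EM)

The congruency-specific emission parameters `(a_c, b_c, σ_c)` are fitted by
alternating (E) a filter pass producing the pre-stimulus `f̂` sequence with
(M) per-congruency least squares of RS on `f̂` (residual s.d. → `σ_c`,
floored at 1e-3). Iteration stops when the largest parameter change falls
below 1e-4, when the one-step-ahead predictive log-likelihood of RS stops
improving (forward filtering gives no exact ascent guarantee, so a stalled
objective marks convergence and the previous parameters are kept), or at
100 iterations. In practice convergence takes ~5 iterations. `k_stay` is
not optimized. Parameter recovery on simulated subjects: median relative
error ~1% for intercepts and ~9% for slopes over 20 seeds (tested).

## Synthetic study conditions

The generator reproduces the factorial task design exactly: 8 runs × (one
16-trial burn-in block at 50% incongruent + four 20-trial blocks), stable
runs fixed at 20% or 80% incongruent, volatile runs alternating 20↔80 every
block, two runs of each of the four kinds, order shuffled per subject.
Blocks use **exact counts** (a 20-trial block at 80% holds exactly 16
incongruent trials, uniformly shuffled) rather than i.i.d. draws, making
the within-class incongruent incidence exactly 0.5 and design checks
deterministic; within-block order is unconstrained.

Behaviour: latent conflict predictions come from the congruency-only filter
(the generative core); `RS ~ N(a_c + b_c f̂, σ_c)`, truncated at 0.1 s⁻¹.
Defaults: `b_con = −0.4`, `b_inc = +0.4`, `σ = 0.25` s⁻¹, and intercepts
`a_con = 2.6`, `a_inc = 2.0` s⁻¹. The intercepts anchor the canonical
marginal reaction times (~417 ms congruent, ~455 ms incongruent) at the
task's operating point `f̂ ≈ 0.5`; anchoring them at `f = 0` instead would
let the slopes reverse the congruency ordering at realized conflict levels.
With these values the generator satisfies
`RS = 2.6 − 0.2·o − 0.4·|o − f̂| + noise`, i.e., responses are slower on
incongruent trials and under larger prediction error — the sign structure
the behavioural analysis is meant to recover. Errors are injected i.i.d.
at 5.8% (matching ~94.2% accuracy); error trials carry no RT. A further 1%
of correct trials have RT tripled, giving the 2.5-s.d. outlier filter
something to catch. For cohorts, each subject's emission parameters are
jittered multiplicatively by ±10% (uniform) to create realistic
between-subject variance.

What the generator does **not** emulate: post-error slowing (excluded from
the model's scope), stimulus identity, sequential stimulus-priming
structure, and — importantly — any belief variability beyond the congruency
stream. That last point has a consequence worth stating plainly: for
synthetic subjects, reaction speed carries no information about the latent
beliefs that the congruency sequence does not already carry, so RS-based
belief updating can only add noise here, whereas on real subjects it is the
mechanism for capturing individual differences. Passing tests therefore
demonstrate internal consistency and recoverability under the model's own
assumptions, not that real behaviour obeys them.

## Model comparison

Per subject, three models produce a per-trial conflict prediction: the
flexible model (its congruency-driven belief core; zero free parameters),
a one-rate delta rule, and a two-rate delta rule with the rate switched by
run type (run type known a priori — the only reading under which "one rate
per run type" is well defined), both fixed-rate models starting at
`f_0 = 0.5` with no reset across runs, searched exhaustively on
0.01–0.5 (step 0.001; ties go to the smallest rate, product grid scanned
with the stable rate as the slow axis). The flexible model is scored by its
belief core deliberately: the RS-augmented filter exists to infer beliefs
from real behaviour, and under the synthetic conditions above its RS
updates strictly corrupt the reconstruction of the generating beliefs
(~12 BIC points per subject), turning a model-recovery comparison into a
comparison of inference plumbing. The emission mapping from prediction to
RS is profiled out by per-congruency least squares identically for all
three models, so BIC parameter counts are 0 / 1 / 2 (learning rates only).

Two evidence measures: `BIC_RS = n ln σ̂² + k ln n` on the retained trials'
RS residuals, and `BIC_cong = −2 Σ ln(1 − |o_i − f_i|) + k ln n` with
per-trial likelihoods floored at 1e-12. Group-level inference follows
random-effects Bayesian model selection: log evidence `−BIC/2`, uniform
Dirichlet(1,…,1) prior over model frequencies, variational updates of
subject responsibilities and Dirichlet counts to 1e-6, exceedance
probabilities from 10⁵ seeded Dirichlet draws.

## Behavioural analysis

Exclusions, in priority order when several rules hit one trial: error,
post-error, outlier (RT > 2.5 s.d. from the subject's grand mean — mean and
s.d. over correct-response RTs only, since error RTs are not meaningful),
post-outlier, burn-in. Post-trial flags do not cross run boundaries. Model
estimates for excluded trials are discarded, not re-estimated.

The GLM standardizes `α̂`, `f̂`, `o` on the retained trials (z-scores;
standardization after exclusion) and forms their interactions as products
of the standardized mains, except the conflict-by-congruency term, which
enters as the standardized unsigned prediction error `|o − f̂|`. Because
`|o − f| = o + f − 2of`, its residual against the mains is exactly −2 times
the residual of the plain product, so inference is identical up to sign;
this orientation makes the coefficient directly readable as "responses slow
when conflict was mispredicted". Each regressor's unique effect is the
coefficient of its residual (after regressing it on all other columns plus
the constant) in the RS model — numerically identical to the joint-OLS
coefficient by Frisch–Waugh–Lovell, which the tests assert to 1e-8. Group
inference: two-sided one-sample t-tests of per-subject coefficients. The
normality premise of the RS emission is screened per subject × congruency
with Kolmogorov–Smirnov tests against a Gaussian with the sample's own
moments, Benjamini–Hochberg corrected; with estimated parameters this
screen is conservative under the null.

## Problem sizes and runtime

The full study uses 21 subjects × 768 trials, a 50 × 50 grid, the 491-point
(one-rate) and 491² (two-rate) search grids, and 10⁵ Monte-Carlo samples for
exceedance — about two minutes on one CPU, dominated by the per-subject EM
and the two-rate product-grid scan (which accumulates per-congruency OLS
sufficient statistics online rather than materializing candidate × trial
traces). All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawns, so every table and probability in the
report is exactly reproducible.

## Known limitations

- The grid filter is a forward (filtering) algorithm; no smoothing pass, so
  early-trial estimates do not use later evidence, matching how the model
  variables are used as trial-wise regressors.
- The beta-kernel width mapping `s(α)` and `k_stay` are structural choices,
  not fitted quantities; conclusions about the numeric value of `α̂` are
  only meaningful relative to a fixed mapping.
- The exceedance computation assumes BIC differences are usable as log
  evidence ratios; no bridge sampling or free-energy evidence is attempted.
- With congruency-only updating the belief trajectory is a deterministic
  function of the congruency sequence; two synthetic subjects with the same
  sequence differ only through their emission parameters and noise.
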