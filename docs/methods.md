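# Methods

This note documents the models, conventions and numerical choices behind
`probswitch`, and what the synthetic-data pipeline does and does not
establish.

## Task generative process

A block is 150 trials of a two-box bandit. The correct box starts on the
left, pays reward with probability 0.75; the incorrect box pays with
probability 0 (both configurable, with the constraint
`p_incorrect ≤ p_correct`). After the participant accumulates a criterion
number of rewarded correct choices — drawn uniformly from {5,…,15} — the
correct box reverses sides, effective on the trial immediately after the
criterion-completing rewarded choice. That next trial is flagged
`reversal_trial` and defines t = 0 for switch-aligned analyses.

Two construction details are deliberate:

* **Exact-proportion outcome sequences.** Reward outcomes for correct
  choices are pre-randomized rather than sampled online: flags are built in
  shuffled chunks of 20 containing exactly 15 ones, so any fully consumed
  chunk realizes 75% exactly while remaining unpredictable trial-to-trial.
  Switch criteria are likewise drawn offline. Four seeded sequence versions
  are generated per configuration and assigned to participants; two-block
  players get distinct versions.
* **Sequence exhaustion.** If a play pattern consumes all pre-generated
  flags or criteria, the schedule extends itself from its own seeded stream;
  sessions never truncate.

Non-responses (the 3-second timeout analogue) are logged with
`responded=False`, consume no reward flag, and do not advance the criterion
count — the criterion counts rewards, which require choices. Sides are
encoded left = 0, right = 1 everywhere, matching the signed regression
coding below.

## Choice models

Both models maintain a two-component internal state and share the policy
`p(a) = exp(β·W(a)) / Σ exp(β·W(·))` with `W(a) = V(a) + st·1[a = a_prev]`,
where `st ∈ [−1, 1]` is a sticky-choice bonus and `β ≥ 0` the inverse
temperature. No stickiness is applied before the first responded trial.
The softmax is evaluated as a logistic in `β(W_left − W_right)` for
numerical stability.

**RL (Q-learning with counterfactual updating).** Values start at
`Q = (0.5, 0.5)` (the uninformative midpoint for binary outcomes; agents
are not told that the task starts with left correct). After choosing `a`
and observing `r ∈ {0,1}`:

    Q(a)  ← Q(a)  + α·(r − Q(a))
    Q(ā)  ← Q(ā)  + α·((1−r) − Q(ā))

with `α = α⁺` when `r = 1` and `α = α⁻` when `r = 0`. The unchosen action
is updated toward the opposite outcome with the *same* outcome-selected
rate — there is no separate counterfactual learning rate. Both updates use
pre-update values. Simpler variants (shared α, `st = 0`, counterfactual
updating off) are exposed as configuration restrictions of the same code
path (`rl-nested:*` model tags), not separate models.

**BI (latent-state filtering).** The belief `b = p(C = left)` starts at
0.5. The emission model is `p(r=1 | a = C) = p_reward` and
`p(r=1 | a ≠ C) = ε` with `ε` fixed at 10⁻⁴ — small because the incorrect
box never pays, nonzero to avoid degeneracy. After each outcome the belief
is updated by Bayes' rule and then propagated through a symmetric switch
kernel, `b' = (1 − p_switch)·post + p_switch·(1 − post)`; the stored state
is the next trial's prior, and the sticky bonus applies to that prior, as
the policy equation dictates. A zero normalizer in the Bayes step raises
rather than silently renormalizing (it cannot occur for `ε > 0`).

**Likelihoods.** Session log-likelihood walks the trial sequence, scoring
each responded action with the pre-update choice probabilities. Non-responded
trials contribute nothing and trigger no update; the previous action carries
over for the stickiness bonus. Multiple blocks are treated as independent
sequences with state reset at block start (blocks were separated by an
unrelated task; no carry-over rule is assumed). The fitting path uses
compiled (numba) kernels; a plain step-by-step evaluator serves as the
reference implementation, and the tests additionally check the Bayesian
filter against exhaustive enumeration over all 2^T latent-state paths.

## Hierarchical estimation

Subject-level parameters are drawn from group-level laws: beta for
unit-interval parameters (α⁺, α⁻, `p_reward`, `p_switch`), gamma
(shape/rate) for β, and normal truncated to [−1, 1] for `st` — the
truncation honors the parameter's defined support while keeping a normal
group law. Hyperpriors: gamma(1,1) on all beta/gamma hyperparameters,
N(0, 10) on the `st` group mean, half-N(0, 10) on its spread.

Sampling exploits the model's conditional structure. Given the
hyperparameters, subjects are independent, so the sampler alternates, several
rounds per recorded sweep:

1. **Subject blocks** (all subjects in parallel, compiled likelihoods):
   one Metropolis proposal per free dimension in unconstrained coordinates
   (logit for unit parameters, log for β, raw for `st`), with
   per-(subject, dimension) step sizes adapted toward 44% acceptance during
   warm-up; plus one joint multivariate proposal per subject along a local
   covariance estimated from warm-up history (refreshed twice, frozen at
   warm-up end), with occasional triple-scale kicks to hop between nearby
   modes. Proposals outside fixed coordinate boxes are rejected, which is a
   valid Metropolis step on the truncated support.
2. **Hyperparameter blocks**: coordinate-wise slice sampling on each
   parameter's hyper pair, using sufficient statistics of the subject
   column, so these updates are essentially free and mix well.

Iteration counts follow the Stan convention: `n_iterations` is total sweeps
per chain including warm-up. Defaults are 4 chains × 1,000 warm-up / 5,000
total; the package's reduced setting (2 chains × 500/500, used throughout
the tests and the acceptance script) holds the same diagnostic thresholds.
A fit is flagged converged when max split-R̂ < 1.01 and min ESS > 40 across
all free parameters (arviz); a random-walk sampler has no divergent
transitions, so the divergence count is structurally zero. Non-convergence
returns a flagged fit with a warning rather than raising. Point estimates
are posterior means on the natural scale. Participants with zero responded
trials are excluded with a warning.

**WAIC** is computed from pointwise posterior log-likelihood draws (thinned
to ≤500 draws): `waic = −2·Σᵢ (lppdᵢ − pᵢ)` with `pᵢ` the *sample* variance
(ddof = 1) of the pointwise log-likelihood, following the convention of
Stan's `loo` package; arviz uses ddof = 0, and the test suite checks
agreement after converting between conventions. The standard error follows
the usual `2·√(n·var(elpdᵢ))` form.

**Generate-and-recover** simulates a cohort from the default group laws,
refits, and reports per-parameter Pearson correlations between generating
and recovered subject parameters. At 20 participants × 300 trials the
package's acceptance bar is r > 0.6 for α⁺ and β and r > 0.5 for `st`
(typical values observed are 0.8–0.97). **Posterior-predictive checks**
re-simulate each participant at their posterior-mean parameters on fresh
schedules and compare the full behavioral summary.

## Behavioral statistics

All history windows are within-block, and a window containing a
non-responded trial is discarded (outcome symbols are undefined there); the
first three trials of each block are therefore ineligible for the 3-back
table, the first two for the aB analysis.

* Performance is correct/responded; non-responses are excluded from both
  numerator and denominator.
* The 3-back table conditions `p(stay)` on the outcomes at (t−3, t−2, t−1),
  "+" = rewarded. Conditions with zero eligible trials carry a missing
  value, never zero. Per-participant tables are the primitive; pooled tables
  are count-weighted.
* The aB analysis keys each eligible trial by the outcome at t−2, whether
  t−1 was a stay or a switch ("a"/"b"), and the outcome at t−1, reporting
  `p(a)` = probability of choosing the t−2 action. **Case convention:**
  lowercase = unrewarded (so "ab" reads "unrewarded a, then an unrewarded
  switch to b"). The convention is a single named constant
  (`metrics.LOWERCASE_UNREWARDED`) and every table-producing function takes
  a flip flag, because the opposite reading also appears in the literature.
  Participants with `p(a|ab) = 0` (never returning after an unrewarded
  switch) are treated as outliers and dropped from that correlation by
  default (toggleable).
* Exclusion criteria (minimum accuracy 0.55, minimum response rate 0.8,
  optional two-block completeness) are configuration, not constants: the
  performance criterion used in the original data collection is not public,
  so the default is a package choice.

## Trait analysis

The questionnaire schema is structural: 20 items, responses 1–4, five
4-item subscales, twelve reverse-scored items mapped `r → 5 − r`. Which
twelve items are reversed is not public; the shipped default (the first
three subscales' items) is an editable placeholder — every analysis depends
only on the schema's structure. Totals range 20–80, subscales 4–16;
z-scoring is over the analyzed (post-exclusion) cohort.

Correlations use a normality gate: Shapiro–Wilk on *both* variables at
α = 0.05; Pearson only if both pass, Spearman otherwise. The report names
the method and both gate p-values. Median splits send ties to the low group
(deterministic); a one-group split is flagged degenerate. Bonferroni gating
rejects at `level / family_size` and reports raw and adjusted decisions.

The choice regression codes, for each lag i ∈ {1,2,3}, `pos_i = −1/+1` if
the left/right box was rewarded at t−i and 0 if no reward occurred, and
`neg_i` likewise for non-rewards — so exactly one of `pos_i`, `neg_i` is
nonzero per responded lag. Interaction columns multiply the z-scored trait
total into each predictor. The random-intercept logistic model is fitted by
statsmodels' variational-Bayes binomial mixed GLM, with Wald-style z and p
values from the posterior mean and SD, and Nakagawa marginal/conditional
pseudo-R² (logistic residual variance π²/3). The tests cross-check the
fixed effects against an independent `glmer` (R lme4) fit. Mean-field VB can
slightly understate posterior SDs; at the row counts used here (≈20,000)
the fixed effects are tightly identified and the approximation is benign.
Per-subscale analyses are the same operations parameterized by subscale
score, reported uncorrected.

## Synthetic cohorts

The generator emulates the study conditions: 70 participants (configurable)
playing 1–2 blocks of 150 trials, choices from the RL or BI model (or a
scripted policy: win-stay/lose-switch, always-stay, always-switch, random,
oracle, lag-1 oracle), parameters drawn from group laws, and questionnaire
responses consistent with planted trait totals.

Default group laws — α⁺ ~ Beta(5,5), α⁻ ~ Beta(4,6), β ~ Gamma(6, 1.2)
(mean 5), st ~ N(0.15, 0.3) truncated to [−1,1] — were calibrated once so
that simulated groups reproduce the canonical group-level signature of this
task: accuracy collapses at t = 0 after a reversal, recovers within 2–3
trials, and overall accuracy sits near 75%. They are plausible settings,
not estimates from any dataset.

Trait totals are drawn from N(40, 8) clipped to [26, 63] and rounded — a
spread typical of undergraduate samples. Item responses are
reverse-engineered by distributing the points above the floor uniformly at
random across items (respecting the 1–4 range) and inverting the reverse
coding, so re-scoring returns the planted totals exactly.

**Plants.** A plant couples the trait latent to a parameter latent in a
Gaussian copula with correlation ρ, preserving both marginals and the
generative model. Behavioral-tendency targets are realized through the
monotonically related parameter: "stay_tendency" modulates `st`. Because
the parameter → behavior chain attenuates correlations, tendency plants
divide ρ by a fixed calibration constant (0.75, measured once from
large-cohort simulation under the default laws) so the *realized*
trait–tendency correlation matches the request; tendency plants with
|ρ| > 0.75 are rejected as infeasible, and the calibration is approximate
under custom group laws.

**What passing tests do not show.** Synthetic cohorts have perfect response
rates, stationary parameters, no reaction times, no session effects, and
questionnaire items that are exchangeable within subscale. Pipeline
correctness and recoverability on these cohorts does not establish that the
models capture individual differences in real populations — indeed the
study motivating this package found group-level fits that did not reproduce
trait effects.

## Problem sizes and runtime choices

The test suite and acceptance script use reduced but statistically adequate
sizes chosen as package defaults: 20 participants × 2 blocks with
2 chains × 500/500 sweeps for convergence and recovery checks, 8 × 1-block
cohorts for the seeded WAIC model-recovery replicates, and 70 × 2 blocks
for the end-to-end trait analyses (matching the study's final sample size).
Compiled likelihood kernels make a full hierarchical fit take on the order
of a minute on one CPU.
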