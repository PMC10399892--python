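# Methods

This note documents the models, the synthetic-data generator, the
sampler, and the design choices behind `asymrl`, in enough detail to
re-derive any number the package computes.

## Task environments

Two generators emulate standard probabilistic instrumental-learning
designs with two options and partial feedback (only the chosen option's
outcome is revealed).

**Stable design.** Four mini-blocks, each a fresh cue pair with constant
reinforcement probabilities — (40, 60), (25, 75), (25, 25) and (75, 75)% —
and 32 trials per mini-block by default.  Block order is a uniformly
random permutation per subject.  Because each mini-block introduces novel
cues, value estimates re-initialise to Q₀ at every mini-block start; a
subject's Q₀ is shared across blocks and options.

**Restless design.** One 100-trial block per condition.  Each option's
reinforcement probability starts from an independent Uniform(0.25, 0.75)
draw and moves ±0.05 per trial with probability ½ each, reflected off the
boundaries: p′ = 1.5 − p above 0.75, p′ = 0.5 − p below 0.25.  A value
exactly on a boundary is legal and unreflected.  One reflection suffices
because steps are smaller than the interval.

**Outcome coding.** Outcomes are coded in units of ±1: gain condition
{+1, 0}, loss {−1, 0}, mixed {+1, −1}.  The "reinforcement probability"
is always the probability of the salient event — a win in gain, the
*penalty* in loss — so a frequently reinforced loss option is a bad
option, and the correct choice there is the option with the lower
reinforcement probability.  (The one-line verbal statement of this coding
in the source literature transposes the labels; the coding used here is
the only one consistent with the Q₀ bounds below and with the sign of
fitted initial values.)

## Learner

The chosen option's value updates by Q ← Q + α·(r − Q), with α = α_P when
the prediction error r − Q is ≥ 0 (ties take the positive branch,
matching the defining equation) and α = α_N otherwise.  The unchosen
option is never updated.  Choices are softmax in the value difference
with inverse temperature β ∈ [0, 20].  Q₀ applies to both options and is
bounded by the condition's worst and best outcome: [0, 1] gain, [−1, 0]
loss, [−1, 1] mixed.

Six variants cross asymmetric/symmetric rates with free/fixed Q₀:
A-VI, S-VI (free Q₀); A-FI, S-FI (Q₀ = mean outcome: 0.5 / −0.5 / 0);
A-FI0, S-FI0 (Q₀ = 0 everywhere).  Symmetric variants impose α_N = α_P.
All variants are nested inside A-VI, and the likelihood code is shared,
so the nesting identities hold to machine precision (tested).

## Hierarchical model

Per condition (conditions are fitted separately), subject i's raw
parameters θ′ᵢ — Q₀′, α_P′, the asymmetry offset δ, and β′, as
applicable to the variant — are drawn from N(μ_θ′, σ_θ′) with priors
μ_θ′ ~ N(0, 2) and σ_θ′ ~ half-Cauchy(0, 5).  The N(0, 2) notation is
read as standard deviation 2 (configurable via `FitConfig.mu_prior_sd`).
Natural parameters are θ = θ_min + Φ(θ′)(θ_max − θ_min) and
α_N = Φ(α_P′ + δ), so μ_δ is the group-level learning asymmetry and is
the quantity pooled and classified in the recovery study.  β is pooled
hierarchically in all variants.

## Sampler

The posterior is sampled with an adaptive Metropolis-within-Gibbs scheme
that exploits the conditional structure of the hierarchy; any correct
sampler would do, and this one is validated against closed forms (below).
Each iteration performs:

1. **Subject blocks.** Given the hypers, subjects are conditionally
   independent; each subject's raw vector takes one joint random-walk
   Metropolis step, vectorised across subjects.  Because the per-subject
   posterior is strongly correlated across (Q₀′, α_P′, δ, β′), the
   proposal uses a per-subject covariance learned during warmup
   (adaptive Metropolis: Welford moments, Cholesky refreshed every 25
   warmup iterations, scale adapted toward 28% acceptance).
2. **Hyper means.** Conjugate normal Gibbs draws.
3. **Hyper sds.** Random-walk Metropolis on log σ with the Jacobian
   correction, adapted toward 44% acceptance.
4. **Interweaving.** Per parameter, a joint (μ, log σ) Metropolis move in
   the non-centered parameterization (subject z-scores held fixed).  This
   is the ancillarity-sufficiency interweaving strategy and is what keeps
   the sampler mixing in the funnel regime σ → 0, which the recovery grid
   hits by construction (all subjects in a cell share one true parameter
   set).
5. **Group translation.** A joint shift of μ and every subject's raw
   vector along directions drawn from a covariance learned from the μ
   trace — the analogous move for cross-parameter correlation of the
   group means.

All adaptation uses Robbins-Monro decay and stops at the end of warmup,
so the retained draws come from a fixed transition kernel.  Chains are
initialised from overdispersed draws of the priors' bulk; a non-finite
initial likelihood is re-drawn (50 attempts) before failing with the
offending subjects named.

**Correctness checks.** With hypers fixed and the RL likelihood replaced
by a Gaussian one, the sampled subject posteriors match the normal-normal
conjugate closed form; with a flat likelihood, the μ marginal reproduces
its N(0, 2) prior.  The likelihood itself is checked against an
independent plain-Python recursion and the constant-α exponential-recency
closed form at 1e-12.

**Chain geometry.** The default (`FitConfig.paper()`) keeps 4 chains ×
6000 draws after 4000 warmup each — 24,000 draws per parameter.  Two
smaller profiles exist for iterative work: `reduced` (4 × 2000/2000) and
`test` (2 × 1500/1500), the profile used by the test suite and the
acceptance script.  Point estimates are trimmed means discarding
floor(0.10·n) samples per side (the rounding rule is a package choice).
Convergence is monitored by split-R̂ (threshold 1.05, configurable) and
bulk ESS (via ArviZ); exceedances are warned about and recorded on the
`PosteriorDraws` object, never silenced.  At the `test` profile the
group-sd chains in near-zero-heterogeneity cells can still show R̂ up to
~1.2; the scientific quantities (μ draws, natural-scale trimmed means)
are stable across seeds and profiles, and the full-scale profile is the
one intended for reported fits.

## Model comparison

DIC is computed at the individual level: the deviance trace is the
per-subject −2·log-likelihood over retained draws, D̄ its mean, and the
plug-in D̂ is evaluated at each subject's trimmed-mean natural
parameters; p_D = D̄ − D̂ and DIC = D̄ + p_D.  Both terms decompose
additively over subjects (tested to 1e-8), which motivates the
subject-wise approximate log evidence −DIC_i/2 feeding group-level
random-effects Bayesian model selection.  How exactly a hierarchical DIC
should be converted to subject evidence is under-specified in the
source analyses; this proxy is one defensible choice and is isolated
behind the evidence-matrix contract, so it can be swapped without
touching the BMS code.

The BMS itself is the standard variational Dirichlet scheme: iterate
subject-wise model assignments g_nk ∝ exp(lme_nk + ψ(α_k) − ψ(Σα))
against α = α₀ + Σ_n g_n (α₀ = 1) to convergence; exceedance
probabilities by Monte-Carlo over the Dirichlet posterior (default 10⁶
draws, seeded); the Bayes omnibus risk from the free-energy comparison
of this model against the null of equal frequencies, F₀ = Σ_n
(logsumexp(lme_n) − log K); and PXP = EP·(1 − BOR) + BOR/K.  Unit
behavior (uniformity, dominance, the K = 2 beta-tail closed form, shift
invariance) is tested.

## Recovery study

The factorial generator crosses Q₀ ∈ {0, 0.25, 0.5, 0.75, 1} with seven
(α_P, α_N) pairs from (0.1, 0.7) to (0.7, 0.1), 30 datasets per cell and
30 subjects per dataset, β = 10 (a β = 5 sensitivity setting is a
one-line config change), on either task; the full grid is 1050 datasets.
Desk-scale analyses (tests, acceptance script) use a 3 × 1 × 5 sub-grid
with the same per-dataset size — 5 replicate datasets of 30 subjects ×
100 trials per cell — which is sufficient to resolve the bias signatures
with margin.  Bias is estimate − truth at the subject level, averaged
within cell; the pooled asymmetry analysis concatenates μ_δ draws across
a cell's replicates and classifies the asymmetry by the sign of the
pooled median, with a zero-truth cell counted correct iff the central
95% interval covers 0.  Loss-condition grids mirror the Q₀ levels onto
[−1, 0].

Expected signatures, all reproduced by the test suite: A-VI recovers its
own parameters with no systematic bias; A-FI (Q₀ pinned at 0.5 in gain)
overestimates α_P and underestimates α_N when true Q₀ < 0.5, flips both
signs when true Q₀ > 0.5, and is unbiased at the pinned value; at true
Q₀ = 0 with symmetric rates the pooled A-FI asymmetry posterior puts
essentially all its mass on α_P > α_N — a decisive miscategorization —
while A-VI's interval covers zero.

Two scale choices deserve note.  The four-variant model-recovery check
uses the stable four-mini-block task: Q₀ re-applies at each of four block
starts there, so a 128-trial session carries four times the initial-value
signal of a single-block session, and the generating model is identified
decisively (PXP ≈ 0.97–1.0 across seeds) at 30 subjects.  On the
single-block restless task the per-subject evidence differences are
small and the protected EP is honestly shrunk toward uniform — a
property of protected model selection, not a defect.  Likewise the
PRR–Q₀ association (below) is computed on equal-probability blocks fitted
in isolation; in a joint fit of all four blocks the hierarchical prior
shrinks per-subject Q₀ toward the group mean and the correlation washes
out.

## Behavioral summaries

Learning curves report the rate of choosing the higher-expected-value
option by within-block trial position; equal-probability blocks have no
correct option and are reported as an explicit undefined marker, with the
preferred-response rate (PRR — the choice rate of the option the subject
picked most often, in [0.5, 1]) used there instead.  A fixed-effects
logistic regression of staying on the previous outcome (IRLS, implemented
in-module, separation flagged at |coef| > 15) provides the win-stay
sanity check; random-slope mixed models are out of scope.  Pearson
correlations and paired t statistics are computed from their closed
formulas with scipy supplying only the reference distributions.  In
simulated 75/75% gain blocks with subjects' true Q₀ spread over [0, 0.5],
the fitted Q₀ correlates negatively with PRR (r ≈ −0.4 to −0.65 across
seeds): the lower the prior expectation, the more the first win locks the
agent onto one arm.

## What the generator does and does not emulate

The synthetic data reproduce the reinforcement structure, trial counts,
outcome coding, block randomization and partial feedback of the two task
designs, and choice behavior of exact softmax Q-learners.  They do not
emulate reaction times, response deadlines and re-prompts, practice
blocks, screen-side counterbalancing, monetary conversion, attention
lapses, or any departure of human choice from the fitted model family
(perseveration kernels, decaying rates, counterfactual updating).
Passing recovery tests therefore certifies the estimation machinery —
that the pipeline recovers what generated the data, and mis-attributes
it in the predicted way when Q₀ is pinned — not that the model family is
a complete account of human learning.

## Numerical notes and limitations

* Choice log-probabilities use log-sigmoid forms stable over the full
  β-bound range; Φ and Φ⁻¹ are scipy's `ndtr`/`ndtri`.
* The per-subject likelihood has a numba-compiled kernel and a pure-numpy
  reference path; tests assert exact agreement, and the package runs
  (slower) without numba.
* All randomness flows through `numpy.random.Generator` streams spawned
  deterministically (SeedSequence) from a single seed per run; dataset
  tags record their derived seeds, and every pipeline stage writes a
  manifest with config, seed and output checksums.
* Degenerate inputs: empty designs, out-of-bounds probabilities or
  parameters, illegal outcome codes, zero-variance correlation inputs and
  empty trimmed means raise with the offending values named; sampler
  non-convergence warns and is recorded rather than raising.
* DIC's plug-in at trimmed means can make p_D noisy at very short chain
  lengths; the comparison tests run at chain lengths where the DIC
  ranking is stable across seeds.
* Trial indices are 0-based within block in all files and tables.
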