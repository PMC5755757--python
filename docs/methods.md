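# Methods

## Generative model of the task

The scene-categorisation task is modelled as a discrete partially observed
Markov decision process. Hidden states factorise into four dimensions:
scene context (Flee, Feed, Wait), gaze location (central fixation, four
quadrants, three choice locations), and vertical/horizontal flips of the
scene. Context and flips are fixed within a trial (identity transitions);
only the location responds to action. Outcomes arrive in two modalities:
the cue seen (*what*: null, bird, seed, cat, right, wrong) and the location
occupied (*where*, an identity mapping — the model assumes proprioceptive
certainty about gaze).

Base layouts put the bird top-left; the companion object sits top-right
(cat for Flee, seed for Feed) or bottom-right (seed for Wait, i.e. on the
bird's diagonal). A vertical flip swaps rows, a horizontal flip swaps
columns; the two commute, giving 3 × 2 × 2 = 12 scene configurations. The
likelihood is deterministic: fixation shows nothing, a quadrant shows the
layout object there, and a choice location returns *right* iff its category
matches the context.

Preferences encode the scoring rules as log prior preferences (nats).
Step-1 utilities are zero (the trial starts at fixation). From step 2 on,
*right* is worth +2·k_cor and *wrong* −4·k_cor; occupying any non-choice
location at step τ carries −0.25·(τ−1)·k_q, so indecision grows costly.
The scales k_cor = exp(ln C_cor) and k_q = exp(ln C_q) multiply the printed
point values and act as precisions on the two preference maps. The horizon
is T = 6 steps (configurable; T ≥ 2 enforced).

## Policies and action selection

Nine one-step policies are re-evaluated at every step: eight direct
saccades and a fixed-form heuristic (state-action) policy encoded by a
deterministic location map H — fixation to the first quadrant of a
preferred order, each quadrant to the next, the last absorbing, choice
locations never targeted (a habit can explore but cannot categorise). The
policy prior is E = [0,…,0, E_h]; with E_h = log 2 a softmax of E gives the
heuristic policy 0.2 and each alternative 0.1 (i.e. 2× per-policy odds; a
description of this bias as roughly 3× circulates, but the softmax value is
what the arithmetic gives and what is implemented).

Expected free energy per policy is G = −epistemic − pragmatic, with
epistemic value the expected Bayesian surprise of the saccade — the
expected KL divergence between the updated and current posterior over the
12-state joint latent — and pragmatic value the expected utility of the
outcome at the target. The policy posterior is π = σ(E − F − G/β). β > 0
is an inverse precision: smaller β sharpens the contribution of G. F, the
free energy of past outcomes, is identical across policies here (all share
the realised history and the location is observed), so it cancels in the
softmax; it is kept in the interface as zeros. β is a fixed per-subject
parameter; no within-trial precision updating is modelled.

## Belief updating

Within a trial the unobserved latents (context and flips) are static and
the likelihood deterministic, so the posterior given the fixation history
is computed exactly by enumeration over the 12 joint configurations;
per-factor marginals are read off the joint. This is the converged limit
of the variational scheme with a family covering the joint. A per-factor
coordinate-ascent (naive mean-field) scheme was evaluated and rejected: on
partial-evidence histories whose consistent-state set is not a product set
it converges to saddle points or wrong corners (total-variation errors up
to 1.0 against the exact posterior), whereas the downstream analyses
require posterior marginals accurate to ~1e-6.

Likelihood entries are floored at exp(−16) before taking logs. The floor
only matters for impossible observations: a history with zero unfloored
likelihood under every configuration raises an inconsistent-scan-path
error (used to reject malformed files); possible histories keep residual
off-support mass below ~1e-6. The floor leaves a matching residue in
derived quantities — e.g. re-fixating a known quadrant has epistemic value
~1e-5 rather than exactly 0.

## Simulation and scoring

A trial starts at fixation; the loop is belief update → policy evaluation →
action selection (sampled from π, or argmax with ties to the lowest policy
index) → gaze-contingent outcome. Choosing ends the trial; otherwise it
ends at T. Score: +2/−4 feedback, −4 on time-out, minus 0.25·n for the
n-th *distinct* square attended (revisits do not pay twice; a time-out
still pays the accrued sampling costs). Saccade counts reported by block
summaries exclude the initial fixation and the choice saccade. The
staircase wall-clock limit of the original protocol is not simulated; the
fixed step horizon T stands in for it.

## Heuristic orders

Since the four quadrants need not be revisited there are 4! = 24 fixed
exploration orders; all are enumerated (reading-like and clockwise among
them). A subject's heuristic map is estimated by argmax over empirical
location-to-location transition frequencies pooled over their trials, ties
to the lowest location index, unvisited locations self-mapped, and
transitions into choice locations excluded so the estimate is a valid
heuristic kernel. A trial is *consistent* with an order when its quadrant
sequence (consecutive repeats collapsed) is a prefix of that order — short
paths are consistent with several orders at once, so per-order frequencies
need not sum to 1. Zero-quadrant trials (immediate choices) are consistent
with everything and are excluded from the favourite-order denominator.

## Model inversion

Data are locations, not policy labels, so the likelihood of an observed
saccade marginalises policies onto targets: P(L) = π_L + π_9·[H(current) =
L], floored at 1e-12 per step. The four parameters (ln β, E_h, ln C_cor,
ln C_q) get a Gaussian prior (mean 0, variance 0.25 each — weakly
informative on the log scale); the MAP is found by L-BFGS from the prior
mean, the posterior covariance is the inverse of a central-difference
Hessian (step 1e-3, symmetrised, diagonal-jittered to positive definite if
needed), and the Laplace log evidence is loglik + log prior + (d/2)log 2π
+ ½ log det Σ. Because belief posteriors and epistemic values at observed
steps do not depend on the parameters, they are precomputed once per
dataset and each likelihood evaluation reduces to a vectorised softmax
(the preference terms are linear in k_cor and k_q); tests verify this
equals the step-by-step replay. The extrinsic-only model zeroes the
epistemic term in G; both models are fitted independently and compared by
log evidence.

## Hierarchical analysis over blocks

Per-subject block posteriors enter a second-level Gaussian linear model
with regressors [1, exp(−(b−1))] — a constant and an exponential decay
with a one-block time constant — giving 4 × 2 = 8 effects (four constants,
four decay coefficients). Block means are treated as observations with
noise equal to their posterior covariance plus a fixed between-block
covariance I/16; no restricted-maximum-likelihood estimation of that
covariance is attempted, keeping the level closed-form. The second-level
prior is zero-mean with variance 0.25 per effect. All 2⁸ = 256 on/off
patterns are scored by Bayesian model reduction ("off" = prior variance
1e-8, mean 0); per-subject evidence changes are summed over subjects and
softmaxed into model probabilities; Bayesian model averages are
moment-matched mixtures under those weights. Reductions rendering the
posterior precision indefinite are excluded with −∞ evidence.

## Phenotyping

Canonical correlation analysis runs on columns normalised to mean 0 and
unit sum of squares (constant columns rejected by name); correlations are
singular values of the whitened cross-covariance, with a 1e-8 ridge and a
warning on rank-deficient within-set covariance. Dimensionality is
assessed by Bartlett's statistic, χ² = −(n−1−(p+q+1)/2)·Σ_{i>k}
log(1−r_i²) with (p−k)(q−k) degrees of freedom (chosen over Rao's F; the
choice only matters at small n), log p-values in nats. Sign indeterminacy
is fixed by making the largest-magnitude loading of each x-vector
positive. The parameter matrix holds six per-subject Bayesian model
averages (four constants plus the two preference decay terms); the
behavioural matrix holds mean score per trial, percentage correct, mean
saccades per trial and — when supplied — mean inter-saccade interval,
which is never modelled and only ever an external column.

## Synthetic cohorts

The generator emulates the study design: 22 subjects × 5 blocks × 100
trials, subject parameters drawn from N(0, 0.5²) per coordinate with the
heuristic bias widened to SD 1 to span heuristic and epistemic phenotypes,
and a favourite fixed order per subject (reading-like 0.45, clockwise
0.40, the remaining 22 orders uniform — reflecting the predominance of
those two strategies). Between-block drift is planted only on the two
preference parameters, as η·exp(−(b−1)) with defaults η = −0.25 for
ln C_cor and η = −1.0 for ln C_q: experience mainly sharpens the
expectation of responding quickly, which is what produces the declining
saccade counts across blocks. An optional synthetic inter-saccade-interval
column (log-normal per subject, around 250 ms) exists solely so the
four-column phenotyping interface can be exercised; it carries no signal.

What the generator does *not* emulate: oculomotor noise, fixation
durations, calibration drift, the staircase time limit, training/testing
display differences, and any correlation structure among the four
parameters (they are drawn independently). Passing tests therefore show
that the pipeline recovers what this population puts in — not that real
subjects satisfy the model.

## Problem sizes and test design

The test suite regenerates all data programmatically. Calibration checks
use 20 replications of 100 trials (parameter recovery), five 100-trial
subjects per arm (model comparison), ten 6-subject cohorts (model search),
fifty n = 200 draws (CVA calibration), and one full default cohort shared
across the slower checks. The block-wise saccade trend is tested by a sign
test across subjects on per-subject least-squares slopes over the five
block means, which uses the whole profile; a first-versus-last-block sign
test behaves similarly but discards three of the five blocks. At 22
subjects both sit near the 0.01 significance threshold for realistic drift
magnitudes, whereas pooling trials per block (as a group-level comparison
would) detects the trend very comfortably.

## Known limitations

- The exact enumeration of the joint posterior is possible because the
  latent space is tiny (12 states); larger grids would need the variational
  machinery this package deliberately avoids.
- β is fixed within subject; schemes with within-trial precision updating
  will attribute some behaviour differently.
- The between-block covariance is fixed rather than estimated, which
  shrinks second-level decay estimates toward zero; planted decays of −0.5
  are recovered at roughly half magnitude, and model search accordingly
  errs on the sparse side.
- In this simulator a moderate heuristic bias does not *reduce*
  categorisation accuracy: with a six-step horizon a full heuristic sweep
  still leaves room for an informed choice, so heuristic-leaning agents
  behave like careful ones. A negative heuristic-bias–accuracy association
  of the kind reported in eye-tracking cohorts plausibly requires the
  wall-clock time pressure this package does not model; consequently the
  leading canonical pair on default cohorts is dominated by the policy
  precision rather than the heuristic bias, and the corresponding
  acceptance check fails by design rather than by accident.
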