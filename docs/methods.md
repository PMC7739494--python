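# Methods

`beastmix` models how people revise a numerical judgement after seeing
the judgements of several peers, in the setting of the Berlin Estimate
AdjuStment Task (BEAST): a participant estimates the number of animals
in a briefly shown image (first estimate `E1`, an integer on a 1–200
slider), observes three peer estimates `X1..X3`, and responds with a
second estimate `E2`.  The quantity of interest is the relative
adjustment

    s = (E2 − E1) / (X̄ − E1),        X̄ = mean(X),

so `s = 0` means the first estimate was kept and `s = 1` a full shift to
the peer mean.  Equivalently `E2 = (1 − s)·E1 + s·X̄`.  An observer who
weights all four estimates equally lands at `s = 0.75` in every
condition, which anchors the design's interpretation and serves as an
exact analytic check throughout the package.

## Task design

Four conditions vary the variance and skewness of the peer distribution
while fixing the mean peer offset at `M = 0.4·E1`:

| condition | peer offsets (× M) | structure |
|-----------|--------------------|-----------|
| LN | 0.8, 1.0, 1.2   | low variance, no skew |
| HN | 0.3, 1.0, 1.7   | high variance, no skew |
| HF | 0.30, 1.35, 1.35 | two-peer cluster far from `E1` |
| HC | 0.50, 0.50, 2.00 | two-peer cluster close to `E1` |

Each offset triple averages exactly 1, so only the shape of the
distribution differs between conditions.  The published design fixes
this qualitative structure but not the numeric offsets; the constants
above are package defaults chosen under the mean-1 constraint and the
cluster structure, and live in configuration (`defaults.yaml`) so they
can be recalibrated.  Peers always sit strictly on the truth side of
`E1` in these conditions.  Filler rounds instead draw three estimates at
random from a pre-recorded pool (they may bracket `E1`), and a control
block shows four peer estimates with no stimulus and no first estimate.

Observed adjustments are classified KEEP (`E2` within a tolerance of
`E1`; default tolerance 0 since estimates are integers), ADOPT (within
tolerance of a peer; nearest peer, lower index on ties), COMPROMISE
(strictly between `E1` and the farthest peer on the adjustment side),
OVERSHOOT (beyond it) or CONTRARY (moved away from every peer).

## Cognitive model

On each round an individual keeps, adopts, or compromises.  With
`d = min_i |Xi − E1| / E1` the relative distance to the nearest peer:

* `P(keep) = logistic(α_k + β_k d)` — keeping is a function of how
  closely the nearest peer confirms the first estimate;
* `P(adopt) = (1 − P(keep)) · logistic(α_a + β_a d)` — adopting the
  nearest peer, composed after keep so the three branch probabilities
  always form a simplex;
* compromising takes the remainder.

Compromise is Bayesian cue combination: personal and social estimates
are Gaussian sources with subjective variances, and the response centres
on the precision-weighted mean

    mu = (E1/σE² + Σ Xi/σi²) / (1/σE² + Σ 1/σi²).

Peer variances are log-linear in two distances (both relative to `E1`):

    σi² = exp( v0 + v_conf·|Xi − E1|/E1 + v_prox·mean_{j≠i}|Xi − Xj|/E1 ),

so `v_conf > 0` is confirmation-based weighting (agreeing peers trusted
more) and `v_prox > 0` proximity-based weighting (peers who agree with
each other trusted more).  All distances are divided by `E1`, which
makes parameters comparable across stimuli of different magnitudes.
The logistic response curves and log-linear variance functions are the
minimal smooth monotone forms consistent with the observed effects; they
are isolated behind `keep_probability` / `peer_variance` so alternatives
can be swapped.

Responses are integers, so the response distribution is a proper pmf on
the slider grid: point masses at `E1` (keep) and the nearest peer
(adopt) plus a normal centred on `mu` with variance
`posterior var + σ_resp²` (σ_resp is motor/slider noise, separate from
subjective uncertainty), discretized over unit grid cells and
renormalized over the slider range.  This makes point masses and
densities commensurable in one likelihood, which sums to 1 over the grid
to ≤1e−9 for any parameters.  The simulator samples the branch and then
the discretized distribution — the same code path the likelihood scores,
verified by Monte-Carlo frequency checks.

Control rounds (four peers, no `E1`) use the peers-only combination: the
confirmation term has no anchor and is omitted; proximity is retained;
the peer mean serves as the reference scale.

Switching each of the four features (keep, adopt, confirmation,
proximity) on or off yields the 16-model family.  A feature is gated by
fixing its parameters (heuristic probability 0, coefficient 0), not by
changing the code path, so pointwise likelihoods are comparable across
the family.

## Hierarchical inference

Individual parameter vectors are drawn from population normals,
`theta_pk ~ Normal(mu_k, sigma_k)`, independently per parameter on the
unconstrained scale.  Priors on group means are weakly informative:
`Normal(0, 2.5)` for intercepts and slopes; for the scale-type
parameters (`log σE`, `v0`, `log σ_resp`), which live on log scales with
physically bounded plausible ranges (estimates are integers on a 1–200
grid, so noise below one grid unit or of order the grid range is
impossible), the priors are located accordingly — e.g.
`log σ_resp ~ Normal(−2.5, 1.0)`.  An unlocated prior there is not
innocuous: the likelihood cannot bound σ_resp from below once it is
small relative to the compromise spread, and the posterior would wander
down the flat tail.  Group sds get half-normal priors with per-parameter
scales — broad for the cognitive parameters, which vary enormously
between people, tight (0.3) for response noise, which plausibly does
not.  All priors are configuration, not hard-coded.

Sampling is adaptive Metropolis-within-Gibbs, designed around the
posterior's geometry:

1. **Individual parameters.**  Joint random-walk proposals per
   participant, executed for all participants at once (their likelihoods
   are conditionally independent, and the trial likelihood is fully
   vectorized).  The proposal covariance is the pooled within-individual
   posterior covariance (Welford-accumulated during warmup); a
   per-participant scalar step adapts to a 23% acceptance rate.
   Componentwise walks fail here: personal variance, baseline peer
   variance and response noise trade off near-collinearly.
2. **Group means.**  Conjugate Gibbs draws.
3. **Group sds.**  Slice sampling on the log scale.
4. **Collective translation moves.**  A group mean and every
   participant's value shift together.  Without these, a collective
   displacement can only happen through the 1/P-rate diffusion of P
   individual walkers.  Directions are the eigenvectors of the
   collective-shift Hessian of the total log-likelihood (computed by
   finite differences a few times during warmup), each with its own
   adaptive step, so soft ridge directions — e.g. confirmation weight
   against baseline peer variance, the classic uncentred-predictor
   ridge — take steps orders of magnitude larger than stiff ones.
   Per-parameter translations run alongside as a safety net.
5. **Interweaved scale moves.**  A group sd and all deviations from the
   group mean rescale together (the non-centred interweaving step),
   curing the same 1/P bottleneck for the spreads.
6. **Initialization.**  A short greedy stochastic hill-climb takes each
   chain to a near-modal state before warmup; the quasi-flat transient
   from a generic start would otherwise dominate short chains.
7. **Optional parallel tempering.**  Each chain can run a small ladder
   of likelihood-tempered replicas with state swaps (`n_temps`);
   with the eigen-direction and interweaving moves in place the ladder
   is off by default in the reduced profiles.

Chains fail loudly when split-chain R-hat (arviz) exceeds a configured
threshold — 1.01 by default, relaxed to ~1.2 in the reduced profiles
used for recovery studies, where short chains estimate R-hat noisily.
Pointwise log-likelihoods are stored per draw for model comparison.

Model comparison uses PSIS-LOO: `looic = −2·elpd_loo` with
Pareto-smoothed importance weights.  The smoothing (empirical-Bayes
generalized-Pareto tail fit, order-statistic replacement, truncation) is
implemented in the package and cross-checked in the tests against the
independent arviz implementation to 1e−6; observations with tail index
k > 0.7 are flagged.  Feature value is summarized over matched model
pairs differing only in that feature (8 pairs per feature in the full
family).

## Synthetic cohorts

The generator reproduces the study design end to end: 95 participants ×
30 main rounds (five per condition, ten filler) in one shuffled order
shared by all participants, plus a five-round control block whose peer
sets emulate the four condition layouts (centred on the pool median, the
cohort-typical estimate) and one filler-style draw; a 100-estimate
pre-recorded pool per stimulus; first estimates from a multiplicative
log-normal error model, `round(truth · exp(ε))`, `ε ~ Normal(−0.1,
0.25)` — count estimation errors scale with the count and large groups
are underestimated.  Stimulus counts default to 35 values spread over
the central slider range, clear of the edges so layout peers fit on the
grid.  Condition peers are placed by the layout with small integer
jitter standing in for nearest-match selection from a finite pool; a
pool-matching mode instead picks the three same-side pool entries
minimizing summed distance to the layout targets (optimal assignment).

The default population parameters are a calibrated fixture, set once so
the cohort reproduces the task's qualitative signatures — adjustment
strongest under LN, near-cluster skew (HC) above far-cluster skew (HF),
keeping concentrated where a single peer confirms, confirmation stronger
than proximity, marked egocentric discounting — and so a
simulate-and-refit study has discriminating power (between-individual
spreads of the scale the task's strategy heterogeneity implies, e.g.
keep slopes `Normal(−8, 5)`).  What the generator does **not** emulate:
perceptual biases beyond log-normal error, order or fatigue effects,
learning across rounds (the task gives no feedback), and any dependence
of strategies on stimulus content.  Passing recovery on this cohort
shows the estimation machinery is sound under the model's own
assumptions, not that the model is true of people.

Mean adjustments in the synthetic cohort (~32% in LN, ~18–22% elsewhere)
sit below the human means; only the qualitative ordering is asserted, as
the quantitative levels depend on the unreleased participant data.

## Belief-dynamics scenarios

1000 agents, parameters drawn from the population distribution (a fitted
posterior's means, or the packaged fixture), each observe ten peer
estimates split between Low = 50 and High = 150 and respond once.
Compositions: 8/2, 5/5 and 2/8 with the agent at Low; and 5/5 with the
agent at 75 — between the clusters, closer to Low — simulated separately
for agents in the upper and lower halves of the confirmation-weighting
distribution (rejection sampling against the population median, which
for a normal population is the group mean).  The agent position 75 was
chosen so that the confirmation-distance contrast between the clusters
(0.33 vs 1.0 in relative units) cleanly separates the strong- and
weak-confirmation subsets; placed midway the contrast is too weak for
the subsets' medians to separate from response noise.  Summaries are
box-plot statistics (median, quartiles, 1.5·IQR whiskers) plus the
fraction of agents keeping exactly.

## Numerical choices and edge cases

* `s` is undefined (None), not clipped, when `|X̄ − E1| < 0.5` grid
  units; such rounds are excluded from s-summaries.
* Log-variances are clipped to ±40 and probabilities floored at 1e−300
  inside the likelihood, so Metropolis proposals can roam without
  overflow; rejected proposals handle the rest.
* Ties (equidistant peers) resolve to the lower index everywhere.
* The discretized normal renormalizes over the slider range, so the pmf
  sums to 1 exactly even when the compromise mean falls near or beyond
  a grid edge.
* Fits are bit-reproducible for a fixed seed (`numpy.random.Generator`
  seeded per chain via `SeedSequence.spawn`).

## Problem sizes

Reduced MCMC profiles without the tempering ladder are used for the
recovery and model-comparison studies: 3 chains × (1000 warmup + 1500
draws) for the parameter-recovery fit (split-chain R-hat ≈ 1.08, bulk
ESS > 30 on the default 95-participant cohort, a few minutes of CPU)
and 2 chains × (500 + 800) for the nested-family comparison fits;
`McmcConfig.reduced()` (2 × 800 + 1200) suits interactive work on
cohorts of ≳30 participants.  The full default profile (4 chains ×
1000 + 1000 with the ladder) is for end-use fits.  Scenario simulations
use the full 1000 agents.

## Known limitations

* Adopt-versus-compromise identification is weak when response noise is
  large: a compromise landing exactly on the nearest peer is
  indistinguishable from adoption on a single round.
* σ_resp has a one-sided identifiability boundary (indistinguishable
  from zero once far below the compromise spread); the located prior
  handles it, and simulate-and-refit shows group means covered when the
  generating noise is of slider-realistic size.
* Group-level posteriors along the confirmation/baseline-variance ridge
  are genuinely wide when only the four structured conditions are fitted
  without filler and control rounds; the full session design is needed
  for sharp recovery.
* The agent-based scenarios are one-shot; no repeated interaction or
  network dynamics.
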