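# Methods

## The task

The package models a stimulus-response learning task built to dissociate two
learning systems.  A session contains 10 independent blocks — 6 with a *set
size* of 3 concurrent stimulus-action associations and 4 with set size 6 —
with a novel stimulus set per block, 9 presentations of each stimulus, 3
response keys, and deterministic binary feedback.  After learning (and a
distractor delay), a surprise *test phase* re-presents every learned stimulus
without feedback.  Because working memory (WM) is capacity-limited and decays
with intervening trials, the set-size manipulation shifts the balance between
WM and slower reinforcement learning (RL): small set sizes can be solved
almost entirely from WM, large set sizes lean on RL, and the feedback-free
test isolates what RL retained.

Presentation order within a block is pseudo-randomized so that the *delay*
between two successive presentations of the same stimulus is near-uniform
over a designed support.  The sequencer draws a no-immediate-repeat sequence
greedily, then hill-climbs with validity-preserving position swaps toward a
flat delay histogram on `{1..3}` for set size 3 and `{1..2*nS-4}` for larger
set sizes — a band around the round-robin spacing `nS-1` chosen because exact
flat occupancy is feasible there under the count and no-repeat constraints
(the wider band up to `2*nS-3` is infeasible at the margin, which biases long
delays low).  Pooled over hundreds of seeded blocks the histogram passes a
chi-square uniformity test at p = 0.01.  The number of test-phase
presentations per stimulus is not fixed by the design description; the
default is 4, chosen for estimation stability, and it is configurable.

## The generative model

Each block tracks two association tables, both initialized at `1/nA`:

* **RL values** `Q(s,a)`, updated by an asymmetric delta rule:
  `Q += alpha+ * delta` when the prediction error `delta = r - Q` is
  positive, `Q += alpha- * delta` otherwise.
* **WM weights** `W(s,a)`: positive outcomes are stored in one shot
  (`W <- r`); negative outcomes move `W` toward `r` at rate
  `nu = alpha-/alpha+` (the same relative neglect of negative feedback as in
  RL; `nu` may exceed 1, in which case `W` can leave `[0,1]` — no clamping is
  applied).  On every trial all of the block's weights *except* the observed
  pair decay toward baseline: `W += phi * (W0 - W)`.

Choice during learning mixes the two softmax policies with a set-size
specific WM reliance `omega_nS` and a lapse:

    P = (1-eps) * [omega * softmax(beta_L W(s,:)) + (1-omega) * softmax(beta_L Q(s,:))] + eps/nA

Test-phase choice uses only the final Q of the stimulus's source block
through a separate inverse temperature `beta_T` (same lapse), with no further
updates.

**Order of within-trial operations.**  The displayed update rules do not pin
down whether decay is applied before or after the current trial's update; we
apply decay first, to every pair except the observed one, then the RL and WM
updates on the observed pair.  This is the only ordering under which the
exclusion of "the association seen in the current trial" does any work.

**Missed responses** (the 1 s deadline) carry no action, no reward, no state
update and no likelihood term.

The vectorized likelihood (a numba kernel evaluating one participant-session
in ~50 us) is checked against an independently written scalar reference to
1e-10 on randomized sessions, and the simulator is checked against the
likelihood by verifying that chosen-action indicators minus teacher-forced
policy probabilities are mean-zero.

## Hierarchical Bayesian estimation

Three hierarchical structures are implemented: `flat` (independent priors per
participant), `single_hierarchy` (one population), and `two_group` (separate
populations per age group).  In every variant `beta_L` is a single value
shared by all participants of a group, with a Gamma(2, 0.04) prior (mean 50,
consistent with the convention of fixing the learning-phase temperature at a
large value and in practice well identified by the data).

Priors (all configurable via `PriorSpec`):

* unit-interval parameters (`alpha+`, `alpha-`, `eps`, `phi`, `omega3`,
  `omega6`): `theta_p ~ Beta(1+a, 1+b)` with `a, b ~ Gamma(2, 0.2)`
  hyperpriors per population; the flat variant uses `Beta(2, 2)`;
* `beta_T ~ Gamma(2, 2/mu)` with `log mu ~ Normal(log 10, 1)`; flat:
  `Gamma(2, 0.2)`.

Sampling is **adaptive Metropolis-within-Gibbs** on unconstrained scales
(logit / log): each participant's 7-vector gets a multivariate random-walk
proposal whose scale adapts to a 0.25 acceptance rate and whose covariance is
estimated from warmup history (Haario-style); `beta_L` and the
hyperparameters get scalar / bivariate random walks (the `(a, b)` pair is
proposed along rotated mean/concentration axes because the posterior is a
ridge).  Default configuration: 4 chains x 500 warmup + 1500 kept.  Pointwise
log-likelihoods are cached and stored per kept draw at the
participant-by-block level — each block's unit pools its learning trials and
its stimuli's test trials, keeping "one block of one participant" as the
smallest data unit — and feed WAIC:

    WAIC = -2 * (lppd - p_waic),  lppd = sum_i log mean_s exp(ll_is),
    p_waic = sum_i var_s(ll_is)

`check_diagnostics` implements the standard thresholds (Rhat <= 1.01,
ESS >= 400 per parameter, BFMI >= 0.2 per chain, zero divergences).  BFMI and
divergences are HMC-era quantities: they are checked whenever a fit carries
energy/divergence sample stats, and pass vacuously for the built-in
random-walk sampler, which has neither.

**Known limitation — sampler efficiency.**  A random-walk sampler has
autocorrelation times orders of magnitude above a gradient-based one on this
posterior (the group-shared `beta_L` and the Beta concentration
hyperparameters are the slowest components).  The recovery correlations,
group contrasts and WAIC orderings reported by the acceptance script are
stable at the configurations used, but the ESS >= 400 bar is not reachable in
reasonable time; treat interval tails from short runs as approximate.

## Validation surface

* **Posterior predictive checks**: full sessions re-simulated from sampled
  posterior draws (default 200), aggregated into accuracy-by-iteration curves
  with 95% predictive bands per group and set size; the asymptotic mean is
  the average of the last three iterations.
* **Parameter recovery**: a cohort is generated from known group
  hyperparameters, refit with the two-group model, and compared to the
  recorded truth.  At 30 participants per group with 2 chains x 250/750 the
  decay rate recovers at r ~ 0.93, WM reliance (set size 3) and the positive
  learning rate above 0.7, and the negative learning rate above 0.5.  The
  lapse rate recovers only weakly (r ~ 0.4): with group means of 0.03-0.05
  and modest dispersion, individual lapse differences produce very few
  distinguishing trials; this is a property of the design, not of the
  sampler.
* **Counterfactual swap**: recipients re-simulated from their posterior-mean
  parameters with one parameter replaced by a donor group's group-level mean
  (used to show that giving older adults the young decay rate moves their
  set-size-6 learning curve toward the young curve).

## Model-independent behavioral analyses

Learning curves collapse accuracy by stimulus iteration (missed trials
excluded).  The trial-level logistic GLM uses set size, delay since the last
*rewarded* presentation of the stimulus (trials with no prior rewarded
presentation are excluded, not imputed), cumulative reward history, trial,
and block, z-scored within participant so coefficients are comparable across
participants; it is fitted per participant with group-level one-sample t
tests on the coefficients (participants with separation or non-convergence
are flagged and excluded).  The age regression predicts age from the
participant coefficients after excluding participants with any coefficient
more than 2 SD above its mean.  Training-vs-test drops use the last three
iterations as "late learning", matching the asymptotic-mean convention.

## Brain-measure linking

Candidate predictors of mean learning accuracy are the 8 z-scored features:
glutamate, GABA and NAA averaged over their three voxels (MFG, IPS,
striatum), gray- and white-matter volume, and cortical thickness in CMF, SF
and RMF kept separate (they come from an anatomical parcellation, not the
voxels).  Feature selection repeats a random 4/5 train / 1/5 validation
split 200 times; per iteration an elastic net with equal L1/L2 weighting is
solved on a penalty path and the subset at the **largest penalty giving a
non-null model** is taken.  Because the coefficients at that penalty are
vanishingly small, the subset is refit by OLS on the training split (a
relaxed elastic net) before scoring on the held-out fifth, and the empty
configuration is recorded when the intercept-only model predicts better — so
a pure-noise outcome drives the average selected-set size toward zero.  The
best configuration is the one with the lowest mean held-out MSE among
configurations appearing in at least 5% of iterations (ties: fewer
predictors), with each candidate re-scored on *all* splits to avoid the
selection bias of scoring a configuration only where it won; it is refit by
OLS for inference.  Its fitted values are the "brain-predicted performance"
axis, regressed on all seven model parameters jointly (posterior means are
the point estimates entering all such regressions).  Anatomical specificity
regresses a parameter on the three regional glutamate values, optionally
residualizing both sides on MFG gray matter and creatine.  Mediation of the
age-decay relationship by glutamate uses the product-of-coefficients
estimator with a nonparametric percentile bootstrap (>= 1000 resamples) — a
deliberate, simpler substitute for quasi-Bayesian ACME machinery.

## The synthetic cohort generator

`CohortSpec` defaults encode the study conditions: 36 young (ages
N(21, 4.4)) and 42 older (N(68, 8.5)) participants; group mean decay 0.174
vs 0.324; WM reliance above 0.5 at set size 3 and below 0.5 at set size 6 in
both groups; a small lapse rate; a group-shared `beta_L`.  Dispersions and
the remaining means were calibrated once so that simulated group learning
accuracies land near 0.74 (young) and 0.60 (older) with the set-size gap
larger in the older group, and then frozen (constants in
`cohort._default_young` / `_default_older`).  Brain measures follow
`glutamate_r = intercept_r - b_phi_r * phi - b_age_r * age + shared + noise`
with the decay coupling strongest in MFG; GABA, NAA, glutamine, creatine and
the structural measures are weakly age-graded nuisance variables with a
shared latent factor inducing modest inter-metabolite correlation (~0.3).
Brain measures are missing for 6/36 young and 18/42 older participants.
Every latent quantity (participant parameters, hyperparameters, coupling
constants) is recorded in the cohort's truth record.

What the generator does *not* emulate: within-group age-performance
gradients beyond what the group parameter distributions imply, the selective
stimulus-neglect strategy some older adults show in set size 6, episodic
contributions to the test phase, response times, and realistic MRS
measurement artifacts.  Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes, not that the assumptions hold in
real cohorts.

## Numerical and problem-size choices

Softmax uses max-subtraction; likelihoods accumulate in log space; the
elastic-net path inputs are centered within each training split (the solver
fits no intercept).  Ties in configuration ranking break toward fewer
predictors.  Degenerate CV splits (constant training outcome) are skipped
and logged.  The acceptance script runs the recovery study at 30
participants per group with 2 chains x 250 warmup / 750 kept draws and the
feature selection at 200 iterations — sizes at which every reported quantity
is stable across seeds while a full run stays in the minutes range on one
core.
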