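# Methods

This note documents the models, estimators, numerical choices and
limitations of the pipeline. All ages and rates use My (million years);
ages are measured backward from the present (tips of an ultrametric
tree at 0).

## Discrete-trait model and stochastic maps

Binary traits evolve under a continuous-time Markov chain with
generator Q; ER ties the two rates, ARD frees gain (q01) and loss
(q10). Likelihoods use Felsenstein pruning with per-node rescaling
(accumulated log-scalers), so trees of 10^4 tips do not underflow.
Transition matrices P(t) = exp(Qt) for all branches are computed from a
single eigendecomposition of Q, validated against `scipy.linalg.expm`
on the longest branch (error > 1e-10, or any negative entry, falls back
to per-branch `expm`).

Rates are fitted by L-BFGS-B on log-rates bounded in [1e-9, 1e3] per
My, with a deterministic start at 1/tree-height plus seeded perturbed
restarts (3 by default) to dodge local optima. AIC = 2k − 2lnL selects
ER vs ARD; ties go to the model with fewer parameters.

The root prior defaults to the stationary distribution of the fitted Q;
a FitzJohn-style weighting (root partials normalized) is available by
flag. This choice shifts origin-timing estimates for very rare traits
and is recorded in every run log.

Stochastic maps are drawn exactly: node states jointly (root from
pi·F, then child-given-parent pre-order), branch interiors
endpoint-conditioned by uniformization (Poisson number of candidate
jumps weighted by R^n, jump chain bridged, uniform order-statistic
times, virtual jumps collapsed). Uniformization has no rejection
pathologies on long or rate-saturated branches; a rejection sampler is
deliberately not used. Zero-length branches (from polytomy resolution)
carry identity transition probabilities and never host transitions.

## Origin timing

For each realization the gain events (0→1 segment boundaries) are
collected in descending age; the origin-timing statistic keeps the
events while the cumulative gain count is in [1, 2] — i.e. the two
oldest gains — and takes their median age. The window is applied
per-realization on integer counts, not on the fractional ensemble-mean
curve, because the estimator is defined per iteration. Realizations
with no gains cannot contribute an origin and are dropped with a logged
count. Ensemble min/max/median/mean/sd are over the per-realization
medians (sd with ddof = 1).

Cross-clade comparisons use the two-sided Wilcoxon rank-sum test
(exact null for small untied samples, normal approximation with tie
correction otherwise; a statistic exactly at the null center returns
p = 1) with Bonferroni correction m = number of pairwise tests.
Treating the per-realization medians as exchangeable samples mirrors
the upstream practice; they are conditional on one fitted Q̂, so the
test inherits that pseudo-replication. We document rather than "fix"
this.

Survival models on branching times: ages x are waiting times with
hazard δ(x). Constant (δ̂ = n/Σx, closed form), Weibull
δ β x^(β−1) (Nelder-Mead on log parameters, three β starts), and
two-rate with a user-specified breakpoint age (closed-form
events/exposure MLE per segment). Likelihood-ratio tests use χ² with
df = 1; fitted alternatives are floored at the constant-model lnL
(they nest it).

## Hidden-rate correlated evolution

Dual states d = 2·t1 + t2 (t1 = nectary, t2 = habit), expanded by R
hidden rate classes to 4R states (index 4c + d). Only single changes
are allowed: one trait, or the hidden class; simultaneous dual changes
are structurally zero — the standard Pagel/corHMM assumption, which the
source analyses do not state explicitly. The class-switch rate is
shared across directions by default (one parameter; a flag frees it).

The four models: dependent R=1 (8 rates), independent R=1 (4),
independent R=2 (9), dependent R=2 (17). Tips observe the dual state
only; likelihood marginalizes hidden classes. AICc uses n = number of
tips. Richer models are warm-started from the embedded optimum of
their nested neighbour (e.g. R=2 from the R=1 solution with a tiny
switch rate), which both speeds fitting and keeps fitted lnL monotone
along nesting chains.

## State-dependent diversification

BiSSE E/D ordinary differential equations are integrated per branch by
a numba-compiled classic RK4 whose step count scales with branch
length × total rate (8 steps per unit, floor 24, cap 4000). This
fixed-step scheme was chosen over an adaptive stepper for compiled
speed and bitwise determinism; accuracy is enforced by tests against
closed forms (E(t) = 1 − e^(−μt) at λ=0; D ∝ e^(−λt) at μ=q=0), a
halved-step oracle, and the equal-rates factorization of the BiSSE
likelihood into constant-rate birth-death × Mk (agreement within 1e-5).
E and D are clamped to [0,1] and ≥0; D is renormalized at nodes with
accumulated log-scalers.

The likelihood conditions on survival of the two root lineages
(D_i / (λ_i (1 − E_i(root))²)) by default; a flag disables it for
oracle comparisons. Root options: flat, FitzJohn, or the "observed
state 0" constraint (mass on nectary-absent states, uniform over hidden
classes) used throughout the five-model comparison. Sampling fraction
f defaults to 1 and is user-suppliable per state (the empirical fern
tree misses well over half of described diversity; any non-default f is
logged).

Model set (turnover τ = λ+μ, extinction fraction ε = μ/λ):
BiSSE-full (k=6), BiSSE-null (k=4), CID-2 (τ, ε vary by hidden class
only; k=7), CID-4 (four hidden classes, shared ε; k=8 — a leaner
variant than the canonical CID-4, keeping the comparison inside the
desk-scale budget), HiSSE-2 (τ, ε per observed×hidden; k=11). Observed
transition rates are shared across classes; one class-switch rate.
AICc with n = tips; Akaike weights from ΔAICc.

MCMC is univariate slice sampling (step-out width 1 on the log scale)
over the six BiSSE log-rates with independent exponential priors whose
means are twice the MLE values — the upstream prior family is unstated,
so an MLE-scaled exponential is our documented choice. Chains are
fully determined by the seed.

## Rate shifts

The stepwise detector fits each partition a birth-death (r = λ−μ,
ε = μ/λ) likelihood assembled from branch-decomposable pieces:
log λ per split; log Ψ(t_top) − log Ψ(t_bot) per internal branch with
log Ψ(t) = −rt + 2log(1−ε) − 2log(1−εe^(−rt)); and for each terminal
branch the geometric-tailed probability P(N = n | stem age) of its
clade's described richness n. Richness 1 reduces to the fully-sampled
contribution, so an all-ones richness table is exactly the no-richness
path. ε collapsing below 1e-4 reports the partition as Yule (k = 1).

Candidates are internal nodes (plus tips with richness > 1); a shift
claims the candidate's branch and subtree except nested earlier shifts.
The step with the best total-AICc improvement is accepted while the
improvement exceeds the stopping threshold (default 4; the upstream
threshold is unstated) up to `max_shifts`; AICc ties go to the older
node. AICc sample size = branching times + richness entries. Shift
age = the age of the shift node's subtending split.

The four-node match links a trait-gain node to any shift within four
parent→child steps below it (the gain node is step 0). The
sliding-window bootstrap pairs the window ladder (10…100 My) with the
step ladder (5…50 My) element-wise — 50% overlap, the most natural
reading of the parallel lists; a flag switches to the full
cross-product. Bins are half-open [start, start + w) in My BP,
covering root height down to 0 (coverage start is configurable; the
default is the root, not the oldest shift). Bootstrap replicates
resample the shift set with replacement (size = number of shifts) and
report per-bin means and 2.5/97.5 percentiles.

## Synthetic data: what it emulates, what it does not

One forward Gillespie engine generates everything, so trait and
diversification simulators share code paths and every generator emits
its ground truth (exact gain ages, hidden paths, per-lineage states).
Clade fixtures are sized 200–400 tips with crown ages of 350 (fern),
250 (angiosperm) and 150 My (ant) — large enough for rate estimation
while keeping the full suite within desk-scale runtimes — and traits
are resimulated (subseed logged) until prevalence lands in the target
window: 1–5% for the rare, clustered nectary traits, 20–60% for ant
plant associations. Taxonomy comes from age-threshold clade cuts
(genus ≈ 12% of crown age, family ≈ 45%, order ≈ 80%); habit is drawn
per species with canopy bias among trait bearers.

The survey tables reproduce only the *marginal* counts of the published
surveys (149 fern bearers in 12 genera / 5 families / 3 orders with the
75/64/6/4 habit split; 3913 EFN angiosperms across 796/119/42): the
species lists are synthetic placeholders. Passing tests therefore
demonstrate that the estimators are correct and calibrated on data with
the assumed structure — not that the biological conclusions hold, and
not that the pipeline is robust to the misspecifications real data
carry (phylogenetic error, non-random sampling, correlated habitat and
diversification confounders). Fixture habit columns are drawn
independently given the trait, so they carry a trait-habit association
without the phylogenetic autocorrelation a real habit character would
have.

## Problem sizes used by the test and acceptance runs

Enumeration oracles use ≤5-tip trees (50 instances). Monte-Carlo
calibration uses n = 2000 maps. Origin-timing recovery uses 30
fixtures of 250 tips with planted gains in [60, 140] My, planted on
identifiable branches (≥3 descendant tips, span ≤ 25 My) — tip data
localize a gain only to its carrying branch, so the branch span bounds
the achievable accuracy of any estimator, and the interval-midpoint
oracle hits the same ceiling on unconstrained branches. The
correlation error-rate suites use 50 replicates of 50–70-tip trees;
shift detection uses 30 Yule replicates (60 tips) and 10 grafted
5×-contrast trees (~80 tips); BiSSE recovery uses 150-tip trees. The
acceptance script runs the full pipeline on the 300/400/250-tip
fixtures with 100 stochastic maps. These sizes are the package's
standard desk-scale configuration; all generators accept larger sizes.

## Known limitations

* Mk and corrHMM fitting use numeric gradients; with 17 free rates the
  dependent R=2 model can need the warm-start chain to reach its
  optimum.
* The MEDUSA variant uses a composite branch-decomposable likelihood,
  not the exact joint density of a partially sampled tree; it matches
  the Yule likelihood exactly and recovers birth-death rates in tests,
  but absolute lnL values are not comparable across differently
  partitioned richness schemes.
* CID-4 is a reduced (shared-ε) variant, as noted above.
* The two-rate survival model takes its breakpoint as given; it does
  not profile over breakpoints.
* No NEXUS input; no tree inference or dating.
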