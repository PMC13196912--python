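# Methods

## The estimation problem

Two treatments for the same indication, each tested against placebo in
separate randomised trials, are to be compared without a head-to-head
study.  Individual patient data (IPD) exist for the *index* treatment's
trials; the *comparator* treatment contributes only published
aggregates: baseline covariate summaries and either an odds ratio (OR)
with confidence interval or arm-level event counts.  Because covariates
that modify the treatment effect are distributed differently across the
two trial populations, the naive anchored contrast estimates a mixture
of two different estimands.  maiclab implements the standard
population-adjustment answer — matching-adjusted indirect comparison —
together with the unadjusted anchored comparisons used as references.

The estimand of every adjusted analysis is the marginal log OR of
index vs comparator treatment **in the comparator trial's population**,
the population whose covariate summaries the weights are matched to.
The simulation engine states and uses the same estimand.

## Moment-matching weights

For modifier set S with target means `m_j` (and optionally variances
`v_j`), the moment matrix has columns `z_ij = x_ij − m_j` and, when
variance matching is requested, `(x_ij − m_j)² − v_j`.  Weights are
`w_i = exp(z_i' θ)` with θ the minimiser of `Q(θ) = (1/N) Σ exp(z_i' θ)`.
This is the method-of-moments fit of a logistic model for trial
membership in which every selected modifier enters linearly; the
gradient of Q is the vector of weighted moment residuals, so the
optimum is *exact* balance, not approximate.

Numerics:

* Damped Newton from θ = 0 with backtracking line search; the problem
  is smooth and strictly convex when the moment matrix has full column
  rank.  No randomness anywhere in the solver.
* Convergence is declared on the **normalized residual**
  `‖∇Q‖∞ / Q ≤ 1e−10`, which is exactly the weighted moment residual.
  The raw gradient also vanishes along infeasible recession directions
  (targets outside the convex hull of the sample, where Q → 0 at
  infinity) and would declare false convergence there; the normalized
  criterion cannot.  After convergence two full Newton polish steps
  push θ to machine precision.
* Infeasible targets exhaust the iteration budget (500) and surface as
  a `ConvergenceError` carrying the partial solution and residuals.
* Weights are normalised to mean 1, making the effective sample size
  `ESS = (Σw)²/Σw²` and all weighted proportions scale-free.  ESS ≤ N,
  with equality exactly at constant weights.

Mean-only matching is the default for every covariate (binary race
indicator, cigarettes/day, HADS anxiety and depression, age), because
trial publications reliably report means for such variables and far
less reliably variances; per-covariate mean+variance matching is
available through the `moments` field of a modifier set.  One weight
model is fitted on the pooled index IPD per modifier set (weights are
re-estimated for each set), and sets are conventionally nested
(set1 ⊂ set2 ⊂ set3) though nesting is not enforced.

## Effect estimation on the reweighted data

The reweighted index effect is the treatment coefficient of the
weighted binomial-logit fit `logit P(y=1) = α + β·T` — the model
deliberately contains **only** the treatment indicator.  MAIC is not
generally doubly robust for nonlinear outcome models, so no outcome
regression is layered on the weights.  Since the model is saturated in
T, β is the difference of weighted-proportion logits, computed in
closed form.

Its variance is the robust sandwich `A⁻¹ B A⁻¹` with
`A = Σ w_i p_i(1−p_i) x_i x_i'` (weighted expected information) and
`B = Σ w_i² (y_i − p_i)² x_i x_i'` (squared weighted scores): weights
enter the score linearly and each participant is one independent unit.
A finite-sample factor `n/(n−p)` is available but off by default (the
plain Huber–White flavour).  Weights are treated as fixed, the standard
practice for MAIC; the simulation results below are the check that
this approximation gives nominal coverage at the sample sizes the
package targets.  Missing outcomes are excluded pairwise per outcome
(complete case per analysis); covariates named by a modifier set must
be complete.

Degenerate inputs raise rather than self-correct: a weighted event
proportion of 0 or 1 in either arm is a `SeparationError` (no silent
continuity correction on the weighted path).

## Unadjusted engines and the anchored contrast

* **Woolf** log OR from a 2×2 table, `se = √(1/a+1/b+1/c+1/d)`, with a
  0.5 continuity correction added to all four cells only when a zero
  cell exists (conventional choice).
* **Fixed-effect inverse-variance pooling** across index trials:
  `d = Σ(dₖ/vₖ)/Σ(1/vₖ)`.  With two index trials a heterogeneity model
  is not meaningfully estimable, so no random-effects option is
  offered.
* **Mantel–Haenszel pooling**, reimplemented from the formulas:
  `OR_MH = Σ(aₖdₖ/nₖ)/Σ(bₖcₖ/nₖ)` with the Robins–Breslow–Greenland
  variance for `ln OR_MH`.  Zero cells receive *no* continuity
  correction; double-zero strata carry no information about the OR and
  are dropped.  On a single zero-free stratum OR_MH equals the simple
  OR and the RBG variance reduces to the Woolf variance — which is why
  the two unadjusted engines agree exactly on single-stratum zero-free
  data (their variances differ on multi-stratum or sparse data).
* **Anchored (Bucher) contrast**: difference of against-placebo log
  ORs, variances summed, two-sided p from the normal reference.  In the
  two-edge placebo-anchored star this is also what full network
  machinery reduces to, for both engines.  Published comparator ORs are
  back-converted via `se = (ln ucl − ln lcl)/(2z)` using the exact
  normal quantile (1.959964… at 95%), so CI round-trips are tight to
  1e−9.

The adjusted pathway is anchored by default as well (weighted index
effect vs placebo, contrasted with the comparator's own against-placebo
effect).  An unanchored sensitivity option — weighted active-arm
log-odds directly against the comparator's active-arm log-odds — exists
behind a flag; it discards the randomisation anchor and is never the
primary analysis.

When only an event *rate* and arm size are published, counts are
recovered as `round(rate × n)` with half-away-from-zero rounding, since
Mantel–Haenszel input must be integral.

## Synthetic data generator

The generator emulates pooled placebo-controlled smoking-cessation
trials: two index trials (default 400 per arm each) and one comparator
trial (default 1000 per arm), with covariates

| covariate | law | default |
|---|---|---|
| race (indicator) | Bernoulli(π) | π = 0.25 index / 0.32 comparator |
| cigarettes/day | 10 + Lognormal(μ, σ) | μ = 2.2, σ = 0.5 (mean ≈ 20, the shift encodes the ≥ 10/day eligibility floor) |
| age (years) | Normal truncated to (18, 80) | 46 ± 11 index / 47 ± 12 comparator |
| HADS anxiety / depression | Binomial(21, q) | q = 0.22 / 0.15 |

Binary outcomes follow
`logit P(y=1) = b₀ + Σ g_j (x_j − r_j) + T·[bₜ + Σ m_j (x_j − r_j)]`
with reference values `r` fixed at the index population's covariate
means, so interactions act only through the treatment term and the
control-arm risk stays covariate-stable unless prognostic terms `g`
are configured.  Effect modification lives on the log-odds scale, the
scale on which ORs are pooled and contrasted.  The default scenario's
six outcomes span abstinence-type endpoints (control-arm risk 6–9%,
index treatment OR ≈ 2.4–2.6 conditional, mild modification by
cigarettes/day) and adverse-event-type endpoints with asymmetric
treatment effects (the comparator drug's conditional nausea OR is 4.5
vs 1.4 for the index drug) — generator defaults chosen as realistic
for the field, not claims about any real trial.

Randomness: one root seed; per-trial child streams are derived from
(seed, trial position), so adding a trial never perturbs earlier
draws.  Every output is a pure function of (config, seed).

The truth oracle computes the marginal log OR of a named treatment in
a named population by Monte Carlo (averaging event probabilities under
T=1 and T=0 over fresh covariate draws, then taking the logit
difference), with a linearised Monte-Carlo SE.  It simulates rather
than reads coefficients because marginal and conditional ORs differ
under prognostic or interaction terms (non-collapsibility).

What the generator does **not** emulate — and hence what passing
simulations cannot certify about real data: informative dropout and
missing outcomes, biochemical verification error in abstinence,
correlated covariates (all covariates are drawn independently),
between-index-trial heterogeneity of the treatment effect, and
unmeasured effect modifiers.  MAIC itself is unbiased only when all
modifiers in imbalance are measured and matched; the simulator can
only demonstrate behaviour when that assumption holds (or is broken
in a controlled, known way).

## Simulation engine and reported operating characteristics

Each replication regenerates both trial ecosystems from a child seed,
collapses the comparator to aggregates, and runs the requested methods.
Reported per method: bias of the contrast log OR against the
Monte-Carlo truth, empirical SE, mean model SE, CI coverage, rejection
rate and mean ESS/N.  Failed replications (non-convergence, separation)
are counted and reported as such; summaries use successes only.

Study conditions used by the shipped scenarios: the null scenario
(identical populations, both treatment effects zero) uses 250/arm index
trials and a 500/arm comparator; the effect-modification scenario uses
a 1-SD upward shift of the comparator population's cigarettes/day mean
with an interaction of ln(1.5) per SD on the index treatment, at
500/arm index trials and a 1000/arm comparator — sizes at which the
fixed-weight sandwich CI attains nominal coverage.  At these settings
the unadjusted anchored contrast is biased by roughly −0.44 on the log
OR scale while the adjusted contrast is unbiased to Monte-Carlo
precision, with mean ESS/N ≈ 0.33 — the textbook bias-for-variance
trade of population adjustment.

## Design choices where the design was open

* **Race** enters as a single binary indicator supplied by the data
  file (reference group vs not): the weight model only needs a
  proportion to match, and finer categorisations can be encoded as
  additional indicator covariates if their summaries are available.
* **Fixed-effect pooling only**, and a two-edge star network only; no
  Bayesian or random-effects network meta-analysis.
* **No weight truncation or winsorisation**, and no entropy-balancing
  variant: extreme weights are reported (min/quartiles/max and ESS) so
  the analyst can see the cost, not hidden by trimming.
* **No multiplicity adjustment** across the outcome × modifier-set
  grid; reports mark p < 0.05 per cell and say so in a footer.
* **Column schemas are user-mapped** in the loader rather than
  hard-coded, so arbitrary IPD exports can be ingested; configs are
  YAML/JSON with unknown keys rejected rather than ignored.

## Known limitations

Binary outcomes only (no time-to-event or continuous endpoints); no
unanchored MAIC as a primary analysis; weights treated as fixed in the
sandwich variance (no weight-estimation uncertainty propagated); the
comparator's aggregate evidence is taken at face value, including any
rate-to-count rounding the source applied before publication.
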