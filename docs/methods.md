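# Methods

`rdsinfer` implements the inference stack used for respondent-driven
sampling (RDS) surveys of hidden populations: recruitment-forest handling,
multiple imputation of missing self-reported network sizes, successive-
sampling (SS) population estimation, a dependence-preserving permutation
test for correlate–outcome associations, and logistic modelling, plus a
synthetic generator that provides ground truth for all of it.

## The sampling model

RDS recruits through the social network of the target population: a handful
of seeds each receive a small number of coupons (3 here) and pass them to
peers; redeemed coupons root successive waves.  Two consequences drive the
statistics in this package:

1. **Unequal inclusion probabilities.**  Better-connected people are reached
   more often.  The SS model formalises the design as `n` sequential draws
   without replacement from a working population of `N` units with selection
   probability proportional to self-reported network size (degree).
2. **Chain dependence.**  Recruiter and recruit resemble each other
   (homophily), so respondents are not independent; naive tests computed as
   if they were over-state significance.

## Successive-sampling weights (`rdsinfer.ss`)

Inclusion probabilities under the SS model have no closed form at interior
`n/N`.  We estimate them by Monte-Carlo simulation using the exponential-
race representation of PPS sequential sampling: unit `i` draws
`T_i = E_i / d_i` (`E_i` standard exponential) and the sample is the `n`
smallest `T_i`.  The weight iteration is

1. initialise `w ∝ 1/d` (the with-replacement approximation);
2. estimate the population degree composition by scaling the weighted
   sample degree frequencies to `N` (largest-remainder rounding);
3. simulate `n_inner_simulations` races over that composition and record
   inclusion frequencies per degree class;
4. set `w ∝ 1/π(class)` and repeat 2–4 until the maximum relative weight
   change drops below `tolerance` or `max_iterations` is reached.

Numerical choices:

* **Degree classes.**  Raw degrees are pooled into classes holding at least
  5 sample members, for stability of the simulated `π`.
* **Isotonic smoothing.**  `π` is non-decreasing in degree under the model,
  but Monte-Carlo noise can invert adjacent classes; a weighted
  pool-adjacent-violators pass restores monotonicity.  This also guarantees
  the documented invariant that higher-degree respondents never receive
  larger weights.
* **Zero-probability floor.**  A class never included across all inner
  simulations is floored at `1/(2·sims)` with a warning.
* **Convergence.**  With finite inner simulations the iteration reaches a
  noise floor rather than the nominal tolerance; the last iterate is then
  returned with `converged=False` and a warning.  The first two iterations
  carry essentially all of the correction.
* **Boundaries.**  `n = N` (census) yields `π ≡ 1` and equal weights;
  `n/N ≥ 0.8` is flagged `near_census`.

Defaults: `N = 15,000` (the study's stated working population size, to
which results are insensitive — `sensitivity_to_N` reports the estimate
over an `N` grid), `n_inner_simulations = 1,000`, `tolerance = 1e-3`,
`max_iterations = 20`.

**Variance** comes from a seed-level tree bootstrap (default `B = 500`):
whole recruitment trees are resampled with replacement until the resampled
size reaches `n` (the last tree truncated in breadth-first order), and SS
weights are recomputed per replicate.  This respects the dependence within
recruitment chains; its interval coverage is checked by simulation.  The
survey this package emulates reports population percentages "± x"; our
output labels that column explicitly as one bootstrap SE.

## Missing network sizes (`rdsinfer.impute`)

Degrees are imputed on the log scale by predictive mean matching inside a
small chained-equations loop: Bayesian-draw linear regression of observed
log-degree on the catalogue covariates plus the recruiter's (possibly
imputed, hence cycled) log-degree, then each missing entry takes the
observed degree of one of its `k = 5` nearest neighbours in predicted-mean
space.  Matching keeps imputations on the observed support (integers ≥ 1,
right-skewed).  `m = 10` completed datasets by default; downstream
estimates combine with the standard rule: pooled estimate = mean, pooled
variance = within-mean + `(1 + 1/m)` × between-variance.  The source survey
does not name its imputation predictors or `m`; both are configuration.

## Dependent permutation test (`rdsinfer.association`)

The null hypothesis is "no correlate–outcome association in a sample with
the observed recruitment and dependence structure".  The test:

1. fits a first-order Markov transition matrix for the (binarised)
   correlate over observed recruiter→recruit pairs (0.5 pseudocounts);
2. regenerates the correlate along the recruitment forest `R` times — roots
   from the observed marginal, each recruit from its parent's transition
   row — leaving the outcome fixed;
3. uses `T = ln OR` (0.5 continuity correction on zero cells) and reports
   the two-sided add-one p-value `(1 + #{|T_r| ≥ |T_obs|}) / (R + 1)`.

Replicates with a constant regenerated correlate are redrawn (capped at
`10·R` draws).  Default `R = 9,999`.

This realisation is one admissible reading of the published description of
the method, which is conceptual; regenerating the outcome instead, or using
the phi coefficient as `T`, are exposed as options without a claimed
default correctness.  Calibration simulations (below) show the construction
is close to nominal but mildly conservative under strong correlate
homophily: a first-order Markov chain extrapolates same-level runs further
than the true without-replacement recruitment process sustains them, so the
null spread of `T` is slightly too wide.  The conservatism is in the safe
direction for the test's stated purpose (guarding against spurious
RDS-induced associations).

## Logistic modelling and selection

Bivariable and multivariable odds ratios come from maximum-likelihood
logistic regression (IRLS via statsmodels GLM/Binomial) with catalogue-
declared reference levels; for a single binary predictor `exp(β)` equals
the cross-product OR exactly, which the tests assert to 6 significant
figures.  The multivariable model includes every variable whose bivariable
model p-value meets the threshold (default `p ≤ 0.05`; the comparator is
configurable because the source survey states "≤" in its methods text and
"<" in a table footnote).  A categorical variable enters whole if any
non-reference level qualifies.  "Do not know/missing" is retained as an
explicit income level; other variables are analysed complete-case.  No
multiple-testing adjustment is applied; the report records how many tests
were run.  Quasi-complete separation (|β| > 15) is flagged, not silently
accepted.  The repeat-event model (≥ 2 events vs one, on the subsample
with any event) reuses the same pathway; permutation p-values are not
computed there because restricting to the subsample fragments the
recruitment chains the dependent null relies on.

## The synthetic generator (`rdsinfer.synthetic`)

What it emulates: a hidden population (default `N = 15,000`) with a
right-skewed degree distribution (negative binomial, mean 9, shape 1.5,
shifted to minimum 1), binary/categorical traits at specified prevalences,
controllable recruiter–recruit homophily, an optional degree–trait
correlation (logistic tilt in log-degree), and a logistic outcome model;
then coupon-limited, without-replacement RDS with Bernoulli coupon
redemption (acceptance 0.5), uniform or degree-weighted seeds, MCAR degree
missingness (10% in the packaged fixture) and optional log-normal degree
reporting noise.

Construction: configuration-model stub matching (self-loops and multi-edges
rejected, isolated nodes reattached) followed by degree-preserving
double-edge swaps that push each trait's edge concordance to
`C(h) = C0 + (1 − C0)·h/(1 + h)` with `C0 = Σ p_l²`, a monotone function of
the homophily weight `h`.  Swaps are proposed in disjoint batches and
accepted when they reduce the total distance to the targets; failure to
reach a target within tolerance raises an error reporting the achieved
concordance (targets above ~0.94 joint concordance on multiple traits can
be infeasible at these densities).  When an outcome target prevalence is
requested the intercept is set by an order-statistic (quantile-coupled)
threshold so the realised population prevalence matches the target exactly.

The packaged `study_shaped_fixture` reproduces the survey's shape —
`N = 15,000`, `n = 539`, 20 seeds, coupon limit 3, trait prevalences at the
published sample values, outcome prevalence 0.439 driven by the published
adjusted correlates, and a repeat-overdose recode at prevalence 0.588 among
those with any event.  Its homophily levels (race/ethnicity, homelessness,
HCV status, regular heroin injection) are synthetic choices: the survey
reports no homophily measurements, so these are set to make recruitment
dependence visible, not estimated from data.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: differential recruitment effort,
non-MCAR degree missingness by default (a covariate-dependent option exists
for stress tests), reporting error in covariates, multiple-coupon
re-recruitment attempts, temporal drift over a two-year field period, and
any drug-market dynamics.  Parameter-recovery results show the estimators
work when the SS model's assumptions approximately hold, not that they are
unbiased for any real survey.

## Simulation study sizes

Chosen as desk-scale defaults and used by both the test suite and
`scripts/acceptance.py`:

* SS parameter recovery: 200 RDS samples (`n = 500`) from populations of
  `N = 5,000` with a 30% trait, homophily `h = 0.5`, log-degree coefficient
  0.8; inner simulations 300, 4 iterations.  Mean absolute bias of the SS
  estimate is compared with 0.02, and with the raw sample proportion's bias
  (~0.10 under these conditions).
* With-replacement limit: `n = 50`, `N = 50,000`, balanced degrees (each of
  1–5 held by ten respondents, so no degree classes are pooled), 8,000
  inner simulations.
* Tree-bootstrap coverage: 200 replicates with `B = 40`, inner simulations
  100, warm-started two-iteration re-weighting.
* Permutation calibration: 500 datasets (`n = 300`, 15 seeds) from 50
  populations of `N = 4,000` with independent traits at homophily 0.5
  (correlate) and 6.0 (outcome); `R = 199`.  The dependent test's rejection
  rate at α = 0.05 is compared with [0.025, 0.075] while the naive Wald
  test's rate exceeds 0.10.
* Null-uniformity: Kolmogorov–Smirnov over 500 iid-null datasets.

## Known limitations

* The permutation null's first-order Markov model is an approximation to
  the recruitment dependence; see above for its mild conservatism.
* SS weights assume degrees are reported without systematic error once
  imputed; reporting noise is available in the generator but no correction
  is attempted in the estimator.
* Multivariable models are unweighted conventional logistic regressions;
  survey-weighted or dependence-adjusted multivariable modelling is out of
  scope, mirroring the method stack this package reproduces.
* `N` is an input, not estimated; population-size estimation is out of
  scope.
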