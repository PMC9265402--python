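# Methods

This note documents the statistical models implemented in `aceindex`, the
choices made where the design was genuinely open, and what the synthetic-data
tests do and do not establish.

## Data model and preprocessing

The analysis connects two tables: a **tract table** with C = 25 neighborhood
variables per census tract (percentages in [0, 100] or non-negative rates per
capita), and a **participant table** with a 0–14 ACE count (dichotomized at
4+), BMI, demographic covariates, and a home-tract identifier.  Participants
nest within tracts; the tract is the neighborhood proxy.

Preprocessing steps, in order:

1. **Complete-case filtering.**  Rows missing any neighborhood variable are
   dropped and counted; no imputation is attempted.
2. **Orientation.**  Each variable carries a direction flag.  Protective
   variables (homeownership, internet access, marital support, fast-food
   access, depression-diagnosis rate, traffic burden, transit access,
   greenspace — 8 of the default 25) are inverted as `max(x) − x_j`, the
   maximum taken over the analysis rows, so that *higher always means
   riskier*.  Orientation precedes both standardization and decile scoring;
   the column maxima are stored so an index can be re-applied to new data.
3. **Standardization** (PCA methods only): each column to mean 0, sample SD 1
   (denominator n−1).  Constant columns are an error naming the column.
4. **Decile scoring** (Bayesian method only): per column, the 9 interior
   empirical quantiles (linear-interpolation/"type 7" convention — the most
   widely used default) become cutpoints; a value's score is the number of
   cutpoints strictly below it, so scores lie in {0,…,9}, all tied values
   share the lowest containing bin, and a column with fewer than 10 distinct
   values simply leaves bins empty (a constant column scores 0).  Cutpoints
   are learned on **tract-level** rows and looked up for participants through
   their tract, matching the tract-level nature of the variables; a
   participant-level mode exists for sensitivity analyses.

PCA standardization and fitting run on participant-level rows (tract values
duplicated per participant) so that the supervised method's response aligns
row-wise and all candidate indexes are built and compared on the same
analysis rows.

## Index constructions

**Threshold-based PCA.**  Starting from a 2-component fit of the
standardized matrix, a variable "loads highly" on a component when
|loading| ≥ 0.15 *and* exceeds its largest absolute loading on every other
component by ≥ 0.10 (the margin is taken against the maximum of the other
components — the strictest reading; with a single component it is vacuous).
Components are added while every component keeps ≥ 4 high-loading variables;
on the first failure the last valid solution is kept (if the initial
2-component fit itself fails, that fit is used), variables high on no
retained component are dropped, and the pass restarts on the reduced set.
The algorithm terminates because each dropping pass strictly shrinks the
variable set and the component count is bounded by it.  The final solution's
components form the index *collectively* — typically two score columns.  An
option (`use_failing_solution`) drops against the failing k-component fit
instead of the last valid one, since either reading of the procedure is
defensible.

**First PC.**  The leading eigenvector of the sample correlation matrix.
Eigenvector signs are arbitrary, so every loading column is flipped to make
its sum positive (ties broken by making the largest-|loading| entry
positive); results are therefore deterministic and order-invariant.

**Supervised PCA.**  Implemented as the dependence-maximizing formulation:
the leading eigenvector of the operator `Z' y_c y_c' Z` with a linear kernel
on the centered binary response, which is rank one and hence proportional to
the vector of column–response covariances.  This matches the verbal
definition of supervised PCA (components with the greatest dependence on a
response); a screening variant (keep the half of variables most correlated
with the response, then take their first PC) is available behind an option
but is not the default.

## Bayesian quantile index regression

The model is `logit(p_i) = β₀ + β₁ Σ_j w_j q_ij` with `w` on the probability
simplex.  Priors: `w ~ Dirichlet(1,…,1)` (flat — the least-informative
standard choice), `β₁ ~ N(0, σ₁²)`, `σ₁ ~ Uniform(0, 100)`, and
`β₀ ~ N(0, 100²)` (a conventional vague normal).  `exp(β₁)` is the odds
ratio of the outcome per one-decile increase of the entire index; because the
weights sum to one, raising every decile score by 1 multiplies the fitted
odds by exactly `exp(β₁)`.

**Sampler.**  Weights are parametrized by unnormalized positive components
`g_j` with independent Gamma(1, 1) priors and `w = g / Σg` — the
Gamma–Dirichlet identity — so every draw lies exactly on the simplex.
Updates are scalar random-walk Metropolis steps (β₀, β₁, σ₁, then each
`log g_j` with the Jacobian term `φ_j − g_j` in the acceptance ratio).
Proposal scales adapt toward a 0.44 acceptance rate (the optimal scalar
random-walk target) during the first `n_adapt` sweeps only and then freeze,
preserving detailed balance for the retained chain; `n_adapt` must not
exceed the burn-in.  The default schedule is 10,000 retained iterations
after 5,000 burn-in with 500 adaptation sweeps, thinning 1, ten quantiles,
one chain (a multi-chain option exists for diagnostics).  Running sums for
the index scores are refreshed every 500 sweeps to cancel floating-point
drift.  Chains are exactly reproducible from the seed.

**Inference.**  Posterior medians and percentile 2.5/97.5% credible
intervals per parameter; `exp` is applied to the β₁ draws *before*
summarizing the odds-ratio scale; the index is significant when the OR
interval excludes 1.  The per-variable weight medians are the reported
index weights; they need not sum to exactly 1 (each is a marginal median)
but in practice their sum stays within [0.9, 1.1].  Weights above the
equal-weight reference `1/C` (0.04 for C = 25) flag above-average
contributors.

**Applying the index.**  The default scores new rows with
`Σ_j median(w_j) · q_ij` on decile scores (internally consistent with the
fitted model); a `raw` mode multiplies the weights into oriented raw
variable values instead.  Both are provided because either reading of
"multiplying posterior weights with the variable's value" is defensible;
the discrepancy is documented rather than resolved.

**Convergence.**  The Geweke diagnostic compares the mean of the first 10%
of a chain with the mean of the last 50% (the conventional window
fractions), each segment's variance-of-the-mean estimated from an
autoregressive spectral density at frequency zero (Yule–Walker fits, order
chosen by AIC up to min(20, n/10)); |z| < 2 is read as convergence, and the
model-level verdict requires every parameter to pass.  Constant chains have
no defined z and are excluded from the verdict.  On strong-signal synthetic
fits the one-at-a-time weight updates mix slowly and individual weight
chains can fail the screen even when point estimates are accurate; the
pipeline reports this honestly (CLI exit code 3) rather than hiding it.

## Method comparison

Each candidate index column enters, alone, a logistic regression of the
binary 4+ ACE outcome (Newton/IRLS, tolerance 1e-8, ≤ 100 iterations;
perfect separation is flagged as non-convergence and the capped quasi-Newton
fit reported).  Models are ranked by AIC = 2k − 2 logL.  A ΔAIC ≥ 3 against
the best model is "meaningfully worse".  A multi-column method (threshold
PCA) is fitted as *separate* per-component models and judged collectively:
it is worse when any of its components is meaningfully worse.  The selected
method is the one owning the single best-AIC model; exact ties are broken by
a fixed, logged priority order (bayes, first_pc, supervised, threshold) —
the ordering never mattered in practice but makes selection deterministic.
The Bayesian model's own deviance-based criterion is not used; the logistic
AIC bridge keeps all four methods on one scale.

## Outcome models

Four linear mixed models of BMI with a tract random intercept, all on the
identical complete-case rows, estimated by REML (statsmodels MixedLM; the
bfgs optimizer first, with fallbacks, because the lbfgs path can return a
degenerate fixed-effect vector when the intercept variance hits the zero
boundary).  Fixed-effect intervals and p-values are large-sample Wald
(significance at p < 0.05); covariates are reference-coded with age 18–34,
male, and White as the reference categories.  Model 2 vs model 3 quantifies how
much the index attenuates the ACE–BMI association.  VIFs
(`1/(1 − R²_j)`, intercept included, categorical predictors expanded to
indicators) are computed for models 3 and 4 on exactly the fixed-effect
designs used in fitting.

## Synthetic data generator

The generator emulates the study conditions: 380 tracts, 1,680 participants,
25 variables, a 32.7% high-ACE prevalence, and an index odds ratio of 1.24
per decile (β₁ = ln 1.24) as defaults.

- **Tract variables** come from a 2-factor linear latent model (loadings
  ~ N(0, 0.8²), unit noise) pushed through `100·expit(·)` for percent-type
  columns and `exp(·)` for rate-type columns, with per-variable offsets
  keeping typical percentages in the tens and rates in single digits.  The
  shared factors induce the co-occurrence that motivates an index in the
  first place.
- **True weights** default to ten weights of 0.07 and fifteen of 0.02 —
  a minority of variables carrying most of the index, bracketing the 0.04
  equal-weight reference.
- **Outcomes.**  The per-tract true score is the weighted decile sum of the
  oriented variables; 4+ ACE status is Bernoulli under the index model, with
  β₀ solved by bisection (tolerance 1e-6) so the population-average
  prevalence hits the target; the raw ACE count is drawn uniformly within
  the implied class range (0–3 or 4–14), since nothing downstream uses
  counts beyond the dichotomy.  BMI adds a linear index effect, an ACE
  effect, covariate effects (signs matching the adjusted associations the
  study design anticipates; magnitudes are generator choices), a tract
  random intercept, and Gaussian noise.  Participants are assigned to tracts
  near-uniformly (a log-normal skew option exists, off by default).

The generator deliberately omits spatial autocorrelation between tracts,
measurement error in the neighborhood sources, and informative missingness —
the analysis models none of these either.  Passing tests on this data
demonstrate that the estimators recover the structure they assume; they do
not validate the assumptions against real neighborhoods.

## Problem sizes used in the test suite

Simulation-backed checks run at sizes chosen to make the relevant sampling
error small relative to the assertion: weight recovery at n = 2000, C = 10
with the full MCMC schedule (tolerances ±0.07 on nonzero weights and < 0.06
on zero-truth medians, fixed from a pilot run of the same configuration);
credible-interval coverage at 100 replicates of n = 400, C = 5 with
shortened chains; the confounding-attenuation pattern at 350 tracts × 1,200
participants over 20 seeds; null-behavior screens at 30–50 seeds of reduced
size.  The acceptance script runs the full pipeline at study scale
(380 × 1,680, C = 25, full schedule).

## Known limitations

- Single-chain Geweke screening is a weak convergence guarantee; slow weight
  mixing under componentwise updates is visible on strong-signal data.  A
  multi-chain potential-scale-reduction check would be stronger.
- The mixed-model suite estimates a random intercept per tract; with purely
  tract-level confounding and large clusters the random intercept absorbs
  much of the between-tract signal, so crude associations (model 2) shrink
  relative to an ordinary regression — visible in the generator's default
  configuration and worth keeping in mind when interpreting attenuation.
- VIFs for indicator columns of unbalanced categorical covariates can exceed
  2 for purely compositional reasons (e.g., a dominant middle age band);
  the per-model VIF reports separate this from index/ACE collinearity.
- The threshold-PCA reduction can legitimately retain variables unrelated to
  the outcome: any ≥ 4 variables sharing an off-outcome component survive
  the rule.  This is a property of the method, not a defect of the
  implementation, and is one reason the outcome-aware constructions compare
  favorably.
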