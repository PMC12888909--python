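# Methods

## Scope and model structure

`riskuq` quantifies the uncertainty in an individual's predicted absolute
breast-cancer risk that is attributable to *missing risk-factor data* —
uncertainty that would vanish if the missing factors were measured. It
deliberately excludes parameter (model) uncertainty and model
misspecification, which require different machinery.

The package couples three components:

1. a **synthetic reference-cohort generator** standing in for the large
   population cohorts an imputation model would be fitted to in practice;
2. a **simplified multifactorial absolute-risk engine** — a log-additive
   relative-risk model over a calibrated baseline hazard with competing
   mortality. Full pedigree/segregation-analysis likelihoods are out of
   scope; the uncertainty framework is agnostic to the inner risk model,
   which is exactly why a transparent stand-in suffices;
3. the **uncertainty machinery**: chained-equations imputation, Monte
   Carlo risk distributions, uncertainty intervals, category
   probabilities, stepwise reclassification flows.

## Risk factors and effect sizes

The default schema carries six questionnaire risk factors (log-normal BMI;
zero-inflated log-normal alcohol intake in g/day; age at menarche; parity
as an ordinal count; HRT use; oral-contraceptive use), one mammographic
density variable (percent density, log-normal), a polygenic score
standardized to N(0,1) in the population, a single 9-category
pathogenic-variant covariate (reference "none" plus BRCA1, BRCA2, PALB2,
CHEK2, ATM, BARD1, RAD51C, RAD51D; at most one variant per person under
the rare-disease assumption, each carrier frequency ≤ 1%), and a
family-history summary (0 / 1 / 2+ affected first-degree relatives).

A continuous variable's risk contribution is
`risk_effect × (transform(x) − center) / scale`, i.e. a log relative risk
per standardized unit on the transform scale; categorical variables carry
one log-RR per level with the reference at 0. Defaults are **illustrative
values of realistic magnitude** (e.g. RR 1.6 per PGS SD, RR 10 for BRCA1,
RR 2.5 for CHEK2, RR 3.3 for 2+ affected relatives): the effect sizes
inside proprietary multifactorial models are not public, and no claim of
calibration to any real cohort is made. Everything is declared in
`default_schema()` and overridable.

## Population model and calibration

Annual baseline incidence and competing (non-breast-cancer) mortality
hazards live on an integer age grid (20–80 years). The default incidence
is a smooth logistic ramp (~1.2/1,000 per year at 40, plateauing near
3/1,000 after 60) and mortality a Gompertz curve — registry-like shapes,
not a specific registry. `calibrate_baseline` divides the baseline hazard
by the cohort-mean relative risk so that the cohort-average individual
hazard equals population incidence at every age (to 1e-6 relative; exact
by construction with age-constant relative risks).

Absolute risk over `[age, age+horizon)` treats hazards as piecewise
constant per year and integrates each year exactly:
`P(event in year t) = S(t) · λ_t/(λ_t+μ_t) · (1 − e^{−(λ_t+μ_t)})`, with
`S(t)` the probability of being event-free and alive at the start of year
t. This matches the constant-hazard closed forms exactly and a month-grid
discretization to high accuracy, and is monotone in any single log-RR and
in the horizon.

Category boundaries follow the 10-year clinical bands: near-population
< 3%, moderate 3–8% (both endpoints inclusive), high > 8%. For general
schemes the rule is: a risk equal to the lowest threshold belongs to the
band above it, equal to any other threshold to the band below.

## Synthetic cohort generator

Covariates other than family history are drawn through a Gaussian copula:
latent scores `z ~ N(0, R)`, margins mapped by inverse CDF. Default latent
correlations are modest and plausible (BMI–density −0.25, BMI–alcohol
+0.10, all else independent); margins are declared per variable
(`DEFAULT_MARGINS`). Family history is *not* in the copula: the affected
first-degree-relative count is drawn by a continuation-ratio logistic on
the PGS and carrier status (P(≥1 relative) ≈ 12% at PGS 0 for
non-carriers, rising with both), so that measuring genetic factors changes
the conditional relationship between family history and risk — the
qualitative behavior that makes stepwise measurement interesting. An
auxiliary `age` column (uniform 40–70) is included as a missingness driver
only; it is not a risk covariate.

What the generator does **not** emulate: real cohort selection effects,
age-dependent covariate distributions, measurement error, pedigree
structure beyond the first-degree count, and any calibrated effect sizes.
Passing tests therefore demonstrate that the *uncertainty machinery* is
correct under a known data-generating process, not that the numbers match
any real population.

Missingness can be imposed MCAR (per-entry Bernoulli) or MAR (logistic on
fully observed drivers). MNAR is excluded: the imputation framework
assumes missingness at random.

## Imputation

Conditional model families by variable type: Gaussian linear regression on
the transform scale (log for positive variables); a two-part model for
zero-inflated alcohol (logistic for P(>0), linear on the log of positive
values); logistic for binary; reference-coded multinomial logistic for
categorical/ordinal (the 9-category PV variable keeps "at most one
variant" by construction, being a single categorical draw). Predictors are
all other schema variables: continuous on the transform scale,
semicontinuous as a (positive-indicator, log-positive-part) pair,
categorical as reference-coded dummies.

Fits use statsmodels (OLS/Logit/MNLogit). Ultra-rare PV categories make
(quasi-)separation routine at feasible cohort sizes; on non-convergence,
non-finite covariance or exploding coefficients the fit falls back to a
ridge-penalized Newton solver (default α = 0.5 on non-intercept
coefficients, intercepts effectively unpenalized so marginal frequencies
stay unbiased), whose penalized Hessian supplies the parameter covariance.
Rank-deficient linear designs use the pseudo-inverse (zero variance in
null directions).

Imputation is "proper": each of the M samples redraws the model parameters
from their asymptotic normal (residual variance from its scaled
inverse-chi-square) before drawing the value, so parameter uncertainty
propagates into the imputations. A bootstrap-free asymptotic draw was
chosen for speed and determinism; `proper=False` gives fixed-parameter
draws. Missing entries are initialized by draws from the observed
marginals (not mean-fill, which would degenerate first-iteration
variances); the visit order is the schema declaration order; defaults are
`n_iter=10` sweeps, 4 chains for diagnostics, and `M=1000` samples for an
individual's distribution. Dataset-level (one-completion) imputation
shares one parameter draw per variable per sweep across rows.

Convergence: per-chain traces of the mean and SD of each imputed variable
across iterations; the Gelman–Rubin statistic
`sqrt(((n−1)/n · W + B/n)/W)` is reported per monitored quantity, with the
conventions R-hat = 1 when both within- and between-chain variances vanish
and +inf when only the within-chain variance does. Observed-vs-imputed
distribution checks report means/SDs and a two-sample KS statistic
(continuous) or level frequencies and total-variation distance
(categorical).

## Uncertainty summaries

The point estimate is the arithmetic mean of the M risks ("mean risk over
unmeasured covariates"). The 95% UI is the equal-tailed *empirical
percentile* interval with inclusive linear interpolation between order
statistics (numpy's default quantile rule) — chosen over highest-density
intervals as the simplest defensible reading of "range containing the risk
with 95% probability"; `level=0` degenerates to the median by convention.
Category probabilities are exact empirical frequencies (integer counts
over M; their correctly rounded sum is exactly 1).

`pgs_sweep` fixes the PGS at standard-normal quantiles Φ⁻¹(p/100) and
recomputes the distribution over the remaining missing factors. The same
seed drives every percentile (common random numbers), so sweep curves are
smooth and directly comparable. With the variant status unknown, the
default model's risk distribution is a bimodal mixture (rare high-RR
carriers); the upper UI endpoint then sits at the mixture gap and UI
widths need not be monotone in the PGS — with carrier status observed
(e.g. "none"), the remaining factors act multiplicatively with roughly
fixed relative spread and widths grow with the point estimate.

## Stepwise measurement and reclassification

`stepwise_measurement` simulates measuring groups (QRF, MD, GF; finer
orders configurable) in sequence. Each of M trajectories draws the
stage-k group from its conditional distribution given the observed data
plus previously drawn groups — implemented by chained-imputing *all*
still-missing variables and retaining only the stage-k group, which
yields the correct conditional marginal. The stage-k risk is the point
estimate with the remaining groups still missing, computed as a nested
Monte Carlo mean over `M_inner` (default 100) inner imputations — the same
"mean over unmeasured covariates" convention as the point estimate; the
final stage needs no inner marginalization. The baseline stage shares one
point estimate (a single size-M inner run) across trajectories, so the
baseline membership is a point mass in the current category.

Flows store integer trajectory counts: transition-matrix row/column sums
reproduce adjacent stage memberships *exactly*, not statistically.
Intermediate memberships legitimately depend on the measurement order;
final-stage memberships do not (same conditional law), which the tests
check against enumeration. The reclassification probability from stage i
to stage j is 1 minus the stage-j membership of stage-i's modal category.

## Numerical and design choices

- Fixed seeds everywhere; a fixed seed yields byte-identical cohorts,
  completed profile sets and output files. Derived seeds stay below 2^31.
- Quantile convention, classification boundary rule, visit order and
  initialization are all fixed and documented above for bit
  reproducibility.
- Degenerate inputs: a fully observed profile yields M identical samples,
  a zero-width UI, one category with probability 1 and zero
  reclassification; `horizon=0` returns risk 0; empty cohorts, ages off
  the grid, non-positive-definite copula matrices, MAR drivers with
  missing entries, and absent categorical training levels raise explicit
  errors.
- Problem sizes in the test suite and acceptance script (reference cohort
  20,000; M = 1,000 for individual distributions; 500 individuals ×
  M = 500 for coverage; M = 10,000 against enumeration oracles; M = 500,
  M_inner = 50 for stepwise flows) were chosen so every Monte Carlo check
  has comfortable statistical resolution at desk scale.

## Known limitations

- Effect sizes, margins and hazards are illustrative; outputs are not
  clinical risk estimates.
- The risk engine has no pedigree likelihood, no ovarian-cancer component,
  no age-varying relative risks, and no ethnicity-specific incidence.
- Family history is a 3-level first-degree count; detailed family
  structure is out of scope.
- Imputation models are main-effects only; no predictive-mean matching,
  no MNAR sensitivity analysis, no multilevel structure.
- Model-parameter and misspecification uncertainty are not quantified.
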