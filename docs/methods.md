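# Methods

## Overview

`symcox` implements a three-stage analysis of right-censored survival data
with a binary death indicator:

1. **Screening** — rank covariates by Mann–Whitney U association between
   their values in the died / survived groups; keep the top k (default 3).
2. **Transformation search** — for each kept covariate, fit
   logistic-wrapped candidate expressions `expit(a + b·g(s·x + d))` over
   the unary bases g ∈ {1/x, eˣ, log x, √x} plus the identity, by maximum
   Bernoulli likelihood; rank by mean log-loss.
3. **Survival modelling** — fit Cox proportional-hazards models on the
   bare winning transformations and on the raw covariates, and compare on
   C-index, horizon AUC, likelihood-ratio statistic and partial AIC.

## Transformation search

### Expression space and canonicalization

Every candidate has the affine-wrapped unary form f(x) = a + b·g(s·x + d).
For the inverse, log and sqrt bases an inner scale c is redundant —
a + b/(c·x + d) ≡ a + (b/c)/(x + d/c), and similarly for log (the scale
becomes an additive constant) and sqrt (it factors into b) — so the
canonical parameterization absorbs it, leaving (a, b, d) free plus an
explicit sign s ∈ {±1} for decreasing arguments.  For exp the inner rate
is not absorbable and the form is a + b·e^{r·x} (an inner offset folds
into b).  The string serializer emits the canonical form; the parser also
accepts the scaled form `a + b/(c*x + d)` and canonicalizes it, which
leaves predictions bit-identical (property-tested to 1e-10).

### Fitting

The mean negative Bernoulli log-likelihood is minimized by multi-start
L-BFGS-B (default 16 restarts per sign) with analytic gradients.  Restart
points are scaled to the data: the intercept starts at logit(ȳ), the
outer slope is drawn relative to the standard deviation of g(s·x + d) at
the drawn offset, the offset is drawn log-uniformly between 10⁻³ and 10
spans above its feasibility bound, and the exp rate is drawn with
|r|·sd(x) roughly in [0.05, 4].  The first restart always starts at the
intercept-only model, which guarantees no fit is ever worse than the
constant-probability baseline (asserted to 1e-6 in tests).

Domain feasibility is a hard optimizer bound: the argument s·x + d must
stay at least 0.1% of the observed covariate span away from the base's
singularity over the whole fitting sample.  This prevents degenerate
solutions that pin a pole or log singularity onto the single most extreme
observation, at the cost of excluding poles closer than 0.1% of a span to
the data — fits like a reciprocal with a pole just below the observed
minimum remain representable.  Convergence is declared at projected-
gradient norm 1e-8; a fit is flagged unconverged only if every restart
hits its iteration limit.  A constant covariate returns the slope-zero
solution at the outcome-entropy loss.

Selection uses mean log-loss directly.  After canonicalization all
shifted bases have three free parameters; exp has three as well (a, b, r),
so likelihood ordering is comparable across candidates.  Ties in loss are
broken alphabetically by base name, making the ranking deterministic and
invariant to the order in which bases are tried.

Censoring is deliberately ignored at this stage: the target is the
recorded death indicator regardless of follow-up length.  This mirrors
standard single-covariate classifier pre-screening, and it means subjects
censored early count as non-events — a statistical caveat to keep in mind
when event rates are low and follow-up very variable.  The survival stage
downstream handles censoring properly.

### What the search can and cannot distinguish

Over a short covariate span, exp with a small rate, log or 1/x with a
pole outside the range, and √x are locally near-affine in each other;
at cohort-scale n (a few hundred) they often differ by fractions of a
millinat of log-loss.  The *fitted curves* then agree closely over the
observed range even when the named base differs.  Base identification is
reliable when the data cover enough curvature — the recovery experiments
use n = 5000 with roughly balanced outcomes for exactly this reason.

## Cox proportional-hazards estimation

The log partial likelihood is maximized by Newton–Raphson with analytic
gradient and observed information, Efron's correction for tied event
times by default (Breslow selectable; the two agree exactly when no event
times are tied).  Covariates are centred and scaled internally for
conditioning; results are transformed back exactly, since the partial
likelihood is invariant to centring and equivariant to scaling.  Step
acceptance uses up to 20 halvings with a tolerance relative to |ll| to
absorb floating-point plateau noise; convergence is declared at gradient
norm < 1e-8.  Monotone likelihood (complete separation in risk sets) is
detected when a standardized coefficient exceeds 10 — a per-SD log-hazard
ratio of e^10 is not a finite MLE — and reported as non-convergence with
a diagnostic instead of silently diverging; Wald inference refuses to run
on such a model.  The covariance is the inverse observed information;
Wald rows report HR = e^b with e^{b ± z·se} confidence bounds (95%
default).  The baseline hazard is never estimated: the package uses only
relative hazards and rank-based metrics.

The likelihood-ratio statistic 2·(ll_model − ll_null) is reported
alongside ll_model and ll_null.  Reports label the LR statistic as the
model-vs-null comparison quantity: it is positive, equals the AIC
difference against the null at equal parameter count, and is the number
comparable across models on the same data — whereas the log partial
likelihood itself is negative and offset by an arbitrary data-dependent
constant.

## Discrimination metrics

**Harrell's C** is computed over admissible pairs: subject i with an
observed event paired with any j whose follow-up is strictly longer, or
exactly equal with j censored (j then survived at least as long).  Pairs
of events tied in time are excluded; tied risk scores score ½.  The
implementation is exact (chunked O(n²)) and is verified against
exhaustive enumeration and against lifelines.

**Horizon AUC** is a cumulative/dynamic estimator: cases are subjects
with an observed event by the horizon; controls depend on the estimator
variant.  The default (`exclude`) takes only subjects still under
observation at the horizon and drops those censored earlier — the
textbook definition, but with heavy administrative censoring it can leave
very few controls at late horizons.  The `include` variant treats every
non-case as a control, reducing to the plain rank AUC of the
death-by-horizon label; it is the variant the comparison study reports at
the maximum-follow-up horizon, where "death during follow-up" is the
natural label.  An inverse-probability-of-censoring-weighted variant
(`ipcw`, Kaplan–Meier estimate of the censoring distribution) is
available behind the same flag.  All variants are compared on the same
pair of models, and the transformed-vs-untransformed ordering is checked
under every variant.

**Kaplan–Meier** curves use the product-limit estimator with Greenwood's
variance and log(−log S) confidence bands (bands stay inside [0, 1] and
collapse to the point estimate at S ∈ {0, 1}).  Subjects censored at an
event time are counted at risk through that time.  Stratified curves use
half-open bins (lower, upper]; empty strata are omitted with a warning.

**Mann–Whitney U** uses midranks, the tie-corrected variance
n₁n₂/12·[(N+1) − Σ(t³−t)/(N(N−1))] and a 0.5 continuity correction by
default (toggleable); the two-sided p comes from the normal
approximation.  Binary covariates are screened through the same code
path, where the statistic degrades gracefully to a comparison of
proportions.

## Synthetic cohort generator

The generator emulates the 299-patient heart-failure cohort the package
targets.  Marginals (defaults, all overridable):

| covariate            | law                        | parameters        |
|----------------------|----------------------------|-------------------|
| age (years)          | truncated normal [40, 95]  | mean 60.8, SD 11.9 |
| ejection fraction (%) | truncated normal [14, 80] | mean 38.1, SD 11.8 |
| serum creatinine (mg/dL) | log-normal             | mean 1.4, SD 1.0  |
| CPK (U/L)            | log-normal                 | mean 581.8, SD 970.3 |
| serum sodium (mEq/L) | normal                     | mean 136.6, SD 4.4 |
| platelets (per µL)   | normal, resampled > 0      | mean 263 k, SD 97 k |
| anaemia / diabetes / high BP / male sex / smoking | Bernoulli | 0.431 / 0.418 / 0.351 / 0.649 / 0.321 |

Truncated-normal parameters are moment-matched: the location and scale
are solved (numerically, once, cached) so the *truncated* law has the
target mean and SD — naively using the targets as location/scale would
bias the age mean upward by about one year.  Log-normals are
moment-matched in closed form.

Event times follow a proportional-hazards mechanism with constant
baseline hazard: T ~ Exponential(λ₀·e^{Σ β_c f_c(x_c)}), censored by an
independent uniform administrative time on [4, 285] days;
time = min(T, C), event = 1{T ≤ C}.  The constant baseline makes the
latent time exactly invertible; Cox estimation is baseline-agnostic, so
recovery tests are unaffected by this choice.  The default true
transformations are the reference heart-failure model — exp(0.056·age),
1/EF and 1/creatinine with log-hazard coefficients 0.014, 53.7 and
−1.515.  (The EF coefficient is stated per unit of 1/EF-percent; it
equals 0.537 per unit of the reciprocal of the EF *fraction* — on the
percent scale the reciprocal spans only ~0.06, so the fraction scale is
the one on which the published-size coefficient carries signal.)  The
default baseline rate 1.288e-3/day was calibrated once by monotone
root-finding so the expected event fraction is 32.1%, the cohort's death
prevalence.

`calibrate_baseline_rate` computes, for each of 20 000 drawn covariate
vectors, the exact conditional probability that the exponential death
time beats the uniform censoring time, and Brent-solves the baseline rate
on the log scale — smooth, strictly monotone, and deterministic at a
fixed seed.

Covariates are sampled independently.  The real cohort certainly has
correlations (age with creatinine, sex with smoking, …) that the
generator does not reproduce, and integer-valued recording (days, EF
percent) is not emulated; passing tests therefore demonstrate correctness
of the estimators and the recoverability of transformations under the
stated mechanism, not calibration of the generator to the joint
distribution of real patients.  A degenerate censoring window (c, c)
reproduces pure administrative censoring at a single date.

## Pipeline conventions

Before the Cox stage, searched transformations are stripped of their
outer affine constants (a, b): the Cox coefficient and baseline hazard
absorb them, so model covariates are bare transformed quantities
(`1/serum_creatinine`, `exp(0.056*age)`) and an identity-forced run
yields two literally identical models.  User-supplied fixed expressions
(`--transform name=expr`) are applied literally.  The AUC horizon
defaults to the cohort's maximum follow-up.  Reports carry a provenance
block (input hash, seeds, ties method, estimator variants) and regenerate
byte-identically from the same inputs; no timestamps are embedded.

## Problem sizes used in the checks

Oracle-equivalence checks run on 6–25-subject toys where exhaustive
enumeration and dense grids are exact.  Recovery experiments use n = 5000
with a widened censoring window (4–1000 days) so roughly half the cohort
has observed events — a balanced target for the search stage and enough
curvature coverage to identify the base family.  The end-to-end study and
the acceptance script run at the cohort's own scale, n = 299.

## Known limitations

* Single-covariate, depth-one expressions only; no interactions or
  nested compositions — by design, to keep the transformations clinically
  interpretable.
* The search's binary target ignores censoring (see above).
* Mean log-loss comparison across bases has no complexity penalty; an
  optional information-criterion mode is not implemented since all
  canonical candidates carry equal parameter counts.
* Printed constants of any externally fitted reference expressions are
  optimizer- and engine-dependent; structural agreement (base family,
  sign, rough rate) is the reproducible contract, and the test suite
  treats it that way.
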