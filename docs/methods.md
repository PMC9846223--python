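# Methods

## The structural system

The model is a fully recursive generalized structural equation model over
observed variables: a DAG in which each endogenous variable is the dependent
variable of exactly one generalized linear equation whose predictors are its
diagram parents.  The built-in diagram has six equations —

1. 4+ANC from a qualified provider (logit) ~ age + education + wealth +
   living children + child-death history + distance + CHW home visit
2. facility delivery (logit) ~ ANC + the same seven
3. PNC from a qualified provider (logit) ~ facility delivery + ANC + the seven
4. care-seeking for a maternal complication (logit) ~ PNC + facility
   delivery + ANC + the seven, *estimated only among women with a
   complication*
5. danger-sign knowledge count (gaussian/identity) ~ PNC + facility delivery
   + ANC + age + education + wealth + children + child-death + CHW visit +
   danger-sign counseling (no distance, no newborn sex)
6. qualified care-seeking for the sick neonate (logit, the outcome) ~
   knowledge (as 0 / 1–4 / 5+ categories) + complication care-seeking + PNC
   + facility delivery + ANC + all background factors + newborn sex +
   distance + counseling

— all estimated on the mothers-of-sick-neonates subpopulation.  Because the
system is recursive with distinct parameters per equation, the likelihood
factorizes and the equations can be fitted independently in topological
order.

Reference categories are the first level of each block (age "<20",
education "no education", wealth "lowest", knowledge "0"); for distance the
reference is "5 km or more", so the coefficient belongs to living within
5 km.  Knowledge is dual-coded by design: a 0–22 count where it is a
dependent variable, three categories (0 / 1–4 / 5+) wherever it is a
predictor; both codings live on one variable spec (`predictor_encoding`).

Care-seeking for a maternal complication is *stored* missing for women
without a complication but enters the outcome equation with missing coded as
the reference ("no qualified care sought"), which is how the published
equation attains its full sick-subset sample size.

## Estimation

Logit equations are fitted by IRLS maximum likelihood (statsmodels GLM,
deviance tolerance 1e-10, at most 100 iterations; the deviance trace is
monitored and any increase across iterations fails the fit); the gaussian
equation is exact OLS.  Perfect separation is detected post-fit (fitted
probabilities within 1e-10 of 0/1) and raised as an error naming the
offending terms; a fixed ridge (λ ≈ 1e-6) can be enabled to push through
separated toy inputs, and is off by default so the fit has exact MLE
semantics.  Rank-deficient designs raise an error naming the collinear
columns.

Coefficient covariances use the sandwich estimator A⁻¹BA⁻¹ — bread A the
observed information (logit) or X′X (gaussian), meat B the sum of
per-observation score outer products — with the HC1 small-sample factor
n/(n−k) at the observation level by default, or the cluster factor
G/(G−1)·(n−1)/(n−k) with scores summed within clusters.  The published
analysis states only that robust standard errors were used, without naming
the estimator or a clustering level; both are provided, observation-level
HC1 being the default.  The joint covariance across equations is
block-diagonal by default (exact for a factorized likelihood under correct
specification); a `stacked_sandwich` mode fills cross-equation blocks from
score cross-products over shared observations for sensitivity analysis.

All intervals are Wald with z = 1.959964; significance stars are two-sided
Wald p-values (< 0.05 → `*`, < 0.01 → `**`).

## The mediation calculus

Every reported effect is a linear combination of products of link-scale
coefficients:

* direct effect — the exposure's coefficient in the outcome equation;
* indirect effect along exposure → M₁ → … → outcome — the product of the
  exposure's coefficient in M₁'s equation and each mediator's own
  coefficient in the next equation;
* total indirect — the sum over pathways; total — direct + total indirect;
* mediation proportion — 100 · total indirect / total, reported only when
  both a direct and an indirect component exist.

The additive identities hold exactly by construction: the total-indirect
value is the floating-point sum of the path values in order, and the total
is direct + total indirect.

**Average relative effect.**  A multi-categorical exposure is summarized by
the arithmetic mean of its per-level link-scale coefficients.  The default
averages only levels significant at p < 0.05 (an exposure leg with no
significant level renders the effect undefined, displayed "–");
`are_mode="all"` averages every non-reference level.  Significant-levels
averaging is the default because it uniquely reproduces the published
per-path cells for education, age, number of children and wealth-via-ANC;
all-levels averaging does not.

**Knowledge as a mediator.**  Its effect on the outcome is the 5+-vs-0
category coefficient (ln 1.44 ≈ 0.36) — the coding that reproduces the
published ANC-via-knowledge and facility-delivery-via-knowledge cells — and
is configurable to any level.

**Pathway sets.**  `enumerate_paths` returns all simple directed paths with
up to `max_mediators` intermediates (default 1, matching the published
single-mediator decomposition), excluding mediators whose own equation is
estimated on a strictly smaller subpopulation than the outcome's: the
complication care-seeking variable is undefined for most of the outcome
population, so a product effect through it is not decomposable (hence ANC
has three mediating pathways, not four).  The built-in diagram additionally
records the conceptual framework's hypothesized mediation pathway sets, and
`decompose` follows them by default.  For every exposure but one this set
coincides with enumeration plus the significance screen; for mother's age
the framework's set is narrower than the regression adjacency (facility
delivery and knowledge only, omitting structurally possible ANC and PNC
channels), a feature of the source analysis that cannot be derived from the
coefficient table.  Structural enumeration remains the fallback for
diagrams without the annotation and for `max_mediators > 1`.

**Delta method.**  For θ = Σ_k w_k Π_j β_kj the gradient is assembled
analytically (∂θ/∂β = Σ over terms containing β of the product of the other
factors, weighted) and SE = √(gᵀΣg).  With the published coefficient table
as a source, Σ is diagonal with SEs backed out of the printed 95% CIs —
(upper − lower)/(2·1.96) on the link scale — as the table publishes no
covariances.  The delta SE is first-order: for a two-factor product it
omits the σ₁²σ₂² term, so its relative deviation from the exact product
sd is ≈ ½/(z₁² + z₂²).  For the pathways of the published analysis this is
under 5% (worst ≈ 4.7%); for weakly identified legs (both |z| near 2) it
can exceed 5%, which is why the simulation cross-check of the delta SEs on
fitted systems is asserted on the strongly identified maternal-care
pathways.

**Display.**  Effects are rounded half away from zero to 2 decimals,
proportions to 1 decimal; internal arithmetic never rounds.

## Reproducing the published decomposition

`reproduce_paper` recomputes the decomposition from the packaged
coefficient transcription and compares it cell-by-cell with the packaged
decomposition transcription.  A curated fixture
(`table3_curated_cells.csv`) versions the comparison surface: 40 cells
reproduce exactly at 2-decimal rounding; the remainder are excluded with a
per-cell justification and fall into two classes — (i) cells whose printed
value reflects unrounded source coefficients (e.g. the facility-delivery-
via-PNC cell prints 0.60 where ln 41.22 × ln 1.18 = 0.62) and (ii) cells
internally inconsistent with the printed sources (the PNC-via-knowledge and
counseling-via-knowledge cells are ≈2× any consistent knowledge→outcome
coefficient; wealth-via-PNC is irreproducible under either averaging mode).
The published mediation proportions equal the proportion formula applied to
the *printed rounded* effect cells for every row (e.g. 0.40/0.63 → 63.5%),
not to the unrounded pipeline values (63.0% for ANC); the comparison
verifies the proportion operation against the printed components and
records that route per cell.

## The synthetic survey generator

The survey records behind the published analysis are access-restricted, so
the generator emulates their statistical structure:

* **Design.**  14 districts × 120 clusters × 10 records (≈16,800 by
  default; `n_records` overrides the total — tests use 17,251), nested
  district/cluster labels, an illness flag at prevalence 0.508, and a
  maternal-complication flag at rate 2993/8765 among mothers of sick
  neonates and 1720/8486 otherwise, reproducing both the published
  complication-equation subsample (N ≈ 2,993) and the overall complication
  count (N ≈ 4,713).
* **Exogenous covariates** are drawn independently from the published
  overall marginals (renormalized from printed percents).  Real covariates
  are correlated (wealth with education, for instance); simulating them
  independently leaves the conditional model correct but makes the
  synthetic marginal structure simpler than reality.
* **Endogenous variables** are drawn in topological order through the DAG
  with the published link-scale coefficients as ground truth: Bernoulli
  (inverse-logit η) for logit equations; for knowledge a latent gaussian
  (residual sd 1.5, a value that keeps the rounded count distribution
  within the instrument's 0–22 support with a realistic spread) rounded to
  the nearest integer and clipped.  An optional per-equation, per-cluster
  link-scale intercept perturbation (`cluster_effect_sd`, default 0 — the
  published model has no cluster effect) supports cluster-robust
  covariance experiments.
* **Intercepts** are not published; they are calibrated in topological
  order by Brent root-finding on one large simulated population (default
  n = 200,000) until each simulated marginal is within ±0.005 of its
  target — the published overall marginals for the maternal-care variables
  (0.273, 0.522, 0.434), 0.650 among the complication subset, 0.365 among
  the sick subset for the outcome, and a mean knowledge count of 3.0
  (consistent with the published category distribution 3.4% / 78.9% /
  17.6%).  The gaussian target is solved on the rounded/clipped scale so
  clipping bias is absorbed.  Everything is deterministic given the design
  seed.

What passing tests show — and do not.  Parameter recovery, CI coverage and
decomposition coverage on this generator demonstrate that the estimator and
the mediation calculus are correct *under the generating model*: GLM
equations with the stated links, independent records, independent exogenous
covariates.  They do not validate the model against design features of real
surveys the generator omits (cluster correlation unless enabled, covariate
correlation, non-response, measurement error), nor the causal ordering of
the hypothesized DAG, which a cross-sectional survey cannot establish.

## Problem sizes used by the test suite

The recovery study simulates at the survey's size (n = 17,251; sick subset
≈ 8,765) over 150 replicates — enough that the per-coefficient coverage
*estimator* (sd ≈ 0.018 at 150 draws) sits comfortably inside the
[0.88, 1.00] acceptance band when true coverage is 0.95.  Calibration uses
n = 200,000; delta-method cross-checks use 10,000 parametric draws.

## Known limitations

* The fixture source carries no cross-equation or within-equation
  covariances, so fixture-based CIs for sums across equations treat
  coefficients as independent; the published CIs were computed from the
  full fitted covariance and differ in the last digit for some rows.
* Product-of-coefficients effects on the odds-ratio scale are
  non-collapsible; no rare-outcome correction is applied (none is part of
  the method being implemented).
* Counterfactual (natural direct/indirect) mediation effects and
  exposure–mediator interactions are out of scope: the calculus is pure
  coefficient algebra on the link scale.
* The significant-levels averaging rule makes the estimand data-dependent
  near the significance threshold; `are_mode="all"` provides the
  deterministic alternative and is used for the coverage studies.
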