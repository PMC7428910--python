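# Methods

This note documents the models implemented in `elmh`, the choices made
where the design was genuinely open, and what the synthetic cohorts do
and do not establish about real questionnaire data.

## The measurement problem

A 44-item workplace mental-health questionnaire (the ELMH instrument)
groups its Likert items into 8 domains — mental health, attitude to
patients, diversified, adjustment, persevering, teamwork, physical
health and behavior — of sizes 16, 5, 4, 4, 5, 4, 4 and 2.  Two
summaries of a respondent drive the classification:

* a **severity measure** θ on a logit scale, estimated from the whole
  response string; and
* a **person-fit statistic**, the outfit mean square, which detects
  response patterns (careless, random, or otherwise aberrant
  responding) that the measurement model cannot account for.

Cutting the (measure, outfit) plane at 0 logits and outfit 2.0 yields
four classes: II — mental illness (high measure, model-consistent
responding), III — healthy, and I/IV — "false MI" / "false health",
where the apparent result carries low confidence because the pattern
misfits.  Exact boundaries go to the low-measure side and to the misfit
side (a measure of exactly 0 is "not above" the cut; outfit exactly 2.0
counts as misfit); the instrument does not define behaviour on the
boundary, so the package fixes it.

## Continuous-response Rasch model

Responses bounded on [m, M] are modelled by the scaled-logistic
expected score

    E_pj = m + (M − m)·σ(θ_p − δ_j),      σ(x) = 1/(1+e^{−x}),

with model variance W_pj = (M − m)²·p_pj(1 − p_pj), p_pj = σ(θ_p−δ_j).
Estimation is joint maximum likelihood on the [0, 1]-rescaled responses
x_pj, using the estimating equations Σ_j (x_pj − p_pj) = 0 for each
person and Σ_p (x_pj − p_pj) = 0 for each item (the continuous
analogue of the dichotomous Rasch score equations).  These are solved
by alternating damped-Newton sweeps; item difficulties are centred to
mean 0 after every sweep (the model is translation-invariant, so a
location constraint is required).  Convergence is declared when the
largest absolute parameter change falls below 1e-6 (configurable), with
a cap of 500 sweeps and a warning plus a `converged` flag if the cap is
hit.  All-minimum or all-maximum response strings have their raw score
pulled 0.3 score units off the boundary (the conventional extreme-score
adjustment) so they receive finite measures.

The person outfit mean square is the average squared standardized
residual across the L items a person answered:

    outfit_p = (1/L) Σ_j (O_pj − E_pj)² / W_pj.

Its expectation is 1 when the data follow the model; values at or above
2.0 flag aberrant patterns.  Outfit is deliberately outlier-sensitive:
an unexpected extreme response on an item far from the person's level
(where W_pj is small) contributes a very large standardized residual.
Infit, standardized fit statistics, and likelihood-based person-fit
indices are out of scope.

Rating-scale category-probability curves are provided for display:
P(k | θ) ∝ exp(Σ_{h≤k}(θ − δ − τ_h)) over categories k = 0..K−1 with
the empty sum 0, so each grid row sums to 1 and adjacent categories are
equally probable exactly at θ = δ + τ_k.

## Synthetic cohorts

The generator is the package's study-condition definition, not a
convenience fixture.  Defaults emulate the cohort the pipeline targets:
352 respondents, 44 items, severity θ ~ N(−0.85, 1) logits (about 20%
of respondents above 0), item difficulties equally spaced on ±4 logits,
and 6.8% aberrant responders, which yields a class structure dominated
by quadrant III, as in the target survey (printed counts 6/63/265/18).

**Conforming responders.**  A model-conforming response is drawn as
m + (M − m)·B with B Beta-distributed with mean p_pj and variance
noise_sd²·p_pj(1 − p_pj), then rounded to the Likert grid.  `noise_sd`
is therefore the residual standard deviation as a fraction of the
model-implied one: at `noise_sd = 1` (the default) the respondent is
exactly as noisy as the model assumes — the Beta degenerates to the
two-point distribution on {m, M}, which is the only distribution on the
interval attaining the model variance — and the outfit statistic is
calibrated (mean ≈ 1).  At `noise_sd = 0` responses equal the rounded
expected scores.  Additive Gaussian noise was rejected because clipping
it at the scale bounds truncates roughly half the variance and shrinks
the recovered difficulties, leaving the fit statistic miscalibrated.

**Aberrant responders.**  Uniform random responses over the Likert
range — the simplest careless/guessing mechanism.  Their outfit is
inflated because random responses on items far from the scale midpoint
land many model standard deviations from expectation.  The ±4-logit
difficulty spread is what makes such items exist; with a narrow spread
random responders are nearly indistinguishable from noisy conformers.

**Dimensionality.**  By default a single severity trait generates all
items (the measurement model's own assumption).  Setting
`domain_trait_sd > 0` adds independent per-domain traits;
`eight_domain_config()` (no shared trait, strong domain traits,
moderate noise) produces data in which exploratory factor analysis
retains exactly the eight domain factors by the eigenvalue ≥ 1 rule.

**Truth labels.**  `true_quadrant` is produced by fitting the Rasch
model to the generated cohort and applying the standard cutoffs — the
same procedure a user of the pipeline would run — not by the aberrant
flag alone.  A conforming responder can land in I/IV by bad luck and an
aberrant one can pass as II/III; the labels reflect that honestly.

**What the simulations do not show.**  Real survey data have
demographic structure, missing responses, category-usage quirks and
multidimensionality that the generator does not emulate, so passing
recovery tests here demonstrates internal consistency of the pipeline,
not validity of the instrument.  Misfit detection also degrades when
contamination is heavy: beyond roughly 10–15% aberrant responders the
jointly re-estimated difficulties shrink toward the centre and mask
misfit, so the "more aberrant responders ⇒ more flagged misfits"
relation is tested (and holds) only in the low-contamination regime the
target survey occupies.

## Factor scoring

Factors are retained by the eigenvalue ≥ 1.0 rule (inclusive),
extracted as principal components of the item correlation matrix and
varimax-rotated; per-item uniqueness is 1 − communality.  Rotation is
an open choice (the instrument's own analysis does not state one);
varimax over principal components is the most common default and is
configurable.  Extracted factors arrive in eigenvalue order, so when
one factor per domain is requested the columns are re-assigned to
domains by maximizing total squared loading on each domain's items
(optimal assignment) and signed so own-domain loadings are positive.

Person scores use the Bartlett weighted-least-squares estimator
F = (ΛᵀΨ⁻¹Λ)⁻¹ΛᵀΨ⁻¹z on standardized responses; standardization uses
the fitting cohort's item means/SDs, which are persisted in the model
bundle so a single new respondent is scored consistently.

For on-device scoring the package ships the eight published linear
shortcuts mapping each domain's raw sum to its factor score
(domain 1: −3.2516 + 0.08190 × sum, …, domain 8: −4.2156 + 0.6377 ×
sum), and can refit such shortcuts on any cohort by per-domain OLS.

## Micro-CNN

The classifier is a deliberately minimal, spreadsheet-style
convolutional network.  The 44 responses are rescaled to [0, 1] and
placed row-major in a 10×10 grid (56 trailing cells zero); 10×10 is the
smallest square whose 3×3-convolution (stride 1) + 2×2 max-pool chain
produces the 16-element pooled layer that makes the parameter count
come out exactly: each of the 4 classes owns 9 filter weights + 1 bias
and 16 pooled-layer weights + 1 bias, 4 × (10 + 17) = 108 parameters in
total.  Rectangular geometries are supported for the two-class
demonstration network (pooled length 8, 38 parameters).

Each class output is an independent sigmoid — there is no softmax — and
the loss is squared error against one-hot targets, averaged over
respondents.  Training is full-batch gradient descent with a fixed
learning rate (default 2.0, at most 5000 epochs, stopping when the loss
improves by less than 1e-8), from seeded uniform(−0.5, 0.5) initial
weights; the best iterate seen is returned, so the reported loss never
exceeds the initial one.  Prediction takes the largest output with ties
broken to the lowest class index.  The backpropagated gradient is
verified against central differences in the test suite.  No train/test
split is applied by default: the reported accuracy is apparent
(resubstitution) accuracy on the fitting cohort, matching how the
target analysis reported its own.

## Discriminant baseline and planning utility

The comparison classifier is classical linear discriminant analysis
with equal class priors (class sizes are extremely unbalanced and the
reference analysis states no priors): class means, pooled within-class
covariance, linear scores.  A singular pooled covariance triggers an
automatic 1e-6 diagonal ridge with a warning.  It is run on the 8
factor scores alone and on the 8 scores plus outfit; the fit statistic
is what separates the low-confidence classes, so the 9-feature set is
expected to do at least as well — the ordering the pipeline reproduces.

Survey planning uses n₀ = z²p(1−p)/margin² with the finite-population
correction n = n₀/(1 + (n₀−1)/N), ceiling-rounded, z = 1.959964 at 95%
and worst-case p = 0.5; N = 1521 gives 307.  Note that a follow-up
figure sometimes quoted alongside this calculation, "530 = 307/(1−0.4)"
for a 40% refusal allowance, is arithmetically inconsistent
(307/0.6 ≈ 512); the utility implements only the stated formula.

## Numerical notes and limitations

* Person/item Newton steps are damped (clipped at 2 logits) and the
  curvature floored at 1e-10; the score equations are monotone, so the
  solves are safe.
* The quadrant-label CSV/JSON schemas carry a `schema_version` field;
  parameter files are validated against the geometry's parameter count
  on load.
* Problem sizes used by the test suite (cohorts of 300–1000 persons,
  20-seed comparisons, one full CNN training run of ≤ 5000 epochs) were
  chosen to make every stochastic property comfortably stable while
  keeping a full run around half a minute.
* The continuous-response Rasch formulation and the outfit definition
  follow the standard forms stated above; where the reference analysis
  left its exact variant unstated (response scale of the instrument,
  EFA rotation, CNN optimizer and input geometry), the choices here are
  declared defaults, each configurable.
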