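# Methods

This note documents the statistical machinery in promcat: the models and
algorithms, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the engine's known
limitations.

## Measurement model

All scales are scored under Masters' partial credit model (PCM), the
polytomous member of the Rasch family.  An item with categories
0…m carries m step thresholds δ₁…δ_m (logits) and

P(X = x | θ) ∝ exp(xθ − Σ_{k≤x} δ_k),  with the empty sum 0 for x = 0.

Thresholds are *not* constrained to be ordered: threshold reversals are
legal PCM solutions and calibration may produce them.  All category
probabilities are computed in log space with max subtraction
(`log_softmax`), so trait values up to |θ| = 30 are handled without
overflow; probability vectors sum to 1 within 1e-12 over that range.

The Fisher information of a PCM item at θ equals the conditional category
variance Var(X | θ), which is also dE(X | θ)/dθ; the test suite checks the
implementation against that derivative identity by finite differences.

### The 0–100 reporting scale

Clinical users see scores on 0–100, not logits.  The transform is linear
between two anchors θ_lo → 0 and θ_hi → 100 and clipped outside.  The
anchors are the EAP estimates for the all-minimum and all-maximum
full-length response vectors of the scale, computed with the same
estimator configuration used for scoring.  This makes the scale
estimator-consistent — a respondent at an extreme raw score maps exactly
to 0 or 100 — and mirrors the usual convention of anchoring transformed
scores to the extreme raw scores.  Since EAP is shrunken by the prior,
the anchors (and hence the points-per-logit slope, typically ≈ 17–20
points/logit for these banks) depend on the prior; calibration and
replay must share one configuration, which the engine enforces by
storing anchors in the bank.

## Item bank calibration

Thresholds are estimated by **marginal maximum likelihood** (MML): EM
over a fixed standard-normal latent density evaluated on a 61-node
evenly spaced grid over ±6 logits, with up to three damped Newton updates
per item per M-step.  The gradient of the expected complete-data log
likelihood with respect to δ_k is Σ_q [P_q(X ≥ k)·n_q − r_q,k] and the
Hessian is minus the weighted covariance of the indicators 1{X ≥ k}.
Convergence is declared when the largest threshold update falls below
1e-6 (iteration cap 500, reported in the result).

Joint (person-by-item) maximum likelihood was considered and rejected:
with a fixed test length L it is inconsistent, inflating the threshold
spread by roughly L/(L−1) — a ~12–15% bias at the 7–12-item scales this
engine targets, which we measured directly and which does not shrink
with sample size.  MML with a normal latent density is consistent here
and matches the Bayesian scoring model used downstream.  Parameter
recovery on simulated 8-item, 4-category scales is ≈ 0.10 logits RMSE at
n = 1000 and ≈ 0.07 at n = 2000.

Identification: the latent location is fixed during EM by the N(0, 1)
density; at convergence all thresholds of the scale are recentered to
mean zero (equivalently, the latent origin is shifted), the conventional
Rasch centering that makes banks comparable across runs.

Category bookkeeping: unobserved *extreme* categories are structurally
collapsed (the coding is shifted/truncated and the collapse recorded in
the result); an unobserved *interior* category is a hard error naming the
item and category, because the step between two never-seen adjacent
categories is not estimable.

Person traits reported with the calibration are per-person maximum
likelihood at the calibrated thresholds (damped Newton, clipped to ±10
logits).  Persons with all-minimum or all-maximum raw scores have no
finite MLE and are reported as excluded from person estimation; they
still inform the thresholds through the marginal likelihood.

### Fit diagnostics

With standardized residual z = (x − E(X|θ̂)) / √Var(X|θ̂) at the person
trait estimates: **outfit** is the unweighted mean of z² per item and
**infit** the information-weighted version Σ(x − E)² / ΣVar.  Under the
model both are near 1, but they center slightly below 1 (roughly
(L−1)/L) because each person's trait is estimated from the same L
responses being diagnosed; tests assert a [0.85, 1.15] band under the
null and that an injected trait-unrelated item stands out well above 1.

## The adaptive engine

EAP estimation integrates the posterior on a fixed evenly spaced grid of
61 nodes over prior_mean ± 6 logits, weighted by the Normal(0, 1) prior
density.  For smooth, effectively compactly supported integrands this
rectangle rule is extremely accurate: estimates agree with dense
10,001-point trapezoid integration within 1e-4 logits (tested), and with
no responses the estimate returns the prior mean and SD within 1e-6.
Every estimate is recomputed from scratch on the same grid with the same
item summation order, so a replay at full length reproduces the
full-length estimator *bitwise*.

Item selection defaults to maximum Fisher information at the current EAP;
`posterior_weighted_info` (information averaged over the current
posterior) is available by configuration.  The first item is selected at
the prior mean — a determinate start without burn-in randomization.
Exact criterion ties break to the lowest bank position; a seeded random
preference order can be configured instead, which is the engine's only
source of randomness.  Stopping is a fixed item count per scale;
standard-error-based stopping is deliberately out of scope (fixed lengths
keep the assessment burden predictable and auditable).

Replay answers each selected item from a recorded complete response
vector; live administration answers from a callback with bounded
re-prompting (default 3 retries) on invalid input.  Both share one code
path, so a scripted callback reproduces a replay trace exactly.

## Replay validation

For each length in the grid, every respondent is replayed and both
administrations are scored on 0–100.  Agreement statistics, with the
difference convention d = cat − full:

* Pearson r between CAT and full-length scores (undefined for constant
  vectors; reported as NaN with a warning);
* RMSE = √mean(d²), in 0–100 points;
* Bland–Altman 95% limits of agreement mean(d) ± 1.96·SD(d), sample
  (n−1) SD.  The classical 1.96 multiplier is used rather than a
  t-quantile; at validation-study sample sizes (hundreds) the difference
  is negligible.  Empirical coverage is ≈ 95% (±2%, tested at n = 10,000)
  when differences are roughly normal.

Sensitivity arms rebuild the analysis set four ways — listwise exclusion
(raw), listwise + Mahalanobis outlier removal, deterministic imputation,
and imputation + outlier removal — and never change the length grid.  On
clean complete data all four arms coincide exactly.

## Quality control

* **Listwise exclusion** drops persons missing any response among the
  scale's items; missingness outside those items is ignored.
* **Mahalanobis screening** computes each person's squared distance from
  the column means under the sample covariance, on the raw category
  codes (screening precedes scoring in the pipeline).  A person is
  flagged when d² exceeds the χ² quantile at 1 − α with df = number of
  items; default α = 0.001, configurable.  Singular covariances are
  ridge-regularized (λ = 1e-6 · trace/p) with a warning.  The flag rate
  tracks α within 1% on multivariate normal data at n = 10,000.
* **Imputation** is deterministic single imputation: the item's modal
  observed category (default; ties to the lower category) or the
  person's rounded within-scale mean, clipped to the legal category
  range.  Every imputed cell is logged.  Model-based or multiple
  imputation was rejected to keep the sensitivity arms interpretable.

## Synthetic data generator

No patient-level responses are publicly available for the instrument the
defaults emulate, so all tests run on synthetic data.  The default
conditions mirror the field-test structure: eight scales of
9, 7, 8, 10, 10, 10, 12, 10 items; 3–5 response categories per item;
item locations drawn N(0, 1) with evenly spaced steps at half-spacing
U(0.2, 1), thresholds centered per scale; respondents drawn θ ~ N(0, 1);
and a demographic mix (ages 8–29, 55% male, cleft types weighted toward
CLAP, a 12-country roster) that matches the real cohort's marginals
qualitatively without claiming its joint distribution.  All randomness
flows through seeded PCG64 (`numpy.random.default_rng`) streams keyed by
(seed, scale, purpose), so every artifact is bit-for-bit reproducible
from the seed.  True trait values are emitted alongside the data for use
as test oracles only.

Injected artifacts provide QC ground truth: cells are set missing
independently at a configured rate, and a configured fraction of persons
are overwritten with **anti-model patterns** — on every item,
independently, the bottom or the top category at random.  No single
trait level can produce such a pattern, so these rows break the
inter-item correlation structure that defines model-consistent
responding.  Randomizing the extreme per item spreads the outliers
across many directions so they do not mask one another in the sample
covariance; a deterministic "mirror of the modal response" was tried and
rejected because all injected persons then share one deviation
direction, inflate the covariance along it, and become undetectable
(measured sensitivity 0).  When a battery is generated, the *same*
persons are corrupted on every scale; screening the combined battery
recovers them with sensitivity ≥ 0.8 (measured 1.0 at n = 1000, 10%
injection, α = 0.001).  Detection power is much lower on a single
9-item scale — multivariate screening needs width.

What passing tests on these data do **not** show: real respondents
violate the PCM (multidimensionality, differential item functioning,
response styles), real missingness is not completely at random, and real
outliers are not maximally inconsistent.  Agreement numbers from the
synthetic replay study (minimum r ≈ 0.98 at two items short of full
length; maximum RMSE ≈ 3.5 points at the reduced battery lengths, n =
500/scale) characterize the engine under model-true conditions and are
expected to be mildly optimistic relative to field data.

## Problem sizes and numerical choices

The default replay study uses 500 respondents per scale and the test
suite completes in under a minute on one CPU; calibration examples use
n = 250–2000.  Quadrature: 61 nodes over ±6 logits everywhere (21
minimum enforced); EAP truncation error is negligible for priors with SD
≈ 1 — widen `quadrature_range` for substantially larger prior SDs.
Convergence tolerances: 1e-6 on threshold updates (calibration) and on
the person Newton steps; Newton steps are damped to a maximum of 1 logit
per update; trait estimates clip at ±10 logits.  Degenerate inputs are
errors, not silent repairs: interior category gaps, incomplete vectors
at replay, fewer than 3 pairs for agreement, empty reference populations
after filtering.

## Score interpretation

The reporting payload expresses a 0–100 score as a **mid-rank
percentile** — 100·(#{ref < s} + ½·#{ref = s})/n — within a reference
population filtered by age interval and category sets for gender, cleft
type, laterality, and country (conjunctive semantics; empty filter = no
filtering), alongside the filtered population's median per scale.
Mid-rank was chosen because it is symmetric, bounded, and well defined
under ties; self-percentiles of a continuous reference average 50.
Filtered subsets below n = 20 are flagged in the payload rather than
suppressed — small reference samples make percentiles unstable, and the
instability should be visible.  Higher scores are clinically better by
convention, and the payload says so explicitly.

## Limitations

* One latent dimension per scale; no differential item functioning,
  graded-response or 2-parameter models, multidimensional IRT, or
  person-fit statistics.
* Fixed-length stopping only; no exposure control or content balancing.
* Interpretation is cross-sectional: without longitudinal anchor-based
  minimal-important-change estimates, score changes over time cannot be
  given a clinical meaning by this engine.
* The Mahalanobis screen is the classical non-robust estimator by
  design (simple, auditable); it degrades at high contamination rates
  and on narrow single scales.
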