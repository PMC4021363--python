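# Methods

## The model

`dietrrr` implements reduced rank regression (RRR, also called redundancy
analysis) for dietary pattern analysis. Let X be the n × p matrix of
standardized food-group intakes and Y the n × q matrix of standardized
risk-factor responses. RRR extracts factors ("dietary patterns")
t_k = X a_k, linear combinations of food groups chosen to maximize the
summed squared correlation with the response set, subject to
orthogonality with the earlier factors. Computationally:

1. fit the multivariate OLS regression Ŷ = X (XᵀX)⁻¹ XᵀY;
2. eigendecompose the sample covariance of Ŷ: the orthonormal
   eigenvectors v_k are the response loadings and the eigenvalues λ_k
   (nonincreasing) the variances of the fitted-response projections;
3. set raw weights a_k = (XᵀX)⁻¹ XᵀY v_k, then rescale so each training
   score has sample SD 1 — participants receive z-scores, and the reported
   weights are in the scaling that reproduces those z-scores.

Equivalently, a_k is the k-th generalized eigenvector of
(S_xy S_yx, S_xx); the test suite verifies this equivalence against an
independent generalized-eigenproblem solve and a direct numerical
maximizer of the criterion.

"Explained variation" of factor k in response j is 100 · corr(t_k, y_j)²;
the report carries a per-factor mean over responses (the criterion RRR
maximizes) and a mean squared correlation with the food columns. Because
responses are standardized before fitting, explained variation summed over
all q factors equals 100 · R² of the OLS regression per response — an
exact conservation identity used as a test invariant. Standardizing the
responses is a modelling choice (it makes the criterion unit-free and the
table percentages comparable across responses); both the z-score-scaled
weights (default, labelled "weights") and the correlation-scaled food
loadings are exposed.

Sign conventions: each factor's sign is fixed at fit time by making the
largest-|weight| food positive; cross-wave comparability is restored later
by aligning the second wave's factors to the first (flip when the weight
dot product is negative). Exact eigenvalue ties would make the factor
order and directions non-unique; the implementation simply takes the
symmetric eigensolver's ordering, which is deterministic for a given
input but unstable under perturbations near a tie.

## The analysis pipeline

The two-wave pipeline mirrors a repeated-measures cohort analysis:

1. **(optional) energy adjustment** — each food column is replaced by its
   residual from a simple regression on total energy (kJ/day), plus the
   column mean, so units and location are kept and the adjusted intake is
   uncorrelated with energy.
2. **standardization** — z-scores per column, sample (n−1) SD. One
   convention is used everywhere (standardization, correlations, explained
   variation). Constant columns are rejected by name; missing cells are
   rejected at read time (complete-case contract, no imputation).
3. **backwards screening** — for each wave and each single response,
   multiple linear regression of the response on all food groups with
   iterative removal of the food with the largest coefficient p-value
   until all remaining p ≤ α (default 0.05; ties drop the later column,
   making the path deterministic). A food enters the pattern model when it
   survives for at least `min_responses` responses (default 3, i.e. "more
   than two") in at least one wave; requiring both waves is a config
   option. Screening runs on standardized intakes without an energy
   covariate by default; both choices are configurable.
4. **pattern-count selection** — Monte-Carlo cross-validation on the
   baseline wave: `cv_n_splits` independent random holdouts of
   `cv_test_fraction` of the participants (defaults 1000 × 10%). Per
   split, foods and responses are standardized with training parameters
   only, and held-out standardized responses are predicted by the rank-k
   regression Ŷ = X B V_k V_kᵀ for every k at once; k = 0 predicts the
   training mean. Squared errors accumulate into PRESS_k. Van der Voet's
   randomization test compares each k against the PRESS minimizer: the
   statistic is the mean paired difference of per-cell squared errors, its
   null is built by independent sign flips, and the add-one p-value has
   floor 1/(1 + n_randomizations). The chosen count is the smallest k not
   significantly worse than the minimizer at α = 0.10 (common practice
   for this test; configurable). Pooling cells across all responses is the
   default aggregation. A chosen k = 0 is a first-class outcome: the
   report then states that no pattern predicts the responses better than
   the null model.
5. **stability assessment** — exploratory scores (fit and score within a
   wave) versus confirmatory scores (weights fixed from wave L, applied
   to the standardized diet of wave D, rescaled to SD 1). By default the
   diet wave is standardized by its own means/SDs — the natural reading
   of scoring "the standardized intake data" of the other year — with the
   loading wave's parameters available as an option. The report is the
   full Pearson matrix over the four blocks (exploratory × 2,
   confirmatory × 2 directions) with two-sided p-values and Fisher-z 95%
   intervals, tanh(atanh r ± z/√(n−3)), plus a structural comparison per
   factor: high-weight foods (|w| strictly > 0.10) shared across waves and
   their sign agreement, and the per-food cross-wave Spearman table
   (average ranks for ties — essential with zero-inflated intakes; a
   zero-variance food yields a missing correlation, never 0). Factors are
   matched across waves by index, as is conventional; |cosine|-based
   assignment is used only as a diagnostic in the recovery analyses.

## The synthetic cohort generator

No suitable raw cohort of this kind is publicly deposited, so the
generator is a first-class module that provides ground truth for every
downstream stage. It emulates an elderly-male cardiovascular cohort
measured five years apart: n = 467 participants, 19 food groups (g/day,
right-skewed, many zero-inflated), six roughly normal risk factors (BMI
kg/m², systolic/diastolic blood pressure mmHg, total and HDL cholesterol
mmol/l, uric acid mmol/l), and a small number of latent diet–risk
patterns each explaining a few percent of response variation.

Generative model, per participant:

- K latent pattern scores, drawn as standard-normal pairs across waves
  with per-pattern tracking correlation ρ (defaults 0.6/0.5/0.4 — chosen
  so pattern-score stability lands in the moderate range reported for
  elderly cohorts, and bracketed by the food-level Spearman tracking of
  roughly 0.14–0.71 that the marginal specs produce);
- latent food values: pattern signal W z + noise (W has orthonormal
  columns; intake noise SD 0.3), pushed through a monotone per-food
  transform x = scale · exp(σ·latent) location-matched to a target median
  (a fallback scale of 25 g/day is used for zero-median foods), then the
  lowest π-quantile of each column censored to 0. Skewness therefore
  lives entirely in the marginal transform: the pattern signal stays
  linear on the latent scale and is recoverable, and zero inflation is
  deterministic quantile censoring, so ranks among non-zeros are
  preserved. Per-food medians, σ (set from median-to-90th-percentile
  ratios) and π follow published food-group descriptives for this kind of
  cohort; a further 17 signal-free food groups can be appended to emulate
  the wider 36-food universe;
- responses: V z + unit-SD Gaussian noise, rescaled to target means/SDs
  on natural units (targets follow published cohort characteristics,
  e.g. BMI 25.7 ± 3.0 kg/m² at baseline). The default patterns are
  anchored on single food groups (high-fibre bread with negative sign,
  beer, cheese) with squared response-side strengths (0.42, 0.34, 0.26)
  spread over orthonormal response profiles. This calibration puts the
  measured first-pattern explained variation near 6% (the few-percent
  scale such patterns show in practice), makes the three patterns
  detectable by cross-validation in the 19-food universe while the
  36-food universe degrades toward fewer patterns, and gives the
  backwards screen a crisp active set to find;
- total energy: kJ/day, correlated ~0.3 with the summed latent diet and
  calibrated to wave-specific means/SDs.

Reproducibility is bit-exact from a single integer seed. Two switches
exist for exactness experiments: `share_wave_noise` reuses the wave-1
noise draws so ρ = 1 makes the waves identical, and
`orthonormalize_latents` whitens the latent scores in-sample, removing
finite-sample factor mixing so that noise-free configurations recover the
true weights exactly.

What the generator does **not** emulate: the survey's food-group
taxonomy and aggregation, seasonality of intake, dropout and mortality
between waves, measurement error correlated across foods, and non-Gaussian
dependence between foods beyond what the shared latent patterns induce.
Passing tests therefore demonstrate correctness of the machinery and its
behavior under a controlled data-generating process, not distributional
fidelity to any particular cohort.

## Numerical choices and degenerate inputs

- X'X with condition number above 1e10 is rejected with a diagnostic;
  k exceeding the rank of the fitted responses is rejected.
- Quantiles use linear interpolation between order statistics (numpy
  default, "type 7").
- The Fisher interval is undefined at |r| = 1; the stability report
  stores the degenerate bounds (r, r) for numerically exact unit
  correlations (the same-wave identity cells) and raises for explicit
  calls with |r| = 1 or n ≤ 3.
- Backwards elimination requires n > p + 1; cross-validation requires
  more training rows than foods and rejects constant training columns.
- All Monte-Carlo machinery (splits, sign flips, the generator) routes
  through numpy `SeedSequence` spawning, so every result is a pure
  function of (data, config, seed).

## Problem sizes used in the checks

The statistical checks run at the cohort's native size (n = 467) with
Monte-Carlo budgets of 200 cross-validation splits and 500 sign-flip
randomizations per test, 20–50 cohort replicates per operating
characteristic, and 400–1000 replicates for the null-calibration and
CI-coverage checks. These budgets give Monte-Carlo standard errors well
inside the asserted margins.

## Known limitations

- **Weight-vector sampling noise.** At n = 467 with patterns explaining
  only a few percent of response variation, the estimated weight vectors
  over p = 19 foods carry substantial sampling noise: the mean absolute
  cosine between estimated and true weight directions plateaus near 0.83
  at this size even in an idealized Gaussian setting with no marginal
  distortion (it reaches ~0.96 at n = 2000). Scores are estimated more
  reliably than weights. This is consistent with the moderate cross-wave
  weight stability such analyses report in practice, and it is the reason
  the package's stability machinery compares scores and high-weight food
  sets rather than trusting raw weight vectors.
- The backwards screen inherits the usual per-test false-retention rate
  of stepwise regression (~α per noise food per response); the
  cross-wave, multi-response retention rule suppresses most of it.
- PRESS-based selection is Monte-Carlo: with the default budgets the
  add-one p-value floor is 1/2001, and selection near the decision
  boundary can change with the seed.
- Energy adjustment is linear (residual method); nonlinear adjustment and
  intake log-transformation are out of scope.
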