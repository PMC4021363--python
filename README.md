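# dietrrr

Reduced rank regression (RRR) dietary patterns and their stability over
repeated dietary measurements.

Nutritional epidemiologists use RRR to extract *dietary patterns* — linear
combinations of food-group intakes — that maximize the explained variation
in a chosen set of disease risk factors, rather than merely describing the
diet (as principal components would). A cohort study that measures diet
twice can then ask whether those patterns are *stable*: do the same foods
carry the pattern, and does the pattern rank individuals the same way,
years apart? That question decides whether a single baseline diet
measurement is a usable proxy for long-term exposure. `dietrrr` packages
the full workflow for a two-wave cohort with p food groups (g/day) and q
risk-factor responses (e.g. BMI, blood pressure, total/HDL cholesterol,
uric acid):

- **Pattern extraction** — for standardized foods X and responses Y,
  factor scores t_k = X a_k with weights a_k solving the generalized
  eigenproblem S_xy S_yx a = λ S_xx a (equivalently, eigendecomposition of
  the fitted-response covariance of Ŷ = X(XᵀX)⁻¹XᵀY). Scores are
  z-scores; explained variation of factor k in response j is
  100·corr(t_k, y_j)².
- **Food-group screening** — backwards elimination of each single response
  on all foods (drop the largest coefficient p-value while it exceeds α),
  with a cross-wave retention rule (kept for ≥ 3 responses in either
  wave).
- **Pattern-count selection** — Monte-Carlo cross-validated PRESS over
  k = 0…k_max with Van der Voet's paired sign-flip randomization test;
  the chosen k is the smallest count not significantly worse than the
  PRESS minimizer (k = 0, "no useful pattern", is a first-class outcome).
- **Stability analysis** — exploratory scores (fit and score in the same
  wave) versus confirmatory scores (weights fixed from one wave, applied
  to the other wave's standardized intakes), with the full Pearson
  correlation matrix, Fisher-z 95% intervals, high-weight food overlap
  (|w| > 0.10) and per-food cross-wave Spearman tracking.
- **Synthetic two-wave cohorts** — a generator with known latent patterns
  (skewed, zero-inflated intakes; calibrated risk factors; per-pattern
  tracking correlations) so every stage can be validated against ground
  truth.

## Worked example

```python
import dietrrr as d

cfg = d.default_config(seed=1)                      # 467 men, 19 foods, 6 risk factors
intake1, intake2, resp1, resp2, truth = d.generate_cohort(cfg)

pipe = d.PipelineConfig(cv_n_splits=200, n_randomizations=500, seed=1)
result = d.run_pipeline(pipe, intake1, resp1, intake2, resp2)

print("chosen k:", result.chosen_k)
print("retained foods:", result.selection.retained_foods)
stab = result.stability
key = ("expl_w1:factor_1", "expl_w2:factor_1")
r = stab.correlations.loc[key]
lo, hi = stab.ci_lower.loc[key], stab.ci_upper.loc[key]
print(f"cross-wave pattern-1 correlation: {r:.2f} (95% CI {lo:.2f}-{hi:.2f})")
print(result.explained["wave1"].round(1))
```

prints (seed 1):

```
chosen k: 3
retained foods: ['high_fibre_bread', 'cheese', 'beer']
cross-wave pattern-1 correlation: 0.51 (95% CI 0.44-0.58)
                   factor_1  factor_2  factor_3  total
bmi                    11.5       2.0       0.2   13.7
total_cholesterol       0.9       2.5       1.3    4.7
hdl_cholesterol         0.1       6.8       1.0    7.9
systolic_bp             7.6       1.6       1.9   11.0
diastolic_bp            2.0       6.6       0.6    9.2
uric_acid              12.5       0.0       1.9   14.3
all_responses           5.7       3.3       1.1   10.1
all_foods              33.9      33.1      33.0  100.0
```

Reading this: the backwards screen kept the three food groups that truly
carry pattern signal in this synthetic cohort; cross-validation selected
k = 3 patterns; the first pattern explains 5.7% of the risk-factor
variation in wave 1 (per-response percentages above it, summing across
factors to the OLS R² per response); and individuals are ranked
moderately consistently by the first pattern five simulated years apart
(r = 0.51). The report files written by
`d.write_pattern_report(result, "out/")` include the weight tables with
high-weight flags, the PRESS curve with p-values, and the full
exploratory/confirmatory correlation matrix.

The same workflow is available from the shell:

```sh
dietrrr simulate --seed 1 -o cohort/
dietrrr run --wave1-intake cohort/intake_wave1.csv \
            --wave1-responses cohort/responses_wave1.csv \
            --wave2-intake cohort/intake_wave2.csv \
            --wave2-responses cohort/responses_wave2.csv \
            --seed 1 -o run/
dietrrr report --run-dir run/
```

Tables are plain CSV: first column the participant id, one column per
food group (g/day; an optional `energy_kj` column enables the
energy-residual adjustment, `--energy-adjust`) or per response. Missing
cells are rejected with their location — the pipeline is complete-case by
contract.

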