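# paintraj

Latent-class analysis of acute postsurgical pain trajectories.

`paintraj` clusters inpatients by the *shape* of their 0–96 h pain-score
trajectories and links cluster membership to long-term pain outcomes:

1. **Trajectory measures** — 24 level/trend/fluctuation measures per
   patient, robust to irregular observation times, with explicit handling
   of degenerate denominators.
2. **Latent clusters** — winsorized z-scoring → correlation-matrix PCA
   (Kaiser retention) → k-means; the number of clusters is selected by the
   cubic clustering criterion, with an explicit "no cluster support" flag.
3. **Trajectory decomposition** — a zero-inflated Conway–Maxwell–Poisson
   (ZICMP) mixed model per cluster separates the *likelihood of
   experiencing pain* from its *conditional intensity* over time
   (Laplace / adaptive Gauss–Hermite integration of a patient random
   intercept).
4. **Normalized AUC profiles** — interval areas under the fitted curves,
   normalized to [0, 1], that add exactly to the full-window area.
5. **Outcome models** — covariate-adjusted logistic regression of
   clinically meaningful pain (NRS ≥ 3) at 30 days and 1 year, with a
   forced cluster factor, backward elimination, and calibration /
   discrimination diagnostics.

A synthetic-cohort generator reproduces the statistical structure the
analysis assumes (two presets: one mirroring the motivating registry
cohort, one well-separated for recovery testing), so the whole pipeline is
testable without access to patient data. See `docs/methods.md` for the
statistical details and rationale.

## Worked example

From `examples/quickstart.py` — simulate a cohort, extract measures,
recover the planted clusters:

```python
from paintraj import (adjusted_rand_index, feature_matrix, generate_cohort,
                      pca_reduce, select_k, standardize,
                      well_separated_scenario)
from paintraj.features import DEFAULT_WINSOR_PCT, FEATURE_NAMES

config = well_separated_scenario(seed=0)
series, baseline, true_labels = generate_cohort(config)

features = feature_matrix(series)
z, _, _ = standardize(features[list(FEATURE_NAMES)],
                      winsor_pct=DEFAULT_WINSOR_PCT)
pca = pca_reduce(z)
k_star, ccc_table, assignment = select_k(
    pca.scores, range(2, 8), seed=0, restarts=50, patient_ids=list(z.index))
```

Output:

```
simulated 800 patients, 22292 pain scores
PCA retained 5 components (88% of variance)
 k       ccc    within_ss
 2 -2.343366 11569.960629
 3  8.065208  7653.052997
 4 43.723649  3910.229301
 5 39.371006  3530.394926
 6 38.451954  3157.962410
 7 39.058424  2823.017552
selected k* = 4, cluster sizes {1: 244, 2: 224, 3: 205, 4: 127}
adjusted Rand index vs planted labels: 0.964
```

Decompose one cluster's trajectory (`examples/trajectory_decomposition.py`):

```python
from paintraj import default_scenario, fit_zicmp, predict_decomposition

config = default_scenario(n_patients=400, seed=0)
series, _, labels = generate_cohort(config)
fit = fit_zicmp([s for s in series if labels[s.patient_id] == 1],
                starts="warm")
print(predict_decomposition(fit, np.arange(0.0, 97.0, 12.0)))
```

```
 time_h    pi  p_pain  mean_pain  cond_intensity       mode
    0.0 0.601   0.395      1.625           4.111 population
   12.0 0.391   0.603      2.533           4.199 population
   24.0 0.254   0.740      3.177           4.295 population
   36.0 0.183   0.811      3.567           4.399 population
   48.0 0.155   0.840      3.788           4.512 population
   60.0 0.157   0.838      3.885           4.634 population
   72.0 0.190   0.806      3.842           4.767 population
   84.0 0.269   0.728      3.576           4.910 population
   96.0 0.417   0.581      2.945           5.065 population
```

The likelihood of pain rises from ~40% to a mid-window peak and falls
again, while the conditional intensity stays near 4–5 — the two components
move independently, which is the point of the decomposition.

Outcome models (`examples/outcome_models.py`):

```
           term   coef  odds_ratio  ci_low  ci_high  p_value
C(cluster)[T.2] -0.523       0.593   0.424    0.830    0.002
C(cluster)[T.3] -0.173       0.841   0.608    1.163    0.296
C(cluster)[T.4] -0.499       0.607   0.316    1.167    0.134
retained covariates: ['age_years', 'baseline_pain'] (n = 1426)
Type III cluster effect: LR = 10.68, df = 3, p = 0.0136
Hosmer-Lemeshow: chi2 = 4.07, df = 8, p = 0.851
ROC AUC 0.634 (bootstrap 95% CI 0.595-0.677)

sex by cluster (published counts): chi2 = 7.30, df = 3, p = 0.0629
unadjusted 30-day OR, cluster 1 vs 2: 1.398 (95% CI 1.078-1.811)
```

The last two lines recompute published summary-table quantities from the
per-cluster counts shipped in `paintraj.reference_data`.

## Pipeline and CLI

`run_pipeline(config, out_dir, seed)` chains
simulate → cohort → features → cluster → ZICMP → profiles → outcomes,
writing CSV/JSON artifacts plus a manifest of SHA-256 digests; reruns with
the same config and seed are byte-identical (`examples/full_pipeline.py`).

The same stages are exposed as a CLI for file-based use:

```bash
paintraj simulate --preset well_separated --n 300 --seed 17 --out sim/
paintraj cohort   --pain sim/pain.csv --baseline sim/baseline.csv --out cohort/
paintraj features --pain cohort/pain_filtered.csv --out features.csv
paintraj cluster  --features features.csv --out clusters/
paintraj zicmp    --pain cohort/pain_filtered.csv --clusters clusters/assignments.csv --out zicmp/
paintraj outcomes --baseline cohort/baseline_filtered.csv --clusters clusters/assignments.csv --out outcomes/
paintraj run      --preset well_separated --seed 17 --out full_run/
```

## Layout

```
src/paintraj/
  cohort.py          data model, inclusion filters, CSV I/O
  synthetic.py       scenario presets and the cohort generator
  features.py        24-measure catalogue, winsorized standardization
  clusters.py        PCA, k-means, cubic clustering criterion, ARI
  zicmp.py           CMP primitives, ZICMP mixed model, decomposition
  profiles.py        normalized AUC profiles, empirical trajectories
  outcomes.py        bivariate tests, logistic models, diagnostics
  reference_data.py  published per-cluster summary counts
  pipeline.py        end-to-end runner with manifest
  cli.py             click CLI (`paintraj`)
docs/methods.md      statistical methods and rationale
examples/            runnable worked examples
tests/               pytest suite (unit oracles + acceptance criteria)
scripts/acceptance.py  one-shot acceptance report
```
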