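# Methods

This document records the statistical methods implemented by `paintraj` and
the methodological choices that are not obvious from the API.

## Cohort model and inclusion rules

A patient's acute course is a series of numeric rating scale (NRS, 0–10)
pain scores time-stamped in hours from the end of surgery. Scores recorded
at the same timestamp (a common artifact of bedside charting) are collapsed
to their maximum — the conservative reading for pain. Analysis restricts to
the first 96 h; patients with an inpatient stay over 4 days or fewer than 4
in-window scores are excluded, and the filter report reconciles counts so
exclusions are auditable. Clinically meaningful pain is NRS ≥ 3, applied to
the 30-day and 1-year follow-up scores; missing follow-up propagates as
missing, never as "no pain".

## Trajectory measure catalogue (24 measures)

Per patient, 24 measures summarize level, trend, and fluctuation:

1. range; 2. mean; 3. SD; 4. coefficient of variation; 5. overall change
(last − first); 6. mean change per hour; 7. change relative to the first
score; 8. change relative to the mean; 9. OLS slope on time;
10. R² of that line; 11. maximum first difference; 12. SD of the first
differences; 13. SD of the first differences per unit time; 14. mean
absolute first difference; 15. maximum absolute first difference;
16. maximum absolute first difference over the mean; 17. maximum absolute
first difference over the slope; 18. SD of the first differences over the
slope; 19. mean second difference; 20. mean absolute second difference;
21. maximum absolute second difference; 22–24. the second-difference
measures normalized by the mean and by the mean absolute first difference.

Because observation times are irregular, "per unit time" quantities use
divided differences. Measures 11, 12, 14 and 15 use raw successive
differences y[j+1] − y[j] (so that 12 and 13 remain distinct measures, as
in the established catalogue, and both reduce to the same value at unit
spacing); measure 13 and all second differences use divided differences
(Δy/Δt, and differences of those over the half-span), which respect the
irregular sampling.

**Degenerate denominators.** Any ratio whose denominator is zero is
replaced by 0 and flagged (per-measure flag columns accompany the feature
matrix). For the slope-denominator measures (17, 18) the guard is
statistical, not exact: |slope| ≤ 2·SE(slope) is treated as a zero
denominator. Near-zero noise slopes otherwise place flat trajectories at
arbitrary ±10³ in the ratio columns and let noise dominate the PCA.

**Standardization.** Columns are z-scored (mean 0, SD 1, ddof = 1);
zero-variance columns are dropped with a warning. The pipeline winsorizes
each column two-sided at 0.5% *before* z-scoring: heavy-tailed ratio
columns otherwise inflate the column SD, collapsing the bulk of the data
toward zero so that a handful of outliers define their own principal
component. Winsorizing before the SD is computed preserves the mean-0/SD-1
postcondition exactly. Plain `standardize()` keeps no winsorization by
default; the pipeline passes `winsor_pct=0.5`.

## Dimension reduction and cluster-count selection

PCA is computed from the correlation matrix of the standardized measures
(eigendecomposition; deterministic sign convention: the largest-magnitude
loading of each component is positive). Components with eigenvalue > 1
(Kaiser criterion) are retained and patients are represented by their
scores on those components.

k-means (multiple restarts, fixed seed) partitions the score space for
each candidate k. The cubic clustering criterion (CCC, the SAS
formulation) compares the observed R² against its expectation under a
uniform hypercube null; the k maximizing CCC is selected. All candidate
CCC values ≤ 0 indicate no cluster support and are flagged on the returned
table (`table.attrs["no_cluster_support"]`). Final cluster labels are
renumbered in decreasing size order.

## Zero-inflated Conway–Maxwell–Poisson (ZICMP) mixed model

Within each cluster, the score Y at time t follows a mixture of a
structural zero (probability π(t), logit-linear in polynomial time) and a
Conway–Maxwell–Poisson count with log rate λ(t) polynomial in time, shared
dispersion ν, and a patient-level Gaussian random intercept b ~ N(0, σ_b²)
on the log rate. Time is scaled to s = t/96 so coefficients are O(1).

The CMP normalizing constant and moments are computed by truncated
summation in log space (streaming log-sum-exp), truncated past the series
mode at relative 1e-12 with a hard cap, and error rather than silently
truncate when the cap binds. ν = 1 recovers the Poisson law and ν = 0 (for
λ < 1) the geometric law exactly.

The marginal likelihood integrates b out by a Laplace approximation at the
per-patient conditional mode (damped Newton, vectorized across patients),
with 20-node adaptive Gauss–Hermite quadrature (centred and scaled at the
mode) available as a cross-check; the two agree to ~1e-6 relative on test
fixtures. Maximization uses L-BFGS-B with numerical gradients from
multiple starts (zero, a Poisson-GLM warm start, and random perturbations
of it); standard errors come from the numerically differentiated observed
information. Setting ν = 1, σ_b = 0 and disabling zero inflation reduces
the model exactly to a Poisson GLM, which is used as an oracle in tests.

The fitted model decomposes the trajectory into the **likelihood of
experiencing pain**, P(Y > 0) = (1 − π)(1 − 1/Z), and the **conditional
intensity** E[Y | Y > 0] = E[Y]/P(Y > 0), with the identity
E[Y] = P(Y > 0) · E[Y | Y > 0] holding at every grid point by
construction. Population (fixed-effects), marginal (integrated over the
random intercept), and per-subject (at the conditional modes) curves are
available.

## Normalized AUC profiles

Areas under the fitted intensity and probability curves are computed by
the trapezoid rule on an hourly grid and normalized by their theoretical
window maximum (sustained NRS 10 → divisor 960; sustained probability 1 →
divisor 96), so profiles lie in [0, 1] and are comparable across cohorts.
Profiles are reported per 8-hour interval (6-hour variant included);
interval contributions sum exactly to the full-window normalized AUC. The
default profile averages per-subject curves evaluated at each patient's
estimated random-intercept mode; a population-curve variant is available.

## Outcome models

Bivariate cluster–covariate screening uses chi-square tests for
categorical variables, ANOVA F (or Kruskal–Wallis when |skewness| > 2) for
continuous ones, and a random-intercept linear mixed model Wald test for
the per-observation acute pain level. Clinically meaningful pain at 30
days and 1 year is modeled by logistic regression with backward
elimination on the likelihood-ratio criterion (stay threshold 0.05) over
the baseline covariates; the cluster factor is forced (reference: cluster
1) and never eliminated. Complete cases on the candidate set are used so
all nested fits share rows. Diagnostics: a Type III likelihood-ratio test
of the overall cluster effect, the Hosmer–Lemeshow calibration chi-square
over deciles of fitted risk, and a patient-level bootstrap of the ROC AUC.
Quasi-separation (|coefficient| > 15) is flagged and the fit marked
unreliable. The 2×2 unadjusted odds ratio uses the Haldane 0.5 continuity
correction when a cell is zero (flagged).

## Synthetic cohort generator

The generator draws per patient: a latent class (fixed mixture weights), a
random intercept, observation times from a homogeneous Poisson process on
(0, 96] h, and scores from the class's ZICMP law capped at NRS 10.
Observation times are *recorded* at the bedside charting resolution
(rounded to the grid, coincident recordings collapsed) — exactly the
artifact the duplicate-collapse rule in the cohort model exists for. This
matters beyond realism: divided differences under a continuous-time
Poisson process have unbounded variance (E[1/Δt²] diverges), so a handful
of tiny-gap patients would otherwise acquire extreme second-difference
features and splinter into spurious clusters. Grid recording bounds Δt
away from zero while keeping the underlying event process Poisson.

Two presets ship with the package. The **default preset** mirrors the
structure of the motivating registry cohort: mixture weights
542/753/696/115 over 2106; an inverse-U likelihood-of-pain class
(40% → ~85% → ~58%), a slowly declining class (~85% → ~42%), a steeply
resolving class (~97% → ~5%), and a low-pain class (≤ 25% throughout);
conditional intensities near 4–5, ~4, 5 → 4 and ~3; 30-day outcome odds
ratios 1/0.67/0.74/0.46 versus cluster 1 (1-year: 1/0.86/0.87/0.80);
covariate marginals matching the published baseline table. Dispersion
differs by class (ν = 1.2/3.0/0.8/2.0) so fluctuation measures carry
between-class signal, the random-intercept SD is 0.08, and charting is
dense (rate 2.5/h recorded hourly, ~88 scores per patient) so per-patient
measure vectors concentrate around their class means. The
**well-separated preset** provides four strongly distinct shapes (high
volatile, smooth decline, smooth rise, flat mild) for recovery testing.

True class curves (`true_curves`) and full config serialization support
oracle-style testing of every downstream stage without registry access.

## Reproducibility

The pipeline writes a manifest with the config hash, per-stage seeds
(fixed offsets from the global seed, so stages are independently
rerunnable) and SHA-256 digests of every artifact; reruns with the same
config and seed are byte-identical. All stochastic components take
explicit seeds.
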