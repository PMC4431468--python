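# Methods

## The reference model and risk scheme

Skin autofluorescence (SAF, arbitrary units) rises roughly linearly with age
in cross-sectional screening data. The package models, per stratum
*g* ∈ {men, women with SR ≤ 10 %, women with SR > 10 %},

    μ_g(a) = α_g + β_g·a        (mean SAF at age a)
    σ_g(a) = γ_g + δ_g·a        (SD of SAF at age a)

fit by weighted least squares to *per-age-group* summary statistics (mean
and SD of SAF per gender × age-group cell), with weights equal to the cell
n. The group-level fit is canonical because published reference data — and
cross-cohort comparisons — exist only as per-age-group means; a
subject-level OLS (`subject_level_slope`) is provided as a cross-check and
agrees with the midpoint fit within 0.003 AU/year on cohorts whose stratum
means are linear in age (tested).

Age-group midpoints: the 18–19 group maps to 18.5, the decade groups to
24.5…64.5, and the open-ended 70–99 group to 74.5. Open-ended tails are
treated as 10-year bands because the simulator draws ages on 70–80 (the
observed female maximum is 80; the male tail beyond is a handful of
subjects) — a heavier tail would be unsupported by data.

Risk boundaries are b_k(a) = μ_g(a) + k·σ_g(a) for k ∈ {1, 2}: group 0
below b₁, group 1 in [b₁, b₂), group 2+ at or above b₂. The two top groups
are merged by design. **Ties escalate** (half-open upward intervals): the
prose definition of the scheme uses strict inequalities on both sides and
leaves a subject sitting exactly on a boundary undefined; escalation is
deterministic and conservative for a screening instrument. Boundary
ordering and positivity of σ_g over the age domain are validated at
construction, not at classification time.

The *conventional* comparison scheme ships only as a clearly-labelled
synthetic placeholder (`data/conventional_scheme_synthetic.yaml`): the
published conventional boundary coefficients exist only as dashed lines in
a figure, so real comparisons require user-supplied coefficients. The
placeholder exercises the machinery and carries no clinical meaning.

## Pooled statistics

`pool_stats` aggregates a stratified table by the law of total variance
with population weighting:

    grand_mean = Σ n_g·x̄_g / Σ n_g
    grand_sd²  = Σ n_g·(s_g² + (x̄_g − grand_mean)²) / Σ n_g

Within-stratum SDs use n−1 by default (the convention of printed summary
tables); pooling applies the formula above verbatim. With `ddof=0` strata
the identity is exact: pooling then reproduces the whole-cohort population
SD to 1e-12 (tested). With n−1 strata the difference is O(Σs_g²/N) ≈ 0.002
AU on a ~2,000-subject cohort — irrelevant at printed precision.

## The synthetic cohort generator

The generator's defaults *are* the study conditions:

* **Strata.** 14 gender × age-group cells with fixed counts and SAF
  mean/SD taken verbatim from the packaged reference grid. The published
  gender totals (1,122 men / 877 women) and the grid's female column sum
  (875) disagree by two subjects; the default configuration adds the two
  to the female 30–39 cell (the largest female cell) so the categorical
  margins — which sum to 877 — can be assigned exactly, while the packaged
  grid itself stays verbatim. `calibrate_generator` without reconciliation
  mirrors the grid exactly (total 1,997).
* **Ages** are uniform integers within each group; 70–99 draws on 70–80.
* **SAF** is normal per stratum, truncated below at 0.5 AU, with a
  lognormal option because real SAF is right-skewed (median < mean); the
  mean/SD parameterization is what the +k·SD scheme consumes. Covariate
  effects are added as centered terms and the residual noise SD is set to
  √(SD² − Var(effects)) so each stratum's marginal mean/SD matches the
  calibration in expectation. Injected defaults: diabetes +0.41 AU (men)
  and +0.53 AU (women); BMI +0.01 AU per kg/m² in men; SR +0.065 AU per
  percent in women. The latter two are slopes consistent with published
  *contrasts* (+0.32 AU overweight-vs-normal men; +0.32 AU high-vs-low-SR
  women) spread over the typical covariate gap between those groups — the
  source reports contrasts only, so the slopes are package choices, fixed
  once and recoverable by within-stratum regression (tested to 3 SE).
* **SR** must have marginal mean 9.5 %, SD 3.0 % and a hard floor at 6 %
  (below which the instrument cannot measure SAF). A normal truncated at
  6 with parent (9.5, 3.0) would have mean ≈ 10.2, so the parent (μ, σ) is
  solved at calibration time such that the *truncated* moments hit
  9.5/3.0 (μ ≈ −1.665, σ ≈ 6.934). The resulting distribution is
  right-skewed with median ≈ 8.7 % and ~75 % of mass below 11 % — matching
  the published medians (8–9 %) without being targeted at them.
* **Categorical margins** (diabetes, smoking, hypertension, exercise,
  nationality) are assigned as exact counts by permutation within gender,
  never sampled — they are calibration constants, not random variables.
  Hypertension prevalence is not published; the default is 25 % per gender
  (281 men / 219 women), a typical adult screening figure, chosen once.
* **Anthropometrics** (height, weight, waist, hip, SBP, DBP) come from a
  Gaussian copula with a fixed target correlation matrix (weight–waist–hip
  block at 0.87, SBP–DBP at 0.65, chosen so that every pair among
  weight/BMI/waist/hip exceeds r = 0.8 after BMI is *recomputed* from
  weight/height²); WHR is recomputed from waist/hip, so the consistency
  invariants hold by construction. Marginal means/SDs per gender bracket
  the published medians and ranges.

What the generator does **not** emulate: age–flag dependence (diabetes is
permuted independently of age within gender, whereas real diabetes
prevalence rises with age), measurement error structure, household or site
clustering, and any SAF–anthropometry correlation beyond the injected BMI
term. Consequently, passing tests demonstrate that the *machinery* is
correct under the calibrated conditions — not that the scheme is clinically
valid, and not that effect estimates on real data would be unconfounded.

## Effect sizes

Residualization is OLS of SAF on the confounders (one-hot encoding for
categoricals, intercept always included, rank checked). The standardized
mean difference uses the pooled-SD Cohen's d; results report both d and the
raw adjusted difference in AU, since effect sizes in this literature are
printed in AU while the defining formula is dimensionless.

The confidence interval inverts the noncentral-t CDF over the
noncentrality parameter: with t_obs = d/√(1/n₁+1/n₂) and df = n₁+n₂−2,
the bounds are the λ solving F_{nct}(t_obs; df, λ) = (1±level)/2, scaled
back by √(1/n₁+1/n₂). Root-finding is Brent's method to 1e-8 with an
expanding bracket; an independent fixed-grid bisection oracle agrees to
1e-6 (tested), and empirical coverage over 10,000 simulated two-group
datasets is 95 % ± 0.6 % (tested). Degrees of freedom stay n₁+n₂−2
regardless of how many confounders were residualized out — the two-group
interface of the classical CI construction; with ~4 confounders at n ≈
2,000 the df distortion is negligible.

## Univariate tests and summaries

Two-group numeric comparisons are gated by Shapiro–Wilk at α = 0.05 in both
groups: t-test if neither rejects, two-sided Wilcoxon rank-sum otherwise.
Shapiro–Wilk on n > 5,000 is applied to a fixed-seed subsample of 5,000
(the test is undefined/overpowered at scale). 2×2 tables use chi-square
**with Yates continuity correction**: on the published diabetes table
(163/959 vs 121/756) the corrected p is 0.6894, which matches the printed
two-decimal value 0.68 under truncation (the uncorrected p, 0.64, does
not); correction is therefore the inferred convention. Summary tables
format each variable as mean (±SD) when normality is not rejected and
median (min–max) otherwise.

## O-PLS

Single-y orthogonal PLS: X and y are mean-centered and unit-variance
scaled (Pareto scaling available); orthogonal components are extracted
iteratively (weight = X-loading of the current predictive scores minus its
projection on the predictive weight, normalized; scores/loadings deflate
X), then the single predictive component is fit on the filtered X. "Two
components" in the standard single-y reporting convention means 1
predictive + 1 orthogonal, the package default. Exact properties tested:
reduction to single-component PLS at n_ortho = 0 (≤1e-8 against an
independent PLS implementation), predictive/orthogonal score orthogonality
(<1e-8), exact removal of rank-structured y-orthogonal variation, and
prediction invariance to shifts along the orthogonal loading direction.

Q²Y = 1 − PRESS/TSS from 7-fold cross-validation, folds stratified on y
quantiles and seeded; centering/scaling are re-estimated inside every
training fold (no leakage), which may differ from legacy chemometrics
software whose internal CV behaviour is undocumented. The permutation test
shuffles y, refits and re-cross-validates, and reports the add-one p-value
(1 + #{null ≥ observed})/(n_perm + 1).

Published model fits on the real cohort (R²X 0.45/0.38, Q²Y 0.39/0.30) are
not reproducible without subject-level data; the default synthetic cohort
is only required to land Q²Y in (0.2, 0.6) per gender — it lands at 0.30
(men) / 0.48 (women), the moderate-predictivity regime typical of noisy
biological outcomes.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; identical config + seed
reproduces cohorts and pipeline artifacts byte-for-byte (manifest hashes
are compared in the tests). Simulation-based checks use: the full
1,999-subject cohort for calibration round trips; 50,000 subjects for
risk-scheme self-consistency (3 binomial SEs around the Φ(1)/Φ(2) masses);
10,000 replicates for CI coverage; 200 replicates at n = 2,000 for
adjusted-effect bias; 100 replicates for the Q²Y ≤ R²Y and permutation-
uniformity checks — sizes at which the tested tolerances are meaningful
while the whole suite stays quick on a laptop.

## Known limitations

* The linear σ_g(a) model can go non-positive outside the fitted domain;
  construction rejects such curves inside the domain, and evaluation
  raises where σ ≤ 0.
* The conventional-scheme comparison is machinery-only until real
  coefficients are supplied.
* Adjusted effects on the default cohort can still carry *cross-gender*
  confounding (e.g. a smoking "effect" appears because smoking is
  male-dominated and gender is not in its confounder list) — a faithful
  reproduction of why per-gender adjustment matters, not a bug.
* The generator's independence assumptions (flags vs age) understate real
  confounding; see above.
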