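# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the readings adopted where the procedure was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Asymmetry preprocessing

For each region with paired measures `L, R > 0`, the asymmetry index is
`AI = (L − R)/((L + R)/2)`, antisymmetric in its arguments and invariant to a
common rescaling of both sides. The preprocessing order is fixed:

1. **Outlier removal** — entries more than 6 SD from the column mean are set
   missing, with mean and SD taken from the column *before* removal and the
   rule applied once (no iteration). It operates on each raw unilateral
   measure separately; an AI is missing if either side was removed. An
   AI-level variant (`outlier_on="ai"`) exists for sensitivity analyses,
   since whether the rule should see raw or derived values is a judgment
   call; raw is the default.
2. **Rank-based inverse normal transform** — `Φ⁻¹((rank − c)/(m − 2c + 1))`
   over the m non-missing entries with the Blom offset `c = 3/8` (van der
   Waerden `c = 0` and Tukey `c = 1/3` are selectable; the choice is
   immaterial beyond the third decimal at cohort sizes). Ties receive
   average ranks and map to identical outputs, so the full pipeline is
   invariant to any monotone rescaling of an AI column.
3. **Residualization** — OLS against the confound design with intercept:
   age in years; nonlinear age `(age − mean(age))²` with the mean taken
   from the analysis sample at preprocessing time; ten genetic principal
   components; scanner X/Y/Z table position; T1 signal- and
   contrast-to-noise; assessment center and genotyping array as
   reference-coded indicators (reference = most frequent level); sex
   (female = 1) unless the sex-difference map is being built; optionally a
   brain-size column for the sensitivity variant. Rank deficiency is
   detected from the QR diagonal and reported with the offending column
   names. Missingness is handled per column (each column's fit uses its
   observed rows); downstream multivariate analyses then take complete
   cases across all 42 columns and report the analysis n explicitly.

## Scalar canonical correlation

With a single score on one side, CCA collapses to multiple regression: the
canonical correlation is `√R²`, the canonical asymmetry index is the fitted
combination, and there is exactly one canonical pair. We therefore compute
the fit by least squares on the centered matrix and use the exact overall
F test, `F = (r²/(1−r²))·((n−p−1)/p)` on `(p, n−p−1)` df, as the parametric
p-value; Bartlett's χ² approximation `−(n − 1 − (p+2)/2)·ln(1−r²)` on p df
is available as a cross-check mode and agrees within a factor of two at
cohort scale. The variate is oriented so its correlation with the score is
non-negative, which makes "positive loading = leftward shift with higher
risk" well defined; loadings are plain Pearson correlations of each AI
column with the oriented variate. Weights are reported both raw (scaled to
a unit-SD variate) and per-SD of each column; loadings are the primary
interpretive output.

Note on interpretation: `√R²` carries an upward finite-sample bias of order
`√(p/n)` (≈ 0.036 at n = 32,256, p = 42 under the null). The planted
*population* values in the generator are therefore recovered with this
predictable inflation; tests that check recovery (±0.02 at a planted 0.10,
n = 30,000) account for it implicitly since the bias there is ≈ 0.007.

## Permutation nulls

*Pattern similarity.* The observed statistic is the Pearson correlation of
the two 42-length loading vectors. Each permutation applies **one shared
row shuffle to both score columns** while the AI matrix stays fixed, so
the within-subject coupling of the scores and the inter-regional
dependence of the AIs are both preserved; both CCAs are re-fit from
scratch and the loading-vector correlation recorded. Since the design
matrix is fixed under this null, all per-permutation fits reuse one thin
QR factorization and run as batched matrix products; a 10,000-draw null at
n ≈ 31,000, p = 42 takes seconds. Permutations are sampled with
replacement from the permutation group. The empirical p-value uses the
add-one rule, two-sided on magnitude by default (`sided="greater"` is
available); add-one keeps p in (0, 1] and unbiased.

*Sex-map similarity.* The observed statistic correlates the 42 sex
t-values (pooled-variance two-sample t, equal to the OLS slope t of AI on
sex; a Welch variant exists) with a loading vector taken from the
sex-adjusted analysis. The null shuffles sex labels and recomputes the
full t-vector per draw **while the loading vector is held at its observed
value**: the stated randomization targets sex, not the score, and
re-deriving loadings would require re-residualizing with permuted sex as a
covariate — a procedure we implement as an optional `refit` callback for
sensitivity checks but do not default to, because the two readings answer
slightly different questions and only the first matches the stated null.

## Synthetic cohort generator

The generator defines the conditions under which the pipeline is validated.
Defaults mirror the study structure: n = 32,256 with 52.6% females; two
scores drawn bivariate normal with correlation 0.08, shifted by a
standardized 0.04 for females (matching the reported sex t-statistics at
this n), then z-scaled; 42 regions split 28/8/6 into surface-area,
thickness, and volume classes; handedness base rates 89.0/9.5/1.5%
(right/left/mixed) from a baseline-category logit with per-score slopes,
default mixed-vs-right log-odds 0.14 and left-vs-right 0.04 per SD of the
first score; a typed phenotype battery with planted effects of the
reported magnitudes plus nulls.

Asymmetry is planted on the AI scale and inverted exactly:
`left = s·(1 + a/2)`, `right = s·(1 − a/2)` for a log-normal bilateral
size *s* (median 2500 mm² / 2.6 mm / 4200 mm³ by measure class, log-SD
0.1), so `(L−R)/((L+R)/2)` returns *a* to machine precision — an analytic
round-trip test. The latent asymmetry per region is

```
a = s_ai · (baseline + c_A·L_A·score_A + c_B·L_B·score_B
            + sex_pattern·(sex − mean) + covariate effects + ε),  ε ~ N(0, 1)
```

with unit-norm planted directions `L_A, L_B` (drawn as an orthonormal pair
when unspecified, so the two risks' patterns are distinct by construction).
With a single planted direction and unit noise, the population canonical
correlation of score on AI matrix equals `c/√(c² + 1)`; the generator
therefore sets `c = r/√(1 − r²)` in closed form to plant a canonical
correlation of `r` (defaults 0.03 and 0.04). Latent values implying a
non-positive side (`|a| ≥ 2`) are clipped just inside the feasible range
and counted; at the default AI scale of 0.05 per latent SD this never
occurs in practice. Outliers are injected by replacing a unilateral
measure with mean ± (7–10) SD of its column (flipped upward if the low
side would be non-positive) at rate 5×10⁻⁴ per cell, exercising the 6 SD
rule without disturbing rank structure; injected positions are recorded so
tests can check the rule removes exactly them. Categorical covariates
affect the latent asymmetry through their standardized level index — a
simplification that residualization with indicator coding removes
regardless.

What the generator does **not** emulate: spatial correlation among
regions beyond what the shared score/sex/covariate factors induce,
non-Gaussian AI marginals (real AI distributions are heavy-tailed beyond
the injected point outliers), missingness mechanisms other than outlier
removal, kinship or population structure behind the genetic principal
components, and any genotype-level structure (scores are simulated
directly, not built from variants). Passing tests therefore demonstrate
correctness of the statistical machinery under a faithful but idealized
dependence structure, not robustness to every artifact of real imaging
data. The log-normal marginal for bilateral size is an assumption, recorded
in the cohort's metadata sidecar.

## Handedness and PheWAS

Handedness contrasts restrict to the two relevant groups (non-right pools
left and mixed), then fit maximum-likelihood logistic models (Newton,
gradient tolerance 10⁻⁸, 100-iteration cap) of membership on score plus
covariates. Separation is flagged (|coefficient| > 50, non-convergence, or
a perfect-separation error) and reported, not penalized away; "prefer not
to answer" is treated as missing.

The phenotype classifier is deliberately simple — a declared codebook type
always wins; otherwise two distinct values → binary, non-numeric → 
unordered, integer-coded with ≤ 10 levels → ordered, else continuous —
because the scientific content is the four-model dispatch, not any
cohort-specific field heuristics. Ordered outcomes use a proportional-odds
(ordered logistic) model with the level order from the codebook; unordered
outcomes use baseline-category logistic with a likelihood-ratio test for
the score (df = k − 1). Fits that fail to converge are excluded from the
adjustment with the reason recorded, which changes m consistently.
`bh_fdr` wraps the standard step-up adjustment with monotone enforcement
and input validation; a brute-force implementation of the step-up
definition serves as its oracle in the tests.

## Seeds, determinism, and problem sizes

Every stochastic component takes an explicit seed. A pipeline run expands
its single seed into per-stage child seeds via `numpy.random.SeedSequence`
(all below 2³¹), so stages can be rerun in isolation; the cohort itself
draws each generation stage (scores, covariates, measures, handedness,
phenotypes, brain size) from independent child streams, so changing the
phenotype battery cannot perturb the scores. Repeated runs are
byte-identical, including written TSVs (fixed float format).

Validation problem sizes are chosen so each property is measured with
adequate Monte-Carlo resolution while the whole suite stays quick: oracle
agreement on 100 random instances at n = 500; null calibration over 200
cohorts at n = 2,000 with 200 permutations each; parameter recovery over
20 cohorts at n = 30,000; handedness coverage over 100 replicates at
n = 100,000 (scores and handedness only); FDR behavior over 200 replicates
of 200 continuous null phenotypes at n = 10,000; one end-to-end run at the
full n = 32,256 with 1,000 permutations. The analysis scripts and the
acceptance script run at full cohort scale with 2,000 permutations.

## Known limitations

- Only one canonical pair is supported (scalar score); no multi-dimensional
  or regularized CCA.
- The parametric CCA p-value assumes approximate normality of the score
  given the AIs; at cohort scale the F and Bartlett forms agree closely,
  and the permutation machinery provides a distribution-free alternative
  for pattern-level questions.
- Under the global null the Benjamini–Hochberg procedure controls FDR at
  exactly q for independent p-values, so realized false-discovery
  proportions fluctuate symmetrically around q across replicate scans.
- Complete-case analysis is the only missing-data strategy; the analysis n
  is always reported alongside results.
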