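# Methods note

This note records the models implemented in `seedallometry`, the
parameter values they use, what the synthetic generator does and does
not claim, and the numerical choices behind the implementation. All
quantitative statements here are either fixed model constants or
quantities computed by the test suite / `scripts/acceptance.py`.

## 1. Elemental correction and mass-balance inversion

Raw CHNS percentages refer to whole dry-seed weight, which still
contains bound water and minerals that are not part of the organic
components. With water fraction 0.11 and mineral fraction 0.04, organic
fractions are obtained by dividing each elemental fraction by
1 − 0.11 − 0.04 = 0.85 (`CorrectionPolicy`).

The corrected elemental vector e = (C, N, S, H) is modelled as a linear
mixture of four components with fixed reference elemental weight
fractions (rows: component; columns: C, N, S, H):

| component              | C     | N     | S     | H     |
|------------------------|-------|-------|-------|-------|
| carbohydrate           | 0.400 | 0     | 0     | 0.066 |
| albumin (S-rich)       | 0.505 | 0.187 | 0.027 | 0.069 |
| S-poor protein + other | 0.519 | 0.194 | 0.001 | 0.068 |
| lipid                  | 0.760 | 0     | 0     | 0.120 |

Inversion solves min‖Mᵀw − e‖² subject to w ≥ 0 with the exact
active-set nonnegative least-squares algorithm (`scipy.optimize.nnls`).
The solve is deterministic, has no tuning parameters, and the 4×4
system is full rank, so data generated by the forward model are
recovered to machine precision; the acceptance suite verifies a
1,000-vector forward/invert round trip to better than 10⁻⁶. The sum of
fractions is not constrained to 1; totals outside [0.90, 1.10] trigger
a warning because they signal data inconsistent with the mixing model.

The lipid hydrogen mole fraction is x = w_lip·H_lip / Σₖ wₖ·Hₖ using
the H column above (hydrogen mass is proportional to hydrogen moles).

## 2. Hydrogen isotope mass balance

All arithmetic is carried out on dimensionless fractional deltas;
per-mil values appear only at the API boundary. Three equations:

1. Source sugars: δ_source = δ_wl(1 + ε_A) + ε_A with ε_A = −171‰
   relative to leaf water δ_wl.
2. Compound class k with exchangeable fraction f_k and offset Δ_k:
   δ_k = (1 − f_k)·δ_source + f_k·(δ_wp(1 + ε_H) + ε_H) − Δ_k, with
   ε_H = +158‰ against pod water δ_wp. Defaults: f = 0.33 / 0.14 / 0.75
   and Δ = 0 / 80 / 70‰ for starch / protein / lipid.
3. Bulk seed: δ_seed = (1 − x)·δ_other + x·δ_lipid, where δ_other is by
   default the unweighted mean of the protein and starch values
   (a weighted variant is exposed via `weighted_other`).

Water scenarios: (a) leaf +60‰ and pod +30‰ above a −33‰ source water
(δ_wl = +27‰, δ_wp = −3‰; the default), (b) +75‰ / 0‰ enrichment
(δ_wl = +42‰, δ_wp = −33‰), (c) all waters at 0‰ absolute. Scenario (c)
yields the analytic anchors δ_seed(x=0) = −133.685‰ and
δ_seed(x=1) = +5.75‰, which the tests check against an independent hand
evaluation to 10⁻⁹. δ_seed is exactly affine in x for any fixed
scenario and constants.

## 3. Synthetic cohort generator

The generator's defaults are the study conditions; they are part of the
model definition and are never adjusted per analysis.

- **Accessions and weights.** Eight accessions with fixed weight
  ranges spanning roughly 1–8 mg; within an accession, weights are
  Beta(2, 2) draws scaled to the range. The default cohort is
  8 accessions × 20 seeds with `rng_seed = 0`.
- **Elemental mode (default).** %N = 5.83 + 0.17·w + noise and
  %H = 7.14 − 0.14·w + noise; %C is drawn around 45 with no weight
  trend; %S has a small-seed bump reflecting albumin enrichment. Noise
  variances are set analytically from the target pooled R² via
  σ² = slope²·Var(w)·(1 − R²)/R², using the pooled across-accession
  weight variance. Targets: R² = 0.36 for %N and 0.38 for the δ²H
  regression; 50-replicate means are verified by the acceptance suite.
- **Biochemical mode.** Component fractions are generated directly:
  carbohydrate 0.37 and albumin 0.13 on average, lipid decaying with
  weight as 0.08 + 0.12·exp(−0.35(w − 1)). Elemental values follow by
  the forward mixing model; this mode is self-consistent with the
  inversion by construction.
- **Isotopes.** δ²H is the scenario prediction at the seed's latent x
  plus calibrated noise; δ¹³C, δ¹⁵N, δ³⁴S carry no weight trend.
- **Metabolome.** 244 analytes in classes with proportions 0.30
  positively trending, 0.20 negatively trending, 0.10 paired
  amino-acid/degradation-product (opposite signs, shared `pair_id`) and
  0.40 null. Log-intensity is baseline + sign·0.08·(w − w̄) +
  accession offset + N(0, 0.5²), exponentiated. The effect size and
  noise were fixed once so that the default OPLS model attains
  R²Y ≈ 0.95 and Q² ≈ 0.76.

The generator claims distributional shape and calibration only; it does
not reproduce any real seed lot's measurements.

## 4. Statistics

- **Univariate screen.** Per-analyte OLS of (log) intensity on weight
  with a slope F-test; constant predictors or responses are flagged
  degenerate rather than given fake p-values. Bonferroni threshold
  α/m with strict inequality; for α = 0.05 and m = 244 this is
  2.049 × 10⁻⁴. Type-I control of the whole chain is verified on
  all-null generated metabolomes.
- **Best subsets.** Exhaustive enumeration up to `nvmax = 5` predictors
  keeping the `nbest = 100` best models per size, computed via Gram
  matrices with a deterministic column-order tie-break. Enumeration is
  refused above 25 predictors; a univariate-R² pre-filter (top 20 by
  default) reduces wide matrices first.
- **PCA / Hotelling T².** PCA by singular value decomposition of the
  centred matrix; the T² cutoff uses the F-distribution critical value
  k(n² − 1)/(n(n − k))·F(k, n − k).
- **OPLS.** NIPALS-style: the predictive weight is w ∝ Xᵀy; orthogonal
  components are deflated from X before the final predictive component.
  With `n_ortho = 0` the model is exactly PLS-1, verified against an
  independent oracle to 10⁻⁸. Orthogonal scores are exactly orthogonal
  to the centred response.
- **Q².** 1 − PRESS/TSS with 7-fold cross-validation over
  seeded-permutation, contiguous-block folds (requires n ≥ 2·folds).
- **CV-ANOVA.** Two methods are exposed. `method="f"` follows the
  published recipe, F = ((TSS − PRESS)/k) / (PRESS/(n − 1 − k)) with
  k = 1 + n_ortho; Monte-Carlo checks in the test suite show it is
  conservative under the null (rejection rate below nominal α).
  `method="randomization"` permutes the response and refits with the
  same folds, giving p = (1 + #better)/(n_rand + 1); it is calibrated
  (uniform p under the null) and is what the acceptance suite tests
  for uniformity. The F method is the default because it is the
  conventional choice and errs on the safe side.

## 5. Numerical choices

- All randomness flows through `numpy.random.Generator` seeded
  explicitly; cohort generation is byte-identical across reruns.
  `scripts/acceptance.py` derives child seeds below 2³¹ from the master
  seed via `SeedSequence`.
- Compositions are stored as fractions of 1 internally; percent and
  per-mil appear only in file I/O and API boundaries.
- p-values are floored at the smallest positive double to keep
  −log₁₀ p finite in volcano tables.

## 6. Limitations

- **Elemental-mode inversion is ill-conditioned for lipid.** The C and
  H rows of the reference matrix make lipid weakly identified when %C
  carries no weight trend: inverting elemental-mode synthetic data
  recovers noisy, sometimes zero, lipid fractions and does not
  reproduce the decreasing lipid–weight relationship. The biochemical
  generator mode is the self-consistent route for studying the
  inversion; elemental mode is intended for the %N / %H allometry and
  the δ²H calibration, where the predicted δ²H is exactly affine in
  the latent x.
- The F-form CV-ANOVA is conservative; use the randomization method
  when calibrated p-values matter.
- Reference elemental fractions are fixed constants; real seed protein
  and lipid classes vary around them, so inverted fractions are model
  estimates, not assays.
- The generator's accession effects are simple offsets; it does not
  model genotype-specific allometric slopes.
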