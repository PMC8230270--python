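# Methods

This note documents the statistical procedures implemented in `scfaforest`,
the assumptions behind them, the synthetic-cohort generator used to exercise
them, and the numerical choices that were genuinely open.

## Problem setting

Fecal short-chain fatty acids (SCFA: acetate, propionate, butyrate, valerate)
and branched-chain fatty acids (BCFA: isobutyrate, isovalerate) are products
of bacterial fermentation of dietary fiber and protein in the gut.  Given a
cross-sectional cohort of two diet groups (vegans and omnivores, 36 samples
each), a species-level 16S read-count table and per-sample fermentation
markers (umol/g wet stool weight), the package asks: *which bacterial species
carry predictive information about the marker concentrations, beyond what
host covariates already explain?*

## Species-inclusion filter

Species enter the regression stage when both hold:

1. present (count > 0) in at least 50% of the samples of *either* diet
   group, and
2. at least 100 reads in at least one sample.

Both thresholds are inclusive — "at least 50%" keeps a species present in
exactly 18 of 36 vegans, and a maximum count of exactly 100 reads passes.
Presence uses no minimum-read floor.  The filter is idempotent and reports a
per-species kept/dropped reason table.

## Diversity

* **Alpha**: Shannon entropy H = −Σ pᵢ ln pᵢ (natural log by default; the
  base is switchable since conventions differ) and the Gini–Simpson index
  1 − Σ pᵢ².  Zero-count taxa are excluded from H; an all-zero sample is an
  error rather than 0, since its diversity is undefined.
* **Beta**: Bray–Curtis dissimilarity 1 − 2Σ min(uᵢ,vᵢ)/(Σu + Σv) on raw
  counts (the analysis works on absolute abundances throughout; a
  relative-abundance switch exists) and the presence/absence Jaccard
  distance.
* **NMDS**: non-metric multidimensional scaling of a distance matrix by
  SMACOF with isotonic (monotone) regression of configuration distances on
  dissimilarity ranks, as implemented in scikit-learn; ties are handled by
  the primary approach (tied dissimilarities are free to order their fitted
  disparities).  The reported quantity is Kruskal stress-1,
  √(Σ(d − d̂)²/Σd²), evaluated by the package's own isotonic fit; the best of
  `n_starts` (default 20) seeded random initialisations is returned.
  Non-convergence is reported as a flag, never an exception, because a
  usable configuration with known stress is still informative.

## Two-group statistics

Continuous variables: Welch is *not* used; the plain two-sample t-test is
applied when both groups pass a Shapiro–Wilk normality screen at α = 0.05,
otherwise the Mann–Whitney U test (exact p for tie-free samples of size ≤ 8,
tie-corrected normal approximation with continuity correction above).
Categorical variables: Fisher's exact test for 2×2 tables with any expected
cell ≤ 5, otherwise the chi-square test without continuity correction; the
chosen rule is recorded in each result.  Raw p-values are reported by
default, mirroring common practice for per-taxon screens; a
Benjamini–Hochberg switch is available.  Correlation structure is summarised
as a pairwise-complete Spearman matrix with two-sided t-approximation
p-values and significance flags at p ≤ 0.05 (`*`) and p < 0.0001 (`**`);
constant columns yield NaN with an explicit flag.

## Cross-validated random-forest selection

For one outcome y (a marker concentration) and feature matrix X (integer-
encoded confounders, optionally species counts):

1. Repeat `n_runs` times (default 100): draw a random unstratified
   train/test split with ⌊0.75·n + 0.5⌋ training samples (72 → 54/18); fit a
   random-forest regressor with `n_trees` (default 2000) on the training
   part; record test-set predictions.
2. Per run, per feature j, compute **%IncMSE** = 100·(MSE with column j
   permuted − test MSE)/test MSE, averaged over 5 independent permutations.
   Importance is computed on the held-out test set (the CV design holds one
   out anyway); it may be negative.  A zero test MSE leaves importance
   undefined (flagged NaN).
3. **Selection**: species whose *mean* %IncMSE across runs is strictly
   greater than the threshold (default 2).  The mean-based reading of
   "across runs" is the default; a per-run frequency criterion (> threshold
   in more than half the runs) is available as `selection_mode="frequency"`.
4. **Tiers**: per outcome, three feature sets are compared — *baseline*
   (confounders only), *full* (confounders + all filtered species; this tier
   drives selection) and *final* (confounders + selected species).  All
   tiers share the same per-run splits, so they are compared on identical
   resamples.  Scores are the mean RMSE = √(Σ(x−y)²/n) and mean
   R² = 1 − SSE/SST across runs, and RMSE-percent = mean RMSE / mean(y) ×
   100 for cross-outcome comparability.  R² of a test split may be negative;
   full-tier R² below baseline or final is the overfitting signature of many
   uninformative features.  An empty selection makes the final tier equal
   the baseline tier (flagged, not an error).

Confounders default to age, sex, BMI, physical activity, smoking status,
fecal pH, and protein, fat, carbohydrate, fiber and alcohol intake —  the
full covariate set of the tier definitions; it is configurable.  Sex and
smoking status are integer-encoded (female/male → 0/1; non-smoker/ex-smoker/
smoker → 0/1/2); forests split on order, so any monotone encoding is
equivalent.

Forest hyperparameters beyond tree count follow R's `randomForest`
regression defaults — `mtry` = ⌊p/3⌋ features per split and a minimum node
size of 5 — the conventional choice for this procedure in the microbiome
literature; they are recorded in the run log and configurable.  Importance
is always computed from held-out test samples; out-of-bag importance is not
offered because scikit-learn forests do not expose per-tree out-of-bag
predictions through a public interface.

Seeding: one master seed fans out to per-stage seeds through a stable
CRC32-based derivation, and within a model each CV run draws its split,
forest and permutation seeds from a spawned `SeedSequence`, so any single
(group, outcome) model is reproducible in isolation.

## Synthetic cohort generator

The study's raw data are not public, so the generator emulates the *shape*
of such a cohort with known ground truth:

* **Counts**: 1200 species; per-species presence is Bernoulli with
  configurable prevalence, and present counts are negative-binomial
  (mean m per species, shape k = 1, minimum 1).  The default tier structure
  — 50 "core" species at 80% prevalence and mean ≈ 600 reads, 550 mid-tier
  species at 25% prevalence and mean ≈ 40, and 600 rare species — yields
  ≈ 50 species passing the inclusion filter at n = 72, matching the candidate
  count the procedure is designed around.
* **Confounders**: age uniform 30–60; BMI normal, clipped to 18–30; fiber,
  protein, fat, carbohydrate and alcohol intakes and fecal pH drawn with
  group contrasts shaped like a Western vegan/omnivore cohort (e.g. pH
  6.41 ± 0.48 vegan vs 6.73 ± 0.45 omnivore; fiber 46 vs 24 g/day).
* **Outcomes**: each marker is intercept + Σ β·log1p(count) over its planted
  species + Σ γ·covariate + Gaussian noise, clipped at zero (clipping events
  are counted in the stored ground truth; defaults make them rare).  Effects
  act on log1p counts because read counts are heavy-tailed; on the raw scale
  a single outlier sample would dominate the planted signal.
* **Structure**: five core species are planted per fatty-acid outcome;
  ammonia shares its planted species with the two BCFA (protein-fermentation
  co-products), giving the positive ammonia–BCFA correlation, and fecal pH
  carries negative effects on the SCFA, giving the inverse pH–SCFA
  correlation.
* **Calibration**: planted effect sizes and noise standard deviations are
  set so that the final-tier forest R² lands in roughly the 0.2–0.45 band at
  n = 72 — the regime the procedure realistically operates in — which makes
  planted-species recovery a demanding but passable test (sensitivity ≥ 0.8
  at ≤ 10% false positives).

A matched *null* configuration removes all planted species effects while
raising the per-marker intercepts to the level the planted species would
otherwise contribute, so null cohorts keep realistic, strictly positive
concentration scales; it is the reference for false-selection rates.

What the generator does **not** emulate: phylogenetic correlation between
taxa, compositional (closed-sum) coupling, sequencing-depth variation
between samples, and zero-inflation beyond the presence/absence layer.
Passing recovery tests therefore show that the procedure works when species
signals are independent and additive on the log scale — not that it is
robust to correlated taxa, where permutation importance is known to split
credit between correlated predictors.

## Problem sizes in tests and the acceptance script

The repeated-cross-validation experiments in the test suite and
`scripts/acceptance.py` run the study design (75/25 splits, >2 %IncMSE
selection) at a reduced simulation size — 25 CV runs of 500 trees, with 20
seeds for recovery tests and fewer in the script — chosen so the whole suite
completes on a single CPU in well under half an hour while leaving the
Monte-Carlo conclusions unchanged.

## Known limitations

* %IncMSE from held-out test sets is systematically smaller and noisier than
  out-of-bag importance from R's `randomForest`; the >2 threshold is
  therefore not directly transferable between the two definitions.
* With only ~18 test samples per run, per-run R² is highly variable;
  conclusions should rest on the across-run means, as the tier tables do.
* The selection threshold is applied per outcome with no multiplicity
  control across the six outcomes; the per-outcome false-positive count
  (≈ ≤ 2 of 50 under the null) multiplies accordingly.
* NMDS stress depends on restarts; with the default 20 starts, configurations
  are stable in practice but global optimality is not guaranteed.
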