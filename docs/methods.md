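# Methods

## Signature derivation

A panel is an annotated single-cell experiment: non-negative integer
counts (genes × cells), one cell-type label per cell, and tissue metadata
(tissue, organ system, developmental stage, optional Uberon/Cell Ontology
IDs carried as opaque text). The pipeline is

1. **Cell-type filter.** Cell types with fewer than `min_cells_per_type`
   (default 30) cells are removed. At least two types must survive; the
   one-vs-rest contrast is undefined otherwise. The threshold is
   inclusive: a 30-cell type stays.
2. **Gene filter.** "Lowly expressed" genes are those detected (count
   > 0) in fewer than `max(gene_min_cells, ceil(gene_min_fraction ·
   n_cells))` cells; defaults 3 cells and 0.1%. These defaults are common
   scRNA-seq practice and keep the per-gene t-statistics
   well-conditioned; both knobs are configurable. Filters run in this
   order (cells first), so the gene-detection threshold refers to the
   retained cells.
3. **Normalization.** log₂(CPM + 1) per cell. A cell with zero total
   count has no library size and is rejected by name rather than
   silently propagated.
4. **t-statistics.** For each gene and cell type, the t-statistic of the
   indicator coefficient in `expr ~ intercept + 1[cell ∈ type]`, fitted
   over all cells of the panel (cells are the observations, not
   per-type mean profiles). This equals the pooled-variance two-sample t
   and is computed from group sufficient statistics; the test suite
   cross-checks it against an independent OLS fit. Zero residual
   variance (e.g. a constant gene) maps to t = 0 — a neutral value that
   keeps the matrix finite. No covariates are included; library-size
   variation is already absorbed by CPM normalization.
5. **Selection.** Per cell type, the top `max(1, floor(top_fraction ·
   |universe|))` genes by t-statistic (default top_fraction = 0.05),
   with ties at the cutoff broken by lexicographic gene symbol so
   selection is deterministic. The 5% is taken of the *post-filter*
   universe, which is also the background of the enrichment test.

Gene symbols are whitespace-stripped and upper-cased on ingest; when two
input rows collapse to one symbol the row with the larger total count is
kept and the collision logged.

## Enrichment test

`p_raw` is the one-sided hypergeometric upper tail `P(X ≥ a)` with
population `|universe|`, `|signature|` successes and `n_mapped` draws —
identical to the one-sided Fisher exact test on the 2×2 table. The
universe is per panel; query genes outside it are dropped and the mapped
count reported. A query with no mapped genes returns p = 1 with a
warning: absence of evidence is a defined result, not an error.

## Permutation adjustment

The reference is a collection of trait-associated gene sets (TAGs) with
lengths restricted to [20, 2000] (inclusive), each precomputed against
every TC. For a query:

- **cumulative factor** = proportion of reference TAGs at least as long
  as the query (the query length is the number of unique normalized
  input symbols). A factor of 0 is floored to 1/n_tags.
- **p_perm** = `max(1, #{reference p ≤ p_raw}) / n_tags × factor`,
  capped at 1. The tie-inclusive count is deliberately conservative and
  bounds the value in [1/n_tags, 1].
- **p_tc** = `#{own p_raw over all TCs ≤ p_raw(i)} / n_tcs`; the vector
  includes TC i itself, so no clamp is needed.
- **combination**: `χ² = −2 ln(p_perm · p_tc)` against a chi-squared
  distribution with 4 df; closed form `e^(−x/2)(1 + x/2)`, which the
  implementation matches to < 10⁻¹² over a wide grid.

Reference columns are stored and matched by `tc_id`
(`panelID|cellTypeLabel`), never by position.

### Statistical caveats, stated plainly

- **The cumulative factor breaks calibration.** The rank term alone is
  calibrated: for queries exchangeable with the reference TAGs its
  distribution is uniform up to discreteness, and the package verifies
  this (Kolmogorov–Smirnov at α = 0.01, 1000-TAG reference, 500 null
  queries, 4-TC panel). Multiplying by the cumulative factor — itself
  roughly uniform when query lengths match the TAG length distribution —
  makes the product stochastically smaller than uniform; empirically the
  KS statistic jumps from ~0.05 to ~0.35. The factor is applied exactly
  as defined in `run_query` because it is part of the method; the
  calibration experiments therefore evaluate the rank p-value with
  factor = 1, which is the component with a distributional guarantee.
  Note the direction: longer queries receive a *smaller* factor and thus
  smaller p_perm.
- **Discreteness.** Raw hypergeometric p-values are discrete — short
  queries place visible mass at p_raw = 1 (zero overlap) — so the rank
  p-value inherits a lump at 1 and is slightly conservative. With 500
  replicates the KS test sits near its detection boundary for this lump:
  individual draws can dip below α = 0.01 without indicating
  anti-conservatism. The acceptance script additionally reports the
  empirical validity excess `max_α [P(p_perm ≤ α) − α − 1/n_tags]`,
  which stays within binomial noise of 0.
- **Dependence.** p_perm and p_tc are both functions of the same p_raw,
  so Fisher's independence assumption does not hold; the combined
  p-value is treated as a ranking score and checked for monotonicity,
  not for uniformity.

## Significance annotation

Bonferroni line = `bonferroni_alpha / n_tcs` (0.05/1355 = 3.69 × 10⁻⁵ at
atlas scale), nominal line = 10⁻³; both strict `<`, both echoed in every
output header. Z-scores are `Φ⁻¹(1 − p)`; p-values at 0 or 1 are clamped
into the open interval with a warning.

## Synthetic data generator

`simulate_panel` draws baseline counts from a negative binomial
(Gamma–Poisson) with mean 0.5 and dispersion 0.3 (`Var = m + d·m²`) —
typical sparse scRNA-seq marginals — and plants disjoint marker sets per
cell type whose mean is multiplied by `effect_size` (default 4) in their
own cells only. Default geometry: 2000 genes, 4 cell types × 100 cells,
20 markers per type. Under these conditions the signature pipeline
recovers ≥ 90% (empirically ~100%) of planted markers. Gene names use a
fixed width so panels of different sizes share a nested gene pool, which
lets one "genome-wide" query map partially into smaller universes — the
mechanism behind the signature-length bias experiment below.

`simulate_tags` draws null TAGs uniformly without replacement, with
lengths log-uniform over [20, 2000] ∩ [1, |universe|] (log-uniform
covers the permitted range without concentrating at either end); an
optional `EnrichmentSpec` mixes a stated fraction of one signature's
genes into each TAG to emulate moderate cell-type specificity. The
fraction is an explicit free parameter, not an estimate of real TAGs.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, realistic mean–variance trends per gene, or association-study
noise (the rare-variant significance filter is represented only by which
genes enter a TAG). Passing tests therefore demonstrate correctness of
the statistics under the stated model, not robustness to real-data
artifacts.

## Bias experiment

Across five panels with universes of 400–3200 genes (signatures 20–160
genes), 300 identical 200-gene queries drawn from the largest pool are
tested everywhere. Mean enrichment Z per panel correlates positively
with mean signature length (Pearson r ≈ 0.8): smaller universes map
fewer query genes, coarsening the discrete p-value and dragging mean Z
down. This reproduces, qualitatively, the length bias that motivates the
permutation adjustment.

## Problem sizes and determinism

Test-suite and acceptance-script simulations use desk-scale sizes (≤ 3200
genes, ≤ 400 cells, ≤ 1000 reference TAGs, ≤ 500 query replicates),
chosen so the whole suite runs in seconds while keeping every statistical
check adequately powered. All randomness flows through
`numpy.random.default_rng` seeds recorded in truth manifests and logs;
identical inputs produce byte-identical outputs (fixed float formatting,
LF line endings, sorted JSON keys).
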