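# Methods

## Scope and data model

`lfqde` operates on protein-level log2 intensity matrices with explicit
missing cells and a two-condition design with at least two replicates per
condition. Raw (linear) intensities are log2-transformed on read; zero raw
intensities are treated as "not quantified" (missing) by default, matching
LFQ export conventions, and this is configurable (`zero_as_missing`).
Contaminant and decoy rows are removed by id prefix (defaults `CON__`,
`REV__`, the common search-engine markers). No between-sample normalization
is applied: the workflow this package implements does not define one, and
silently normalizing would change every downstream number; users can
pre-normalize upstream if their acquisition requires it.

## Imputation

Missing cells are routed per protein × condition replicate group by
detection count:

- **MNAR rule (≤ 1 detection).** The group is treated as below the detection
  limit. Missing cells are drawn from
  `N(mean_s − shift·sd_s, (width·sd_s)²)` with `shift = 2.5`,
  `width = 0.3`, where `mean_s`/`sd_s` are the *per-sample column*
  statistics over observed values (n−1 denominator). The column-wise reading
  is the only computable one — with ≤ 1 detection the protein-level spread is
  undefined — and matches standard left-shifted imputation practice. With
  `sd_s = 0` the draw degenerates to the column mean.
- **MLE rule (≥ 2 detections).** Missing cells are drawn from the Normal
  maximum-likelihood fit to the group's observed values (mean = arithmetic
  mean, variance with the n denominator, as the MLE dictates; observed-data
  column summaries use n−1, as that definition dictates). The draw is
  stochastic rather than a deterministic mean fill: repeating completions is
  only informative if each completion varies.

**Cycles and randomness.** The completion is repeated `n_cycles = 20` times.
One root `SeedSequence(seed)` spawns an independent substream per cycle; each
cycle fills a full-shape standard-normal matrix and uses the entry at each
missing position, so a cell's imputed value depends only on (cycle, row,
column) and results are independent of traversal order or parallelism.
Observed cells are copied bit-exactly into every cycle.

## Differential testing

Per cycle, a moderated two-sample t-test:

- pooled two-group variance `s_g²` with `d_g = n1 + n2 − 2` df;
- empirical-Bayes prior `(d0, s0²)` refit on each cycle's variances by
  moment matching on `log s²`: with
  `e_g = log s_g² − ψ(d_g/2) + log(d_g/2)`, the model gives
  `E[e] = log s0² − ψ(d0/2) + log(d0/2)` and
  `Var[e] = ψ′(d_g/2) + ψ′(d0/2)`; `ψ′(d0/2)` is solved by Newton iteration
  (relative tolerance 1e−8). When the empirical variance of `e` does not
  exceed `ψ′(d_g/2)` there is no detectable between-protein spread: `d0` is
  unbounded and `s0²` is estimated by the raw first moment `mean(s²)`
  (exactly unbiased on that boundary, and equal to the common value when all
  variances coincide — the log-scale estimate would carry a Jensen bias
  there);
- `s̃_g² = (d0 s0² + d_g s_g²)/(d0 + d_g)`;
  `t_g = Δ̄_g / sqrt(s̃_g² (1/n1 + 1/n2))` referred to `t(d0 + d_g)`
  (standard Normal when `d0 = ∞`), two-sided; p-values are clamped to the
  smallest positive float so `p ∈ (0, 1]`;
- Benjamini–Hochberg step-up adjustment (own implementation,
  cross-checked in the tests against a quadratic brute force and
  statsmodels).

Fold changes are oriented second condition minus first, condition order
taken from the design file and logged at run time.

**Significance.** Default `dual_threshold`: `|log2FC| ≥ 1` and `q ≤ 0.05`.
An optional `curve` mode makes the effective adjusted-p threshold rise from
0 at `|lfc| = lfc_min` toward `q_max` asymptotically,
`q_thr = q_max·(1 − 2^(−k(|lfc| − lfc_min)))` with steepness `k` (default 1
per log2 unit). The curve's exact functional form is this package's choice;
the dual threshold is the default because it is the plainer reading of the
combined criterion.

**Aggregation over cycles.** Final log2FC is the cycle mean; p and q are
cycle medians (diagnostics only); `n_cycles_significant` counts per-cycle
calls; the final flag requires a *strict majority* of cycles significant
*and* the aggregated fold change itself passing the fold-change cut, so a
reported call is always supported by its reported effect size. Majority
voting was chosen over Rubin's-rules pooling as transparent and directly
testable; the conjunction with the aggregated-lfc cut resolves the rare
pathological case where per-cycle calls straddle the cut with mixed signs.
Descriptive chart counts use the looser strict thresholds
(`|log2FC| > 0.5`, raw `p < 0.05`) and are independent config fields from
the final criteria.

## Multivariate summaries

PCA runs on the across-cycle mean matrix (logged) for stability: SVD of the
samples × proteins matrix after centring and, by default, unit-variance
scaling per protein (n−1 sd; zero-variance proteins dropped with a warning).
Explained-variance proportions are `σ_i²/Σσ²`. Clustering computes a
distance matrix — `1 − Pearson r` by default; `1 − |r|` and Euclidean
available because heatmap conventions vary — and feeds it to unweighted
average linkage (UPGMA, via `scipy.cluster.hierarchy`; an independent naive
implementation serves as the test oracle). Metric and linkage are orthogonal
options.

## Enrichment

Over-representation is the one-sided hypergeometric upper tail
(Fisher exact test for enrichment), sets intersected with the universe
first; the universe defaults to all quantified proteins after contaminant
filtering, i.e. the tested population. A two-sided variant is available
behind a flag. For signed regulon sets, the activation z-score is the
sign-agreement statistic `z = (n_agree − n_disagree)/√(n_agree + n_disagree)`
between observed call directions and expected member directions; this
formula is the package's own choice of the standard agreement statistic, and
it is antisymmetric under flipping the expected signs. Members without a
usable observed direction are ignored; a set with none yields NaN rather
than an error.

## Reporting utilities

Volcano tables emit `(lfc, −log10 p)` with categories at the chart
thresholds and threshold-line metadata; zero p-values are clamped with a
warning. Boxplot statistics use linear-interpolation quartiles (the common
default; stated because conventions differ) with whiskers at the furthest
datum within 1.5 IQR of the box, clamped to the box when no datum lies
beyond a quartile so `whisker_lo ≤ Q1 ≤ median ≤ Q3 ≤ whisker_hi` always
holds; outliers are the points beyond the whiskers. Relative qPCR expression
is `2^(−ΔΔCt)`.

## Synthetic data

The generator emulates a two-condition, three-replicate LFQ experiment:
per-protein baselines `N(20, 2.5²)` log2 units (grand mean and
between-protein spread typical of LFQ intensity tables), replicate noise
`N(0, 0.3²)`, a 4% differential fraction with effect magnitudes
`|N(2, 0.5²)|` and alternating signs (balanced up/down), soft left-censoring
`P(missing | value) = logistic((16 − value)/0.8)` — i.e. 50% dropout about
1.6 between-protein SDs below the grand mean, giving ~9% missing cells
overall — plus 2% missing completely at random. Censoring is soft
(logistic) rather than a hard threshold so realistic detection-count
patterns arise while every cell's mechanism stays known. Defaults scale
down freely for fast tests (hundreds of proteins).

What it does *not* emulate: peptide-level structure and shared-peptide
ambiguity, between-sample shifts or batch effects, intensity-dependent
variance trends, and heavy-tailed noise. Passing tests therefore demonstrate
the correctness and calibration of the *procedure* under a clean generative
model, not performance on any particular instrument's output.

## Problem sizes and numerical choices

The test suite and the acceptance script use 100 null datasets of 2,000
proteins (2 × 3 design, 20 cycles) for error-rate estimates, 100,000 draws
for imputation-moment checks, and 5,000 proteins for variance-prior
recovery — sizes at which the Monte-Carlo standard errors used in the
assertions (3 SE bands) are small relative to the quantities measured.
Trigamma inversion iterates Newton to 1e−8 relative tolerance; oracle
equivalence tests assert at 1e−8 to 1e−12; determinism is asserted
bit-exactly. UPGMA ties are broken deterministically by the linkage
implementation; distance matrices are symmetrized (averaging a 1-ulp
asymmetry) and clipped to [0, 2] for the correlation metric.

## Known limitations

- **No FDR control under missingness.** The detection-conditional downshift
  rule imputes a replicate group with ≤ 1 detection ~`2.5·sd_s` below the
  column mean, where `sd_s` is dominated by *between-protein* spread
  (~2.5 log2 units). A protein detected in one group but not the other —
  which arises by chance near the detection limit, and even under purely
  random missingness at realistic rates — therefore acquires a fabricated
  fold change of 2 or more with small within-group variance, and is called
  significant in nearly every cycle. Under a global-null simulation the mean
  per-dataset false-discovery proportion is ~0.85–0.9 rather than the 0.05
  the adjusted-p threshold suggests (the suite demonstrates this; with
  complete data the same testing stack keeps the null call rate within the
  nominal level). Practically: calls driven by one-sided detection should be
  reported as *differential detection*, not quantitative fold changes, and
  screened by detection counts — the DE table's provenance columns and the
  missingness labels make that audit straightforward.
- Only two-group designs; no covariates, paired tests, or >2 conditions.
- The moderated test assumes a common variance prior across the intensity
  range (no intensity-dependent trend).
- Enrichment quality is entirely determined by the user-supplied sets; no
  curated knowledge base ships with the package.
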