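# Methods

## The P50/P50 transcriptional-divergence statistic

For one cell with expression vector `x` over genes, drop all nonexpressed
genes (`x_g = 0`), sort the remaining `G` values, and define

    P50/P50 = (sum of the top ⌊G/2⌋ values) / (sum of the bottom ⌊G/2⌋ values).

The statistic is ≥ 1 by construction, is invariant to uniform scaling of a
cell's values (so raw counts and CP10k give identical values), and grows
when highly expressed genes are amplified while lowly expressed genes are
suppressed — a proxy for transcriptional plasticity. Numerical choices:

* **Odd `G`:** the median value is excluded from both halves, keeping the
  two halves the same size. This is symmetric and revisitable; whether the
  original formulation includes the median gene is not recoverable from
  the sources available to us.
* **Ties** are broken by gene index when sorting; the two half-sums are
  order-invariant under equal values, so this only fixes determinism.
* Cells with fewer than 2 expressed genes get a flagged missing value
  (NaN), never a silent 1.
* The default input layer is raw counts (the statistic is a count-sum
  ratio); a normalized layer can be requested, and rank-based downstream
  tests are invariant to monotone within-cell transforms either way.

The two-phase comparison (`compare_divergence`) is a two-sided Wilcoxon
rank-sum test on the per-cell values, pooled across patients.

## TF screen

For every transcription factor in a user-supplied list, the screen
computes (i) the Spearman correlation `rho` between the TF's normalized
(log1p CP10k) expression and per-cell divergence, with its t-approximation
p-value, and (ii) a two-sided rank-sum test of naive vs post expression,
with `log2fc = log2((mu_post + eps)/(mu_naive + eps))`, `eps = 1e-9`, on
CP10k (non-log) means. Benjamini–Hochberg adjustment is applied
*separately* to the two p-value columns, within the family of tested TFs
only. TFs expressed (raw count > 0) in fewer than `min_cells = 3` cells
are reported with missing statistics and excluded from both BH
denominators. The table is sorted by `rho` descending and `rank_by_rho`
is a permutation of 1..n_tested.

A caveat worth stating: because divergence is computed from the same
counts as the TF expression values, a gene that carries a large share of
a cell's counts contributes to its own divergence, and sequencing-depth
variation couples every gene to divergence after normalization. At
thousands of cells these effects are statistically detectable. The screen
is therefore best read as a *ranking*; the synthetic generator pins the
cell total (below) so that its calibration checks isolate the statistical
machinery from the depth confound.

## Pseudo-bulk paired comparison

Per patient and phase, the mean of a gene's normalized expression is the
pseudo-bulk value. Patients lacking either phase are excluded with a
warning. The paired contrast is a two-sided Wilcoxon signed-rank test on
the per-patient (post, naive) pairs (skipped with fewer than 3 complete
pairs), and `n_increased` counts patients with `mean_post > mean_naive`.

## Rank-test implementations

Rank-sum p-values are exact for total `n ≤ 10` via tie-aware enumeration
of all C(n+m, n) group assignments on average ranks (two-sided p =
`min(1, 2·min(#sums ≥ obs, #sums ≤ obs)/total)`), and use the normal
approximation with tie and continuity corrections (scipy) above that.
Signed-rank p-values are exact for up to 15 nonzero differences (all 2^n
sign patterns, zeros dropped) and normal-approximate beyond. Fully tied
data returns p = 1 with a degenerate flag. BH adjustment delegates to
statsmodels' step-up implementation.

## Gene-module scores

Genes are ranked by mean normalized expression and cut into `n_bins = 24`
equal-occupancy bins. Each module gene draws `n_ctrl = 100` control genes
from its own bin (excluding module genes; with replacement when the bin is
small), seeded for reproducibility. A cell's score is
`mean(module genes) − mean(control draw)`, which centers at ~0 for a
signal-free module and is invariant to adding a constant to all of a
cell's values. A plain module-mean variant (`method="mean"`) is provided
for sensitivity analysis. The antigen alias SSEA1 → FUT4 (also CD133 →
PROM1, CD117 → KIT) is applied when resolving module symbols, and applied
aliases plus missing genes are recorded on the output.

## Cluster enrichment and differential expression

Cluster enrichment is one-vs-each: the feature is tested between every
unordered pair of clusters (two-sided rank-sum), all k(k−1)/2 p-values are
BH-adjusted as a single family per feature, and each cluster is summarized
by its *largest* adjusted p (`max_fdr`) over its k−1 pairs. A cluster is
flagged enriched only when its median exceeds every other cluster's.
Singleton clusters are excluded with a warning. The repeated one-vs-rest
reading of "per-cluster worst FDR" is available by calling the one-vs-rest
DE per cluster; pairwise is the default.

`de_one_vs_rest` rank-sum-tests every gene (target cluster vs all other
cells, normalized layer), BH-adjusts across all tested genes, and returns
rows with `fdr < 0.005` and `log2fc > 0` by default. `de_two_group` tests
replicate columns per gene and thresholds on the raw p (< 0.05), matching
how bulk contrasts are usually reported in this setting; with 4 vs 4
replicates the smallest attainable exact two-sided p is 2/70 ≈ 0.029.
`intersect_signatures` returns the genes called in the same direction in
both tables; opposite-direction genes are excluded.

## IHC h-score

Per-cell mean DAB intensities of one compartment are pooled across *all*
tissues and cut at the nearest-rank 1/3 and 2/3 quantiles
(`np.quantile(..., method="inverted_cdf")`); a value equal to a cut point
falls in the lower bin; all-equal intensities degenerate to "medium" with
a flag. Per tissue,

    h = 100 · (3·high_n + 2·medium_n + 1·low_n) / (high_n + medium_n + low_n + total_n)

with `total_n` the tissue's classified-cell count. Because every cell is
binned, the denominator is twice the cell count and the range compresses
to [50, 150] (all-low 50, balanced tertiles 100, all-high 150). This
formula is applied exactly as specified upstream of this package; the
textbook variant `100·(3h+2m+l)/total` (range [100, 300] when every cell
is binned) is available behind `classical=True`. Phases are compared by a
two-sided rank-sum test on per-tissue h.

## Morphometrics

Tumor volume from a caliper diameter is `V = π(d/2)³` — reproduced
verbatim from the measurement protocol this package serves, including the
absence of the 4/3 sphere factor, so values are comparable with that
protocol's reported numbers rather than geometric sphere volumes.
Spheroid volume converts a projected area to a diameter assuming a
circular projection (`d = 2√(A/π)`) and reuses the same formula. Percent
change is `100·(V_day − V_baseline)/V_baseline` per animal and flank;
series with a zero baseline are flagged and excluded, a missing baseline
day is an error.

## Synthetic cohort generator

The generator produces data with the statistical structure the analyses
assume, plus a ground-truth manifest, so every stage is testable without
external downloads. It is a stand-in: its distributions are chosen for
tractability and are not fitted to any dataset (the truth manifest says
so explicitly).

**Model.** Gene base means are log-normal(μ=0, σ=1). Each cell carries a
plasticity factor `f ~ Beta(2, 4)`. The top half of genes (by base mean)
is scaled by `(1 + amp·f)` in every cell (`amp = 1.0`), so expected
divergence increases with `f`; post-phase cells get an additional
`(1 + shift·f)` factor (`shift = 0.6`), raising expected divergence after
treatment. One planted TF (named SOX9, base mean 8× the median gene) has
mean `∝ (1 + 6·coupling·f)` (`coupling = 0.8`), strictly increasing in
`f`, and is additionally scaled 1.6× in post cells (population-level
induction). A rare cluster (fraction 0.006 of cells, matching the
sub-percent stem-like population such cohorts report) carries the
12-gene ovarian CSC marker module at fold change 4. Patient structure is
per-patient, per-gene log-normal mean jitter (σ = 0.1), which averages
out of the divergence ratio and therefore does not cluster the statistic
by patient.

**Counts.** Per-cell gene weights are Gamma(r, μ/r) with dispersion
`r = 2` and counts are multinomial at a pinned library size (the sum of
base means, ≈1900) — i.e., negative-binomial composition conditioned on
the cell total. Pinning the total is deliberate: the divergence statistic
is mechanically depth-dependent, and a random library size per cell makes
*every* gene spuriously correlated with divergence after normalization.
Holding depth fixed makes divergence a pure composition readout, which
the null-calibration properties of the screen and the group test rely
on. Real data does not have this property; see Limitations.

**Sizes.** Defaults are 11 patients (the longitudinal cohort size this
emulates) × 2 phases × 60 cells, 1000 genes of which 120 are labeled TFs,
module size 12. These desk-scale sizes keep a 20-seed recovery sweep in
seconds while leaving all planted effects comfortably detectable.

**IHC.** Nuclear DAB intensities are Gamma(shape 4) around a tissue mean
(base 5, additive tissue effect σ = 0.3, clipped positive), with a +2.0
additive post-phase shift; 4 tissues per patient per phase, 50 cells per
tissue. A shift that would drive the mean nonpositive is rejected at
configuration time.

**Bulk contrasts.** Two tables of log2 expression (4 replicates per
group, gene base ~N(5, 2), noise σ = 0.5) share planted sets of 50 up-
and 50 down-regulated genes (|Δ| = 2) and each carries a private
perturbed set of 50, so the intersection is informative.

**Seeding.** One global seed is expanded into fixed per-stage substreams
(`numpy.random.SeedSequence.spawn`), so adding or consuming one stage
never perturbs another stage's draws; identical config + seed reproduces
outputs bit for bit.

**Null configurations.** `null_config` switches off the planted signals
(phase shift, TF coupling, TF post fold change) while keeping baseline
plasticity — the appropriate null for the divergence group test, whose
type-I error is then nominal (measured ≈4–5% at α = 0.05 over 400
simulations). For the screen's null calibration the baseline amplitude
must also be zero: with `amp > 0` every top-half gene is genuinely
coupled to divergence through `f`, so that configuration is not a null
for the screen.

## What passing tests do and do not show

The generator omits doublets, ambient RNA, batch effects, per-cell depth
variation, dropout beyond what the count model implies, and any fitted
relationship to real cohorts. Passing recovery and calibration tests
shows the estimators and tests are implemented correctly and behave
nominally under controlled structure; it does not certify performance on
real data, where sequencing depth, SCTransform-style normalization,
imputation, and patient heterogeneity all interact with the divergence
statistic. In particular the depth confound discussed above means
screen FDRs on real data should be treated as ranking scores.

## Problem sizes used by the test suite and acceptance script

Recovery sweeps use 20 seeds of the default configuration; type-I
calibration uses 400 simulations of a reduced configuration (4 patients ×
40 cells × 400 genes); the screen null uses 6 cohorts; oracle
equivalences use 1000 random vectors each. The full suite runs in about
half a minute and `scripts/acceptance.py` in about 20 seconds on one CPU.
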