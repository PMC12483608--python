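# divscreen

Quantitative building blocks for studying treatment-induced
transcriptional plasticity in tumors, written for computational biologists
analyzing longitudinal single-cell cohorts (e.g. high-grade serous ovarian
cancer sampled before and after neo-adjuvant chemotherapy), tissue
microarrays, and xenograft experiments.

The core quantity is **per-cell transcriptional divergence (P50/P50)**:
after removing nonexpressed genes, the ratio of the summed expression of
the top 50% of expressed genes to the summed expression of the bottom 50%,

    P50/P50 = Σ_{g ∈ top ⌊G/2⌋} x_g  /  Σ_{g ∈ bottom ⌊G/2⌋} x_g  ≥ 1,

a proxy for transcriptional plasticity that rises when a cell amplifies
its highly expressed genes and suppresses its lowly expressed ones.
Around it the package provides:

* **divergence group tests** — Wilcoxon rank-sum comparison of P50/P50
  between treatment phases;
* **a TF screen** — Spearman ρ of every transcription factor's normalized
  expression against divergence, plus naive-vs-post differential
  expression, each with its own Benjamini–Hochberg FDR column;
* **patient-paired pseudo-bulk** — per-patient phase means of one gene
  with a paired signed-rank test and a count of patients that increased;
* **gene-module scores** with expression-matched control bins, and
  **one-vs-each cluster enrichment** summarized by the worst pairwise FDR;
* **cluster and two-group differential expression** and two-contrast
  **signature intersection** (common up/down gene sets);
* **IHC h-scores** from per-cell DAB intensities (pooled tertile binning,
  `h = 100·(3·high + 2·medium + low)/(high + medium + low + total)`) with
  a phase group test;
* **tumor and spheroid morphometrics** (`V = π(d/2)³`, percent-change
  series);
* a **seeded synthetic cohort generator** (counts, cell metadata, IHC
  tables, bulk contrasts) with ground-truth manifests, so every stage is
  testable without external data;
* strict **cell QC** (count, nucleosome-signal, TSS-enrichment and
  mitochondrial thresholds) and CP10k·log1p normalization;
* 10x-style MTX / TSV readers and writers and a `divscreen` CLI exposing
  every stage (`simulate`, `qc`, `divergence`, `screen`, `module-score`,
  `cluster-test`, `de`, `intersect`, `pseudobulk`, `hscore`, `volume`).

The statistical estimators follow scikit-learn conventions
(`TranscriptionalDivergence`, `CP10kLogNormalizer`, `ModuleScorer`,
`TFDivergenceScreen`, `QCCellFilter` expose `fit`/`transform` and fitted
attributes, and compose with sklearn pipelines); the module-level
functions are thin wrappers operating on an AnnData.

## Worked example

```python
import divscreen as ds

cohort = ds.simulate_cohort(ds.SimConfig(seed=0))   # 1328 cells x 1000 genes
norm = ds.normalize_cp10k_log(cohort.adata)

table = ds.divergence_table(norm, layer="counts")
res = ds.compare_divergence(table)
print(f"median P50/P50: naive={res.median_b:.2f}  post={res.median_a:.2f}  "
      f"rank-sum p={res.p_value:.2e}")

screen = ds.tf_screen(norm, table, cohort.truth["tf_ids"])
print(screen.head(3)[["rho", "fdr_corr", "log2fc_phase", "fdr_de"]].round(3))

rows, paired, n_inc = ds.pseudobulk_paired(norm, "SOX9")
print(f"SOX9 increased in {n_inc} of {len(rows)} patients (paired p={paired.p_value:.4f})")

scores = ds.module_score(norm, cohort.truth["module_genes"], seed=0)
summary, _ = ds.cluster_enrichment(scores.to_numpy(), norm.obs["cluster"].to_numpy())
print(summary.round(4).to_string())
```

prints

```
median P50/P50: naive=4.06  post=4.18  rank-sum p=4.70e-17
         rho  fdr_corr  log2fc_phase  fdr_de
tf_id
SOX9   0.424     0.000         0.702   0.000
TF090  0.106     0.001         0.010   0.996
TF102  0.056     0.106         0.006   0.733
SOX9 increased in 11 of 11 patients (paired p=0.0010)
         n_cells  median  max_fdr  enriched
cluster
C3           260  0.0279   0.9730     False
C1           284  0.0823   0.1736     False
C0           257  0.0593   0.9730     False
C2           259  0.0302   0.9477     False
C4           260  0.0463   0.7353     False
rare           8  1.2191   0.0000      True
```

Reading the output: divergence is significantly higher in post-treatment
cells; the planted TF (named SOX9 in the generator) tops the screen by ρ
and is strongly induced after treatment (log2FC 0.70, FDR ≈ 0); its
pseudo-bulk mean rises in all 11 patients; and the planted rare stem-like
cluster (8 of 1328 cells) is the only cluster enriched for the 12-gene
CSC marker module, with the smallest worst-pairwise FDR.

The same pipeline runs from the shell:

```sh
divscreen --seed 0 --out sim simulate
divscreen --out out divergence --counts sim/counts --meta sim/cell_meta.tsv
divscreen --out out hscore --stains sim/ihc_stains.tsv
```

## Layout

```
src/divscreen/
  simulate.py    synthetic cohort / IHC / bulk generators + truth manifests
  io.py          MTX & TSV readers/writers, gene lists, manifests
  qc.py          QC thresholds & filter, CP10k-log1p normalizer
  divergence.py  P50/P50 statistic, tables, group test
  stats.py       rank tests (exact + asymptotic), Spearman, BH
  screen.py      TF screen, patient-paired pseudo-bulk
  modules.py     module scores, cluster enrichment, DE, intersection
  histo.py       stain binning, h-scores, volumes, percent change
  cli.py         click command-line interface
docs/methods.md  model, defaults, numerical choices, limitations
```
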