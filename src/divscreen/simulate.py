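"""Synthetic cohort, IHC and bulk-contrast generators.

The generators emulate the statistical structure the downstream analyses
assume, with a ground-truth manifest for every planted signal:

* overdispersed scRNA counts with log-normal gene means: per-cell gene
  weights are Gamma distributed (negative-binomial-style dispersion) and
  counts are multinomial at a fixed library size, i.e. negative-binomial
  composition conditioned on the cell total. Pinning the total makes the
  per-cell divergence statistic reflect transcriptome composition rather
  than sampling depth, which the calibration of the downstream tests
  relies on. Patient structure enters as per-patient per-gene mean
  jitter, with two treatment phases per patient;
* a per-cell plasticity factor f ~ Beta(a, b) scales the top half of gene
  means by (1 + baseline_amp * f) in every cell, so divergence tracks f;
  post-treatment cells get an additional (1 + shift * f) factor, which
  raises the expected P50/P50 divergence after treatment;
* one planted transcription factor (named SOX9) whose mean is a strictly
  increasing function of f, so its expression is monotonically coupled to
  divergence; its mean is additionally scaled by a fold change in
  post-treatment cells (population-level induction after chemotherapy);
* a rare (< 1%) stem-like cluster whose module genes (named after the 12
  ovarian CSC markers) are scaled by a fold change;
* per-cell nuclear DAB intensities (Gamma) with an additive post-treatment
  shift at the tissue level;
* two bulk differential contrasts sharing a planted up/down gene set.

A single seed is expanded into fixed per-stage substreams so adding a
stage never perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .io import write_cell_meta, write_counts, write_truth_manifest

__all__ = ["SimConfig", "SyntheticCohort", "simulate_cohort", "simulate_ihc",
           "simulate_bulk_contrasts", "write_cohort", "CSC_MARKERS"]

# 12-gene ovarian CSC marker module; the antigen name SSEA1 maps to FUT4
CSC_MARKERS = ["PROM1", "CD44", "ALDH1A1", "CD24", "KIT", "ENG",
               "VCAM1", "EPCAM", "NES", "SOX2", "FUT4", "THY1"]


@dataclass(frozen=True)
class SimConfig:
    """All generator knobs; the seed fully determines every output."""

    n_patients: int = 11
    cells_per_patient_per_phase: int = 60
    n_genes: int = 1000
    n_tfs: int = 120
    nb_dispersion: float = 2.0
    mean_logexpr_mu: float = 0.0
    mean_logexpr_sigma: float = 1.0
    plasticity_shape_a: float = 2.0
    plasticity_shape_b: float = 4.0
    planted_tf_coupling: float = 0.8
    planted_tf_post_foldchange: float = 1.6
    plasticity_baseline_amp: float = 1.0
    post_phase_divergence_shift: float = 0.6
    rare_cluster_fraction: float = 0.006
    rare_cluster_module_foldchange: float = 4.0
    module_size: int = 12
    n_clusters: int = 5
    patient_effect_sd: float = 0.1
    ihc_tissues_per_patient: int = 4
    ihc_cells_per_tissue: int = 50
    ihc_base_mean: float = 5.0
    ihc_shape: float = 4.0
    ihc_tissue_sd: float = 0.3
    ihc_post_shift: float = 2.0
    bulk_n_replicates: int = 4
    bulk_n_shared_up: int = 50
    bulk_n_shared_down: int = 50
    bulk_n_private: int = 50
    bulk_effect_lfc: float = 2.0
    bulk_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_patients": self.n_patients,
            "cells_per_patient_per_phase": self.cells_per_patient_per_phase,
            "n_genes": self.n_genes,
            "n_tfs": self.n_tfs,
            "module_size": self.module_size,
            "ihc_tissues_per_patient": self.ihc_tissues_per_patient,
            "ihc_cells_per_tissue": self.ihc_cells_per_tissue,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if not 0 < self.rare_cluster_fraction < 0.05:
            raise ValueError("rare_cluster_fraction must lie in (0, 0.05)")
        if self.rare_cluster_module_foldchange < 1:
            raise ValueError("rare_cluster_module_foldchange must be >= 1")
        if not 0 <= self.planted_tf_coupling <= 1:
            raise ValueError("planted_tf_coupling must lie in [0, 1]")
        if self.post_phase_divergence_shift < 0:
            raise ValueError("post_phase_divergence_shift must be nonnegative")
        if self.plasticity_baseline_amp < 0:
            raise ValueError("plasticity_baseline_amp must be nonnegative")
        if self.planted_tf_post_foldchange <= 0:
            raise ValueError("planted_tf_post_foldchange must be positive")
        if self.nb_dispersion <= 0 or self.plasticity_shape_a <= 0 or self.plasticity_shape_b <= 0:
            raise ValueError("dispersion and Beta shapes must be positive")
        if self.module_size + self.n_tfs > self.n_genes:
            raise ValueError("module_size + n_tfs must not exceed n_genes")
        if self.ihc_base_mean + min(0.0, self.ihc_post_shift) <= 0:
            raise ValueError("ihc_post_shift would produce a nonpositive mean intensity")
        if self.bulk_n_replicates < 3:
            raise ValueError("bulk contrasts need at least 3 replicates per group")


@dataclass
class SyntheticCohort:
    """Counts + annotations + ground-truth manifest."""

    adata: ad.AnnData
    truth: dict = field(default_factory=dict)


def _substreams(seed: int, n: int = 8):
    return np.random.SeedSequence(int(seed)).spawn(n)


def _gene_names(cfg: SimConfig) -> tuple[list[str], list[str], list[str]]:
    tf_names = ["SOX9"] + [f"TF{i:03d}" for i in range(1, cfg.n_tfs)]
    module = list(CSC_MARKERS[: cfg.module_size])
    module += [f"MODG{i:03d}" for i in range(len(module), cfg.module_size)]
    n_other = cfg.n_genes - len(tf_names) - len(module)
    other = [f"G{i:04d}" for i in range(n_other)]
    return tf_names, module, other


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw a full synthetic single-cell cohort with ground truth."""
    cfg = config
    ss = _substreams(cfg.seed)
    rng_genes = np.random.default_rng(ss[0])
    rng_cells = np.random.default_rng(ss[1])
    rng_counts = np.random.default_rng(ss[2])
    rng_qc = np.random.default_rng(ss[3])

    tf_names, module_names, other_names = _gene_names(cfg)
    gene_names = tf_names + module_names + other_names
    planted_tf = tf_names[0]
    tf_idx0 = 0

    base = rng_genes.lognormal(cfg.mean_logexpr_mu, cfg.mean_logexpr_sigma, cfg.n_genes)
    base[tf_idx0] = 8.0 * float(np.median(base))  # planted TF sits high in the top half
    order = np.argsort(base)
    top_half = np.zeros(cfg.n_genes, dtype=bool)
    top_half[order[cfg.n_genes - cfg.n_genes // 2 :]] = True

    n_main = cfg.n_patients * 2 * cfg.cells_per_patient_per_phase
    n_rare = int(math.ceil(cfg.rare_cluster_fraction * n_main))
    n_cells = n_main + n_rare

    patients = np.empty(n_cells, dtype=object)
    phases = np.empty(n_cells, dtype=object)
    clusters = np.empty(n_cells, dtype=object)
    i = 0
    for p in range(cfg.n_patients):
        for phase in ("naive", "post"):
            for _ in range(cfg.cells_per_patient_per_phase):
                patients[i] = f"P{p + 1:02d}"
                phases[i] = phase
                i += 1
    clusters[:n_main] = np.array(
        [f"C{k}" for k in rng_cells.integers(0, cfg.n_clusters, n_main)], dtype=object
    )
    for j in range(n_rare):  # rare stem-like cells live in naive tissue
        patients[n_main + j] = f"P{(j % cfg.n_patients) + 1:02d}"
        phases[n_main + j] = "naive"
        clusters[n_main + j] = "rare"

    f = rng_cells.beta(cfg.plasticity_shape_a, cfg.plasticity_shape_b, n_cells)
    # patient structure: per-patient multiplicative jitter of each gene mean;
    # iid across genes, so it averages out of the per-cell P50/P50 ratio
    patient_jitter = rng_cells.lognormal(0.0, cfg.patient_effect_sd, (cfg.n_patients, cfg.n_genes))
    patient_idx = np.array([int(p[1:]) - 1 for p in patients])

    mu = np.tile(base, (n_cells, 1))
    post_mask = phases == "post"
    # top-half scaling: baseline plasticity in every cell, extra shift post
    top_factor = 1.0 + cfg.plasticity_baseline_amp * f
    top_factor[post_mask] *= 1.0 + cfg.post_phase_divergence_shift * f[post_mask]
    mu[:, top_half] *= top_factor[:, None]
    # planted TF mean: strictly increasing in f whenever coupling > 0
    mu[:, tf_idx0] = base[tf_idx0] * (1.0 + 6.0 * cfg.planted_tf_coupling * f)
    if top_half[tf_idx0]:
        mu[:, tf_idx0] *= top_factor
    mu[post_mask, tf_idx0] *= cfg.planted_tf_post_foldchange
    module_idx = np.array([gene_names.index(g) for g in module_names])
    rare_mask = clusters == "rare"
    mu[np.ix_(rare_mask, module_idx)] *= cfg.rare_cluster_module_foldchange
    mu *= patient_jitter[patient_idx]

    # gamma-compound multinomial: NB-like dispersion at a pinned cell total
    r = cfg.nb_dispersion
    weights = rng_counts.gamma(r, mu / r)
    probs = weights / weights.sum(axis=1, keepdims=True)
    libsize = int(round(base.sum()))
    counts = rng_counts.multinomial(libsize, probs).astype(np.int64)

    cell_ids = [f"cell_{k:05d}" for k in range(n_cells)]
    obs = pd.DataFrame(
        {
            "patient_id": patients,
            "phase": phases,
            "cluster": clusters,
            "plasticity": f,
            "rna_counts": counts.sum(axis=1),
            "atac_counts": rng_qc.integers(2000, 50000, n_cells),
            "nucleosome_signal": rng_qc.uniform(0.5, 1.5, n_cells),
            "tss_enrichment": rng_qc.uniform(2.0, 8.0, n_cells),
            "pct_mito": rng_qc.uniform(0.0, 10.0, n_cells),
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    adata = ad.AnnData(
        X=counts,
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene_id")),
    )
    adata.uns["layer_tag"] = "counts"
    truth = {
        "planted_tf": planted_tf,
        "tf_ids": tf_names,
        "module_genes": module_names,
        "rare_cell_ids": [cell_ids[k] for k in np.flatnonzero(rare_mask)],
        "plasticity": dict(zip(cell_ids, f.tolist())),
        "generator_note": "synthetic stand-in; distributions are not derived from any dataset",
    }
    return SyntheticCohort(adata=adata, truth=truth)


def simulate_ihc(config: SimConfig) -> pd.DataFrame:
    """Per-cell nuclear DAB intensities with a post-treatment shift.

    Intensities are Gamma distributed around a tissue-level mean (phase
    mean plus an additive tissue effect, clipped to stay positive).
    """
    cfg = config
    rng = np.random.default_rng(_substreams(cfg.seed)[4])
    rows = []
    for p in range(cfg.n_patients):
        for phase in ("naive", "post"):
            for t in range(cfg.ihc_tissues_per_patient):
                mean = cfg.ihc_base_mean + (cfg.ihc_post_shift if phase == "post" else 0.0)
                mean = max(mean + rng.normal(0.0, cfg.ihc_tissue_sd), 0.05)
                vals = rng.gamma(cfg.ihc_shape, mean / cfg.ihc_shape, cfg.ihc_cells_per_tissue)
                tissue = f"P{p + 1:02d}_{phase}_T{t + 1}"
                for c, v in enumerate(vals):
                    rows.append((f"{tissue}_c{c + 1}", tissue, f"P{p + 1:02d}",
                                 phase, "nuclear", float(v)))
    return pd.DataFrame(
        rows, columns=["cell_id", "tissue_id", "patient_id", "phase", "compartment", "dab_mean"]
    )


def simulate_bulk_contrasts(config: SimConfig):
    """Two replicate-group expression tables sharing a planted DE gene set.

    Returns ``(table_a, table_b, truth)``. Each table has genes in rows and
    replicate columns named ``ctrl_i`` / ``trt_i`` (log2 expression).
    Shared up/down gene sets are perturbed in the same direction in both
    contrasts; each contrast also carries a private perturbed set.
    """
    cfg = config
    rng = np.random.default_rng(_substreams(cfg.seed)[5])
    genes = [f"BG{i:04d}" for i in range(cfg.n_genes)]
    n_shared = cfg.bulk_n_shared_up + cfg.bulk_n_shared_down
    n_special = n_shared + 2 * cfg.bulk_n_private
    if n_special > cfg.n_genes:
        raise ValueError("planted gene sets exceed the gene universe")
    perm = rng.permutation(cfg.n_genes)
    up_idx = perm[: cfg.bulk_n_shared_up]
    down_idx = perm[cfg.bulk_n_shared_up : n_shared]
    privA = perm[n_shared : n_shared + cfg.bulk_n_private]
    privB = perm[n_shared + cfg.bulk_n_private : n_special]

    base = rng.normal(5.0, 2.0, cfg.n_genes)
    n_rep = cfg.bulk_n_replicates
    tables = []
    for which, priv in (("A", privA), ("B", privB)):
        effect = np.zeros(cfg.n_genes)
        effect[up_idx] = cfg.bulk_effect_lfc
        effect[down_idx] = -cfg.bulk_effect_lfc
        signs = np.where(np.arange(len(priv)) % 2 == 0, 1.0, -1.0)
        effect[priv] = signs * cfg.bulk_effect_lfc
        ctrl = base[:, None] + rng.normal(0, cfg.bulk_noise_sd, (cfg.n_genes, n_rep))
        trt = (base + effect)[:, None] + rng.normal(0, cfg.bulk_noise_sd, (cfg.n_genes, n_rep))
        df = pd.DataFrame(
            np.hstack([ctrl, trt]),
            index=pd.Index(genes, name="gene_id"),
            columns=[f"ctrl_{i + 1}" for i in range(n_rep)] + [f"trt_{i + 1}" for i in range(n_rep)],
        )
        tables.append(df)
    truth = {
        "shared_up": [genes[i] for i in up_idx],
        "shared_down": [genes[i] for i in down_idx],
        "private_A": [genes[i] for i in privA],
        "private_B": [genes[i] for i in privB],
    }
    return tables[0], tables[1], truth


def null_config(config: SimConfig) -> SimConfig:
    """The same conditions with the phase shift and TF coupling off.

    Baseline plasticity (and its divergence variation) remains: the null
    removes the planted signals, not the biology the cohort emulates.
    """
    return replace(
        config,
        planted_tf_coupling=0.0,
        planted_tf_post_foldchange=1.0,
        post_phase_divergence_shift=0.0,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write counts (MTX dir), cell meta TSV and the truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(cohort.adata, out / "counts")
    write_cell_meta(cohort.adata.obs, out / "cell_meta.tsv")
    flat = {
        "planted_tf": cohort.truth["planted_tf"],
        "tf_ids": cohort.truth["tf_ids"],
        "module_genes": cohort.truth["module_genes"],
        "rare_cell_ids": cohort.truth["rare_cell_ids"],
        "generator_note": cohort.truth["generator_note"],
    }
    write_truth_manifest(flat, out / "truth.txt")
    return out
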