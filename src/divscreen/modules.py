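"""Gene-module scoring and cluster-level statistics.

Module scores use the control-bin construction: genes are binned by mean
expression, each module gene draws control genes from its own bin, and a
cell's score is the mean expression of the module genes minus the mean of
the controls. This centers the score at zero for a module with no signal
regardless of the modules' expression magnitude.

Cluster enrichment is one-vs-each: a feature is tested between every
unordered pair of clusters (two-sided rank-sum), BH-adjusted as a single
family, and each cluster is summarized by the *largest* adjusted p over
its pairs — a cluster is only called enriched when it beats every other
cluster.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

from .stats import bh_adjust, wilcoxon_rank_sum

__all__ = [
    "GENE_ALIASES",
    "resolve_module_genes",
    "ModuleScorer",
    "module_score",
    "cluster_enrichment",
    "de_one_vs_rest",
    "de_two_group",
    "intersect_signatures",
]

# non-HGNC antigen names mapped to gene symbols
GENE_ALIASES = {"SSEA1": "FUT4", "CD133": "PROM1", "CD117": "KIT"}

_LOG2FC_EPS = 1e-9


def resolve_module_genes(gene_ids, var_names):
    """Map module symbols onto matrix genes, applying known aliases.

    Returns ``(present, missing, aliases_applied)``.
    """
    var_set = set(var_names)
    present, missing, applied = [], [], {}
    for g in gene_ids:
        if g in var_set:
            present.append(g)
        elif g in GENE_ALIASES and GENE_ALIASES[g] in var_set:
            present.append(GENE_ALIASES[g])
            applied[g] = GENE_ALIASES[g]
        else:
            missing.append(g)
    return present, missing, applied


class ModuleScorer(TransformerMixin, BaseEstimator):
    """Per-cell module score with expression-matched control genes.

    Parameters
    ----------
    module_genes
        Gene symbols in the module.
    n_bins, n_ctrl
        Number of mean-expression bins and control genes sampled per
        module gene (with replacement when a bin is smaller than n_ctrl).
    method
        'control' (default, control-bin difference) or 'mean' (plain mean
        of module genes, for sensitivity analysis).
    random_state
        Seed for control sampling.
    """

    def __init__(self, module_genes=(), n_bins: int = 24, n_ctrl: int = 100,
                 method: str = "control", random_state: int = 0):
        self.module_genes = module_genes
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl
        self.method = method
        self.random_state = random_state

    def fit(self, X, y=None, *, feature_names):
        X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
        feature_names = list(feature_names)
        present, missing, applied = resolve_module_genes(self.module_genes, feature_names)
        if not present:
            raise ValueError(f"no module gene present in the matrix; missing: {missing}")
        self.module_idx_ = np.array([feature_names.index(g) for g in present])
        self.missing_genes_ = missing
        self.aliases_applied_ = applied
        if self.method == "mean":
            self.control_idx_ = np.array([], dtype=int)
            return self
        means = X.mean(axis=0)
        # equal-occupancy bins on the rank of the gene means
        ranks = pd.Series(means).rank(method="first")
        bins = pd.qcut(ranks, min(self.n_bins, len(ranks)), labels=False).to_numpy()
        rng = np.random.default_rng(self.random_state)
        module_set = set(self.module_idx_.tolist())
        ctrl = []
        for j in self.module_idx_:
            pool = np.flatnonzero((bins == bins[j]) & ~np.isin(np.arange(len(bins)), list(module_set)))
            if pool.size == 0:  # degenerate bin made only of module genes
                pool = np.flatnonzero(bins == bins[j])
            replace = pool.size < self.n_ctrl
            ctrl.append(rng.choice(pool, size=self.n_ctrl, replace=replace))
        self.control_idx_ = np.concatenate(ctrl)
        return self

    def transform(self, X) -> np.ndarray:
        X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
        module_mean = X[:, self.module_idx_].mean(axis=1)
        if self.method == "mean":
            return module_mean
        ctrl_mean = X[:, self.control_idx_].mean(axis=1)
        return module_mean - ctrl_mean


def module_score(adata, module_genes, n_bins: int = 24, n_ctrl: int = 100,
                 method: str = "control", seed: int = 0) -> pd.Series:
    """Per-cell module score on the normalized layer of an AnnData."""
    if adata.uns.get("layer_tag") != "log1p_cp10k":
        raise ValueError("module_score expects a log1p_cp10k-normalized matrix")
    scorer = ModuleScorer(module_genes, n_bins=n_bins, n_ctrl=n_ctrl,
                          method=method, random_state=seed)
    scorer.fit(adata.X, feature_names=list(adata.var_names))
    scores = scorer.transform(adata.X)
    s = pd.Series(scores, index=adata.obs_names, name="module_score")
    s.attrs["missing_genes"] = scorer.missing_genes_
    s.attrs["aliases_applied"] = scorer.aliases_applied_
    return s


def cluster_enrichment(feature, clusters):
    """One-vs-each cluster enrichment of a per-cell feature.

    Returns ``(summary, pairs)``: per-cluster max BH-adjusted p over its
    pairwise tests (with an ``enriched`` flag set only when the cluster's
    median exceeds every other cluster's), and the full pairwise table.
    Singleton clusters are excluded with a warning.
    """
    feature = np.asarray(feature, dtype=float)
    clusters = np.asarray(clusters)
    labels = [c for c in pd.unique(clusters)]
    sizes = {c: int((clusters == c).sum()) for c in labels}
    singles = [c for c in labels if sizes[c] < 2]
    if singles:
        warnings.warn(f"singleton clusters excluded: {singles}", stacklevel=2)
        labels = [c for c in labels if sizes[c] >= 2]
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters with >= 2 cells")
    values = {c: feature[clusters == c] for c in labels}
    medians = {c: float(np.median(values[c])) for c in labels}
    pair_rows = []
    for a, b in combinations(labels, 2):
        res = wilcoxon_rank_sum(values[a], values[b])
        pair_rows.append((a, b, res.p_value))
    pairs = pd.DataFrame(pair_rows, columns=["cluster_a", "cluster_b", "p"])
    pairs["fdr"] = bh_adjust(pairs["p"].to_numpy())
    rows = []
    for c in labels:
        mask = (pairs["cluster_a"] == c) | (pairs["cluster_b"] == c)
        max_fdr = float(pairs.loc[mask, "fdr"].max())
        enriched = all(medians[c] > medians[o] for o in labels if o != c)
        rows.append((c, sizes[c], medians[c], max_fdr, enriched))
    summary = pd.DataFrame(
        rows, columns=["cluster", "n_cells", "median", "max_fdr", "enriched"]
    ).set_index("cluster")
    return summary, pairs


def _de_frame(stats_rows) -> pd.DataFrame:
    df = pd.DataFrame(stats_rows, columns=["gene_id", "log2fc", "p"]).set_index("gene_id")
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    df["direction"] = np.where(df["log2fc"] > 0, "up", "down")
    return df


def de_one_vs_rest(adata, cluster_col: str, target_cluster,
                   fdr_max: float = 0.005, lfc_min: float = 0.0) -> pd.DataFrame:
    """Rank-sum DE of one cluster against all remaining cells.

    Tests every gene on the normalized layer, BH-adjusts across all tested
    genes, and returns the rows with ``fdr < fdr_max`` and
    ``log2fc > lfc_min`` sorted by fdr. The full table is available via
    ``result.attrs['n_tested']``.
    """
    labels = adata.obs[cluster_col].to_numpy()
    in_target = labels == target_cluster
    if not in_target.any():
        raise ValueError(f"cluster {target_cluster!r} not found in {cluster_col!r}")
    if in_target.sum() < 3 or (~in_target).sum() < 3:
        raise ValueError("target cluster and complement each need >= 3 cells")
    if adata.uns.get("layer_tag") != "log1p_cp10k":
        raise ValueError("de_one_vs_rest expects a log1p_cp10k-normalized matrix")
    X = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X, dtype=float)
    cp10k = np.expm1(X)
    rows = []
    for j, g in enumerate(adata.var_names):
        a, b = X[in_target, j], X[~in_target, j]
        res = wilcoxon_rank_sum(a, b)
        lfc = float(np.log2((cp10k[in_target, j].mean() + _LOG2FC_EPS)
                            / (cp10k[~in_target, j].mean() + _LOG2FC_EPS)))
        rows.append((g, lfc, res.p_value))
    df = _de_frame(rows)
    out = df[(df["fdr"] < fdr_max) & (df["log2fc"] > lfc_min)].sort_values("fdr")
    out.attrs["n_tested"] = len(df)
    return out


def de_two_group(table: pd.DataFrame, cols_a=None, cols_b=None,
                 p_max: float = 0.05) -> pd.DataFrame:
    """Per-gene two-group rank-sum DE on a replicate expression table.

    Thresholds on the raw p-value (``p < p_max``); direction is the sign
    of the mean difference (B minus A, on the table's own scale).
    Columns default to the ``ctrl_*`` / ``trt_*`` naming of the bulk
    generator.
    """
    if cols_a is None:
        cols_a = [c for c in table.columns if str(c).startswith("ctrl")]
    if cols_b is None:
        cols_b = [c for c in table.columns if str(c).startswith("trt")]
    if len(cols_a) < 3 or len(cols_b) < 3:
        raise ValueError("need at least 3 replicates per group")
    A = table[cols_a].to_numpy(dtype=float)
    B = table[cols_b].to_numpy(dtype=float)
    rows = []
    for i, g in enumerate(table.index):
        res = wilcoxon_rank_sum(B[i], A[i])
        rows.append((g, float(B[i].mean() - A[i].mean()), res.p_value))
    df = _de_frame(rows)
    out = df[df["p"] < p_max].sort_values("p")
    out.attrs["n_tested"] = len(df)
    return out


def intersect_signatures(table_a: pd.DataFrame, table_b: pd.DataFrame):
    """Shared up/down gene sets of two differential tables.

    Genes with opposite directions in the two tables are excluded.
    Returns ``(common_up, common_down, counts)``.
    """
    up_a = set(table_a.index[table_a["direction"] == "up"])
    dn_a = set(table_a.index[table_a["direction"] == "down"])
    up_b = set(table_b.index[table_b["direction"] == "up"])
    dn_b = set(table_b.index[table_b["direction"] == "down"])
    common_up = sorted(up_a & up_b)
    common_down = sorted(dn_a & dn_b)
    counts = {"n_common_up": len(common_up), "n_common_down": len(common_down)}
    return common_up, common_down, counts
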