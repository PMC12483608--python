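"""Transcription-factor divergence screen and patient-paired pseudo-bulk.

The screen ranks every supplied TF by the Spearman correlation between its
normalized expression and per-cell transcriptional divergence, alongside a
naive-vs-post rank-sum differential test. BH adjustment is applied
separately within the tested TF family for the two p-value columns. TFs
expressed in fewer than ``min_cells`` cells are reported with missing
statistics and excluded from both BH denominators.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator

from .stats import bh_adjust, spearman_rho, wilcoxon_rank_sum, wilcoxon_signed_rank

__all__ = ["TFDivergenceScreen", "tf_screen", "pseudobulk_paired"]

_LOG2FC_EPS = 1e-9


def _log2fc(mu_post: float, mu_naive: float) -> float:
    return float(np.log2((mu_post + _LOG2FC_EPS) / (mu_naive + _LOG2FC_EPS)))


class TFDivergenceScreen(BaseEstimator):
    """Feature screen of TF columns against a per-cell divergence target.

    Parameters
    ----------
    min_cells
        Minimum number of cells with a nonzero raw count for a TF to be
        tested (default 3).

    Attributes
    ----------
    results_ : DataFrame indexed by TF id, sorted by rho descending, with
        columns n_cells_expressing, rho, p_corr, fdr_corr, log2fc_phase,
        p_de, fdr_de, rank_by_rho.
    """

    def __init__(self, min_cells: int = 3):
        self.min_cells = min_cells

    def fit(self, X, y, *, phase, counts, feature_names):
        """Screen every column of X (normalized expression) against y.

        ``counts`` carries the raw counts (same shape) for the expression
        filter; ``phase`` is the per-cell 'naive'/'post' label; X is the
        log1p CP10k layer (CP10k means for the fold change are recovered by
        expm1).
        """
        X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
        counts = counts.toarray() if sparse.issparse(counts) else np.asarray(counts)
        y = np.asarray(y, dtype=float)
        phase = np.asarray(phase)
        ok = ~np.isnan(y)
        X, counts, y, phase = X[ok], counts[ok], y[ok], phase[ok]
        naive = phase == "naive"
        post = phase == "post"
        cp10k = np.expm1(X)

        rows = []
        for j, name in enumerate(feature_names):
            n_expr = int((counts[:, j] > 0).sum())
            if n_expr < self.min_cells:
                rows.append((name, n_expr, np.nan, np.nan, np.nan, np.nan))
                continue
            rho, p_corr = spearman_rho(X[:, j], y)
            de = wilcoxon_rank_sum(X[post, j], X[naive, j])
            lfc = _log2fc(float(cp10k[post, j].mean()), float(cp10k[naive, j].mean()))
            rows.append((name, n_expr, rho, p_corr, lfc, de.p_value))
        res = pd.DataFrame(
            rows,
            columns=["tf_id", "n_cells_expressing", "rho", "p_corr", "log2fc_phase", "p_de"],
        ).set_index("tf_id")
        tested = res["p_corr"].notna()
        res["fdr_corr"] = np.nan
        res["fdr_de"] = np.nan
        if tested.any():
            res.loc[tested, "fdr_corr"] = bh_adjust(res.loc[tested, "p_corr"].to_numpy())
            res.loc[tested, "fdr_de"] = bh_adjust(res.loc[tested, "p_de"].to_numpy())
        res = res.sort_values("rho", ascending=False, na_position="last")
        res["rank_by_rho"] = np.nan
        res.loc[res["rho"].notna(), "rank_by_rho"] = np.arange(1, int(tested.sum()) + 1)
        self.results_ = res
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X=None):  # convenience accessor, sklearn-style
        return self.results_


def tf_screen(adata, div_table: pd.DataFrame, tf_list, min_cells: int = 3) -> pd.DataFrame:
    """Run the divergence screen for the TFs present in the matrix.

    ``adata`` must carry the log1p CP10k layer in X and raw counts in
    ``layers['counts']``; ``div_table`` must be indexed by the same cells.
    """
    if adata.uns.get("layer_tag") != "log1p_cp10k":
        raise ValueError("tf_screen expects a log1p_cp10k-normalized matrix")
    present = [t for t in tf_list if t in adata.var_names]
    if not present:
        raise ValueError("no TF from the list is present in the matrix")
    missing = sorted(set(tf_list) - set(present))
    sub = adata[:, present]
    div = div_table.loc[adata.obs_names, "divergence"].to_numpy()
    phase = adata.obs["phase"].to_numpy()
    est = TFDivergenceScreen(min_cells=min_cells).fit(
        sub.X, div, phase=phase, counts=sub.layers["counts"], feature_names=present
    )
    res = est.results_
    res.attrs["missing_tfs"] = missing
    return res


def pseudobulk_paired(adata, gene_id: str):
    """Patient-paired pseudo-bulk comparison of one gene across phases.

    Per patient and phase, the mean of the normalized (log1p CP10k)
    expression is computed; patients lacking either phase are excluded
    with a warning. Returns ``(per_patient_frame, GroupTestResult|None,
    n_increased)`` where the paired signed-rank test is skipped (None)
    with fewer than 3 complete pairs.
    """
    if gene_id not in adata.var_names:
        raise KeyError(f"gene {gene_id!r} not in matrix")
    if adata.uns.get("layer_tag") != "log1p_cp10k":
        raise ValueError("pseudobulk_paired expects a log1p_cp10k-normalized matrix")
    expr = adata[:, gene_id].X
    expr = np.asarray(expr.toarray() if sparse.issparse(expr) else expr).ravel()
    df = pd.DataFrame(
        {"patient_id": adata.obs["patient_id"], "phase": adata.obs["phase"], "expr": expr}
    )
    means = df.groupby(["patient_id", "phase"], observed=True)["expr"].mean().unstack()
    complete = means.dropna(subset=["naive", "post"]) if {"naive", "post"} <= set(means.columns) else means.iloc[0:0]
    dropped = sorted(set(means.index) - set(complete.index))
    if dropped:
        warnings.warn(f"patients missing a phase were excluded: {dropped}", stacklevel=2)
    rows = pd.DataFrame(
        {
            "mean_naive": complete["naive"],
            "mean_post": complete["post"],
            "increased": complete["post"] > complete["naive"],
        }
    )
    n_increased = int(rows["increased"].sum())
    test = None
    if len(rows) >= 3:
        test = wilcoxon_signed_rank(rows["mean_post"].to_numpy(), rows["mean_naive"].to_numpy())
    return rows, test, n_increased
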