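"""Per-cell transcriptional divergence (P50/P50).

The statistic captures how strongly a cell's expressed transcriptome is
dominated by its most highly expressed genes: drop all nonexpressed genes,
then divide the summed expression of the top half of the expressed genes by
the summed expression of the bottom half. Values are >= 1 by construction;
higher values indicate a more divergent (plastic) transcriptional state.
For an odd number of expressed genes the median gene is excluded from both
halves, keeping them the same size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

from .stats import GroupTestResult, wilcoxon_rank_sum

__all__ = [
    "DivergenceProfile",
    "TranscriptionalDivergence",
    "transcriptional_divergence",
    "divergence_table",
    "compare_divergence",
]


@dataclass
class DivergenceProfile:
    """P50/P50 decomposition for one cell."""

    n_expressed: int
    top_sum: float
    bottom_sum: float
    divergence: float  # nan when fewer than 2 genes are expressed


def _profile_from_values(values: np.ndarray) -> DivergenceProfile:
    expressed = values[values > 0]
    g = int(expressed.size)
    if g < 2:
        return DivergenceProfile(g, float("nan"), float("nan"), float("nan"))
    expressed = np.sort(expressed)[::-1]
    half = g // 2
    top = float(expressed[:half].sum())
    bottom = float(expressed[g - half :].sum())
    return DivergenceProfile(g, top, bottom, top / bottom)


def transcriptional_divergence(cell_values) -> DivergenceProfile:
    """Compute the P50/P50 profile of a single cell's value vector.

    Cells with fewer than 2 expressed genes yield a flagged missing result
    (``divergence`` is NaN) rather than a silent 1.
    """
    values = np.asarray(cell_values, dtype=float).ravel()
    if np.any(values < 0):
        raise ValueError("expression values must be nonnegative")
    return _profile_from_values(values)


class TranscriptionalDivergence(TransformerMixin, BaseEstimator):
    """Transformer mapping a cells-by-genes matrix to per-cell P50/P50.

    Stateless (``fit`` only records the input dimension); ``transform``
    returns an ``(n_cells, 1)`` array so the estimator composes with
    sklearn pipelines. Cells with fewer than ``min_expressed`` expressed
    genes map to NaN.
    """

    def __init__(self, min_expressed: int = 2):
        self.min_expressed = min_expressed

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _validate(X):
        if sparse.issparse(X):
            X = X.tocsr()
            if (X.data < 0).any():
                raise ValueError("expression values must be nonnegative")
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (cells x genes)")
        if (X < 0).any():
            raise ValueError("expression values must be nonnegative")
        return X

    def transform(self, X) -> np.ndarray:
        X = self._validate(X)
        out = np.empty((X.shape[0], 1))
        for i in range(X.shape[0]):
            row = X.getrow(i).toarray().ravel() if sparse.issparse(X) else X[i]
            prof = _profile_from_values(row)
            out[i, 0] = prof.divergence if prof.n_expressed >= max(2, self.min_expressed) else np.nan
        return out

    def profile_frame(self, X) -> pd.DataFrame:
        """Full per-cell decomposition (n_expressed, top/bottom sums, ratio)."""
        X = self._validate(X)
        rows = []
        for i in range(X.shape[0]):
            row = X.getrow(i).toarray().ravel() if sparse.issparse(X) else X[i]
            p = _profile_from_values(row)
            rows.append((p.n_expressed, p.top_sum, p.bottom_sum, p.divergence))
        return pd.DataFrame(rows, columns=["n_expressed", "top_sum", "bottom_sum", "divergence"])


def divergence_table(adata, layer: str = "counts", subset=None) -> pd.DataFrame:
    """Per-cell divergence table joined to cell annotations.

    Parameters
    ----------
    adata
        AnnData, cells x genes, with raw counts in ``layers['counts']``.
    layer
        'counts' (default) or any layer / 'X' present on the object.
    subset
        Optional boolean mask or index over cells (e.g. an epithelial
        label); an empty subset is an error.
    """
    if layer == "X":
        mat = adata.X
    elif layer in adata.layers:
        mat = adata.layers[layer]
    elif layer == "counts":
        mat = adata.X
    else:
        raise KeyError(f"layer {layer!r} not found")
    obs = adata.obs
    if subset is not None:
        mask = np.asarray(subset)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        if len(idx) == 0:
            raise ValueError("cell subset is empty")
        mat = mat[idx]
        obs = obs.iloc[idx]
    est = TranscriptionalDivergence()
    table = est.profile_frame(mat)
    table.index = obs.index
    return pd.concat([obs, table], axis=1)


def compare_divergence(table: pd.DataFrame, group_col: str = "phase") -> GroupTestResult:
    """Two-sided rank-sum comparison of divergence between two groups.

    Groups are the two levels of ``table[group_col]`` (conventionally
    'naive' vs 'post'); NaN divergences are dropped. The result's
    ``direction`` refers to the second (alphabetically later) group so that
    'greater' means post > naive for the standard phase labels.
    """
    vals = table["divergence"]
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    a = vals[table[group_col] == groups[0]].dropna().to_numpy()
    b = vals[table[group_col] == groups[1]].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 cells with a divergence value")
    res = wilcoxon_rank_sum(b, a, alternative="two-sided")
    return res
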