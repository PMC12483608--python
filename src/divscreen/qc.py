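"""Cell-level quality control and library-size normalization.

QC thresholds follow the multiome filtering rule: cells with more than
1e5 or fewer than 1,000 RNA (or ATAC) counts, nucleosome signal above 2,
TSS enrichment below 1, or mitochondrial percentage above 50 are removed.
All comparisons are strict, so a cell sitting exactly on a threshold is
kept. A criterion whose metric is absent for a cell is skipped for that
cell and flagged in the report.

Normalization is CP10k + log1p: counts are scaled to 10,000 per cell and
natural-log transformed. The downstream statistics are rank-based and
therefore invariant to this (or any other) monotone within-cell transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "QCThresholds",
    "QCReport",
    "QCCellFilter",
    "apply_qc",
    "CP10kLogNormalizer",
    "normalize_cp10k_log",
]

# metric column -> (threshold attribute, removal predicate name)
_CRITERIA = (
    ("rna_counts", "max_counts", "rna_counts_high"),
    ("rna_counts", "min_counts", "rna_counts_low"),
    ("atac_counts", "max_counts", "atac_counts_high"),
    ("atac_counts", "min_counts", "atac_counts_low"),
    ("nucleosome_signal", "max_nucleosome_signal", "nucleosome_signal_high"),
    ("tss_enrichment", "min_tss_enrichment", "tss_enrichment_low"),
    ("pct_mito", "max_pct_mito", "pct_mito_high"),
)


@dataclass
class QCThresholds:
    """Strict-inequality removal thresholds for cell QC."""

    max_counts: int = 100_000
    min_counts: int = 1_000
    max_nucleosome_signal: float = 2.0
    min_tss_enrichment: float = 1.0
    max_pct_mito: float = 50.0

    def __post_init__(self):
        if not self.min_counts < self.max_counts:
            raise ValueError("min_counts must be below max_counts")
        for name in ("max_nucleosome_signal", "min_tss_enrichment", "max_pct_mito"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    removed_by_criterion: dict = field(default_factory=dict)
    skipped_criteria: list = field(default_factory=list)
    survivors: list = field(default_factory=list)


def _criterion_fails(values: pd.Series, attr: str, thresholds: QCThresholds) -> pd.Series:
    thr = getattr(thresholds, attr)
    if attr.startswith("max"):
        fails = values > thr
    else:
        fails = values < thr
    return fails.fillna(False)  # absent metric -> criterion skipped for that cell


class QCCellFilter(BaseEstimator):
    """Row filter applying the strict-inequality QC rule to a metrics frame.

    ``fit`` takes the per-cell QC metrics table and records the boolean
    keep mask (``support_``) plus a :class:`QCReport`; ``transform``
    subsets any aligned cells-by-genes matrix or frame.
    """

    def __init__(self, thresholds: QCThresholds | None = None):
        self.thresholds = thresholds

    def fit(self, qc: pd.DataFrame, y=None):
        thr = self.thresholds or QCThresholds()
        if not isinstance(qc, pd.DataFrame):
            raise TypeError("QC metrics must be a DataFrame")
        if "rna_counts" not in qc.columns:
            raise ValueError("QC metrics block missing (no rna_counts column)")
        removed_by: dict[str, int] = {}
        skipped: list[str] = []
        fail_any = pd.Series(False, index=qc.index)
        for col, attr, label in _CRITERIA:
            if col not in qc.columns or qc[col].isna().all():
                skipped.append(label)
                continue
            fails = _criterion_fails(qc[col].astype(float), attr, thr)
            removed_by[label] = int(fails.sum())
            fail_any |= fails
        keep = ~fail_any
        if not keep.any():
            raise ValueError("QC removed every cell; check thresholds and metrics")
        self.support_ = keep.to_numpy()
        self.report_ = QCReport(
            n_input=len(qc),
            n_kept=int(keep.sum()),
            removed_by_criterion=removed_by,
            skipped_criteria=skipped,
            survivors=list(qc.index[keep]),
        )
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        if X.shape[0] != self.support_.size:
            raise ValueError("X rows do not match the fitted QC table")
        if isinstance(X, pd.DataFrame):
            return X.loc[self.support_]
        return X[self.support_]


def apply_qc(adata, thresholds: QCThresholds | None = None):
    """Filter an AnnData by the QC rule; returns (filtered copy, QCReport).

    The input object is left untouched.
    """
    flt = QCCellFilter(thresholds).fit(adata.obs)
    out = adata[flt.get_support()].copy()
    return out, flt.report_


class CP10kLogNormalizer(TransformerMixin, BaseEstimator):
    """ln(1 + 10,000 * count / cell_total) transform on a counts matrix."""

    def fit(self, X, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if sparse.issparse(X):
            X = X.toarray()
        X = np.asarray(X, dtype=float)
        totals = X.sum(axis=1)
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            raise ValueError(f"cells with zero total counts: rows {zero[:10].tolist()}")
        return np.log1p(X * (10_000.0 / totals[:, None]))


def normalize_cp10k_log(adata):
    """Return a copy with X = log1p(CP10k); raw counts kept in layers['counts'].

    Errors if the object is not on the counts layer (no silent
    double-normalization).
    """
    tag = adata.uns.get("layer_tag", "counts")
    if tag != "counts":
        raise ValueError(f"normalize expects a counts layer, found {tag!r}")
    out = adata.copy()
    counts = out.X.toarray() if sparse.issparse(out.X) else np.asarray(out.X, dtype=float)
    out.layers["counts"] = counts
    out.X = CP10kLogNormalizer().fit_transform(counts)
    out.uns["layer_tag"] = "log1p_cp10k"
    return out
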