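"""Readers and writers for the formats the pipeline touches.

Counts travel as a 10x-style MTX directory (matrix.mtx + features.tsv +
barcodes.tsv, genes in rows) or a dense TSV whose top-left header token
declares the orientation ('gene_id': genes in rows; 'cell_id': cells in
rows). Everything else is tab-separated UTF-8 with a header row; missing
values are empty fields. In memory, counts live in an AnnData (cells x
genes) with ``uns['layer_tag']`` recording the layer semantics.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_counts",
    "write_counts",
    "read_cell_meta",
    "write_cell_meta",
    "read_gene_list",
    "write_truth_manifest",
    "read_truth_manifest",
    "file_checksum",
]

_PHASE_ALIASES = {
    "naive": "naive",
    "treatment-naive": "naive",
    "treatment_naive": "naive",
    "pre": "naive",
    "post": "post",
    "post-nact": "post",
    "post_nact": "post",
}

_QC_NUMERIC_COLS = (
    "rna_counts",
    "atac_counts",
    "nucleosome_signal",
    "tss_enrichment",
    "pct_mito",
)


def _dedupe(names):
    """De-duplicate symbols by appending '.1', '.2', ... to repeats."""
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return out


def _read_mtx_dir(path: Path) -> ad.AnnData:
    matrix_file = path / "matrix.mtx"
    features_file = next((path / n for n in ("features.tsv", "genes.tsv") if (path / n).exists()), None)
    barcodes_file = path / "barcodes.tsv"
    missing = [str(f) for f in (matrix_file, barcodes_file) if not f.exists()]
    if features_file is None:
        missing.append(str(path / "features.tsv"))
    if missing:
        raise FileNotFoundError(f"MTX directory incomplete, missing: {missing}")
    mat = spio.mmread(matrix_file).tocsr()  # genes x cells (10x convention)
    features = pd.read_csv(features_file, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(barcodes_file, sep="\t", header=None, dtype=str)[0].tolist()
    if features.shape[0] != mat.shape[0]:
        raise ValueError(
            f"dimension mismatch: matrix declares {mat.shape[0]} genes but "
            f"features file has {features.shape[0]} lines"
        )
    if len(barcodes) != mat.shape[1]:
        raise ValueError(
            f"dimension mismatch: matrix declares {mat.shape[1]} cells but "
            f"barcodes file has {len(barcodes)} lines"
        )
    dupes = pd.Series(barcodes)[pd.Series(barcodes).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate cell barcodes: {dupes}")
    # gene id = symbol column (column 2) when present, else column 1
    symbols = features[1] if features.shape[1] >= 2 else features[0]
    gene_ids = _dedupe(symbols.tolist())
    adata = ad.AnnData(
        X=mat.T.tocsr(),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    adata.uns["layer_tag"] = "counts"
    return adata


def _read_dense_tsv(path: Path) -> ad.AnnData:
    df = pd.read_csv(path, sep="\t", index_col=0)
    token = df.index.name
    if token not in {"gene_id", "cell_id"}:
        raise ValueError(
            "dense counts TSV must declare orientation via its top-left header "
            f"token ('gene_id' or 'cell_id'), found {token!r}"
        )
    if token == "gene_id":
        df = df.T  # to cells x genes
    if df.index.duplicated().any():
        raise ValueError(f"duplicate cell ids: {df.index[df.index.duplicated()].tolist()}")
    adata = ad.AnnData(
        X=df.to_numpy(dtype=float),
        obs=pd.DataFrame(index=pd.Index(df.index.astype(str), name="cell_id")),
        var=pd.DataFrame(index=pd.Index(_dedupe(df.columns.astype(str)), name="gene_id")),
    )
    adata.uns["layer_tag"] = "counts"
    return adata


def read_counts(path) -> ad.AnnData:
    """Read counts from an MTX directory or a dense TSV into an AnnData."""
    path = Path(path)
    if path.is_dir():
        adata = _read_mtx_dir(path)
    else:
        adata = _read_dense_tsv(path)
    X = adata.X
    data = X.data if sparse.issparse(X) else np.asarray(X)
    if (data < 0).any():
        raise ValueError("counts must be nonnegative")
    return adata


def write_counts(adata: ad.AnnData, out_dir) -> Path:
    """Write an AnnData's X as a 10x-style MTX directory (genes in rows)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sparse.coo_matrix(X.T if not sparse.issparse(X) else X.T)
    field = "integer" if adata.uns.get("layer_tag", "counts") == "counts" else "real"
    spio.mmwrite(out / "matrix.mtx", mat, field=field)
    feats = pd.DataFrame({0: adata.var_names, 1: adata.var_names, 2: "Gene Expression"})
    feats.to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    return out


def read_cell_meta(path) -> pd.DataFrame:
    """Read a per-cell annotation table; requires a cell_id column.

    Phase strings are case-normalized onto {naive, post}; unknown columns
    are preserved untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in df.columns:
        raise ValueError("cell meta file must contain a cell_id column")
    df = df.set_index("cell_id")
    if "phase" in df.columns:
        norm = df["phase"].str.strip().str.lower().map(_PHASE_ALIASES)
        bad = df["phase"].notna() & norm.isna()
        if bad.any():
            raise ValueError(
                f"unrecognized phase labels: {df.loc[bad, 'phase'].unique().tolist()}"
            )
        df["phase"] = norm
    for col in _QC_NUMERIC_COLS:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
                raise ValueError(
                    f"column {col!r} has unparsable numeric values in rows {bad_rows.tolist()[:5]}"
                ) from None
    return df


def write_cell_meta(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=True, index_label="cell_id")
    return path


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one symbol per line, '#' comments allowed."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return genes


def write_truth_manifest(truth: dict, path) -> Path:
    """Flat key=value manifest; list values are comma-joined."""
    lines = []
    for key, val in truth.items():
        if isinstance(val, (list, tuple, np.ndarray)):
            val = ",".join(str(v) for v in val)
        lines.append(f"{key}={val}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def read_truth_manifest(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, val = line.partition("=")
        out[key] = val.split(",") if "," in val else val
    return out


def file_checksum(path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()
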