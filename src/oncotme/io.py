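"""File I/O: MTX count triplets, dense counts, GMT, TSV tables.

All tabular writers emit tab-separated UTF-8 with a header row, LF line
endings and a deterministic column order; readers tolerate CRLF.  Count
matrices are stored genes-as-rows in Matrix Market format with ``genes.tsv``
and ``barcodes.tsv`` sidecars (the barcode file carries the per-cell
``condition`` and ``cluster`` columns).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread, mmwrite

MATRIX_FILE = "matrix.mtx"
GENES_FILE = "genes.tsv"
BARCODES_FILE = "barcodes.tsv"
BARCODE_COLUMNS = ("barcode", "condition", "cluster")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
    return path


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_counts(adata: AnnData, outdir) -> Path:
    """Write an MTX triplet (matrix.mtx genes x cells, genes.tsv, barcodes.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    mmwrite(str(outdir / MATRIX_FILE), X.T.tocoo().astype(np.int64))
    write_tsv(pd.DataFrame({"gene": adata.var_names}), outdir / GENES_FILE)
    meta = pd.DataFrame(
        {
            "barcode": adata.obs_names,
            "condition": adata.obs["condition"].astype(str),
            "cluster": adata.obs["cluster"].to_numpy(),
        }
    )
    write_tsv(meta, outdir / BARCODES_FILE)
    return outdir


def _validate_meta(meta: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in BARCODE_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(
            f"{source}: missing required column(s) {missing}; expected "
            f"{list(BARCODE_COLUMNS)}"
        )
    if meta["barcode"].duplicated().any():
        raise ValueError(f"{source}: duplicate cell barcodes")
    return meta


def read_counts(path, meta_path=None) -> AnnData:
    """Read a count matrix into AnnData (cells x genes, integer counts).

    ``path`` is either a directory holding the MTX triplet, or a dense
    CSV/TSV (genes as rows, first column gene names, remaining columns
    cells) with a separate barcode metadata table at ``meta_path``.
    Dimension mismatches between the matrix and sidecar files are an error
    naming the files; non-integer counts and duplicate identifiers are
    rejected.
    """
    path = Path(path)
    if path.is_dir():
        mat = sp.csr_matrix(mmread(path / MATRIX_FILE)).T  # -> cells x genes
        genes = read_tsv(path / GENES_FILE)["gene"].astype(str)
        meta = _validate_meta(read_tsv(path / BARCODES_FILE), str(path / BARCODES_FILE))
        if mat.shape[1] != len(genes):
            raise ValueError(
                f"{path / MATRIX_FILE} has {mat.shape[1]} genes but "
                f"{path / GENES_FILE} lists {len(genes)}"
            )
        if mat.shape[0] != len(meta):
            raise ValueError(
                f"{path / MATRIX_FILE} has {mat.shape[0]} cells but "
                f"{path / BARCODES_FILE} lists {len(meta)}"
            )
        data = mat
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        dense = pd.read_csv(path, sep=sep, index_col=0)
        genes = dense.index.astype(str).to_series().reset_index(drop=True)
        if meta_path is None:
            raise ValueError("dense counts require a barcode metadata table")
        meta = _validate_meta(read_tsv(meta_path), str(meta_path))
        if dense.shape[1] != len(meta):
            raise ValueError(
                f"{path} has {dense.shape[1]} cells but {meta_path} lists "
                f"{len(meta)}"
            )
        vals = dense.to_numpy()
        data = sp.csr_matrix(vals.T)
    if genes.duplicated().any():
        raise ValueError("duplicate gene identifiers")
    arr = data.data if sp.issparse(data) else data
    if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
        raise ValueError("counts must be non-negative integers")
    obs = pd.DataFrame(
        {
            "condition": pd.Categorical(meta["condition"].astype(str)),
            "cluster": meta["cluster"].to_numpy(),
        },
        index=meta["barcode"].astype(str).to_numpy(),
    )
    var = pd.DataFrame(index=pd.Index(genes.to_numpy(), name="gene"))
    return AnnData(X=data.astype(np.int32), obs=obs, var=var)


def write_gmt(sets: dict[str, list[str]], path, description: str = "synthetic") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sets[name]]) + "\n")
    return path


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\r\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets


def read_lr_pairs(path) -> pd.DataFrame:
    df = read_tsv(path)
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise ValueError(f"{path}: pair table missing column {col!r}")
    return df[["ligand", "receptor"]].astype(str)


def write_lr_pairs(df: pd.DataFrame, path) -> Path:
    return write_tsv(df[["ligand", "receptor"]], path)


def read_tumor_tsv(path) -> pd.DataFrame:
    df = read_tsv(path)
    if "subject" not in df.columns or "day" not in df.columns:
        raise ValueError(f"{path}: tumor table needs 'subject' and 'day' columns")
    return df
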