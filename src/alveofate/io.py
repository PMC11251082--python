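"""10x-style MTX triplet and CSV readers/writers.

A dataset directory holds ``matrix.mtx`` (MatrixMarket coordinate, genes x
cells, 1-based per the standard), ``features.tsv`` (gene_id <tab>
gene_symbol), ``barcodes.tsv`` (one barcode per line) and ``metadata.tsv``
(per-cell annotations keyed by barcode).  Dense CSV export (cells as rows,
header = gene symbols, first column = barcode) is supported as a lighter
alternative.  Round trips are exact for counts, symbols, barcodes and
metadata.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .containers import AnnotatedCounts

MATRIX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
BARCODES_FILE = "barcodes.tsv"
METADATA_FILE = "metadata.tsv"


def write_counts(data: AnnotatedCounts, path: str | Path) -> Path:
    """Write the MTX triplet + metadata TSV into directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(data.counts.T)  # genes x cells, 10x orientation
    mmwrite(path / MATRIX_FILE, mat, field="integer")
    with open(path / FEATURES_FILE, "w") as fh:
        for g in data.gene_symbols:
            fh.write(f"{g}\t{g}\n")
    with open(path / BARCODES_FILE, "w") as fh:
        for b in data.barcodes:
            fh.write(f"{b}\n")
    data.cell_meta.to_csv(path / METADATA_FILE, sep="\t", index_label="barcode")
    return path


def read_counts(path: str | Path) -> AnnotatedCounts:
    """Read a dataset from an MTX triplet directory or a dense CSV file."""
    path = Path(path)
    if path.is_dir():
        return _read_mtx_dir(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    raise ValueError(f"cannot read counts from {path}: expected a triplet "
                     "directory or a .csv file")


def _read_mtx_dir(path: Path) -> AnnotatedCounts:
    mat_path = path / MATRIX_FILE
    for f in (mat_path, path / FEATURES_FILE, path / BARCODES_FILE):
        if not f.exists():
            raise FileNotFoundError(f"missing triplet file: {f}")
    mat = mmread(mat_path)
    counts = np.asarray(sp.coo_matrix(mat).todense()).T  # cells x genes
    features = []
    for ln, line in enumerate((path / FEATURES_FILE).read_text().splitlines(), 1):
        cols = line.rstrip("\n").split("\t")
        if len(cols) not in (2, 3):
            raise ValueError(
                f"{path / FEATURES_FILE}:{ln}: expected 2 or 3 tab-separated "
                f"columns, found {len(cols)}"
            )
        features.append(cols[1])
    barcodes = [b for b in (path / BARCODES_FILE).read_text().splitlines() if b]
    if counts.shape[1] != len(features):
        raise ValueError(
            f"matrix has {counts.shape[1]} genes but features file lists {len(features)}"
        )
    if counts.shape[0] != len(barcodes):
        raise ValueError(
            f"matrix has {counts.shape[0]} cells but barcodes file lists {len(barcodes)}"
        )
    meta_path = path / METADATA_FILE
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col="barcode")
        if len(meta) != len(barcodes) or list(meta.index.astype(str)) != barcodes:
            raise ValueError("metadata barcodes do not match barcodes file")
    else:
        meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return AnnotatedCounts(counts=counts.astype(np.int64), gene_symbols=features,
                           cell_meta=meta)


def write_counts_csv(data: AnnotatedCounts, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(data.counts, index=pd.Index(data.barcodes, name="barcode"),
                      columns=data.gene_symbols)
    df.to_csv(path)
    meta_path = path.with_suffix(".meta.tsv")
    data.cell_meta.to_csv(meta_path, sep="\t", index_label="barcode")
    return path


def _read_csv(path: Path) -> AnnotatedCounts:
    df = pd.read_csv(path, index_col=0)
    meta_path = path.with_suffix(".meta.tsv")
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col="barcode")
    else:
        meta = pd.DataFrame(index=pd.Index(df.index.astype(str), name="barcode"))
    return AnnotatedCounts(counts=df.to_numpy(), gene_symbols=list(df.columns),
                           cell_meta=meta)
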