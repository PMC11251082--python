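"""Core in-memory containers shared by every pipeline stage.

The package works on two matrix containers: :class:`AnnotatedCounts` holds raw
UMI-style integer counts with per-cell metadata, and :class:`ExpressionMatrix`
holds normalized (and possibly imputed) expression values together with a log
of the transforms that produced them.  Both can be converted to
:class:`anndata.AnnData` for interoperability with the wider single-cell
ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MITO_PREFIXES = ("mt-", "MT-")

#: metadata columns the generators always populate
META_COLUMNS = ("timepoint", "genotype", "dataset_id")


def is_mito_symbol(symbol: str) -> bool:
    """True if a gene symbol denotes a mitochondrially encoded gene."""
    return symbol.startswith(MITO_PREFIXES)


@dataclass
class AnnotatedCounts:
    """Cells x genes integer count matrix with per-cell annotations.

    Parameters
    ----------
    counts
        ``(n_cells, n_genes)`` array of non-negative integers.
    gene_symbols
        Unique gene symbols, one per matrix column.  Mitochondrial genes are
        identified by the ``mt-``/``MT-`` prefix.
    cell_meta
        One row per cell (index = barcode).  Generators record ``timepoint``,
        ``genotype``, ``dataset_id`` and, for synthetic data, ``true_state``
        and latent-trajectory ground truth.
    """

    counts: np.ndarray
    gene_symbols: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_symbols = list(self.gene_symbols)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if len(self.gene_symbols) != self.counts.shape[1]:
            raise ValueError(
                f"gene_symbols length {len(self.gene_symbols)} != "
                f"{self.counts.shape[1]} matrix columns"
            )
        if len(self.cell_meta) != self.counts.shape[0]:
            raise ValueError(
                f"cell_meta has {len(self.cell_meta)} rows but matrix has "
                f"{self.counts.shape[0]} cells"
            )
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            dupes = pd.Index(self.gene_symbols)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"gene symbols not unique: {dupes}")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.counts.size and not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)

    # -- convenience ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> list[str]:
        return list(self.cell_meta.index.astype(str))

    def mito_mask(self) -> np.ndarray:
        return np.array([is_mito_symbol(g) for g in self.gene_symbols])

    def mito_fractions(self) -> np.ndarray:
        """Observed mitochondrial count fraction per cell (0 where total 0)."""
        mask = self.mito_mask()
        total = self.counts.sum(axis=1).astype(float)
        mito = self.counts[:, mask].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1.0), 0.0)
        return frac

    def subset_cells(self, mask_or_idx) -> "AnnotatedCounts":
        idx = np.asarray(mask_or_idx)
        return AnnotatedCounts(
            counts=self.counts[idx],
            gene_symbols=list(self.gene_symbols),
            cell_meta=self.cell_meta.iloc[np.flatnonzero(idx)].copy()
            if idx.dtype == bool
            else self.cell_meta.iloc[idx].copy(),
        )

    def to_anndata(self):
        import anndata

        ad = anndata.AnnData(
            X=self.counts.astype(np.float32),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_symbols, name="gene")),
        )
        return ad


@dataclass
class ExpressionMatrix:
    """Cells x genes real-valued expression in normalized/log (or imputed) space."""

    values: np.ndarray
    gene_symbols: list[str]
    cell_meta: pd.DataFrame
    transform_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_symbols = list(self.gene_symbols)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x genes)")
        if len(self.gene_symbols) != self.values.shape[1]:
            raise ValueError("gene_symbols length mismatch")
        if len(self.cell_meta) != self.values.shape[0]:
            raise ValueError("cell_meta row count mismatch")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def barcodes(self) -> list[str]:
        return list(self.cell_meta.index.astype(str))

    def gene_index(self, symbol: str) -> int:
        """Column index of a symbol; case-insensitive fallback for cross-species lookups."""
        try:
            return self.gene_symbols.index(symbol)
        except ValueError:
            folded = [g.upper() for g in self.gene_symbols]
            try:
                return folded.index(symbol.upper())
            except ValueError:
                raise KeyError(f"gene {symbol!r} not present") from None

    def gene_values(self, symbol: str) -> np.ndarray:
        return self.values[:, self.gene_index(symbol)]

    def with_values(self, values: np.ndarray, note: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            gene_symbols=list(self.gene_symbols),
            cell_meta=self.cell_meta,
            transform_log=[*self.transform_log, note],
        )

    def to_anndata(self):
        import anndata

        ad = anndata.AnnData(
            X=self.values.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_symbols, name="gene")),
        )
        ad.uns["transform_log"] = list(self.transform_log)
        return ad
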