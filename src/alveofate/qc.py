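"""Quality control and normalization.

Cells whose mitochondrial count fraction exceeds a threshold (strictly
greater) are removed: 20% for organoid and human libraries, 10% for in vivo
libraries.  An optional minimum-total-count filter is exposed but off by
default.  Normalization scales each retained cell to a common total
(default 10,000 counts) and applies the natural log(1 + x) transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AnnotatedCounts, ExpressionMatrix

#: mito-fraction cutoffs used by the respective analyses
MITO_THRESHOLD_ORGANOID = 0.20
MITO_THRESHOLD_HUMAN = 0.20
MITO_THRESHOLD_INVIVO = 0.10

DEFAULT_TARGET_SUM = 10_000


@dataclass(frozen=True)
class QCParams:
    max_mito_fraction: float = MITO_THRESHOLD_ORGANOID
    min_total_counts: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0,1]")
        if self.min_total_counts is not None and self.min_total_counts < 0:
            raise ValueError("min_total_counts must be non-negative")


def qc_filter(data: AnnotatedCounts, params: QCParams,
              report: dict | None = None) -> AnnotatedCounts:
    """Remove cells with mito fraction strictly above the threshold.

    Gene set and cell ordering are preserved.  If ``report`` is a dict it is
    filled with in/out counts per criterion.  When no mitochondrial genes can
    be identified a warning is raised and all cells pass the mito criterion
    (flagged in the report).
    """
    mito_mask = data.mito_mask()
    n = data.n_cells
    if not mito_mask.any():
        warnings.warn("no mitochondrial genes (mt-/MT- prefix) found; "
                      "mito filter passes all cells")
        keep_mito = np.ones(n, dtype=bool)
        no_mito_genes = True
    else:
        frac = data.mito_fractions()
        keep_mito = frac <= params.max_mito_fraction
        no_mito_genes = False

    keep = keep_mito.copy()
    removed_low_count = 0
    if params.min_total_counts is not None:
        totals = data.counts.sum(axis=1)
        keep_counts = totals >= params.min_total_counts
        removed_low_count = int((keep_mito & ~keep_counts).sum())
        keep &= keep_counts

    if report is not None:
        report.update(
            n_cells_in=n,
            n_cells_out=int(keep.sum()),
            removed_mito=int((~keep_mito).sum()),
            removed_low_count=removed_low_count,
            max_mito_fraction=params.max_mito_fraction,
            min_total_counts=params.min_total_counts,
            no_mito_genes=no_mito_genes,
        )
    return data.subset_cells(keep)


def qc_report_frame(report: dict) -> pd.DataFrame:
    """QC report as a one-row table ready for TSV export."""
    return pd.DataFrame([report])


def normalize_log(data: AnnotatedCounts, target_sum: int = DEFAULT_TARGET_SUM) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then apply ln(1 + x).

    Zero-total cells cannot be normalized and are excluded with a warning.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = data.counts.sum(axis=1).astype(float)
    nonzero = totals > 0
    if not nonzero.any():
        raise ValueError("no cell with nonzero total counts")
    if (~nonzero).any():
        warnings.warn(f"excluding {int((~nonzero).sum())} zero-total cell(s) "
                      "from normalization")
    counts = data.counts[nonzero].astype(float)
    scaled = counts * (target_sum / totals[nonzero])[:, None]
    values = np.log1p(scaled)
    return ExpressionMatrix(
        values=values,
        gene_symbols=list(data.gene_symbols),
        cell_meta=data.cell_meta.iloc[np.flatnonzero(nonzero)].copy(),
        transform_log=[f"normalize_total(target_sum={target_sum})", "log1p"],
    )
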