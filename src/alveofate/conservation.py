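"""Cross-dataset conserved-receptor identification and co-expression statistics.

Receptor hit sets from independent datasets (possibly mixing mouse-case and
human-case symbols) are harmonized by case-folded symbol equality and
intersected exactly; the double-positive fraction and signature-gene
correlation quantify co-expression of candidate receptors with partner genes
and with the injury/plasticity program.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .states import CommunityLabels


@dataclass
class ConservedReceptorReport:
    """Per-dataset post-filter receptor hits and their harmonized intersection."""

    hit_sets: dict[str, frozenset[str]]      # dataset tag -> harmonized symbols
    intersection: tuple[str, ...]            # sorted harmonized symbols
    expression_summaries: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "hit_sets": {k: sorted(v) for k, v in self.hit_sets.items()},
            "intersection": list(self.intersection),
            "n_conserved": len(self.intersection),
        }


def harmonize_symbols(symbols: Sequence[str]) -> frozenset[str]:
    """Case-fold gene symbols to uppercase (Itga3 <-> ITGA3)."""
    return frozenset(s.upper() for s in symbols)


def conserved_receptors(hit_sets: Sequence[Sequence[str]],
                        dataset_tags: Sequence[str] | None = None) -> ConservedReceptorReport:
    """Exact intersection of case-harmonized receptor hit sets (>= 2 sets)."""
    if len(hit_sets) == 0:
        raise ValueError("no hit sets given")
    if len(hit_sets) < 2:
        raise ValueError("need at least 2 hit sets to intersect")
    if dataset_tags is None:
        dataset_tags = [f"dataset{i}" for i in range(len(hit_sets))]
    if len(dataset_tags) != len(hit_sets):
        raise ValueError("dataset_tags length mismatch")
    harmonized = {t: harmonize_symbols(s) for t, s in zip(dataset_tags, hit_sets)}
    inter = frozenset.intersection(*harmonized.values())
    return ConservedReceptorReport(
        hit_sets=harmonized,
        intersection=tuple(sorted(inter)),
    )


def receptor_expression_summary(matrix: ExpressionMatrix, labels: CommunityLabels,
                                genes: Sequence[str]) -> pd.DataFrame:
    """Mean relative expression of each gene per community (heatmap-style table)."""
    comm = labels.assignment.to_numpy()
    rows = []
    for g in genes:
        v = matrix.gene_values(g)
        for c in range(labels.n_communities):
            rows.append({"gene": g, "community": c,
                         "mean_expression": float(v[comm == c].mean())})
    return pd.DataFrame(rows)


def double_positive_fraction(matrix: ExpressionMatrix, gene_a: str, gene_b: str,
                             labels: CommunityLabels,
                             threshold: float = 0.0) -> pd.DataFrame:
    """Per community, the fraction of cells with both genes strictly above threshold.

    "Relative expression > 0" uses whatever space ``matrix`` is in (imputed
    by default in the pipeline; raw normalized as the alternative mode).
    """
    va = matrix.gene_values(gene_a)  # KeyError names the missing gene
    vb = matrix.gene_values(gene_b)
    pos = (va > threshold) & (vb > threshold)
    comm = labels.assignment.to_numpy()
    rows = []
    for c in range(labels.n_communities):
        mask = comm == c
        rows.append({
            "community": c,
            "n_cells": int(mask.sum()),
            "fraction_double_positive": float(pos[mask].mean()) if mask.any() else np.nan,
        })
    return pd.DataFrame(rows)


def signature_gene_correlation(matrix: ExpressionMatrix, gene: str,
                               score: pd.Series) -> tuple[float, float]:
    """Spearman correlation (rho, p) between a gene's expression and a signature score.

    Constant gene or constant score makes the correlation undefined; reported
    as (nan, nan).
    """
    v = matrix.gene_values(gene)
    s = np.asarray(score, dtype=float)
    if len(v) != len(s):
        raise ValueError("score and matrix disagree on cell count")
    if len(v) < 3:
        raise ValueError("need at least 3 cells")
    if np.ptp(v) == 0 or np.ptp(s) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(v, s)
    return float(rho), float(p)
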