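"""Wilcoxon rank-sum differential expression, BH control, and panel filters.

DE runs on normalized log values (not imputed values: diffusion sharing makes
rank tests anti-conservative).  Per gene, a two-sided Wilcoxon rank-sum
(Mann-Whitney U) with tie correction and normal approximation compares the
group against the reference; p-values are Benjamini-Hochberg adjusted across
genes; log2 fold changes use expm1'd means with a small pseudocount.  The
TF filter (p < 0.05 and log2FC > 1) and the receptor filter (p < 0.05) are
expressed through :class:`FilterParams`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

LOG2FC_PSEUDOCOUNT = 1e-9


@dataclass(frozen=True)
class FilterParams:
    """DE-table filtering thresholds; comparisons are strict (p < p_max, |lfc| > lfc_min)."""

    p_max: float = 0.05
    lfc_min: float = 0.0
    direction: Literal["up", "down", "both"] = "up"
    use_adjusted: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError("p_max must lie in (0,1]")
        if self.direction not in ("up", "down", "both"):
            raise ValueError("direction must be 'up', 'down' or 'both'")


def rank_genes(matrix: ExpressionMatrix, group_mask: np.ndarray,
               reference_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Two-sided rank-sum DE of ``group`` vs ``reference`` (default: rest).

    Returns a DETable indexed by gene symbol with columns ``mean_in``,
    ``mean_out`` (expm1 scale), ``log2_fold_change``, ``ranksum_statistic``
    (Mann-Whitney U of the group), ``p_value`` and BH ``adjusted_p``.
    """
    group_mask = np.asarray(group_mask, dtype=bool)
    if reference_mask is None:
        reference_mask = ~group_mask
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if group_mask.sum() < 2 or reference_mask.sum() < 2:
        raise ValueError("both groups need at least 2 cells")

    x_in = matrix.values[group_mask]
    x_out = matrix.values[reference_mask]
    # exact null for tiny untied samples, tie-corrected normal approx otherwise
    res = stats.mannwhitneyu(x_in, x_out, alternative="two-sided",
                             method="auto", axis=0)
    mean_in = np.expm1(x_in).mean(axis=0)
    mean_out = np.expm1(x_out).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lfc = np.log2((mean_in + LOG2FC_PSEUDOCOUNT) / (mean_out + LOG2FC_PSEUDOCOUNT))
    adj = multipletests(res.pvalue, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "mean_in": mean_in,
            "mean_out": mean_out,
            "log2_fold_change": lfc,
            "ranksum_statistic": res.statistic,
            "p_value": res.pvalue,
            "adjusted_p": adj,
        },
        index=pd.Index(matrix.gene_symbols, name="gene"),
    )


def rank_genes_by_label(matrix: ExpressionMatrix, labels: Sequence,
                        group, reference="rest") -> pd.DataFrame:
    """Label-based wrapper: ``labels`` may be community ids or metadata values."""
    lab = np.asarray(labels)
    group_mask = lab == group
    if not group_mask.any():
        raise ValueError(f"group {group!r} is empty")
    ref_mask = None if (isinstance(reference, str) and reference == "rest") else lab == reference
    return rank_genes(matrix, group_mask, ref_mask)


def filter_by_panel(table: pd.DataFrame, panel, params: FilterParams) -> list[str]:
    """Panel genes passing the p and log2FC criteria, in table order.

    Symbols are matched case-insensitively; returned symbols use the table's
    spelling.  Thresholds are strict: a gene at exactly ``p_max`` is excluded.
    """
    symbols = tuple(panel) if not hasattr(panel, "symbols") else panel.symbols
    if not symbols:
        raise ValueError("empty panel")
    panel_fold = {s.upper() for s in symbols}
    p = table["adjusted_p"] if params.use_adjusted else table["p_value"]
    lfc = table["log2_fold_change"]
    in_panel = table.index.str.upper().isin(panel_fold)
    sig = p.to_numpy() < params.p_max
    if params.direction == "up":
        eff = lfc.to_numpy() > params.lfc_min
    elif params.direction == "down":
        eff = lfc.to_numpy() < -params.lfc_min
    else:
        eff = np.abs(lfc.to_numpy()) > params.lfc_min
    return table.index[in_panel & sig & eff].tolist()


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum on raw values (e.g. organoid diameters, um).

    Uses the exact null distribution for small untied samples; returns
    ``(statistic, p_value)``.  Two completely tied samples give p = 1.0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        return float(len(a) * len(b) / 2), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
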