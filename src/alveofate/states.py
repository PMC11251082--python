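"""Leiden communities, bin-matched signature scoring, and state classification.

The signature score of a cell is the mean expression of the panel genes minus
the mean of expression-bin-matched control genes: genes are ranked by mean
expression across cells and cut into ``n_bins`` equal-size bins; for every
panel gene, ``n_control`` control genes are sampled (seeded) from its bin.
A score of 0 therefore means "no different from background", and states are
classified by thresholding the injury/plasticity and AT2 scores at 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .graph import NeighborGraph
from .panels import GenePanel

STATE_CLASSES = (
    "injury-high/AT2-low",
    "injury-low/AT2-high",
    "double-high",
    "double-low",
)


@dataclass
class CommunityLabels:
    """Cell -> community assignment from modularity-style optimization."""

    assignment: pd.Series  # index = barcode, values = int community id
    resolution: float
    seed: int

    def __post_init__(self) -> None:
        ids = np.sort(self.assignment.unique())
        if len(ids) and not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("community ids must be contiguous from 0")

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max()) + 1 if len(self.assignment) else 0

    def members(self, community: int) -> np.ndarray:
        return np.flatnonzero(self.assignment.to_numpy() == community)


@dataclass
class SignatureScoreTable:
    """Cells x panels signature scores plus the control-gene configuration."""

    scores: pd.DataFrame  # index = barcode, one column per panel
    control_config: dict = field(default_factory=dict)


def _graph_to_igraph(graph: NeighborGraph) -> igraph.Graph:
    W = graph.affinity.tocoo()
    mask = W.row < W.col  # undirected: keep upper triangle
    edges = list(zip(W.row[mask].tolist(), W.col[mask].tolist()))
    g = igraph.Graph(n=graph.n_cells, edges=edges)
    g.es["weight"] = W.data[mask].tolist()
    return g


def leiden_communities(graph: NeighborGraph, resolution: float = 1.0,
                       seed: int = 0,
                       barcodes: list[str] | None = None) -> CommunityLabels:
    """Leiden partition of the affinity graph (RB-configuration modularity)."""
    if graph.n_cells == 0:
        raise ValueError("empty graph")
    g = _graph_to_igraph(graph)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    membership = np.asarray(part.membership)
    # relabel contiguous 0..m-1 in order of first appearance (leidenalg already
    # yields contiguous ids, but don't rely on it)
    _, membership = np.unique(membership, return_inverse=True)
    idx = pd.Index(
        barcodes if barcodes is not None else range(graph.n_cells), name="barcode"
    )
    return CommunityLabels(
        assignment=pd.Series(membership, index=idx, name="community"),
        resolution=resolution,
        seed=seed,
    )


def _expression_bins(mean_expr: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-size expression bins by rank of mean expression."""
    n = len(mean_expr)
    order = np.argsort(mean_expr, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def score_signature(matrix: ExpressionMatrix, panel: GenePanel,
                    n_bins: int = 25, n_control: int = 50,
                    seed: int = 0) -> pd.Series:
    """Bin-matched control signature score, one value per cell.

    Panel symbols are matched case-insensitively; missing symbols are dropped
    with a warning, and a panel with no symbol present is rejected.
    """
    folded = {g.upper(): i for i, g in enumerate(matrix.gene_symbols)}
    present, missing = [], []
    for s in panel.symbols:
        (present if s.upper() in folded else missing).append(s)
    if not present:
        raise ValueError(
            f"no symbol of panel {panel.name!r} present in matrix: missing {missing}"
        )
    if missing:
        warnings.warn(f"panel {panel.name!r}: dropping absent symbols {missing}")

    panel_idx = np.array([folded[s.upper()] for s in present])
    mean_expr = matrix.values.mean(axis=0)
    bins = _expression_bins(mean_expr, n_bins)

    rng = np.random.default_rng(seed)
    panel_set = set(panel_idx.tolist())
    non_panel = np.array([i for i in range(matrix.n_genes) if i not in panel_set])
    if len(non_panel) == 0:
        raise ValueError("no control genes available outside the panel")
    control: set[int] = set()
    for gi in panel_idx:
        pool = np.flatnonzero(bins == bins[gi])
        pool = pool[~np.isin(pool, list(panel_set))]
        if len(pool) == 0:
            continue
        take = min(n_control, len(pool))
        control.update(rng.choice(pool, size=take, replace=False).tolist())
    if not control:
        # every panel gene sat alone in its bin (tiny matrices): fall back to
        # the whole non-panel background
        control = set(non_panel.tolist())

    ctrl_idx = np.fromiter(sorted(control), dtype=int)
    score = matrix.values[:, panel_idx].mean(axis=1) - matrix.values[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=matrix.cell_meta.index, name=panel.name)


def score_signatures(matrix: ExpressionMatrix, panels: list[GenePanel],
                     n_bins: int = 25, n_control: int = 50,
                     seed: int = 0) -> SignatureScoreTable:
    cols = {
        p.name: score_signature(matrix, p, n_bins=n_bins, n_control=n_control, seed=seed)
        for p in panels
    }
    return SignatureScoreTable(
        scores=pd.DataFrame(cols),
        control_config={"n_bins": n_bins, "n_control_genes": n_control, "seed": seed},
    )


def classify_states(scores: SignatureScoreTable, injury_panel: str = "injury_plasticity",
                    at2_panel: str = "at2") -> pd.Series:
    """Quadrant state call from injury and AT2 scores thresholded at 0.

    "High" means score strictly > 0 (scores are background-relative, so 0 is
    the natural null); all-zero scores therefore classify as double-low.
    """
    for name in (injury_panel, at2_panel):
        if name not in scores.scores.columns:
            raise KeyError(f"panel {name!r} not scored")
    inj = scores.scores[injury_panel].to_numpy() > 0
    at2 = scores.scores[at2_panel].to_numpy() > 0
    out = np.where(
        inj & ~at2, STATE_CLASSES[0],
        np.where(~inj & at2, STATE_CLASSES[1],
                 np.where(inj & at2, STATE_CLASSES[2], STATE_CLASSES[3])),
    )
    return pd.Series(out, index=scores.scores.index, name="state_class")


def state_class_counts(classes: pd.Series, meta: pd.DataFrame,
                       by: str = "timepoint",
                       labels: CommunityLabels | None = None) -> pd.DataFrame:
    """Class counts per metadata group (and per community if labels given)."""
    df = pd.DataFrame({"state_class": classes, by: meta[by]})
    if labels is not None:
        df["community"] = labels.assignment
        return df.groupby([by, "community", "state_class"], observed=True).size().rename("n").reset_index()
    return df.groupby([by, "state_class"], observed=True).size().rename("n").reset_index()
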