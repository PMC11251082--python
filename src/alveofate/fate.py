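"""Diffusion pseudotime and absorbing-Markov-chain fate probabilities.

A random walk on the cell-cell affinity graph, oriented so that steps never
decrease pseudotime, is absorbed by designated terminal cell sets.  The
absorption probabilities B solve the linear system of the absorbing chain,

    B = (I - Q)^(-1) R,

where Q is the transient-to-transient and R the transient-to-absorbing block
of the oriented, row-normalized transition matrix.  This reproduces the
stochastic-process contract of Palantir-style fate analysis while remaining
exactly solvable at desk scale (no waypoint subsampling).

Pseudotime is the graph-geodesic distance from the start anchor: shortest
paths through the kNN graph with edge lengths measured in the embedding,
anchored at the start-community cell farthest from the terminal sets, then
shifted/scaled so the start set sits at 0 and the farthest cell at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components

from .graph import NeighborGraph
from .states import CommunityLabels


@dataclass
class FateAnchors:
    """Start cells and named terminal cell sets (indices into the graph)."""

    start_cells: np.ndarray
    terminal_sets: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        self.start_cells = np.asarray(self.start_cells, dtype=int)
        self.terminal_sets = {k: np.asarray(v, dtype=int) for k, v in self.terminal_sets.items()}
        if len(self.start_cells) == 0:
            raise ValueError("start set is empty")
        names = list(self.terminal_sets)
        for name in names:
            if len(self.terminal_sets[name]) == 0:
                raise ValueError(f"terminal set {name!r} is empty")
        start = set(self.start_cells.tolist())
        for i, a in enumerate(names):
            sa = set(self.terminal_sets[a].tolist())
            if sa & start:
                raise ValueError(f"terminal set {a!r} overlaps the start set")
            for b in names[i + 1:]:
                sb = set(self.terminal_sets[b].tolist())
                if sa & sb:
                    raise ValueError(f"terminal sets {a!r} and {b!r} overlap")

    @property
    def fates(self) -> list[str]:
        return list(self.terminal_sets)

    def terminal_all(self) -> np.ndarray:
        return np.concatenate([v for v in self.terminal_sets.values()])


@dataclass
class FatePosterior:
    """Per-cell fate probabilities (rows sum to 1) and pseudotime in [0,1]."""

    probabilities: pd.DataFrame  # index = barcode, one column per fate
    pseudotime: pd.Series

    def __post_init__(self) -> None:
        p = self.probabilities.to_numpy()
        if p.size:
            if p.min() < -1e-8 or p.max() > 1 + 1e-8:
                raise ValueError("fate probabilities outside [0,1]")
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("fate probability rows must sum to 1 (+-1e-8)")


def anchors_from_communities(labels: CommunityLabels, start_community: int,
                             terminal_communities: Mapping[str, int]) -> FateAnchors:
    """Build anchors from community ids (fate label -> community id)."""
    return FateAnchors(
        start_cells=labels.members(start_community),
        terminal_sets={f: labels.members(c) for f, c in terminal_communities.items()},
    )


# ---------------------------------------------------------------------------
# pseudotime
# ---------------------------------------------------------------------------

def _check_reachable(graph: NeighborGraph, anchors: FateAnchors) -> None:
    n_comp, comp = connected_components(graph.affinity, directed=False)
    start_comp = set(comp[anchors.start_cells].tolist())
    for fate, cells in anchors.terminal_sets.items():
        bad = [int(c) for c in cells if comp[c] not in start_comp]
        if bad:
            raise ValueError(
                f"terminal cells unreachable from start set (fate {fate!r}): {bad}"
            )


def _metric_graph(graph: NeighborGraph) -> sp.csr_matrix:
    """Symmetric kNN graph weighted by embedding (Euclidean) edge lengths."""
    n = graph.n_cells
    rows = np.repeat(np.arange(n), graph.k)
    cols = graph.neighbors.ravel()
    d = graph.distances.ravel()
    D = sp.csr_matrix((d, (rows, cols)), shape=(n, n))
    return D.maximum(D.T)


def start_anchor(graph: NeighborGraph, anchors: FateAnchors) -> int:
    """The start-set cell geodesically farthest from the terminal sets.

    Anchoring at the far end of the start set (rather than its centre) makes
    pseudotime monotone across the whole start community.
    """
    from scipy.sparse.csgraph import dijkstra

    D = _metric_graph(graph)
    d_term = dijkstra(D, indices=anchors.terminal_all(), min_only=True,
                      directed=False)
    start = anchors.start_cells
    finite = np.isfinite(d_term[start])
    if not finite.any():
        return int(start[0])
    return int(start[finite][np.argmax(d_term[start][finite])])


def diffusion_pseudotime(graph: NeighborGraph, anchors: FateAnchors) -> np.ndarray:
    """Per-cell ordering distance from the start set, scaled to [0,1].

    Pseudotime is the shortest-path (geodesic) distance through the kNN graph
    from the start anchor, with edge lengths measured in the embedding; the
    minimum over start cells is shifted to 0 and the farthest cell to 1.
    Cells in components disconnected from the start are pinned to the maximum.
    """
    from scipy.sparse.csgraph import dijkstra

    _check_reachable(graph, anchors)
    D = _metric_graph(graph)
    root = start_anchor(graph, anchors)
    pt = dijkstra(D, indices=[root], min_only=True, directed=False)
    finite = np.isfinite(pt)
    pt[~finite] = pt[finite].max() if finite.any() else 0.0
    pt = pt - pt[anchors.start_cells].min()
    pt = np.maximum(pt, 0.0)
    m = pt.max()
    if m > 0:
        pt = pt / m
    return pt


# ---------------------------------------------------------------------------
# absorbing chain
# ---------------------------------------------------------------------------

def _oriented_transitions(graph: NeighborGraph, pseudotime: np.ndarray,
                          anchors: FateAnchors) -> sp.csr_matrix:
    """Affinity edges oriented toward non-decreasing pseudotime.

    Back-edges are removed (equal pseudotime keeps both directions);
    non-terminal cells left without an outgoing edge are reconnected to their
    nearest (embedding-distance) strictly-forward neighbor, or to the nearest
    terminal cell when none exists.  Terminal cells are absorbing.
    """
    n = graph.n_cells
    terminal = np.zeros(n, dtype=bool)
    terminal[anchors.terminal_all()] = True

    W = sp.triu(graph.affinity, k=1).tocoo()
    r, c, w = W.row, W.col, W.data
    fwd = pseudotime[c] >= pseudotime[r]   # i -> j allowed
    bwd = pseudotime[r] >= pseudotime[c]   # j -> i allowed (both kept at ties)
    P = sp.csr_matrix(
        (np.concatenate([w[fwd], w[bwd]]),
         (np.concatenate([r[fwd], c[bwd]]), np.concatenate([c[fwd], r[bwd]]))),
        shape=(n, n),
    )

    out_deg = np.asarray((P > 0).sum(axis=1)).ravel()
    sinks = np.flatnonzero((out_deg == 0) & ~terminal)
    if len(sinks):
        P = P.tolil()
        emb = graph.embedding
        term_idx = anchors.terminal_all()
        for i in sinks:
            forward = np.flatnonzero(pseudotime > pseudotime[i])
            cands = forward if len(forward) else term_idx
            cands = cands[cands != i]
            d = np.linalg.norm(emb[cands] - emb[i], axis=1)
            P[i, int(cands[np.argmin(d)])] = 1.0
        P = P.tocsr()

    # absorbing rows for terminal cells; row-normalize transient rows
    Pc = P.tocoo()
    keep = ~terminal[Pc.row]
    term_idx = np.flatnonzero(terminal)
    P = sp.csr_matrix(
        (np.concatenate([Pc.data[keep], np.ones(len(term_idx))]),
         (np.concatenate([Pc.row[keep], term_idx]),
          np.concatenate([Pc.col[keep], term_idx]))),
        shape=(n, n),
    )
    rs = np.asarray(P.sum(axis=1)).ravel()
    rs[rs == 0] = 1.0
    return (sp.diags(1.0 / rs) @ P).tocsr()


def absorption_probabilities(P: sp.spmatrix,
                             terminal_sets: Mapping[str, Sequence[int]]) -> np.ndarray:
    """Exact absorption probabilities of a Markov chain into terminal sets.

    ``P`` is a row-stochastic transition matrix whose terminal rows are
    absorbing (handled regardless); the solution is B = (I - Q)^(-1) R on the
    transient block.  Returns an ``(n, n_fates)`` array in the order of
    ``terminal_sets``.  Raises if a transient state cannot reach any terminal
    set (singular system), listing the offending states.
    """
    P = sp.csr_matrix(P, dtype=float)
    n = P.shape[0]
    fates = list(terminal_sets)
    terminal = np.zeros(n, dtype=bool)
    fate_of = np.full(n, -1, dtype=int)
    for fi, f in enumerate(fates):
        cells = np.asarray(terminal_sets[f], dtype=int)
        terminal[cells] = True
        fate_of[cells] = fi
    transient = np.flatnonzero(~terminal)

    B = np.zeros((n, len(fates)))
    for fi in range(len(fates)):
        B[fate_of == fi, fi] = 1.0

    if len(transient):
        from scipy.sparse.csgraph import dijkstra as _dijkstra

        hops = _dijkstra(P.T.tocsr(), indices=np.flatnonzero(terminal),
                         min_only=True, directed=True, unweighted=True)
        unreachable = [int(i) for i in transient if not np.isfinite(hops[i])]
        if unreachable:
            raise ValueError(
                f"isolated transient cells cannot reach any terminal set: {unreachable}"
            )
        Q = P[transient][:, transient].tocsc()
        R = np.zeros((len(transient), len(fates)))
        Pt = P[transient].tocsr()
        for fi, f in enumerate(fates):
            cols = np.asarray(terminal_sets[f], dtype=int)
            R[:, fi] = np.asarray(Pt[:, cols].sum(axis=1)).ravel()
        I = sp.identity(len(transient), format="csc")
        B_trans = spla.spsolve(I - Q, R)
        if B_trans.ndim == 1:
            B_trans = B_trans[:, None]
        B[transient] = B_trans

    # guard against round-off, then renormalize
    B = np.clip(B, 0.0, 1.0)
    return B / B.sum(axis=1, keepdims=True)


def fate_probabilities(graph: NeighborGraph, pseudotime: np.ndarray,
                       anchors: FateAnchors,
                       barcodes: Sequence[str] | None = None) -> FatePosterior:
    """Exact absorption probabilities of the pseudotime-oriented walk."""
    n = graph.n_cells
    pseudotime = np.asarray(pseudotime, dtype=float)
    P = _oriented_transitions(graph, pseudotime, anchors)
    B = absorption_probabilities(P, anchors.terminal_sets)
    idx = pd.Index(barcodes if barcodes is not None else range(n), name="barcode")
    return FatePosterior(
        probabilities=pd.DataFrame(B, index=idx, columns=anchors.fates),
        pseudotime=pd.Series(pseudotime, index=idx, name="pseudotime"),
    )


def community_fate_summary(posterior: FatePosterior, labels: CommunityLabels,
                           n_bins: int = 10) -> pd.DataFrame:
    """Per-community, per-fate mean probability and binned histogram.

    Returns a tidy frame: community, fate, mean, n_cells, and ``bin_0 ..
    bin_{n_bins-1}`` counts over [0,1].
    """
    if len(labels.assignment) != len(posterior.probabilities):
        raise ValueError("labels do not cover the posterior's cells")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    comm = labels.assignment.to_numpy()
    for c in range(labels.n_communities):
        mask = comm == c
        for fate in posterior.probabilities.columns:
            p = posterior.probabilities.loc[mask, fate].to_numpy()
            hist, _ = np.histogram(p, bins=edges)
            rows.append({
                "community": c,
                "fate": fate,
                "n_cells": int(mask.sum()),
                "mean_probability": float(p.mean()) if mask.any() else np.nan,
                **{f"bin_{i}": int(h) for i, h in enumerate(hist)},
            })
    return pd.DataFrame(rows)
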