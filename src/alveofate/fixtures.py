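"""Worked-example fixtures: toy matrices, toy chains, and seeded sim configs.

``make_fixtures`` writes every toy used by the derived-value tests into a
directory (by default the repository's ``fixtures/``), bit-exactly
reproducible, and re-runs any standalone oracle script found next to a toy so
the expected outputs stay in sync.  The oracle scripts are deliberately naive
(explicit loops, Monte-Carlo, enumeration) and never import this package.
"""

from __future__ import annotations

import json
import runpy
from pathlib import Path

import numpy as np

#: 15-node absorbing chain: a root (0) feeding two arms that drain into
#: terminal sets X = {12, 13} and Y = {14}; edge weights are hand-picked.
FATE_TOY_EDGES = [
    # node 0: root, splits 60/40
    (0, 1, 0.6), (0, 2, 0.4),
    # arm via 1 (mostly to X side)
    (1, 3, 0.5), (1, 4, 0.3), (1, 2, 0.2),
    (3, 5, 0.7), (3, 6, 0.3),
    (4, 6, 0.6), (4, 7, 0.4),
    (5, 8, 1.0),
    (6, 8, 0.5), (6, 9, 0.5),
    (8, 12, 0.8), (8, 10, 0.2),
    # arm via 2 (mostly to Y side)
    (2, 7, 0.6), (2, 9, 0.4),
    (7, 9, 0.3), (7, 11, 0.7),
    (9, 10, 0.5), (9, 11, 0.5),
    (10, 13, 0.6), (10, 14, 0.4),
    (11, 14, 0.9), (11, 10, 0.1),
]
FATE_TOY_TERMINALS = {"X": (12, 13), "Y": (14,)}

#: 4-cell imputation toy: 2-D coordinates and a 3-gene expression matrix
IMPUTE_TOY_COORDS = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.2), (2.2, 0.4)]
IMPUTE_TOY_EXPR = [
    (1.0, 0.0, 2.0),
    (2.0, 1.0, 1.0),
    (0.0, 3.0, 1.5),
    (4.0, 0.5, 0.0),
]

#: 10-cell QC toy: mito fractions 0.05 x6 and 0.25 x4; threshold 0.20 keeps 6
QC_TOY_ROWS = [(95, 5)] * 6 + [(75, 25)] * 4

DE_TOY_GROUPS = {"a": (1.0, 2.0, 3.0), "b": (10.0, 11.0, 12.0)}

SYMMETRIC_Y_CONFIG = {
    "kind": "branching",
    "branch_asymmetry": 0.5,
    "n_cells_per_timepoint": 500,
    "n_genes": 300,
    "seed": 0,
    "note": ("mirror-image branches: the generative fate of every root cell "
             "is 0.5 per branch by construction"),
}


def _write_fate_toy(d: Path) -> None:
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "transitions.tsv", "w") as fh:
        fh.write("from\tto\tprob\n")
        for i, j, p in FATE_TOY_EDGES:
            fh.write(f"{i}\t{j}\t{p}\n")
    with open(d / "terminals.tsv", "w") as fh:
        fh.write("fate\tnode\n")
        for fate, nodes in FATE_TOY_TERMINALS.items():
            for n in nodes:
                fh.write(f"{fate}\t{n}\n")


def _write_impute_toy(d: Path) -> None:
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "coords.tsv", "w") as fh:
        fh.write("cell\tx\ty\n")
        for i, (x, y) in enumerate(IMPUTE_TOY_COORDS):
            fh.write(f"c{i}\t{x}\t{y}\n")
    with open(d / "expr.tsv", "w") as fh:
        fh.write("cell\tg1\tg2\tg3\n")
        for i, row in enumerate(IMPUTE_TOY_EXPR):
            fh.write(f"c{i}\t" + "\t".join(str(v) for v in row) + "\n")


def _write_qc_toy(d: Path) -> None:
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "counts.tsv", "w") as fh:
        fh.write("cell\tGeneA\tmt-Sim1\n")
        for i, (a, m) in enumerate(QC_TOY_ROWS):
            fh.write(f"c{i}\t{a}\t{m}\n")


def _write_de_toy(d: Path) -> None:
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "groups.tsv", "w") as fh:
        fh.write("group\tvalue\n")
        for g, vals in DE_TOY_GROUPS.items():
            for v in vals:
                fh.write(f"{g}\t{v}\n")


def load_fate_toy() -> tuple[np.ndarray, dict[str, tuple[int, ...]]]:
    """The 15-node toy as a dense row-stochastic matrix + terminal sets."""
    n = 15
    P = np.zeros((n, n))
    for i, j, p in FATE_TOY_EDGES:
        P[i, j] = p
    for fate, nodes in FATE_TOY_TERMINALS.items():
        for t in nodes:
            P[t, t] = 1.0
    assert np.allclose(P.sum(axis=1), 1.0)
    return P, dict(FATE_TOY_TERMINALS)


def make_fixtures(outdir: str | Path = "fixtures",
                  run_oracles: bool = True) -> Path:
    """(Re)generate the fixture directory; oracle outputs refresh if present."""
    out = Path(outdir)
    _write_fate_toy(out / "fate_toy")
    _write_impute_toy(out / "impute_toy")
    _write_qc_toy(out / "qc_toy")
    _write_de_toy(out / "de_toy")
    (out / "symmetric_y.json").write_text(
        json.dumps(SYMMETRIC_Y_CONFIG, indent=2) + "\n")
    if run_oracles:
        for oracle in sorted(out.glob("*/oracle.py")):
            runpy.run_path(str(oracle), run_name="__main__")
    return out
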