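"""Naive matrix-power oracle for the 4-cell imputation toy.

Standalone: reads coords.tsv and expr.tsv from this directory, builds the
adaptive Gaussian kernel (k=2) with explicit loops, symmetrizes,
row-normalizes, applies the operator t=2 times, and writes
expected_imputed.tsv.  Run:  python oracle.py
"""

import math
from pathlib import Path

HERE = Path(__file__).parent
K = 2
T = 2


def read_tsv(path):
    rows = []
    with open(path) as fh:
        header = fh.readline().split()
        for line in fh:
            rows.append([float(x) for x in line.split()[1:]])
    return header[1:], rows


def main():
    _, coords = read_tsv(HERE / "coords.tsv")
    genes, expr = read_tsv(HERE / "expr.tsv")
    n = len(coords)

    dist = [[math.dist(coords[i], coords[j]) for j in range(n)] for i in range(n)]
    kernel = [[0.0] * n for _ in range(n)]
    for i in range(n):
        others = sorted((dist[i][j], j) for j in range(n) if j != i)
        knn = others[:K]
        sigma = knn[-1][0]
        for d, j in knn:
            kernel[i][j] = math.exp(-(d * d) / (sigma * sigma))

    sym = [[(kernel[i][j] + kernel[j][i]) / 2 for j in range(n)] for i in range(n)]
    markov = [[sym[i][j] / sum(sym[i]) for j in range(n)] for i in range(n)]

    out = [row[:] for row in expr]
    for _ in range(T):
        nxt = [[sum(markov[i][l] * out[l][g] for l in range(n))
                for g in range(len(genes))] for i in range(n)]
        out = nxt

    with open(HERE / "expected_imputed.tsv", "w") as fh:
        fh.write("cell\t" + "\t".join(genes) + "\n")
        for i, row in enumerate(out):
            fh.write(f"c{i}\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


if __name__ == "__main__":
    main()
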