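"""Monte-Carlo random-walk oracle for the 15-node absorbing-chain toy.

Standalone: reads transitions.tsv (from to prob) and terminals.tsv
(fate node) from this directory, runs 10^5 random walks from every
non-terminal node, and writes expected_absorption.tsv with the empirical
absorption frequencies and their standard errors.  Run:  python oracle.py
"""

import random
from pathlib import Path

HERE = Path(__file__).parent
N_WALKS = 100_000
SEED = 20240516


def main():
    edges = {}
    with open(HERE / "transitions.tsv") as fh:
        fh.readline()
        for line in fh:
            i, j, p = line.split()
            edges.setdefault(int(i), []).append((int(j), float(p)))

    fate_of = {}
    with open(HERE / "terminals.tsv") as fh:
        fh.readline()
        for line in fh:
            fate, node = line.split()
            fate_of[int(node)] = fate
    fates = sorted(set(fate_of.values()))

    nodes = sorted(edges)
    rng = random.Random(SEED)
    with open(HERE / "expected_absorption.tsv", "w") as fh:
        fh.write("node\t" + "\t".join(fates) + "\t" + "\t".join(f"se_{f}" for f in fates) + "\n")
        for start in nodes:
            if start in fate_of:
                continue
            counts = {f: 0 for f in fates}
            for _ in range(N_WALKS):
                node = start
                while node not in fate_of:
                    targets, probs = zip(*edges[node])
                    node = rng.choices(targets, weights=probs)[0]
                counts[fate_of[node]] += 1
            freqs = [counts[f] / N_WALKS for f in fates]
            ses = [(p * (1 - p) / N_WALKS) ** 0.5 for p in freqs]
            fh.write(f"{start}\t" + "\t".join(f"{p:.6f}" for p in freqs)
                     + "\t" + "\t".join(f"{s:.6f}" for s in ses) + "\n")


if __name__ == "__main__":
    main()
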