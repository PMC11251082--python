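"""Exact-enumeration oracle for the two-sample rank-sum toy.

Enumerates all C(6,3) = 20 assignments of the pooled ranks of
{1,2,3} vs {10,11,12} and writes the exact two-sided p-value of the observed
rank-sum to expected_p.txt.  Run:  python oracle.py
"""

from itertools import combinations
from pathlib import Path

HERE = Path(__file__).parent
A = [1.0, 2.0, 3.0]
B = [10.0, 11.0, 12.0]


def main():
    pooled = sorted(A + B)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # no ties here
    observed = sum(ranks[v] for v in A)
    mean_rank_sum = len(A) * (len(pooled) + 1) / 2

    splits = list(combinations(range(len(pooled)), len(A)))
    obs_dev = abs(observed - mean_rank_sum)
    extreme = sum(
        1 for c in splits
        if abs(sum(i + 1 for i in c) - mean_rank_sum) >= obs_dev - 1e-12
    )
    p = extreme / len(splits)
    (HERE / "expected_p.txt").write_text(f"{p:.12g}\n")


if __name__ == "__main__":
    main()
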