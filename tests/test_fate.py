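"""Pseudotime and absorbing-Markov fate probabilities."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from alveofate import (
    FateAnchors,
    absorption_probabilities,
    community_fate_summary,
    diffusion_pseudotime,
    fate_probabilities,
    knn_graph,
)
from alveofate.fixtures import load_fate_toy
from alveofate.states import CommunityLabels


def line_graph(n=10, k=2):
    pts = np.arange(n, dtype=float)[:, None]
    return knn_graph(pts, k)


class TestAnchors:
    def test_terminal_sets_must_be_disjoint(self):
        with pytest.raises(ValueError, match="overlap"):
            FateAnchors(start_cells=[0], terminal_sets={"a": [5], "b": [5, 6]})
        with pytest.raises(ValueError, match="start"):
            FateAnchors(start_cells=[3], terminal_sets={"a": [3]})
        with pytest.raises(ValueError, match="empty"):
            FateAnchors(start_cells=[], terminal_sets={"a": [1]})


class TestPseudotime:
    def test_start_cells_at_zero(self):
        g = line_graph()
        anchors = FateAnchors(start_cells=[0], terminal_sets={"end": [9]})
        pt = diffusion_pseudotime(g, anchors)
        assert pt[0] == 0.0
        assert pt.max() == pytest.approx(1.0)

    def test_path_graph_monotone_in_hop_index(self):
        g = line_graph(10, 2)
        anchors = FateAnchors(start_cells=[0], terminal_sets={"end": [9]})
        pt = diffusion_pseudotime(g, anchors)
        assert (np.diff(pt) > 0).all()

    def test_unreachable_terminal_rejected_by_name(self):
        # two separated clusters: terminal in the far component
        pts = np.vstack([np.random.default_rng(0).normal(0, 0.1, (5, 2)),
                         np.random.default_rng(1).normal(100, 0.1, (5, 2))])
        g = knn_graph(pts, 2)
        anchors = FateAnchors(start_cells=[0], terminal_sets={"far": [9]})
        with pytest.raises(ValueError, match="9"):
            diffusion_pseudotime(g, anchors)

    def test_recovers_latent_ordering_on_branching_data(
            self, symmetric_branching_result):
        """Rank correlation with the generative latent position > 0.9."""
        res = symmetric_branching_result
        u = res["norm"].cell_meta.latent_time.to_numpy()
        rho = spearmanr(res["pseudotime"], u).statistic
        assert rho > 0.9


class TestAbsorption:
    def test_terminal_cell_has_probability_one_for_own_fate(self):
        P, terms = load_fate_toy()
        B = absorption_probabilities(P, terms)
        assert B[12].tolist() == [1.0, 0.0]
        assert B[14].tolist() == [0.0, 1.0]

    def test_linear_chain_single_fate(self):
        g = line_graph(6, 1)
        anchors = FateAnchors(start_cells=[0], terminal_sets={"end": [5]})
        pt = np.arange(6, dtype=float)
        post = fate_probabilities(g, pt, anchors)
        np.testing.assert_allclose(post.probabilities["end"], 1.0)

    def test_mirror_image_y_graph_exactly_half(self):
        """Exact 0.5 per fate at the root of a mirror-symmetric Y."""
        coords = np.array([[0, 0], [1, 1], [2, 1], [3, 1],
                           [1, -1], [2, -1], [3, -1]], dtype=float)
        g = knn_graph(coords, 2)
        pt = coords[:, 0].copy()
        anchors = FateAnchors(start_cells=[0], terminal_sets={"A": [3], "B": [6]})
        post = fate_probabilities(g, pt, anchors)
        assert post.probabilities.iloc[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_toy_matches_committed_random_walk_oracle(self, fixtures_dir):
        """15-node toy: linear-system solution vs 10^5 Monte-Carlo walks."""
        P, terms = load_fate_toy()
        B = absorption_probabilities(P, terms)
        exp = pd.read_csv(fixtures_dir / "fate_toy" / "expected_absorption.tsv",
                          sep="\t", index_col=0)
        for node in exp.index:
            for fi, fate in enumerate(terms):
                se = max(exp.loc[node, f"se_{fate}"], 1e-6)
                assert abs(B[node, fi] - exp.loc[node, fate]) < 3 * se

    def test_random_chain_matches_inline_monte_carlo(self):
        """Random 25-node forward chain vs an inline random-walk oracle."""
        rng = np.random.default_rng(77)
        n, terminals = 25, {"X": [22, 23], "Y": [24]}
        P = np.zeros((n, n))
        for i in range(22):
            targets = rng.choice(np.arange(i + 1, n), size=min(3, n - i - 1),
                                 replace=False)
            w = rng.random(len(targets))
            P[i, targets] = w / w.sum()
        for t in (22, 23, 24):
            P[t, t] = 1.0
        B = absorption_probabilities(P, terminals)

        n_walks = 20_000
        wrng = np.random.default_rng(88)
        for start in (0, 5, 10):
            hits = 0
            for _ in range(n_walks):
                node = start
                while node < 22:
                    node = wrng.choice(n, p=P[node])
                hits += node in (22, 23)
            p_mc = hits / n_walks
            se = np.sqrt(max(p_mc * (1 - p_mc), 1e-6) / n_walks)
            assert abs(B[start, 0] - p_mc) < 3 * se

    def test_singular_transient_block_rejected(self):
        # 0 <-> 1 closed loop that never reaches the terminal 2
        P = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1.0]])
        with pytest.raises(ValueError, match="cannot reach"):
            absorption_probabilities(P, {"t": [2]})

    def test_posterior_rows_sum_to_one(self, symmetric_branching_result):
        p = symmetric_branching_result["posterior"].probabilities.to_numpy()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-8)
        assert p.min() >= 0 and p.max() <= 1


class TestBranchRecovery:
    def test_monotone_commitment_along_pseudotime(self, asymmetric_branching_result):
        """Mean fate probability toward a branch rises along that branch."""
        res = asymmetric_branching_result
        meta = res["norm"].cell_meta
        on_a = (meta.latent_branch == "A").to_numpy()
        pt = res["pseudotime"][on_a]
        fate_a_col = res["posterior"].probabilities.columns[0]  # at1 = branch A tip
        p = res["posterior"].probabilities[fate_a_col].to_numpy()[on_a]
        bins = np.quantile(pt, np.linspace(0, 1, 6))
        means = [p[(pt >= lo) & (pt <= hi)].mean()
                 for lo, hi in zip(bins[:-1], bins[1:])]
        assert all(b >= a - 0.05 for a, b in zip(means[:-1], means[1:]))
        assert means[-1] > means[0]

    def test_root_community_recovers_branch_asymmetry(
            self, asymmetric_branching_result):
        """Root-community mean fate recovers the generative 0.7 within 0.1."""
        res = asymmetric_branching_result
        p_at1 = res["root_mean_fate"]["at1"]  # branch A carries the AT1 program
        assert abs(p_at1 - 0.7) <= 0.1


class TestSummary:
    def test_terminal_community_degenerate_histogram(self):
        P, terms = load_fate_toy()
        B = absorption_probabilities(P, terms)
        post_df = pd.DataFrame(B, columns=list(terms))
        post = type("P", (), {"probabilities": post_df})()
        labels = CommunityLabels(
            assignment=pd.Series([0] * 12 + [1, 1, 2]), resolution=1.0, seed=0)
        summary = community_fate_summary(post, labels, n_bins=5)
        row = summary[(summary.community == 1) & (summary.fate == "X")].iloc[0]
        assert row["bin_4"] == 2 and row["mean_probability"] == 1.0

    def test_symmetric_root_community_mean_half(self, symmetric_branching_result):
        res = symmetric_branching_result
        summary = community_fate_summary(res["posterior"], res["labels"])
        root = summary[summary.community == res["start_community"]]
        for _, row in root.iterrows():
            assert row["mean_probability"] == pytest.approx(0.5, abs=0.1)
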