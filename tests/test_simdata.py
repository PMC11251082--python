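"""Generator tests: determinism, count law, trajectory and trio structure."""

import numpy as np
import pytest
from scipy import stats

from alveofate import (
    CONSERVED_RECEPTOR_PANEL,
    SimConfig,
    StateProgram,
    generate_branching,
    generate_conserved_receptor_trio,
    generate_timecourse,
)

SMALL = dict(n_cells_per_timepoint=50, n_genes=100)


def one_state_programs(marker_means):
    return [StateProgram("solo", marker_means,
                         {tp: 1.0 for tp in ("Day4", "Day7", "Day10", "Day14")})]


class TestTimecourse:
    def test_bit_identical_under_seed(self):
        cfg = SimConfig(seed=7, **SMALL)
        a, b = generate_timecourse(cfg), generate_timecourse(cfg)
        assert np.array_equal(a.counts, b.counts)
        assert a.cell_meta.equals(b.cell_meta)
        assert (generate_timecourse(SimConfig(seed=8, **SMALL)).counts != a.counts).any()

    def test_weights_must_sum_to_one(self):
        bad = [StateProgram("s", {"Cldn4": 5.0}, {"Day4": 0.5, "Day7": 1.0,
                                                  "Day10": 1.0, "Day14": 1.0})]
        with pytest.raises(ValueError, match="sum to"):
            generate_timecourse(SimConfig(seed=0, **SMALL), bad)

    def test_unknown_program_symbol_named_in_error(self):
        cfg = SimConfig(seed=0, gene_symbols=("GeneA", "GeneB"), **SMALL)
        with pytest.raises(ValueError, match="Nonexistent1"):
            generate_timecourse(cfg, one_state_programs({"Nonexistent1": 3.0}))

    @pytest.mark.parametrize("dispersion", [np.inf, 2.0])
    def test_zero_marker_mean_silences_gene(self, dispersion):
        cfg = SimConfig(seed=3, nb_dispersion=dispersion, **SMALL)
        data = generate_timecourse(cfg, one_state_programs({"Cldn4": 0.0}))
        gi = data.gene_symbols.index("Cldn4")
        assert (data.counts[:, gi] == 0).all()

    def test_injury_program_absent_at_late_timepoints(self):
        # transient injury state: weighted 1.0 at Day 4 and 0 afterwards
        programs = [
            StateProgram("injury", {"Cldn4": 10.0},
                         {"Day4": 1.0, "Day7": 0.0, "Day10": 0.0, "Day14": 0.0}),
            StateProgram("at2", {"Etv5": 10.0},
                         {"Day4": 0.0, "Day7": 1.0, "Day10": 1.0, "Day14": 1.0}),
        ]
        data = generate_timecourse(SimConfig(seed=5, **SMALL), programs)
        meta = data.cell_meta
        assert (meta.loc[meta.timepoint == "Day14", "true_state"] != "injury").all()
        assert (meta.loc[meta.timepoint == "Day4", "true_state"] == "injury").all()

    def test_marker_mean_matches_monte_carlo_oracle(self):
        """Empirical marker mean within 3 SE of a naive 10x-replicate oracle.

        The oracle re-implements the generative law (log-normal library times
        normalized relative means, gamma-Poisson counts) with plain loops and
        its own rng, for one single-state configuration.
        """
        marker, mean = "Cldn4", 12.0
        cfg = SimConfig(n_cells_per_timepoint=125, n_genes=100, seed=42)
        data = generate_timecourse(cfg, one_state_programs({marker: mean}))
        gi = data.gene_symbols.index(marker)
        observed = data.counts[:, gi].mean()

        # oracle: same generative law (random gene baselines, library,
        # per-cell program activity, gamma-Poisson), independent
        # implementation and rng; each replicate redraws the baselines so the
        # replicate spread is the SE of one full realization
        rng = np.random.default_rng(987_654)
        n_nuclear = sum(1 for s in data.gene_symbols if not s.startswith("mt-"))
        mu_log = np.log(cfg.library_size_mean) - cfg.library_size_sigma**2 / 2
        sig = cfg.program_activity_sigma
        rep_means = []
        for _ in range(12):
            base = rng.lognormal(0.0, 1.0, n_nuclear)
            base[0] = 1.0  # the program gene's fixed off-state baseline
            other_sum = base[1:].sum()
            vals = []
            for _ in range(500):
                lib = rng.lognormal(mu_log, cfg.library_size_sigma)
                activity = rng.lognormal(-sig**2 / 2, sig)
                rho = activity * mean / (activity * mean + other_sum)
                lam = rng.gamma(cfg.nb_dispersion, lib * rho / cfg.nb_dispersion)
                vals.append(rng.poisson(lam))
            rep_means.append(np.mean(vals))
        spread = np.std(rep_means, ddof=1)  # SE of a single 500-cell realization
        assert abs(observed - np.mean(rep_means)) < 3 * spread

    def test_negative_binomial_overdispersion(self):
        """Within-state per-gene variance exceeds the mean at finite dispersion."""
        cfg = SimConfig(n_cells_per_timepoint=300, n_genes=60, seed=11,
                        nb_dispersion=5.0)
        data = generate_timecourse(cfg, one_state_programs({"Cldn4": 10.0}))
        assert data.n_cells >= 1000
        counts = data.counts[:, ~data.mito_mask()]
        means = counts.mean(axis=0)
        variances = counts.var(axis=0)
        high = means > 5  # genes with enough signal for a stable estimate
        assert (variances[high] > means[high]).all()

    def test_true_state_labels_come_from_programs(self, wt_timecourse):
        assert set(wt_timecourse.cell_meta.true_state) <= {
            "plastic", "AT1_intermediate", "AT2_intermediate", "AT1", "AT2",
        }

    def test_mito_fractions_realised(self, wt_timecourse):
        realised = wt_timecourse.mito_fractions()
        target = wt_timecourse.cell_meta.mito_fraction.to_numpy()
        assert np.abs(realised - target).mean() < 0.01


class TestBranching:
    def test_full_asymmetry_puts_all_cells_on_branch_a(self):
        data = generate_branching(SimConfig(seed=2, **SMALL), branch_asymmetry=1.0)
        post = data.cell_meta[data.cell_meta.latent_branch != "root"]
        assert (post.latent_branch == "A").all()

    def test_asymmetric_branch_fraction_in_binomial_ci(self):
        """Branch-A fraction at asymmetry 0.7 falls in the closed-form 99% CI."""
        data = generate_branching(SimConfig(seed=9, n_cells_per_timepoint=500),
                                  branch_asymmetry=0.7)
        post = data.cell_meta[data.cell_meta.latent_branch != "root"]
        n = len(post)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.7)
        assert lo <= (post.latent_branch == "A").sum() <= hi

    def test_latent_ground_truth_recorded(self):
        data = generate_branching(SimConfig(seed=2, **SMALL), 0.5)
        meta = data.cell_meta
        assert {"latent_branch", "latent_time"} <= set(meta.columns)
        assert meta.latent_time.between(0, 1).all()
        # symmetric generative fate: root cells precede the branch point
        assert (meta.loc[meta.latent_branch == "root", "latent_time"] < 0.25).all()

    def test_asymmetry_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            generate_branching(SimConfig(seed=0, **SMALL), branch_asymmetry=1.2)


class TestReceptorTrio:
    def test_decoys_disjoint_and_symbol_cases(self):
        trio = generate_conserved_receptor_trio(
            SimConfig(seed=4, n_cells_per_timepoint=40, n_genes=120),
            CONSERVED_RECEPTOR_PANEL.symbols, decoys_per_dataset=10,
        )
        d0, d1, d2 = trio.decoys_by_dataset
        assert not (set(d0) & set(d1) or set(d0) & set(d2) or set(d1) & set(d2))
        shared = set(trio.shared_receptors)
        assert not any(shared & set(d) for d in trio.decoys_by_dataset)
        human = trio.datasets[2]
        assert all(s == s.upper() for s in human.gene_symbols)
        mouse = trio.datasets[0]
        assert any(s != s.upper() for s in mouse.gene_symbols)

    def test_overlapping_decoys_rejected(self):
        cfg = SimConfig(seed=4, n_cells_per_timepoint=40, n_genes=120)
        with pytest.raises(ValueError, match="overlap"):
            generate_conserved_receptor_trio(
                cfg, ("ITGA3",), decoys=[("Egfr",), ("Egfr",), ("Met",)]
            )
        with pytest.raises(ValueError, match="shared"):
            generate_conserved_receptor_trio(
                cfg, ("ITGA3",), decoys=[("Itga3",), ("Egfr",), ("Met",)]
            )

    def test_shared_receptors_upshifted_in_kras_cells(self):
        trio = generate_conserved_receptor_trio(
            SimConfig(seed=6, n_cells_per_timepoint=150, n_genes=150),
            CONSERVED_RECEPTOR_PANEL.symbols, decoys_per_dataset=5,
        )
        for ds in trio.datasets:
            folded = {s.upper(): i for i, s in enumerate(ds.gene_symbols)}
            kras = (ds.cell_meta.genotype == "KRAS").to_numpy()
            for r in trio.shared_receptors:
                gi = folded[r]
                assert ds.counts[kras, gi].mean() > 1.5 * ds.counts[~kras, gi].mean()
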