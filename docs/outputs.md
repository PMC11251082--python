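# From pipeline outputs to published-figure-style readouts

Each table the pipeline writes corresponds to a standard readout of temporal
AT2-state studies. All commands below accept `--seed`; outputs land in the
run directory and are byte-reproducible.

| readout | command | output |
|---|---|---|
| Per-community AT1/AT2 signature-score distributions (violin-style) | `alveofate run-all --outdir out/` | `signature_scores.tsv` + `communities.tsv` (join on barcode) |
| Per-community fate-probability histograms from the plasticity state | `alveofate fate-demo --seed 1` or `run-all` | `community_fate_summary.tsv` (`bin_0..bin_9` columns per community × fate) |
| Injury/plasticity-vs-AT2 state calls per community and time point | `run-all` | `state_classes.tsv`, `state_class_counts.tsv` |
| Conserved-receptor identification across three datasets | `alveofate conserve --seed 1 --outdir out/` | `conserved_receptors.json` (per-dataset hits + intersection) |
| Relative receptor expression by community (heatmap-style) | `alveofate.conservation.receptor_expression_summary` | tidy gene × community table |
| Double-positive (e.g. Itga3⁺Src⁺) fraction per community | `alveofate.conservation.double_positive_fraction` | community / n_cells / fraction table |
| Receptor–injury-signature correlation | `alveofate.conservation.signature_gene_correlation` | Spearman rho + p |
| Two-group organoid-size comparison (rank-sum) | `alveofate.diffexp.compare_groups` | statistic + p-value |

The committed toys under `fixtures/` back the derived-value tests:

* `impute_toy/` — 4-cell imputation toy with its naive matrix-power oracle
  (`oracle.py`) and committed output.
* `fate_toy/` — 15-node absorbing chain with a 10⁵-walk Monte-Carlo oracle
  and committed absorption frequencies.
* `qc_toy/` — 10 cells at mito fractions {0.05×6, 0.25×4}; the 0.20 filter
  keeps exactly 6.
* `de_toy/` — {1,2,3} vs {10,11,12} with the exact-enumeration oracle
  (p = 0.1).
* `symmetric_y.json` — the seeded symmetric-branching configuration; the
  generative fate of every root cell is 0.5 per branch by construction.

Every oracle script runs standalone (`python fixtures/<toy>/oracle.py`) and
never imports the package; `alveofate.fixtures.make_fixtures()` regenerates
the directory bit-exactly and refreshes the oracle outputs.
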