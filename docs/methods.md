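# Methods

This note documents the models and procedures implemented in `alveofate`,
the defaults they ship with, and the reasoning behind the choices that were
genuinely open.

## Synthetic data model

### Count law

Every cell's nuclear gene counts follow a gamma–Poisson (negative binomial)
law. A cell in state *s* with library size *L* has expected counts
`mu_g = L * rho_g`, where `rho` is the state's relative-expression vector
normalized to sum to 1, and observed counts

```
lambda_g ~ Gamma(shape = r, scale = mu_g / r),   count_g ~ Poisson(lambda_g)
```

with a single dispersion (NB size) parameter `r = nb_dispersion`. `r → ∞`
recovers the Poisson limit; the default `r = 20` gives the mild per-gene
overdispersion (biological coefficient of variation ≈ `1/sqrt(r)` ≈ 0.22)
typical of UMI counts from a transcriptionally homogeneous population.
Library sizes are log-normal with mean `library_size_mean` (default 20,000
counts/cell, a realistic droplet-platform depth) and log-scale sd 0.35 —
this depth variation is exactly what total-count normalization must remove.

Relative expression combines a per-gene baseline with state programs.
Baselines are log-normal across genes (log-sd 1), **except that any gene
named by a state program gets a fixed off-state baseline of 1.0**. Marker
genes have a defined resting level, and — more importantly for the branching
benchmark — the fixed off-state keeps the two trajectory branches
geometrically exchangeable: with random baselines the branch whose marker
genes happened to draw larger baselines started "closer" to the root in
expression space, which biased the symmetric fate split by up to ±0.17
across seeds.

### State programs and per-cell activity

A `StateProgram` overrides baselines for its marker genes (a mean of 0
silences the gene) and carries per-time-point sampling weights that must sum
to 1 across the states of a genotype at each time point. The bundled design
emulates a four-time-point (Day 4/7/10/14) organoid course:

* **WT** — a single injury/plasticity state at Day 4 (15 genes: the core
  injury panel plus the DATP/IFN-γ/primed-AT2 sub-signature genes, means
  10–20 relative units) resolving through AT1/AT2 intermediates into AT1 and
  AT2 terminal states at Day 14 (9 magnitude-balanced marker genes each, all
  at 20).
* **KRAS** — the plastic state is retained at every time point and
  additionally expresses the conserved receptor set (Itga3, Src, Ocln,
  Adipor1, Plxnb2, St14, Itgb1, Lsr at 10–14); an AT2-high subpopulation
  appears only at Day 10 (20%) and Day 14 (40%).

Each cell draws a log-normal **program activity** multiplier (log-sd 0.25,
mean 1) applied to all of its state's marker genes jointly. States are
distributions rather than points, and co-programmed genes rise and fall
together within a state — without this, within-state variation is purely
compositional (a cell that happens to sample more injury counts has
proportionally fewer counts left for everything else after normalization),
which produces a spurious *negative* rank correlation between a receptor and
the signature it is programmed with.

### Branching trajectory

`generate_branching` places each cell at a latent time `u` uniform within
its time point's quarter of [0, 1]. Cells with `u < 0.25` lie on the root
segment; later cells join branch A with probability `branch_asymmetry`
(0.5 = symmetric). Expression means interpolate linearly: injury-high root
program → attenuated junction program (0.2×) → AT1 (branch A) or AT2
(branch B) tip program. The tip programs are magnitude-balanced (equal gene
count and level) so both branches traverse expression space at the same
speed. `latent_branch` and `latent_time` are stored as ground truth.

### Mitochondrial content

Mitochondrial genes carry the `mt-` prefix and are filled in *after* nuclear
sampling so that each cell's realised mito fraction matches a sampled target
(normal per state, default mean 0.05, sd 0.02, clipped to [0, 0.95]):
`mito_total = round(T·f/(1−f))` distributed multinomially over the mito
genes. QC therefore sees exactly the artefact it filters.

### Conserved-receptor trio

Three early-stage datasets (tags `organoid`, `invivo`, `human`), each with
WT and KRAS cells. The shared receptor set is up-shifted ×3 in KRAS cells of
*all three*; each decoy receptor (drawn disjointly from the bundled receptor
panel) is up-shifted in exactly one. Two datasets use mouse-case symbols,
the third uppercase human-case, so the downstream intersection must
case-harmonize. All receptor-panel genes take the fixed 1.0 baseline, giving
every receptor comparable detection power.

### What the generator does not emulate

No doublets, no ambient RNA, no batch effects, no mesenchymal compartment,
no gene–gene correlation beyond the shared program-activity factor, and no
dropout model beyond what the NB law implies. Passing tests demonstrate that
the pipeline's inference machinery recovers known truth under the stated
noise model — not that it is robust to the full artefact spectrum of real
droplet data.

## Pipeline stages

### QC and normalization

Cells with mitochondrial fraction strictly greater than the threshold are
removed (0.20 for organoid/human-style data, 0.10 for in vivo-style data;
the comparison is strict so threshold-exact cells survive). An optional
minimum-total-count filter ships disabled. Normalization scales each cell to
`target_sum` (default 10,000 — the field-standard depth, as no particular
value is canonical) and applies natural `log(1+x)`. Zero-total cells cannot
be scaled and are dropped with a warning. After normalization,
`expm1(values)` row-sums equal `target_sum` to within 1e-6 relative.

### Embedding, kNN graph, imputation

PCA is a centered full SVD (deterministic); component variances are
non-increasing by construction. The kNN graph uses exact all-pairs Euclidean
search (the package targets desk-scale data; no approximate index), with
ties broken deterministically toward the lower cell index. Affinities use
the adaptive Gaussian kernel `exp(−d²/σᵢ²)` with `σᵢ` the distance to the
k-th neighbour, symmetrized as `(K + Kᵀ)/2`; self-loops are excluded before
symmetrization. Row-normalizing yields the Markov operator `M` (row sums 1
within 1e-10; fully disconnected cells get a self-transition of 1), and
imputation returns `Mᵗ X` for all genes with defaults `k=5, t=5, n_pca=30`.
Because `M` is row-stochastic, imputation preserves constants, never expands
a gene's range, and `t=0` is the identity.

Imputed values feed **signature scoring and co-expression calls only**.
Differential expression runs on non-imputed normalized values (diffusion
sharing makes rank tests anti-conservative), and the neighbour graph used
for clustering and pseudotime is likewise built on the *non-imputed* PCA
embedding: strong diffusion collapses trajectory branches into thin
filaments in which a walker's branch choice at the junction no longer
reflects branch cell density, which destabilizes fate probabilities.

### Communities and signature scores

Leiden community detection runs on the symmetrized affinity graph
(RB-configuration modularity, resolution default 1.0, seeded, iterated to a
local optimum). Signature scores use the bin-matched control construction:
genes are ranked by mean expression and cut into 25 equal-size bins; for
each panel gene, 50 control genes are sampled (seeded) from its bin,
excluding panel genes; the score is the panel mean minus the control-union
mean per cell. If every panel gene sits alone in its bin (tiny matrices) the
whole non-panel background serves as control. Scores are invariant to adding
a per-cell constant, and 0 means "indistinguishable from background", so
state classification thresholds both the injury/plasticity and AT2 scores at
0 (strictly positive = high; all-zero scores classify double-low). Panel
symbol matching is case-insensitive throughout (mouse `Itga3` ≡ human
`ITGA3`).

### Pseudotime and fate probabilities

Pseudotime is the geodesic (shortest-path) distance from the start anchor
through the kNN graph, with edge lengths measured in the embedding, shifted
so the start set's minimum is 0 and scaled so the farthest cell is 1. The
start anchor is the start-community cell geodesically farthest from the
terminal sets. Two alternatives were evaluated and rejected during design:
Euclidean distance in multiscale diffusion components ordered branch cells
measurably worse than the geodesic on synthetic benchmarks, and anchoring at
the start-community medoid put the pseudotime origin mid-community, making
the ordering V-shaped over the earliest cells.

The fate chain is built on a *dense* adaptive Gaussian kernel
(`exp(−d²/(σᵢσⱼ))`, bandwidth 2× the k-th-neighbour distance, weights below
1e-4 dropped) rather than the hard kNN edge set: at a branch point the
relevant quantity is the local cell-density mass of each branch, and a
k-edge cut is dominated by the identity of a handful of nearest neighbours.
The bandwidth factor was chosen by a design sweep (1× tracked small-sample
density fluctuations; 3× began to over-smooth).

Edges are oriented toward non-decreasing pseudotime; exact ties keep both
directions. Terminal cells (the latest-time-point members of each terminal
community) are made absorbing; non-terminal cells left without an outgoing
edge are reconnected to their nearest strictly-forward neighbour (or nearest
terminal cell if none exists). Absorption probabilities solve the linear
system `B = (I − Q)⁻¹ R` exactly — no waypoint subsampling, desk scale
permits the full solve. A transient block with no path to any terminal set
is reported as an error listing the offending cells. Posterior rows sum to 1
within 1e-8 after a round-off clip-and-renormalize.

Start and terminal communities can be given explicitly or selected
automatically: the start community holds the largest number of
earliest-time-point cells; terminal candidates hold ≥10% of all
latest-time-point cells, and the candidate whose late cells score highest on
each fate panel (AT1, AT2) becomes that fate's terminal community.

### Differential expression and filters

Per gene, a two-sided Wilcoxon rank-sum (Mann–Whitney U) compares group vs
reference on normalized log values — exact null for tiny untied samples,
tie-corrected normal approximation otherwise — with Benjamini–Hochberg
adjustment across genes. `log2FC = log2((mean_in+ε)/(mean_out+ε))` on
`expm1`-scale means with ε = 1e-9. Panel filters apply strict thresholds
(`p < p_max`, `|log2FC| > lfc_min` in the stated direction) against raw p by
default — the printed cutoffs do not specify adjustment — with
`use_adjusted` as a switch. `compare_groups` applies the same test to raw
measurements (e.g. organoid diameters in µm); two fully tied samples return
p = 1.0.

### Conservation and co-expression

Receptor hit sets are harmonized by case-folded symbol equality only (the
comparisons are symbol-level; no homology database) and intersected exactly.
The double-positive fraction counts cells with both genes strictly above 0
in relative (imputed by default) expression, per community.
Signature–gene association uses Spearman rank correlation for robustness to
expression skew; a constant gene or score yields an undefined correlation,
reported as NaN.

## Reproducibility machinery

One global seed derives all stage seeds via `SeedSequence` (each below
2³¹). Pipeline outputs are TSV/MTX/JSON with fixed float formatting, so a
rerun under the same config and seed is byte-identical; the manifest records
per-stage parameters and SHA-256 hashes of every output file.

## Benchmark problem sizes

The branching fate benchmark uses 500 cells per time point (~2000 total),
300 genes, `k=15`, 30 PCs; the conserved-receptor benchmark uses 150 cells
per genotype per dataset, 250 genes, and 20 decoys per dataset over 20
seeded replicates. These sizes preserve the statistical structure of the
full-scale analyses at a scale a laptop solves exactly.

## Known limitations

* Exact kNN and the dense fate kernel are O(n²) memory/time — appropriate
  up to tens of thousands of cells, not hundreds of thousands.
* Automatic terminal selection assumes each terminal fate dominates a
  distinct late-time-point community; datasets without fate commitment (e.g.
  a pure KRAS course) need explicit anchors or produce a reported skip.
* The discrete-state time-course generator can produce disconnected state
  islands at small k; fate analysis on such data correctly refuses rather
  than inventing a path.
* Signature scores depend mildly on the control-gene seed; all defaults are
  seeded and recorded.
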