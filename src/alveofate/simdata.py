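"""Synthetic time-course scRNA-seq generator.

Emulates the statistical structure the downstream pipeline assumes: a
four-time-point (Day 4/7/10/14) design in which wild-type AT2 cells pass
through a transient injury/plasticity state before resolving into AT1 and AT2
terminal states, while KRAS-mutant cells retain the plastic state and only a
late subpopulation re-activates the AT2 program.  Counts follow a negative
binomial over per-state marker-gene programs, scaled by a log-normal library
size; mitochondrial genes (``mt-`` prefix) are filled in to hit a sampled
per-cell mitochondrial fraction so that QC can be exercised exactly as the
pipeline computes it.

Three generators are provided:

``generate_timecourse``
    discrete cell states sampled per time point from :class:`StateProgram` s;
``generate_branching``
    a continuous Y-shaped trajectory (root segment splitting into two
    branches) with latent branch identity and position stored as ground truth;
``generate_conserved_receptor_trio``
    three datasets (two mouse-case, one human-case) sharing a conserved set of
    receptors up-shifted in early-stage KRAS cells, plus dataset-specific
    decoy receptors.

All randomness flows through a single :class:`numpy.random.Generator` seeded
from ``SimConfig.seed``; identical config + seed gives bit-identical counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import AnnotatedCounts
from .panels import bundled_panel, receptor_panel

DEFAULT_TIMEPOINTS = ("Day4", "Day7", "Day10", "Day14")

_WEIGHT_TOL = 1e-6


@dataclass(frozen=True)
class StateProgram:
    """Expression program of one cell state across the time course.

    ``marker_means`` override the per-gene baseline (arbitrary relative
    expression units, >= 0) for the genes they name; a mean of 0 silences the
    gene in this state.  ``timepoint_weights`` give the state's sampling
    proportion at each time point; across the states of a genotype the weights
    at a fixed time point must sum to 1.
    """

    state_name: str
    marker_means: Mapping[str, float]
    timepoint_weights: Mapping[str, float]

    def __post_init__(self) -> None:
        for g, m in self.marker_means.items():
            if m < 0:
                raise ValueError(f"negative marker mean for {g!r} in state {self.state_name!r}")
        for tp, w in self.timepoint_weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight {w} for {tp!r} outside [0,1] in {self.state_name!r}")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic generator; defaults are the package's study conditions."""

    n_cells_per_timepoint: int = 500
    n_genes: int = 300
    nb_dispersion: float = 20.0  # NB size; var = mu + mu^2/size.  inf = Poisson
    library_size_mean: int = 20_000
    library_size_sigma: float = 0.35
    mito_fraction_mean: float = 0.05
    mito_fraction_sd: float = 0.02
    mito_fraction_by_state: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    program_activity_sigma: float = 0.25  # per-cell log-normal program intensity
    n_mito_genes: int = 10
    genotype: str = "WT"
    dataset_id: str = "sim"
    seed: int = 0
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    gene_symbols: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("n_cells_per_timepoint", "n_genes", "library_size_mean", "n_mito_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.nb_dispersion > 0):  # also rejects NaN; inf allowed
            raise ValueError("nb_dispersion must be positive (inf = Poisson limit)")
        if not 0.0 <= self.mito_fraction_mean <= 1.0:
            raise ValueError("mito_fraction_mean must lie in [0,1]")
        for st, (m, _s) in self.mito_fraction_by_state.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"mito fraction mean for state {st!r} outside [0,1]")
        if self.genotype not in ("WT", "KRAS"):
            raise ValueError("genotype must be 'WT' or 'KRAS'")


# ---------------------------------------------------------------------------
# default state programs (the emulated study design)
# ---------------------------------------------------------------------------

# Injury/plasticity program: the core panel plus DATP/IFNg/primed-AT2 genes
# that mark the same transitional state.
_INJURY = dict(Cldn4=20, Krt8=20, Nr4a3=14, Ifngr1=14, Ndrg1=14, Sox9=10, Hmga2=10,
               Itga2=10, Sprr1a=14, Ly6a=10, Irf7=10, Cxcl16=10, Tmem173=10,
               Orm1=10, Cbr4=10)
# Terminal programs are magnitude-balanced (equal gene count and level) so the
# two branches of the Y-trajectory have equal "speed" in expression space.
_AT1_FULL = {g: 20 for g in ("Hopx", "Igfbp2", "Ager", "Pdpn", "Cav1", "Aqp5",
                             "Timp3", "Sema3b", "Spock2")}
_AT2_FULL = {g: 20 for g in ("Etv5", "Lyz2", "Abca3", "Sftpc", "Sftpb", "Lamp3",
                             "Sftpa1", "Napsa", "Cxcl15")}
_AT1_INTER = {**{g: 8 for g in _AT1_FULL}, "Krt8": 6, "Cldn4": 6}
_AT2_INTER = {**{g: 8 for g in _AT2_FULL}, "Krt8": 6, "Nr4a3": 6}


def default_programs(genotype: str = "WT") -> list[StateProgram]:
    """State x time-point design emulating the organoid time course.

    WT: a single plastic state at Day 4 resolving through AT1/AT2
    intermediates into AT1 and AT2 terminal states at Day 14.  KRAS: the
    plastic state is retained at every time point; an AT2-high subpopulation
    appears only late.
    """
    if genotype == "WT":
        return [
            StateProgram("plastic", _INJURY,
                         {"Day4": 1.0, "Day7": 0.2, "Day10": 0.0, "Day14": 0.0}),
            StateProgram("AT1_intermediate", _AT1_INTER,
                         {"Day4": 0.0, "Day7": 0.4, "Day10": 0.5, "Day14": 0.0}),
            StateProgram("AT2_intermediate", _AT2_INTER,
                         {"Day4": 0.0, "Day7": 0.4, "Day10": 0.5, "Day14": 0.0}),
            StateProgram("AT1", _AT1_FULL,
                         {"Day4": 0.0, "Day7": 0.0, "Day10": 0.0, "Day14": 0.5}),
            StateProgram("AT2", _AT2_FULL,
                         {"Day4": 0.0, "Day7": 0.0, "Day10": 0.0, "Day14": 0.5}),
        ]
    if genotype == "KRAS":
        kras_plastic = {**_INJURY, "Itga3": 14, "Src": 12, "Ocln": 10, "Adipor1": 10,
                        "Plxnb2": 10, "St14": 10, "Itgb1": 10, "Lsr": 10}
        return [
            StateProgram("injury_high", kras_plastic,
                         {"Day4": 1.0, "Day7": 1.0, "Day10": 0.8, "Day14": 0.6}),
            StateProgram("AT2_high", _AT2_FULL,
                         {"Day4": 0.0, "Day7": 0.0, "Day10": 0.2, "Day14": 0.4}),
        ]
    raise ValueError(f"unknown genotype {genotype!r}")


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _mito_symbols(n: int) -> list[str]:
    return [f"mt-Sim{i + 1}" for i in range(n)]


def _gene_universe(config: SimConfig, program_symbols: Sequence[str]) -> list[str]:
    """Nuclear gene symbols followed by mito genes; program symbols must be present."""
    if config.gene_symbols is not None:
        symbols = list(config.gene_symbols)
        known = set(symbols)
        for s in program_symbols:
            if s not in known:
                raise ValueError(f"unknown gene symbol in program: {s!r}")
        if not any(s.startswith(("mt-", "MT-")) for s in symbols):
            symbols = symbols + _mito_symbols(config.n_mito_genes)
        return symbols
    named: list[str] = []
    seen: set[str] = set()
    for s in list(program_symbols) + [
        s for p in ("injury_plasticity", "at2", "at1", "datp", "ifng", "primed_at2")
        for s in bundled_panel(p).symbols
    ] + ["Sftpc", "Sftpb", "Src"]:
        if s not in seen:
            named.append(s)
            seen.add(s)
    n_fill = max(config.n_genes - len(named), 0)
    fillers = [f"Gene{i + 1:04d}" for i in range(n_fill)]
    return named + fillers + _mito_symbols(config.n_mito_genes)


def _baseline(rng: np.random.Generator, nuclear: Sequence[str],
              program_symbols: Sequence[str] = ()) -> np.ndarray:
    """Per-gene baseline relative expression (log-normal across genes).

    Genes that belong to any state program are given a fixed off-state
    baseline of 1.0: marker genes have a defined resting level, and the
    symmetric off-state keeps trajectory branches geometrically exchangeable.
    """
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(nuclear))
    prog = set(program_symbols)
    if prog:
        idx = [i for i, s in enumerate(nuclear) if s in prog]
        base[idx] = 1.0
    return base


def _sample_nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, size=dispersion) via gamma-Poisson; Poisson at dispersion=inf."""
    if math.isinf(dispersion):
        return rng.poisson(mean)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def _library_sizes(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    mu = math.log(config.library_size_mean) - config.library_size_sigma**2 / 2
    return rng.lognormal(mean=mu, sigma=config.library_size_sigma, size=n)


def _add_mito(rng: np.random.Generator, counts: np.ndarray, n_mito: int,
              fractions: np.ndarray) -> np.ndarray:
    """Append mito-gene columns whose totals realise the sampled fractions."""
    totals = counts.sum(axis=1)
    mito_tot = np.round(totals * fractions / np.maximum(1.0 - fractions, 1e-9)).astype(int)
    mito = np.vstack([
        rng.multinomial(t, np.full(n_mito, 1.0 / n_mito)) for t in mito_tot
    ]) if len(mito_tot) else np.zeros((0, n_mito), dtype=int)
    return np.hstack([counts, mito])


def _sample_mito_fraction(rng: np.random.Generator, config: SimConfig,
                          states: Sequence[str]) -> np.ndarray:
    means = np.array([
        config.mito_fraction_by_state.get(s, (config.mito_fraction_mean,
                                              config.mito_fraction_sd))[0]
        for s in states
    ])
    sds = np.array([
        config.mito_fraction_by_state.get(s, (config.mito_fraction_mean,
                                              config.mito_fraction_sd))[1]
        for s in states
    ])
    return np.clip(rng.normal(means, sds), 0.0, 0.95)


def _relative_means(baseline: np.ndarray, symbols: Sequence[str],
                    program: Mapping[str, float]) -> np.ndarray:
    rel = baseline.copy()
    index = {s: i for i, s in enumerate(symbols)}
    for g, m in program.items():
        rel[index[g]] = m
    return rel


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_timecourse(config: SimConfig,
                        programs: Sequence[StateProgram] | None = None) -> AnnotatedCounts:
    """Draw a discrete-state time course from negative-binomial state programs."""
    if programs is None:
        programs = default_programs(config.genotype)
    if not programs:
        raise ValueError("at least one StateProgram required")
    prog_symbols = [g for p in programs for g in p.marker_means]
    symbols = _gene_universe(config, prog_symbols)
    n_mito = sum(1 for s in symbols if s.startswith(("mt-", "MT-")))
    nuclear = [s for s in symbols if not s.startswith(("mt-", "MT-"))]
    if [s for s in symbols if s.startswith(("mt-", "MT-"))] != symbols[len(nuclear):]:
        raise ValueError("mitochondrial genes must come after nuclear genes")

    # per-time-point weights must sum to 1 across states
    for tp in config.timepoints:
        w = sum(p.timepoint_weights.get(tp, 0.0) for p in programs)
        if abs(w - 1.0) > _WEIGHT_TOL:
            raise ValueError(
                f"state weights at {tp!r} sum to {w:.6f}, expected 1.0"
            )

    rng = np.random.default_rng(config.seed)
    base = _baseline(rng, nuclear, prog_symbols)
    index = {s: i for i, s in enumerate(nuclear)}
    marker_idx = {p.state_name: np.array([index[g] for g in p.marker_means], dtype=int)
                  for p in programs}
    marker_val = {p.state_name: np.array(list(p.marker_means.values()), dtype=float)
                  for p in programs}

    rows, states, tps = [], [], []
    sig = config.program_activity_sigma
    for tp in config.timepoints:
        weights = np.array([p.timepoint_weights.get(tp, 0.0) for p in programs])
        drawn = rng.choice(len(programs), size=config.n_cells_per_timepoint, p=weights)
        lib = _library_sizes(rng, config, config.n_cells_per_timepoint)
        # per-cell program intensity: states are distributions, not points,
        # and co-programmed marker genes rise and fall together within a state
        activity = rng.lognormal(-sig**2 / 2, sig, size=len(drawn)) if sig > 0 \
            else np.ones(len(drawn))
        rel = np.tile(base, (len(drawn), 1))
        for ci, pi in enumerate(drawn):
            name = programs[pi].state_name
            rel[ci, marker_idx[name]] = activity[ci] * marker_val[name]
        rho = rel / rel.sum(axis=1, keepdims=True)
        counts = _sample_nb(rng, lib[:, None] * rho, config.nb_dispersion)
        rows.append(counts)
        states.extend(programs[i].state_name for i in drawn)
        tps.extend([tp] * config.n_cells_per_timepoint)

    counts = np.vstack(rows)
    fracs = _sample_mito_fraction(rng, config, states)
    counts = _add_mito(rng, counts, n_mito, fracs)

    meta = pd.DataFrame(
        {
            "timepoint": tps,
            "genotype": config.genotype,
            "dataset_id": config.dataset_id,
            "true_state": states,
            "mito_fraction": fracs,
        },
        index=pd.Index([f"bc{i:06d}" for i in range(len(states))], name="barcode"),
    )
    return AnnotatedCounts(counts=counts, gene_symbols=symbols, cell_meta=meta)


# --- branching ---------------------------------------------------------------

_ROOT_PROGRAM = _INJURY
_JUNCTION_PROGRAM = {g: m * 0.2 for g, m in _INJURY.items()}


def generate_branching(config: SimConfig, branch_asymmetry: float = 0.5, *,
                       branch_point: float = 0.25,
                       tip_programs: tuple[Mapping[str, float], Mapping[str, float]]
                       = (_AT1_FULL, _AT2_FULL)) -> AnnotatedCounts:
    """Y-shaped trajectory: a root segment splitting into branches A and B.

    Each cell has a latent time ``u`` uniform within its time point's quarter
    of [0,1]; cells past ``branch_point`` lie on branch A with probability
    ``branch_asymmetry``.  Expression means interpolate linearly from the
    injury-high root program, through an attenuated junction program, to the
    branch tip programs (AT1 for A, AT2 for B), with NB noise and library
    scaling on top.  Latent branch and position are stored in ``cell_meta``
    (columns ``latent_branch``, ``latent_time``) as recoverable ground truth.
    """
    if not 0.0 <= branch_asymmetry <= 1.0:
        raise ValueError("branch_asymmetry must lie in [0,1]")
    prog_a, prog_b = tip_programs
    all_syms = list(_ROOT_PROGRAM) + list(prog_a) + list(prog_b)
    symbols = _gene_universe(config, all_syms)
    nuclear = [s for s in symbols if not s.startswith(("mt-", "MT-"))]
    n_mito = len(symbols) - len(nuclear)

    rng = np.random.default_rng(config.seed)
    base = _baseline(rng, nuclear, all_syms)
    rel_root = _relative_means(base, nuclear, _ROOT_PROGRAM)
    rel_junc = _relative_means(base, nuclear, _JUNCTION_PROGRAM)
    rel_a = _relative_means(base, nuclear, prog_a)
    rel_b = _relative_means(base, nuclear, prog_b)

    n_tp = len(config.timepoints)
    n = config.n_cells_per_timepoint * n_tp
    tps = np.repeat(config.timepoints, config.n_cells_per_timepoint)
    u = np.concatenate([
        rng.uniform(i / n_tp, (i + 1) / n_tp, size=config.n_cells_per_timepoint)
        for i in range(n_tp)
    ])
    on_branch = u >= branch_point
    branch_a = rng.random(n) < branch_asymmetry
    branch = np.where(on_branch, np.where(branch_a, "A", "B"), "root")

    rel = np.empty((n, len(nuclear)))
    root_idx = ~on_branch
    s_root = (u[root_idx] / branch_point)[:, None] if branch_point > 0 else 0.0
    rel[root_idx] = (1 - s_root) * rel_root + s_root * rel_junc
    for lab, tip in (("A", rel_a), ("B", rel_b)):
        idx = on_branch & (branch == lab)
        s = ((u[idx] - branch_point) / (1 - branch_point))[:, None]
        rel[idx] = (1 - s) * rel_junc + s * tip

    lib = _library_sizes(rng, config, n)
    rho = rel / rel.sum(axis=1, keepdims=True)
    counts = _sample_nb(rng, lib[:, None] * rho, config.nb_dispersion)
    fracs = np.clip(rng.normal(config.mito_fraction_mean, config.mito_fraction_sd, n),
                    0.0, 0.95)
    counts = _add_mito(rng, counts, n_mito, fracs)

    meta = pd.DataFrame(
        {
            "timepoint": tps,
            "genotype": config.genotype,
            "dataset_id": config.dataset_id,
            "true_state": np.where(on_branch, np.char.add("branch", branch), "root"),
            "latent_branch": branch,
            "latent_time": u,
            "mito_fraction": fracs,
        },
        index=pd.Index([f"bc{i:06d}" for i in range(n)], name="barcode"),
    )
    return AnnotatedCounts(counts=counts, gene_symbols=symbols, cell_meta=meta)


# --- conserved-receptor trio -------------------------------------------------

@dataclass(frozen=True)
class ReceptorTrio:
    """Three synthetic datasets plus the embedded conservation ground truth."""

    datasets: tuple[AnnotatedCounts, AnnotatedCounts, AnnotatedCounts]
    shared_receptors: tuple[str, ...]          # harmonized (uppercase) symbols
    decoys_by_dataset: tuple[tuple[str, ...], ...]


def _mouse_case(symbol: str) -> str:
    return symbol[0].upper() + symbol[1:].lower() if symbol else symbol


def generate_conserved_receptor_trio(
    config: SimConfig,
    shared_receptors: Sequence[str],
    decoys_per_dataset: int = 20,
    *,
    decoys: Sequence[Sequence[str]] | None = None,
    receptor_fold: float = 3.0,
) -> ReceptorTrio:
    """Three early-stage WT/KRAS datasets with an embedded conserved receptor set.

    The shared receptors are up-shifted (x ``receptor_fold``) in early-stage
    KRAS cells of *all three* datasets; each decoy receptor is up-shifted in
    exactly one dataset.  Datasets 1 and 2 use mouse-case symbols, dataset 3
    human-case (uppercase), exercising case-insensitive harmonization
    downstream.
    """
    shared_up = {s.upper() for s in shared_receptors}
    pool = [r for r in receptor_panel().symbols if r.upper() not in shared_up]
    rng = np.random.default_rng(config.seed)

    if decoys is None:
        if 3 * decoys_per_dataset > len(pool):
            raise ValueError(
                f"receptor panel has only {len(pool)} non-shared receptors; "
                f"cannot draw 3 x {decoys_per_dataset} disjoint decoys"
            )
        order = rng.permutation(len(pool))
        decoys = tuple(
            tuple(pool[j] for j in order[i * decoys_per_dataset:(i + 1) * decoys_per_dataset])
            for i in range(3)
        )
    else:
        decoys = tuple(tuple(d) for d in decoys)
        if len(decoys) != 3:
            raise ValueError("decoys must list one set per dataset (3)")
        folded = [set(s.upper() for s in d) for d in decoys]
        for i, f in enumerate(folded):
            if f & shared_up:
                raise ValueError(
                    f"decoy set {i} overlaps shared receptors: {sorted(f & shared_up)}"
                )
        for i in range(3):
            for j in range(i + 1, 3):
                if folded[i] & folded[j]:
                    raise ValueError(
                        f"decoy sets {i} and {j} overlap: {sorted(folded[i] & folded[j])}"
                    )

    # mouse-case gene universe shared by all datasets; dataset 3 is uppercased
    receptors_mouse = [_mouse_case(r) for r in receptor_panel().symbols]
    n_fill = max(config.n_genes - len(receptors_mouse), 0)
    fillers = [f"Gene{i + 1:04d}" for i in range(n_fill)]
    nuclear = receptors_mouse + fillers
    symbols = nuclear + _mito_symbols(config.n_mito_genes)
    nuc_index = {s.upper(): i for i, s in enumerate(nuclear)}

    tags = ("organoid", "invivo", "human")
    n_per_group = config.n_cells_per_timepoint
    datasets = []
    for d, tag in enumerate(tags):
        base = _baseline(rng, nuclear, receptors_mouse)
        rel_wt = base.copy()
        rel_kras = base.copy()
        for s in shared_up | {x.upper() for x in decoys[d]}:
            rel_kras[nuc_index[s]] = base[nuc_index[s]] * receptor_fold
        rows, genos = [], []
        for geno, rel in (("WT", rel_wt), ("KRAS", rel_kras)):
            lib = _library_sizes(rng, config, n_per_group)
            rho = rel / rel.sum()
            rows.append(_sample_nb(rng, lib[:, None] * rho[None, :], config.nb_dispersion))
            genos.extend([geno] * n_per_group)
        counts = np.vstack(rows)
        fracs = np.clip(
            rng.normal(config.mito_fraction_mean, config.mito_fraction_sd, len(genos)),
            0.0, 0.95,
        )
        counts = _add_mito(rng, counts, config.n_mito_genes, fracs)
        ds_symbols = [s.upper() for s in symbols] if tag == "human" else list(symbols)
        meta = pd.DataFrame(
            {
                "timepoint": "early",
                "genotype": genos,
                "dataset_id": tag,
                "mito_fraction": fracs,
            },
            index=pd.Index([f"{tag}_bc{i:06d}" for i in range(len(genos))], name="barcode"),
        )
        datasets.append(AnnotatedCounts(counts=counts, gene_symbols=ds_symbols,
                                        cell_meta=meta))

    return ReceptorTrio(
        datasets=tuple(datasets),
        shared_receptors=tuple(sorted(shared_up)),
        decoys_by_dataset=tuple(tuple(sorted(s.upper() for s in d)) for d in decoys),
    )
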