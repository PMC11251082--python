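"""End-to-end orchestration: configuration, stage execution, manifest.

``run_pipeline`` executes qc -> normalize -> embed -> impute -> cluster ->
score -> classify -> fate -> DE -> panel filters on one dataset, writing every
intermediate as TSV/MTX/JSON under the output directory and recording a
manifest (stage parameters, output hashes).  Two self-contained analyses used
throughout the tests are also defined here:

``branching_fate_analysis``
    symmetric/asymmetric Y-trajectory -> fate probabilities of the
    root (plasticity-state) community toward the two branch-tip fates;
``conserved_receptor_analysis``
    three-dataset DE -> receptor filter -> harmonized intersection.

All stage seeds derive deterministically from one global seed; identical
config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmwrite

from . import io as afio
from .conservation import ConservedReceptorReport, conserved_receptors
from .containers import AnnotatedCounts, ExpressionMatrix
from .diffexp import FilterParams, rank_genes_by_label, filter_by_panel
from .fate import FateAnchors, anchors_from_communities, \
    community_fate_summary, diffusion_pseudotime, fate_probabilities
from .graph import ImputeParams, dense_kernel_graph, knn_graph, magic_impute, \
    markov_operator, pca_embed
from .panels import CONSERVED_RECEPTOR_PANEL, GenePanel, bundled_panel, \
    load_panel_file, receptor_panel
from .qc import QCParams, MITO_THRESHOLD_INVIVO, MITO_THRESHOLD_ORGANOID, \
    normalize_log, qc_filter, qc_report_frame
from .simdata import SimConfig, generate_branching, \
    generate_conserved_receptor_trio, generate_timecourse
from .states import classify_states, leiden_communities, score_signatures, \
    state_class_counts

_FLOAT_FMT = "%.6g"


def derive_seed(global_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed below 2^31."""
    ss = np.random.SeedSequence([int(global_seed), int(stage_index)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    outdir: str = "alveofate_run"
    seed: int = 0
    input_path: str | None = None
    simulate: dict = field(default_factory=lambda: {
        "kind": "branching", "genotype": "WT", "branch_asymmetry": 0.5,
        "n_cells_per_timepoint": 125, "n_genes": 300,
    })
    qc: dict = field(default_factory=lambda: {"max_mito_fraction": 0.20})
    normalize: dict = field(default_factory=lambda: {"target_sum": 10_000})
    impute: dict = field(default_factory=lambda: {"k": 5, "t": 5, "n_pca": 30})
    neighbors: dict = field(default_factory=lambda: {"k": 15})
    leiden: dict = field(default_factory=lambda: {"resolution": 1.0})
    panels: list = field(default_factory=lambda: ["injury_plasticity", "at2", "at1"])
    score: dict = field(default_factory=lambda: {
        "n_bins": 25, "n_control": 50, "use_imputed": True,
    })
    fate: dict = field(default_factory=lambda: {"enabled": True})
    de: dict = field(default_factory=lambda: {"contrasts": [
        {"name": "early_vs_rest", "key": "timepoint", "group": "Day4",
         "reference": "rest"},
    ]})

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.input_path is not None and not Path(cfg.input_path).exists():
            raise FileNotFoundError(cfg.input_path)
        return cfg


def _resolve_panels(specs: list) -> list[GenePanel]:
    out = []
    for s in specs:
        if isinstance(s, GenePanel):
            out.append(s)
        elif Path(str(s)).exists() and str(s).endswith(".txt"):
            out.append(load_panel_file(s))
        else:
            out.append(bundled_panel(str(s)))
    return out


# ---------------------------------------------------------------------------
# automatic anchor selection
# ---------------------------------------------------------------------------

def select_start_community(labels, meta: pd.DataFrame,
                           timepoints: list[str] | None = None) -> int:
    """Community holding the largest number of earliest-time-point cells."""
    tps = timepoints or sorted(meta["timepoint"].unique(),
                               key=_timepoint_order_key)
    earliest = tps[0]
    mask = (meta["timepoint"] == earliest).to_numpy()
    counts = pd.Series(labels.assignment.to_numpy()[mask]).value_counts()
    return int(counts.idxmax())


def select_terminal_communities(labels, meta: pd.DataFrame, scores,
                                fate_panels: tuple[str, str] = ("at1", "at2"),
                                timepoints: list[str] | None = None,
                                min_share: float = 0.1) -> dict[str, int]:
    """Pick one terminal community per fate panel among late-stage communities.

    Candidate communities hold at least ``min_share`` of all latest-time-point
    cells (endpoints are anchored at the final time point); among candidates,
    the community whose latest-time-point cells have the highest mean score of
    a fate panel becomes that fate's terminal community.
    """
    tps = timepoints or sorted(meta["timepoint"].unique(), key=_timepoint_order_key)
    latest = tps[-1]
    comm = labels.assignment.to_numpy()
    latest_mask = (meta["timepoint"] == latest).to_numpy()
    n_latest = max(int(latest_mask.sum()), 1)
    candidates = [
        c for c in range(labels.n_communities)
        if (latest_mask & (comm == c)).sum() / n_latest >= min_share
    ]
    if len(candidates) < 2:
        raise ValueError(
            f"need >= 2 latest-time-point communities for terminal fates, found {candidates}"
        )
    chosen: dict[str, int] = {}
    for panel_name in fate_panels:
        means = {
            c: scores.scores[panel_name].to_numpy()[latest_mask & (comm == c)].mean()
            for c in candidates
        }
        chosen[panel_name] = int(max(means, key=means.get))
    if len(set(chosen.values())) < len(chosen):
        raise ValueError(f"terminal fates collapse onto one community: {chosen}")
    return chosen


def auto_fate_anchors(labels, meta: pd.DataFrame, scores,
                      fate_panels: tuple[str, str] = ("at1", "at2")):
    """Start community + latest-time-point terminal sets, selected automatically.

    Terminal sets are the latest-time-point cells of each terminal community
    (community labels + time-point filter); the start set is the whole
    earliest-time-point-dominant community.  Returns ``(anchors, start_id,
    terminal_ids)``.
    """
    tps = sorted(meta["timepoint"].unique(), key=_timepoint_order_key)
    start = select_start_community(labels, meta, timepoints=tps)
    terms = select_terminal_communities(labels, meta, scores,
                                        fate_panels=fate_panels, timepoints=tps)
    latest_idx = np.flatnonzero((meta["timepoint"] == tps[-1]).to_numpy())
    start_cells = labels.members(start)
    terminal_sets = {
        f: np.setdiff1d(np.intersect1d(labels.members(c), latest_idx), start_cells)
        for f, c in terms.items()
    }
    anchors = FateAnchors(start_cells=start_cells, terminal_sets=terminal_sets)
    return anchors, start, terms


def _timepoint_order_key(tp: str):
    import re

    m = re.search(r"(\d+)", str(tp))
    return (0, int(m.group(1))) if m else (1, str(tp))


# ---------------------------------------------------------------------------
# manifest helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.data = {"package": "alveofate 0.1.0", "config": asdict(config),
                     "stages": {}}

    def record(self, stage: str, params: dict, outputs: list[Path],
               status: str = "ok") -> None:
        self.data["stages"][stage] = {
            "parameters": params,
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p) for p in outputs},
            "status": status,
        }

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True, default=str))
        return path


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, **kw)
    return path


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the full flow on one dataset; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)

    # stage 0: input
    if config.input_path is not None:
        data = afio.read_counts(config.input_path)
        manifest.record("input", {"path": config.input_path}, [])
    else:
        sim = dict(config.simulate)
        kind = sim.pop("kind", "timecourse")
        asym = sim.pop("branch_asymmetry", 0.5)
        sim_cfg = SimConfig(seed=derive_seed(config.seed, 0), **sim)
        data = (generate_branching(sim_cfg, asym) if kind == "branching"
                else generate_timecourse(sim_cfg))
        counts_dir = afio.write_counts(data, outdir / "counts")
        manifest.record("simulate", {"kind": kind, **sim},
                        sorted(counts_dir.iterdir()))

    # stage 1: qc
    qc_params = QCParams(**config.qc)
    report: dict = {}
    data = qc_filter(data, qc_params, report=report)
    out = _write_tsv(qc_report_frame(report), outdir / "qc_report.tsv", index=False)
    manifest.record("qc", config.qc, [out])

    # stage 2: normalize
    norm = normalize_log(data, **config.normalize)
    out = _write_tsv(
        pd.DataFrame(norm.values, index=norm.cell_meta.index, columns=norm.gene_symbols),
        outdir / "normalized.tsv",
    )
    manifest.record("normalize", config.normalize, [out])

    # stage 3: embed + impute
    imp_params = ImputeParams(**config.impute)
    n_pca = min(imp_params.n_pca, min(norm.n_cells, norm.n_genes) - 1)
    emb = pca_embed(norm, n_pca)
    impute_graph = knn_graph(emb, imp_params.k)
    imputed = magic_impute(norm, ImputeParams(imp_params.k, imp_params.t, n_pca),
                           graph=impute_graph)
    emb_out = _write_tsv(
        pd.DataFrame(emb, index=norm.cell_meta.index,
                     columns=[f"PC{i+1}" for i in range(emb.shape[1])]),
        outdir / "embedding.tsv",
    )
    op_path = outdir / "operator.mtx"
    mmwrite(op_path, markov_operator(impute_graph).matrix.tocoo())
    imp_out = _write_tsv(
        pd.DataFrame(imputed.values, index=imputed.cell_meta.index,
                     columns=imputed.gene_symbols),
        outdir / "imputed.tsv",
    )
    manifest.record("impute", {"k": imp_params.k, "t": imp_params.t, "n_pca": n_pca},
                    [emb_out, op_path, imp_out])

    # stage 4: clustering graph + leiden
    cluster_graph = knn_graph(emb, config.neighbors["k"])
    labels = leiden_communities(cluster_graph, resolution=config.leiden["resolution"],
                                seed=derive_seed(config.seed, 4),
                                barcodes=norm.barcodes)
    out = _write_tsv(labels.assignment.to_frame(), outdir / "communities.tsv")
    manifest.record("cluster", {**config.leiden, "k": config.neighbors["k"]}, [out])

    # stage 5: signature scores
    panels = _resolve_panels(config.panels)
    score_space = imputed if config.score.get("use_imputed", True) else norm
    scores = score_signatures(score_space, panels,
                              n_bins=config.score["n_bins"],
                              n_control=config.score["n_control"],
                              seed=derive_seed(config.seed, 5))
    out = _write_tsv(scores.scores, outdir / "signature_scores.tsv")
    manifest.record("score", dict(config.score), [out])

    # stage 6: state classification (needs injury + at2 panels)
    outs = []
    panel_names = [p.name for p in panels]
    if "injury_plasticity" in panel_names and "at2" in panel_names:
        classes = classify_states(scores)
        outs.append(_write_tsv(classes.to_frame(), outdir / "state_classes.tsv"))
        counts_tbl = state_class_counts(classes, norm.cell_meta, labels=labels)
        outs.append(_write_tsv(counts_tbl, outdir / "state_class_counts.tsv",
                               index=False))
        manifest.record("classify", {}, outs)

    # stage 7: fate
    if config.fate.get("enabled", True):
        try:
            start = config.fate.get("start_community", "auto")
            terms = config.fate.get("terminal_communities", "auto")
            if start == "auto" or terms == "auto":
                anchors, start, terms = auto_fate_anchors(labels, norm.cell_meta,
                                                          scores)
            else:
                anchors = anchors_from_communities(labels, int(start),
                                                   {k: int(v) for k, v in terms.items()})
            pt = diffusion_pseudotime(cluster_graph, anchors)
            chain_graph = dense_kernel_graph(emb, config.neighbors["k"])
            posterior = fate_probabilities(chain_graph, pt, anchors,
                                           barcodes=norm.barcodes)
            fate_tbl = posterior.probabilities.copy()
            fate_tbl.insert(0, "pseudotime", posterior.pseudotime)
            o1 = _write_tsv(fate_tbl, outdir / "fate_probabilities.tsv")
            o2 = _write_tsv(community_fate_summary(posterior, labels),
                            outdir / "community_fate_summary.tsv", index=False)
            manifest.record("fate", {"start_community": start,
                                     "terminal_communities": terms}, [o1, o2])
        except ValueError as exc:
            manifest.record("fate", {"error": str(exc)}, [], status="skipped")

    # stage 8: DE + panel filters
    for contrast in config.de.get("contrasts", []):
        name = contrast["name"]
        meta = norm.cell_meta
        mask = np.ones(norm.n_cells, dtype=bool)
        for key, val in contrast.get("subset", {}).items():
            mask &= (meta[key] == val).to_numpy()
        sub = ExpressionMatrix(norm.values[mask], norm.gene_symbols,
                               meta.iloc[np.flatnonzero(mask)],
                               transform_log=list(norm.transform_log))
        lab = sub.cell_meta[contrast["key"]].to_numpy()
        try:
            table = rank_genes_by_label(sub, lab, contrast["group"],
                                        contrast.get("reference", "rest"))
        except ValueError as exc:
            manifest.record(f"de:{name}", {"error": str(exc)}, [], status="skipped")
            continue
        o1 = _write_tsv(table, outdir / f"de_{name}.tsv")
        tf_hits = filter_by_panel(table, bundled_panel("tf"),
                                  FilterParams(p_max=0.05, lfc_min=1.0, direction="up"))
        rc_hits = filter_by_panel(table, receptor_panel(),
                                  FilterParams(p_max=0.05, direction="up"))
        o2 = outdir / f"de_{name}_tf_hits.txt"
        o2.write_text("".join(f"{g}\n" for g in tf_hits))
        o3 = outdir / f"de_{name}_receptor_hits.txt"
        o3.write_text("".join(f"{g}\n" for g in rc_hits))
        manifest.record(f"de:{name}", {k: v for k, v in contrast.items()},
                        [o1, o2, o3])

    manifest.write()
    return manifest.data


# ---------------------------------------------------------------------------
# headline analyses
# ---------------------------------------------------------------------------

def branching_fate_analysis(seed: int, branch_asymmetry: float = 0.5,
                            n_cells_per_timepoint: int = 500,
                            n_genes: int = 300, k: int = 15, n_pca: int = 30,
                            resolution: float = 1.0) -> dict:
    """Fate probabilities of the root community on a Y-shaped time course.

    Generates a branching dataset, runs QC, normalization, PCA, kNN graph,
    Leiden, signature-based terminal selection (AT1/AT2 tip communities among
    Day-14-dominant communities), diffusion pseudotime from the Day-4-dominant
    root community, and the absorbing-chain fate solver.  Returns the mean
    per-fate probability over root-community cells plus all intermediates.
    """
    cfg = SimConfig(n_cells_per_timepoint=n_cells_per_timepoint, n_genes=n_genes,
                    seed=derive_seed(seed, 0))
    data = generate_branching(cfg, branch_asymmetry)
    data = qc_filter(data, QCParams(max_mito_fraction=MITO_THRESHOLD_ORGANOID))
    norm = normalize_log(data)
    n_pca = min(n_pca, min(norm.n_cells, norm.n_genes) - 1)
    imputed = magic_impute(norm, ImputeParams(5, 5, n_pca))
    emb = pca_embed(norm, n_pca)
    g = knn_graph(emb, k)
    labels = leiden_communities(g, resolution=resolution, seed=derive_seed(seed, 4),
                                barcodes=norm.barcodes)
    scores = score_signatures(imputed, [bundled_panel("at1"), bundled_panel("at2")],
                              seed=derive_seed(seed, 5))
    anchors, start, terms = auto_fate_anchors(labels, norm.cell_meta, scores)
    pt = diffusion_pseudotime(g, anchors)
    chain_graph = dense_kernel_graph(emb, k)
    posterior = fate_probabilities(chain_graph, pt, anchors, barcodes=norm.barcodes)
    root_cells = labels.members(start)
    root_mean = posterior.probabilities.iloc[root_cells].mean(axis=0)
    return {
        "data": data,
        "norm": norm,
        "graph": g,
        "labels": labels,
        "start_community": start,
        "terminal_communities": terms,
        "pseudotime": pt,
        "posterior": posterior,
        "root_mean_fate": root_mean,  # Series indexed by fate panel name
    }


def conserved_receptor_analysis(seed: int,
                                shared: GenePanel = CONSERVED_RECEPTOR_PANEL,
                                decoys_per_dataset: int = 20,
                                n_cells_per_group: int = 150,
                                n_genes: int = 250,
                                receptor_fold: float = 3.0,
                                use_adjusted: bool = False) -> dict:
    """DE -> receptor filter (p<0.05) -> three-way harmonized intersection.

    Returns the :class:`ConservedReceptorReport` together with the embedded
    ground truth from the generator.
    """
    cfg = SimConfig(n_cells_per_timepoint=n_cells_per_group, n_genes=n_genes,
                    seed=derive_seed(seed, 0))
    trio = generate_conserved_receptor_trio(cfg, shared.symbols,
                                            decoys_per_dataset,
                                            receptor_fold=receptor_fold)
    hits, tags = [], []
    for ds in trio.datasets:
        tag = ds.cell_meta["dataset_id"].iloc[0]
        thr = MITO_THRESHOLD_INVIVO if tag == "invivo" else MITO_THRESHOLD_ORGANOID
        filtered = qc_filter(ds, QCParams(max_mito_fraction=thr))
        norm = normalize_log(filtered)
        table = rank_genes_by_label(norm, norm.cell_meta["genotype"], "KRAS", "WT")
        hit = filter_by_panel(table, receptor_panel(),
                              FilterParams(p_max=0.05, direction="up",
                                           use_adjusted=use_adjusted))
        hits.append(hit)
        tags.append(tag)
    report = conserved_receptors(hits, tags)
    return {"trio": trio, "report": report, "hits": dict(zip(tags, hits))}


def run_conservation(datasets: list[AnnotatedCounts], tags: list[str],
                     filter_params: FilterParams | None = None,
                     outdir: str | Path | None = None) -> ConservedReceptorReport:
    """Conservation flow on user-provided datasets (KRAS-vs-WT early contrast)."""
    filter_params = filter_params or FilterParams(p_max=0.05, direction="up")
    hits = []
    for ds, tag in zip(datasets, tags):
        thr = MITO_THRESHOLD_INVIVO if tag == "invivo" else MITO_THRESHOLD_ORGANOID
        filtered = qc_filter(ds, QCParams(max_mito_fraction=thr))
        norm = normalize_log(filtered)
        table = rank_genes_by_label(norm, norm.cell_meta["genotype"], "KRAS", "WT")
        hits.append(filter_by_panel(table, receptor_panel(), filter_params))
    report = conserved_receptors(hits, tags)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "conserved_receptors.json").write_text(
            json.dumps(report.to_json_dict(), indent=2))
        rows = [{"dataset": t, "receptor": r} for t, hs in report.hit_sets.items()
                for r in sorted(hs)]
        _write_tsv(pd.DataFrame(rows), outdir / "receptor_hits.tsv", index=False)
    return report
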