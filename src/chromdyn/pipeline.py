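"""End-to-end driver: simulate -> binarize -> train -> decode -> dynamics ->
timecourse -> correlate -> report.

Every stage reads its inputs from and writes its outputs into a single run
directory, so stages can be re-run individually (that is what the CLI
subcommands do) or chained by :func:`run_pipeline`. A ``run.log`` records the
seed, package version and parameters of every stage.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._constants import MARKS
from . import io as cio
from .binarize import BinarizedTrackSet, bin_coverage, binarize_samples
from .correlate import stagewise_heatmap_table, timecourse_correlation
from .dynamics import (build_state_matrix, category_fraction_timecourse,
                       dominant_gene_state, origin_fractions, transition_flows)
from .grid import BinGrid
from .hmm import StateModel, baum_welch_train, collapse_states, decode
from .simulate import SimulationConfig, simulate_dataset, write_dataset
from .timecourse import (ExpressionMatrix, fpkm, signal_matrix, tmm_factors,
                         timecourse_analysis)

logger = logging.getLogger(__name__)

DEFAULT_PIPELINE_CONFIG = {
    "simulate": {},                 # SimulationConfig overrides
    "binarize": {"pvalue_cutoff": 1e-4, "pool_replicates": True},
    "train": {"K": 6, "max_iter": 100, "tol": 1e-3, "n_restarts": 2},
    "decode": {"method": "posterior"},
    "dynamics": {"flank_bp": 2000},
    "timecourse": {"degree": 4, "r2_cutoff": 0.7, "rna_k": 4, "mark_k": None,
                   "enhancer_scheme": "genebody_1.5-10kb", "mark": "H3K27ac"},
    "correlate": {"scheme": "genebody_1.5-10kb", "mark": "H3K27ac",
                  "stage_k": 3},
}


def load_config(path=None, seed: int = 0) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_PIPELINE_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, vals in user.items():
            cfg.setdefault(section, {}).update(vals or {})
    cfg.setdefault("simulate", {})["seed"] = int(
        cfg["simulate"].get("seed", seed))
    return cfg


def _setup_run_logging(run_dir: Path):
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("chromdyn")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def _log_stage(run_dir: Path, stage: str, params: dict):
    logger.info("stage=%s version=%s params=%s", stage, __version__,
                json.dumps(params, default=str))


# --------------------------------------------------------------------------- #
# stages
# --------------------------------------------------------------------------- #

def stage_simulate(run_dir: Path, cfg: dict):
    sim_cfg = SimulationConfig.from_dict(cfg["simulate"])
    _log_stage(run_dir, "simulate", {"seed": sim_cfg.seed,
                                     "m": sim_cfg.grid.total_bins})
    truth, marks, expr = simulate_dataset(sim_cfg)
    write_dataset(run_dir / "data", sim_cfg, truth, marks, expr)
    return sim_cfg, truth, marks, expr


def _load_tracks(run_dir: Path, sim_cfg: SimulationConfig):
    grid = BinGrid.from_json(run_dir / "data" / "grid.json")
    mark_tracks: dict = {}
    controls: dict = {}
    for tp in sim_cfg.timepoint_labels:
        mark_tracks[tp] = {m: [] for m in MARKS}
        controls[tp] = []
        for r in range(sim_cfg.n_replicates):
            for m in MARKS:
                p = run_dir / "data" / "tracks" / f"{m}_{tp}_rep{r+1}.bedGraph"
                mark_tracks[tp][m].append(bin_coverage(str(p), grid))
            pi = run_dir / "data" / "tracks" / f"input_{tp}_rep{r+1}.bedGraph"
            controls[tp].append(bin_coverage(str(pi), grid))
    return grid, mark_tracks, controls


def stage_binarize(run_dir: Path, cfg: dict, sim_cfg: SimulationConfig,
                   marks=None, inputs=None) -> BinarizedTrackSet:
    _log_stage(run_dir, "binarize", cfg["binarize"])
    if marks is not None:
        grid = sim_cfg.grid
        mark_tracks = {tp: {m: [marks.tracks[(tp, m, r)]
                                for r in range(sim_cfg.n_replicates)]
                            for m in MARKS}
                       for tp in sim_cfg.timepoint_labels}
        controls = {tp: [marks.inputs[(tp, r)]
                         for r in range(sim_cfg.n_replicates)]
                    for tp in sim_cfg.timepoint_labels}
    else:
        grid, mark_tracks, controls = _load_tracks(run_dir, sim_cfg)
    bts = binarize_samples(mark_tracks, controls, MARKS,
                           pvalue_cutoff=cfg["binarize"]["pvalue_cutoff"],
                           pool_replicates=cfg["binarize"]["pool_replicates"])
    bdir = run_dir / "binarized"
    bdir.mkdir(exist_ok=True)
    for key, mat in bts.presence.items():
        name = key if isinstance(key, str) else f"{key[0]}_rep{key[1]+1}"
        cio.write_binarized_tsv(mat, MARKS, grid, bdir / f"{name}.tsv")
    return bts


def stage_train(run_dir: Path, cfg: dict, bts: BinarizedTrackSet,
                seed: int) -> StateModel:
    _log_stage(run_dir, "train", {**cfg["train"], "seed": seed})
    seqs = []
    pooled_keys = [k for k in bts.presence if isinstance(k, str)]
    if pooled_keys:
        for key in pooled_keys:
            seqs.extend(bts.sequences(key))
    else:
        # per-replicate mode: replicates of one timepoint share a hidden path
        tps = sorted({k[0] for k in bts.presence})
        for tp in tps:
            keys = sorted(k for k in bts.presence if k[0] == tp)
            seqs.extend(bts.grouped_sequences(keys))
    tr = cfg["train"]
    model = baum_welch_train(seqs, K=tr["K"], mark_names=MARKS, seed=seed,
                             max_iter=tr["max_iter"], tol=tr["tol"],
                             n_restarts=tr["n_restarts"])
    collapse_states(model)
    model.to_json(run_dir / "model.json")
    model.emission_table().to_csv(run_dir / "emissions.tsv", sep="\t",
                                  index_label="state")
    return model


def stage_decode(run_dir: Path, cfg: dict, bts: BinarizedTrackSet,
                 model: StateModel, sim_cfg: SimulationConfig) -> dict:
    _log_stage(run_dir, "decode", cfg["decode"])
    sdir = run_dir / "segmentations"
    sdir.mkdir(exist_ok=True)
    segs = {}
    for tp in sim_cfg.timepoint_labels:
        keys = [k for k in bts.presence
                if k == tp or (isinstance(k, tuple) and k[0] == tp)]
        # per-replicate mode decodes all replicates jointly (shared path)
        key = keys[0] if len(keys) == 1 else keys
        seg = decode(bts, key, model, method=cfg["decode"]["method"])
        segs[tp] = seg
        cio.write_segmentation_bed(seg, sdir / f"{tp}.bed")
    return segs


def stage_dynamics(run_dir: Path, cfg: dict, segs: dict,
                   genes: pd.DataFrame, sim_cfg: SimulationConfig):
    _log_stage(run_dir, "dynamics", cfg["dynamics"])
    matrix = build_state_matrix(list(segs.items()))
    ddir = run_dir / "dynamics"
    ddir.mkdir(exist_ok=True)
    matrix.to_frame().to_csv(ddir / "state_matrix.tsv", sep="\t", index=False)

    fractions = category_fraction_timecourse(matrix)
    fractions.to_csv(ddir / "category_fractions.tsv", sep="\t",
                     index_label="timepoint")
    tps = list(matrix.timepoints)
    flows = []
    for a, b in list(zip(tps[:-1], tps[1:])) + [(tps[0], tps[-1])]:
        flows.append(transition_flows(matrix, a, b).to_long()
                     .assign(t_from=a, t_to=b))
    pd.concat(flows, ignore_index=True).to_csv(ddir / "transition_flows.tsv",
                                               sep="\t", index=False)
    try:
        origins = origin_fractions(matrix, tps[-1], "enhancer", tps[0])
    except ValueError as exc:   # no enhancer bins decoded at the last timepoint
        logger.warning("enhancer origins unavailable: %s", exc)
        origins = pd.Series(np.nan, index=list(fractions.columns),
                            name="enhancer")
    origins.to_frame("fraction").to_csv(ddir / "enhancer_origins.tsv", sep="\t",
                                        index_label="origin_category")
    dom = dominant_gene_state(matrix, genes, flank_bp=cfg["dynamics"]["flank_bp"])
    dom.to_csv(ddir / "dominant_gene_states.tsv", sep="\t")
    return matrix, fractions, origins, dom


def stage_timecourse(run_dir: Path, cfg: dict, expr, marks, sim_cfg,
                     seed: int):
    tc = cfg["timecourse"]
    _log_stage(run_dir, "timecourse", tc)
    tdir = run_dir / "timecourse"
    tdir.mkdir(exist_ok=True)

    # RNA: TMM-scaled counts-per-million, log2(x+1), then fit + cluster
    factors = tmm_factors(expr.counts)
    eff_lib = expr.counts.sum(axis=0) * factors
    cpm = expr.counts.div(eff_lib, axis=1) * 1e6
    log_expr = np.log2(cpm + 1.0)
    rna = timecourse_analysis(log_expr, expr.meta, degree=tc["degree"],
                              r2_cutoff=tc["r2_cutoff"], k=tc["rna_k"],
                              seed=seed)
    factors.to_frame().to_csv(tdir / "tmm_factors.tsv", sep="\t",
                              index_label="sample")
    rna.table.to_csv(tdir / "rna_timecourse.tsv", sep="\t")

    # enhancer mark signal: windowed RPM per sample, same fit + cluster
    mark = tc["mark"]
    tracks = {f"{tp}_rep{r+1}": marks.tracks[(tp, mark, r)]
              for tp in sim_cfg.timepoint_labels
              for r in range(sim_cfg.n_replicates)}
    sig = signal_matrix(tracks, expr.genes, tc["enhancer_scheme"], expr.meta,
                        mark)
    sig_result = timecourse_analysis(sig.values, sig.meta, degree=tc["degree"],
                                     r2_cutoff=tc["r2_cutoff"],
                                     k=tc["mark_k"], seed=seed)
    sig.values.to_csv(tdir / f"{mark}_rpm.tsv", sep="\t", index_label="gene")
    sig_result.table.to_csv(tdir / f"{mark}_timecourse.tsv", sep="\t")
    return rna, sig, sig_result, log_expr


def stage_correlate(run_dir: Path, cfg: dict, expr, marks, sim_cfg,
                    rna_result, seed: int):
    co = cfg["correlate"]
    _log_stage(run_dir, "correlate", co)
    cdir = run_dir / "correlation"
    cdir.mkdir(exist_ok=True)
    gene_lengths = pd.Series(
        (expr.genes["end"] - expr.genes["start"]).to_numpy(),
        index=expr.genes["name"])
    fpkm_mat = fpkm(expr.counts, gene_lengths, expr.library_sizes)
    em = ExpressionMatrix(values=fpkm_mat, meta=expr.meta,
                          normalization="fpkm")
    mark = co["mark"]
    tracks = {f"{tp}_rep{r+1}": marks.tracks[(tp, mark, r)]
              for tp in sim_cfg.timepoint_labels
              for r in range(sim_cfg.n_replicates)}
    sig = signal_matrix(tracks, expr.genes, co["scheme"], expr.meta, mark)
    dyn = list(rna_result.dynamic_features)
    gene_set = dyn if dyn else list(fpkm_mat.index)
    corr = timecourse_correlation(em, sig, gene_set)
    corr.to_csv(cdir / "mark_expression_correlation.tsv", sep="\t")
    k_stage = min(co["stage_k"], len(gene_set))
    stages = stagewise_heatmap_table(em, gene_set, k=k_stage, seed=seed)
    stages.to_csv(cdir / "stage_clusters.tsv", sep="\t")
    return corr, stages


def stage_report(run_dir: Path, results: dict):
    _log_stage(run_dir, "report", {})
    cio.write_json(results, run_dir / "report.json")


# --------------------------------------------------------------------------- #

def run_pipeline(run_dir, config: dict | None = None, seed: int = 0) -> dict:
    """Run every stage in order; returns the report dictionary."""
    run_dir = Path(run_dir)
    cfg = config if config is not None else load_config(seed=seed)
    handler = _setup_run_logging(run_dir)
    t0 = time.time()
    try:
        sim_cfg, truth, marks, expr = stage_simulate(run_dir, cfg)
        bts = stage_binarize(run_dir, cfg, sim_cfg, marks=marks)
        model = stage_train(run_dir, cfg, bts, seed=seed)
        segs = stage_decode(run_dir, cfg, bts, model, sim_cfg)
        matrix, fractions, origins, dom = stage_dynamics(
            run_dir, cfg, segs, expr.genes, sim_cfg)
        rna, sig, sig_result, log_expr = stage_timecourse(
            run_dir, cfg, expr, marks, sim_cfg, seed=seed)
        corr, stages = stage_correlate(run_dir, cfg, expr, marks, sim_cfg,
                                       rna, seed=seed)
        tps = list(sim_cfg.timepoint_labels)
        report = {
            "seed": seed,
            "version": __version__,
            "n_bins": sim_cfg.grid.total_bins,
            "n_genes": len(expr.genes),
            "model_K": model.K,
            "model_log_likelihood": model.log_likelihood,
            "category_fractions": {tp: fractions.loc[tp].to_dict()
                                   for tp in tps},
            "enhancer_origin_fractions": origins.to_dict(),
            "n_dynamic_genes": int(rna.table["dynamic"].sum()),
            "rna_cluster_k": rna.chosen_k,
            "n_dynamic_mark_features": int(sig_result.table["dynamic"].sum()),
            "mark_cluster_k": sig_result.chosen_k,
            "median_mark_expression_r": float(corr["r"].median()),
            "elapsed_s": time.time() - t0,
        }
        stage_report(run_dir, report)
        return report
    finally:
        logging.getLogger("chromdyn").removeHandler(handler)
        handler.close()
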