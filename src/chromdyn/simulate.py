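"""Synthetic five-time-point, three-replicate chromatin time course.

Emulates the study design the pipeline targets: a small genome tiled into
200-bp bins, hidden per-bin chromatin states following planted
(start-category -> end-category) trajectories, per-state Bernoulli presence of
five histone marks, Poisson read counts over an input background, and gene
expression coupled to four planted temporal archetypes. Everything carries a
known ground truth so each downstream stage can be scored.

Spatial coherence: states are drawn in contiguous runs (geometric run lengths,
mean 5 bins) rather than i.i.d. bins, mimicking chromatin domains. Trajectory
types are allocated to runs by largest-remainder quotas so the realized
(t0, tEnd) genome fractions match the requested mixture to within one run.
Gene neighborhoods (gene body +/- flank) are planted as single homogeneous
runs, which makes each gene's dominant-state truth exact. Replicates share the
hidden state path and differ only in Bernoulli presence and count noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._constants import CATEGORIES, MARKS
from .grid import BinGrid, BinnedTrack
from . import io as cio

# ---------------------------------------------------------------------------- #
# default planted model: 6 states = one per category + a weak/poised enhancer
# ---------------------------------------------------------------------------- #

DEFAULT_STATE_NAMES = (
    "promoter", "enhancer_strong", "enhancer_weak",
    "repressed", "heterochromatin", "quiescent",
)

# rows: states, cols: MARKS = (H3K27ac, H3K4me1, H3K4me3, H3K27me3, H3K9me3)
DEFAULT_EMISSION_TRUTH = np.array([
    [0.70, 0.10, 0.90, 0.05, 0.02],   # promoter
    [0.90, 0.85, 0.10, 0.02, 0.02],   # strong enhancer
    [0.10, 0.75, 0.05, 0.05, 0.02],   # weak/poised enhancer (K4me1, low K27ac)
    [0.02, 0.05, 0.10, 0.85, 0.05],   # Polycomb-repressed
    [0.02, 0.02, 0.02, 0.10, 0.90],   # heterochromatin
    [0.02, 0.02, 0.02, 0.02, 0.02],   # quiescent
])

DEFAULT_CATEGORY_OF_STATE = {
    1: "promoter", 2: "enhancer", 3: "enhancer",
    4: "repressed", 5: "heterochromatin", 6: "quiescent",
}

# genome fractions by (category at t0 -> category at tEnd); the enhancer
# compartment grows over the course, at the expense of quiescent, promoter and
# repressed ground, echoing an inflammation-to-tumor chromatin trajectory.
DEFAULT_TRAJECTORY_MIX = {
    ("quiescent", "quiescent"): 0.55,
    ("quiescent", "enhancer"): 0.10,
    ("promoter", "enhancer"): 0.04,
    ("repressed", "enhancer"): 0.02,
    ("promoter", "promoter"): 0.08,
    ("enhancer", "enhancer"): 0.08,
    ("repressed", "repressed"): 0.05,
    ("heterochromatin", "heterochromatin"): 0.05,
    ("quiescent", "heterochromatin"): 0.03,
}

# log2-FPKM archetype means over the five time points (weeks 0,2,4,7,10):
# late induction, plateau-then-decline, early transient, monotone decline.
DEFAULT_ARCHETYPE_MEANS = np.array([
    [3.0, 3.1, 3.4, 4.8, 6.5],
    [3.0, 5.5, 5.5, 5.0, 3.5],
    [3.0, 6.0, 4.8, 3.8, 3.2],
    [6.0, 5.2, 4.3, 3.4, 2.6],
])

DEFAULT_TIMEPOINTS = ("control", "2w", "4w", "7w", "10w")
DEFAULT_WEEKS = (0.0, 2.0, 4.0, 7.0, 10.0)


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic time course."""

    chrom_sizes: tuple = (("chr1", 1_200_000), ("chr2", 800_000))
    bin_size: int = 200
    n_timepoints: int = 5
    n_replicates: int = 3
    timepoint_labels: tuple = DEFAULT_TIMEPOINTS
    weeks: tuple = DEFAULT_WEEKS
    emission_truth: np.ndarray = field(
        default_factory=lambda: DEFAULT_EMISSION_TRUTH.copy())
    state_names: tuple = DEFAULT_STATE_NAMES
    category_of_state: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_OF_STATE))
    trajectory_mix: dict = field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORY_MIX))
    mean_run_bins: float = 5.0
    bg_rate: float = 1.0
    fg_rate: float = 20.0
    n_genes: int = 200
    gene_length: int = 2_000
    gene_flank: int = 2_000
    expr_library_size: float = 5e6
    archetype_means: np.ndarray = field(
        default_factory=lambda: DEFAULT_ARCHETYPE_MEANS.copy())
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        self.emission_truth = np.asarray(self.emission_truth, dtype=np.float64)
        self.archetype_means = np.asarray(self.archetype_means, dtype=np.float64)
        total = sum(self.trajectory_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"trajectory_mix fractions sum to {total}, not 1")
        for (a, b) in self.trajectory_mix:
            if a not in CATEGORIES or b not in CATEGORIES:
                raise ConfigError(f"unknown category in trajectory {(a, b)}")
        if np.any((self.emission_truth < 0) | (self.emission_truth > 1)):
            raise ConfigError("emission_truth probabilities outside [0,1]")
        if self.fg_rate <= self.bg_rate:
            raise ConfigError("fg_rate must exceed bg_rate")
        if self.n_timepoints != len(self.timepoint_labels) or \
                self.n_timepoints != len(self.weeks):
            raise ConfigError("timepoint labels/weeks inconsistent with n_timepoints")
        if self.archetype_means.shape[1] != self.n_timepoints:
            raise ConfigError("archetype_means must have one column per timepoint")
        K = self.emission_truth.shape[0]
        if set(self.category_of_state) != set(range(1, K + 1)):
            raise ConfigError("category_of_state must cover states 1..K")
        missing = ({c for pair in self.trajectory_mix for c in pair}
                   - set(self.category_of_state.values()))
        if missing:
            raise ConfigError(f"trajectory_mix uses categories with no planted "
                              f"state: {missing}")

    @property
    def grid(self) -> BinGrid:
        return BinGrid(self.chrom_sizes, self.bin_size)

    @property
    def marks(self) -> tuple:
        return MARKS

    def states_of_category(self, cat: str) -> list[int]:
        return [s for s, c in self.category_of_state.items() if c == cat]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["emission_truth"] = self.emission_truth.tolist()
        d["archetype_means"] = self.archetype_means.tolist()
        d["trajectory_mix"] = {f"{a}->{b}": v
                               for (a, b), v in self.trajectory_mix.items()}
        d["category_of_state"] = {str(k): v
                                  for k, v in self.category_of_state.items()}
        d["chrom_sizes"] = [list(t) for t in self.chrom_sizes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "trajectory_mix" in d:
            d["trajectory_mix"] = {tuple(k.split("->")): v
                                   for k, v in d["trajectory_mix"].items()}
        if "category_of_state" in d:
            d["category_of_state"] = {int(k): v
                                      for k, v in d["category_of_state"].items()}
        if "chrom_sizes" in d:
            d["chrom_sizes"] = tuple(tuple(t) for t in d["chrom_sizes"])
        for key in ("timepoint_labels", "weeks", "state_names"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, for recovery scoring."""

    config: SimulationConfig
    state_matrix_truth: np.ndarray            # (m, n) 1-based state ids
    category_matrix_truth: np.ndarray         # (m, n) category names
    genes: pd.DataFrame                       # BED6 gene annotation
    dominant_state_truth: pd.DataFrame        # gene x timepoint categories
    emission_truth: np.ndarray
    cluster_truth: pd.Series | None = None    # gene -> archetype id (1..4)
    presence_truth: dict | None = None        # (tp, mark, rep) -> bool vector

    def validate(self):
        m, n = self.config.grid.total_bins, self.config.n_timepoints
        if self.state_matrix_truth.shape != (m, n):
            raise ValueError("state matrix truth has wrong shape")
        if self.cluster_truth is not None and \
                not self.genes["name"].isin(self.cluster_truth.index).all():
            raise ValueError("every gene needs a cluster_truth entry")


# ---------------------------------------------------------------------------- #
# gene placement
# ---------------------------------------------------------------------------- #

def place_genes(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic, non-overlapping, evenly spaced gene placement.

    Genes (with their flanks) never overlap each other or chromosome edges;
    starts/ends snap to bin boundaries so a gene window is a clean bin block.
    """
    footprint = config.gene_length + 2 * config.gene_flank
    margin = config.gene_flank + config.bin_size
    total_len = sum(n for _, n in config.chrom_sizes)
    genes = []
    gi = 0
    for chrom, clen in config.chrom_sizes:
        quota = int(round(config.n_genes * clen / total_len))
        quota = min(quota, config.n_genes - gi)
        usable = clen - 2 * margin
        if quota <= 0:
            continue
        pitch = usable / quota
        if pitch < footprint:
            raise ConfigError(
                f"genome too small to place {config.n_genes} genes "
                f"({footprint} bp each incl. flanks)")
        for g in range(quota):
            start = margin + int(g * pitch)
            start = (start // config.bin_size) * config.bin_size
            gi += 1
            genes.append({
                "chrom": chrom, "start": start,
                "end": start + config.gene_length,
                "name": f"gene{gi:04d}", "score": 0,
                "strand": "+" if gi % 2 else "-",
            })
    if gi < config.n_genes:
        raise ConfigError("gene quota rounding left genes unplaced; "
                          "adjust n_genes or chromosome sizes")
    return pd.DataFrame(genes)


# ---------------------------------------------------------------------------- #
# state trajectories
# ---------------------------------------------------------------------------- #

def _quota_assign(run_lengths: np.ndarray, pairs: list, fracs: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Assign a trajectory-pair index to each run so realized bin fractions
    match ``fracs`` (largest-remainder quotas; runs visited in random order)."""
    total = int(run_lengths.sum())
    quota = fracs * total
    remaining = quota.copy()
    order = rng.permutation(len(run_lengths))
    choice = np.empty(len(run_lengths), dtype=np.int64)
    for ri in order:
        j = int(np.argmax(remaining))
        choice[ri] = j
        remaining[j] -= run_lengths[ri]
    return choice


def simulate_state_trajectories(config: SimulationConfig):
    """Draw the planted bins x timepoints state matrix.

    Returns ``(truth, state_matrix)``; the truth also carries the gene
    annotation and each gene's dominant-state truth (its window is planted as
    one homogeneous run).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    grid = config.grid
    genes = place_genes(config)
    n_tp = config.n_timepoints
    pairs = list(config.trajectory_mix.keys())
    fracs = np.array([config.trajectory_mix[p] for p in pairs])

    # carve runs chromosome by chromosome: gene windows are fixed runs,
    # gaps are filled with geometric-length runs (mean mean_run_bins)
    run_bounds: list[tuple[int, int]] = []   # global [lo, hi) bin ranges
    gene_run_index: dict[str, int] = {}
    p_geo = 1.0 / config.mean_run_bins
    for chrom, _ in config.chrom_sizes:
        sl = grid.chrom_slice(chrom)
        gsub = genes[genes["chrom"] == chrom]
        anchors = []
        for _, g in gsub.iterrows():
            lo, hi = grid.interval_bins(chrom, g["start"] - config.gene_flank,
                                        g["end"] + config.gene_flank)
            anchors.append((lo, hi, g["name"]))
        anchors.sort()
        cursor = sl.start
        for lo, hi, name in anchors + [(sl.stop, sl.stop, None)]:
            while cursor < lo:
                run = min(int(rng.geometric(p_geo)), lo - cursor)
                run_bounds.append((cursor, cursor + run))
                cursor += run
            if name is not None:
                gene_run_index[name] = len(run_bounds)
                run_bounds.append((lo, hi))
                cursor = hi

    lengths = np.array([hi - lo for lo, hi in run_bounds], dtype=np.int64)
    choice = _quota_assign(lengths, pairs, fracs, rng)

    # realize category trajectories and concrete states per run
    cat_matrix = np.empty((grid.total_bins, n_tp), dtype=object)
    state_matrix = np.empty((grid.total_bins, n_tp), dtype=np.int64)
    for (lo, hi), ci in zip(run_bounds, choice):
        c0, c1 = pairs[ci]
        switch = n_tp if c0 == c1 else int(rng.integers(1, n_tp))
        state0 = int(rng.choice(config.states_of_category(c0)))
        state1 = state0 if c0 == c1 else int(rng.choice(
            config.states_of_category(c1)))
        for t in range(n_tp):
            cat, st = (c0, state0) if t < switch else (c1, state1)
            cat_matrix[lo:hi, t] = cat
            state_matrix[lo:hi, t] = st

    dom = {}
    for name, ri in gene_run_index.items():
        lo, _ = run_bounds[ri]
        dom[name] = list(cat_matrix[lo, :])
    dominant = pd.DataFrame.from_dict(dom, orient="index",
                                      columns=list(config.timepoint_labels))
    dominant = dominant.loc[genes["name"]]
    dominant.index.name = "gene"

    truth = PlantedTruth(
        config=config,
        state_matrix_truth=state_matrix,
        category_matrix_truth=cat_matrix,
        genes=genes,
        dominant_state_truth=dominant,
        emission_truth=config.emission_truth.copy(),
    )
    truth.validate()
    return truth, state_matrix


# ---------------------------------------------------------------------------- #
# mark counts
# ---------------------------------------------------------------------------- #

@dataclass
class MarkData:
    """Simulated binned count tracks: marks, inputs and presence truth."""

    tracks: dict       # (timepoint, mark, rep) -> BinnedTrack
    inputs: dict       # (timepoint, rep) -> BinnedTrack


def simulate_mark_counts(truth: PlantedTruth, config: SimulationConfig) -> MarkData:
    """Poisson counts per (timepoint, mark, replicate) plus input tracks.

    Per bin and replicate, mark presence ~ Bernoulli(emission_truth[state, mark]);
    counts ~ Poisson(fg_rate) where present, Poisson(bg_rate) otherwise; input
    tracks are pure Poisson(bg_rate). The drawn presence indicators are kept on
    the truth object for binarization scoring.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    grid = config.grid
    m = grid.total_bins
    tracks, inputs, presence = {}, {}, {}
    for t, tp in enumerate(config.timepoint_labels):
        states0 = truth.state_matrix_truth[:, t] - 1
        for j, mark in enumerate(config.marks):
            p = config.emission_truth[states0, j]
            for r in range(config.n_replicates):
                present = rng.random(m) < p
                lam = np.where(present, config.fg_rate, config.bg_rate)
                counts = rng.poisson(lam).astype(np.float64)
                tracks[(tp, mark, r)] = BinnedTrack(grid, counts)
                presence[(tp, mark, r)] = present
        for r in range(config.n_replicates):
            inputs[(tp, r)] = BinnedTrack(
                grid, rng.poisson(config.bg_rate, size=m).astype(np.float64))
    truth.presence_truth = presence
    return MarkData(tracks=tracks, inputs=inputs)


# ---------------------------------------------------------------------------- #
# expression
# ---------------------------------------------------------------------------- #

@dataclass
class ExpressionData:
    counts: pd.DataFrame
    fpkm: pd.DataFrame
    genes: pd.DataFrame
    meta: pd.DataFrame
    library_sizes: pd.Series


def simulate_expression(truth: PlantedTruth,
                        config: SimulationConfig) -> ExpressionData:
    """Archetype-driven expression counts and FPKM for the planted genes.

    Each gene gets one of the four temporal archetypes (balanced assignment,
    random order); per replicate, log2 FPKM = archetype mean at the time point
    + Normal(0, noise_sd). Counts are Poisson with mean
    FPKM x length_kb x library_millions at a fixed nominal library size.
    """
    if config.n_genes < config.archetype_means.shape[0]:
        raise ConfigError("need at least one gene per archetype")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    genes = truth.genes
    n_arch = config.archetype_means.shape[0]
    arch = np.tile(np.arange(n_arch), -(-len(genes) // n_arch))[:len(genes)]
    rng.shuffle(arch)
    cluster_truth = pd.Series(arch + 1, index=genes["name"], name="archetype")

    samples, meta_rows = [], []
    log2v = {}
    for t, tp in enumerate(config.timepoint_labels):
        for r in range(config.n_replicates):
            s = f"{tp}_rep{r+1}"
            samples.append(s)
            meta_rows.append({"sample": s, "timepoint": tp,
                              "week": config.weeks[t], "replicate": r + 1})
            mu = config.archetype_means[arch, t]
            log2v[s] = mu + rng.normal(0.0, config.noise_sd, size=len(genes))
    fpkm_vals = pd.DataFrame({s: 2.0 ** v for s, v in log2v.items()},
                             index=genes["name"])
    length_kb = (genes["end"] - genes["start"]).to_numpy() / 1e3
    lib_m = config.expr_library_size / 1e6
    lam = fpkm_vals.mul(length_kb * lib_m, axis=0)
    counts = pd.DataFrame(rng.poisson(lam.to_numpy()).astype(np.int64),
                          index=fpkm_vals.index, columns=fpkm_vals.columns)
    meta = pd.DataFrame(meta_rows)
    truth.cluster_truth = cluster_truth
    truth.validate()
    return ExpressionData(
        counts=counts, fpkm=fpkm_vals, genes=genes, meta=meta,
        library_sizes=pd.Series(config.expr_library_size, index=samples,
                                name="library_size"),
    )


# ---------------------------------------------------------------------------- #
# full fixture + on-disk layout
# ---------------------------------------------------------------------------- #

def simulate_dataset(config: SimulationConfig):
    """Run all three generators; returns (truth, mark_data, expr_data)."""
    truth, _ = simulate_state_trajectories(config)
    marks = simulate_mark_counts(truth, config)
    expr = simulate_expression(truth, config)
    return truth, marks, expr


def write_dataset(out_dir, config: SimulationConfig, truth: PlantedTruth,
                  marks: MarkData, expr: ExpressionData) -> dict:
    """Write the fixture as bedGraph/BED/TSV plus a JSON manifest of the truth."""
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "config": config.to_dict(),
                "library_sizes": {}, "files": []}

    def _rec(path):
        manifest["files"].append(str(path.relative_to(out)))

    for (tp, mark, r), tr in marks.tracks.items():
        p = out / "tracks" / f"{mark}_{tp}_rep{r+1}.bedGraph"
        cio.write_bedgraph(tr, p)
        manifest["library_sizes"][f"{mark}_{tp}_rep{r+1}"] = tr.library_size
        _rec(p)
    for (tp, r), tr in marks.inputs.items():
        p = out / "tracks" / f"input_{tp}_rep{r+1}.bedGraph"
        cio.write_bedgraph(tr, p)
        manifest["library_sizes"][f"input_{tp}_rep{r+1}"] = tr.library_size
        _rec(p)

    cio.write_genes_bed(expr.genes, out / "genes.bed"); _rec(out / "genes.bed")
    cio.write_matrix_tsv(expr.counts, out / "expression_counts.tsv", "gene")
    _rec(out / "expression_counts.tsv")
    cio.write_matrix_tsv(expr.fpkm, out / "expression_fpkm.tsv", "gene")
    _rec(out / "expression_fpkm.tsv")
    cio.write_sample_meta(expr.meta, out / "samples.tsv"); _rec(out / "samples.tsv")

    smt = config.grid.bin_table()
    for j, tp in enumerate(config.timepoint_labels):
        smt[f"state_{tp}"] = truth.state_matrix_truth[:, j]
        smt[f"category_{tp}"] = truth.category_matrix_truth[:, j]
    smt.to_csv(out / "state_matrix_truth.tsv", sep="\t", index=False)
    _rec(out / "state_matrix_truth.tsv")
    truth.dominant_state_truth.to_csv(out / "dominant_state_truth.tsv", sep="\t")
    _rec(out / "dominant_state_truth.tsv")
    truth.cluster_truth.to_csv(out / "cluster_truth.tsv", sep="\t")
    _rec(out / "cluster_truth.tsv")
    config.grid.to_json(out / "grid.json"); _rec(out / "grid.json")

    cio.write_json(manifest, out / "manifest.json")
    return manifest
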