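"""Readers and writers for the plain-text formats the pipeline exchanges.

bedGraph and BED are 0-based half-open. Matrices travel as TSV with a header
row and a feature-id index column; sample metadata as a TSV sidecar with
columns ``sample, timepoint, week, replicate``.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .grid import BinGrid, BinnedTrack

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bedgraph(track: BinnedTrack, path, omit_zero: bool = True) -> None:
    """Write a binned track as bedGraph (one record per non-zero bin)."""
    tab = track.grid.bin_table()
    tab["value"] = track.values
    if omit_zero:
        tab = tab[tab["value"] != 0]
    tab.to_csv(path, sep="\t", header=False, index=False)


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    genes[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path) -> pd.DataFrame:
    """Read a BED6 gene annotation (chrom, start, end, gene id, score, strand)."""
    genes = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS,
                        dtype={"chrom": str, "name": str, "strand": str})
    genes["start"] = genes["start"].astype(int)
    genes["end"] = genes["end"].astype(int)
    return genes


def write_matrix_tsv(values: pd.DataFrame, path, index_label: str = "feature") -> None:
    values.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample": str, "timepoint": str})
    return meta


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_segmentation_bed(segmentation, path) -> None:
    """Segmentation as BED: name=state id, extra column = collapsed category."""
    tab = segmentation.grid.bin_table()
    tab["state"] = [f"E{s}" for s in segmentation.states]
    tab["category"] = segmentation.categories
    tab.to_csv(path, sep="\t", header=False, index=False)


def read_segmentation_bed(path, grid: BinGrid):
    """Round-trip a segmentation BED back into a Segmentation object."""
    from .hmm import Segmentation

    tab = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "state", "category"])
    if len(tab) != grid.total_bins:
        raise ValueError("segmentation BED does not match grid")
    states = tab["state"].str.lstrip("E").astype(int).to_numpy()
    return Segmentation(grid, states, np.ones(len(tab)),
                        categories_override=tab["category"].to_numpy())


def write_binarized_tsv(presence: np.ndarray, marks, grid: BinGrid, path) -> None:
    """Binarized bins x marks matrix with coordinates and a mark-naming header."""
    tab = grid.bin_table()
    for j, m in enumerate(marks):
        tab[m] = presence[:, j].astype(int)
    tab.to_csv(path, sep="\t", index=False)


def read_binarized_tsv(path, grid: BinGrid):
    tab = pd.read_csv(path, sep="\t")
    marks = [c for c in tab.columns if c not in ("chrom", "start", "end")]
    if len(tab) != grid.total_bins:
        raise ValueError("binarized matrix does not match grid")
    return tab[marks].to_numpy(dtype=np.uint8), marks
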