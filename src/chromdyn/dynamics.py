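"""Cross-time-point chromatin-state accounting.

The central object is the bins x timepoints state matrix (m x n: m 200-bp
bins, n time points). From it we derive category fractions per time point,
5x5 transition flow matrices between any two time points (the table behind an
alluvial/Sankey plot), origin fractions of a target category, and the dominant
chromatin state of every gene (modal category over the bins in the gene body
+/- flank window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._constants import CATEGORIES
from .grid import BinGrid
from .hmm import Segmentation

logger = logging.getLogger(__name__)

_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass
class StateMatrix:
    """Per-bin raw state and collapsed category across ordered time points."""

    grid: BinGrid
    timepoints: tuple                  # ordered labels, e.g. control, 2w, ...
    states: np.ndarray                 # (m, n) 1-based raw state ids
    category_codes: np.ndarray         # (m, n) indices into CATEGORIES

    def __post_init__(self):
        self.timepoints = tuple(self.timepoints)
        m, n = self.grid.total_bins, len(self.timepoints)
        if self.states.shape != (m, n) or self.category_codes.shape != (m, n):
            raise ValueError("state matrix shape inconsistent with grid/timepoints")
        if self.category_codes.min() < 0 or self.category_codes.max() >= len(CATEGORIES):
            raise ValueError("invalid category code")

    def col(self, timepoint) -> int:
        try:
            return self.timepoints.index(timepoint)
        except ValueError:
            raise KeyError(f"timepoint {timepoint!r} not in matrix") from None

    def categories(self, timepoint) -> np.ndarray:
        codes = self.category_codes[:, self.col(timepoint)]
        return np.asarray(CATEGORIES, dtype=object)[codes]

    def to_frame(self) -> pd.DataFrame:
        tab = self.grid.bin_table()
        for j, tp in enumerate(self.timepoints):
            tab[f"state_{tp}"] = self.states[:, j]
            tab[f"category_{tp}"] = np.asarray(CATEGORIES)[self.category_codes[:, j]]
        return tab


def category_codes_from(values) -> np.ndarray:
    """Map category names to their fixed integer codes."""
    arr = np.asarray(values)
    out = np.empty(arr.shape, dtype=np.int8)
    for c, i in _CAT_INDEX.items():
        out[arr == c] = i
    unknown = ~np.isin(arr, CATEGORIES)
    if unknown.any():
        raise ValueError(f"unknown categories: {set(arr[unknown])}")
    return out


def build_state_matrix(
    segmentations: Mapping[str, Segmentation] | Sequence[tuple[str, Segmentation]],
) -> StateMatrix:
    """Assemble the m x n matrix from one segmentation per time point.

    Input order defines column (time) order; all segmentations must share one
    grid. Raw states and collapsed categories are both retained.
    """
    items = list(segmentations.items()) if isinstance(segmentations, Mapping) \
        else list(segmentations)
    if len(items) < 2:
        raise ValueError("need at least two timepoints")
    grid = items[0][1].grid
    for tp, seg in items:
        if seg.grid != grid:
            raise ValueError(f"segmentation for {tp!r} is on a different grid")
    states = np.column_stack([seg.states for _, seg in items])
    codes = np.column_stack([category_codes_from(seg.categories)
                             for _, seg in items])
    return StateMatrix(grid, tuple(tp for tp, _ in items), states, codes)


def state_matrix_from_categories(grid: BinGrid, timepoints: Sequence[str],
                                 categories: np.ndarray,
                                 states: np.ndarray | None = None) -> StateMatrix:
    """Build a StateMatrix directly from category names (e.g. planted truth)."""
    codes = category_codes_from(categories)
    if states is None:
        states = codes.astype(np.int64) + 1
    return StateMatrix(grid, tuple(timepoints), states, codes)


# --------------------------------------------------------------------------- #
# analytics
# --------------------------------------------------------------------------- #

def category_fraction_timecourse(matrix: StateMatrix) -> pd.DataFrame:
    """Fraction of the genome in each category at each time point."""
    m = matrix.grid.total_bins
    rows = []
    for j, tp in enumerate(matrix.timepoints):
        counts = np.bincount(matrix.category_codes[:, j],
                             minlength=len(CATEGORIES))
        rows.append(counts / m)
    return pd.DataFrame(rows, index=list(matrix.timepoints),
                        columns=list(CATEGORIES))


@dataclass
class TransitionSummary:
    """5x5 category flow between two time points, in bins and percentages."""

    source: str
    target: str
    counts: pd.DataFrame       # rows: source category, cols: target category
    row_pct: pd.DataFrame      # of each source category, where did it go
    col_pct: pd.DataFrame      # of each target category, where did it come from

    def to_long(self) -> pd.DataFrame:
        """Long-format (source, target, count, pct_of_source, pct_of_target)
        table, directly consumable by Sankey/alluvial plotters."""
        recs = []
        for s in CATEGORIES:
            for t in CATEGORIES:
                recs.append({
                    "source": s, "target": t,
                    "count": int(self.counts.loc[s, t]),
                    "pct_of_source": self.row_pct.loc[s, t],
                    "pct_of_target": self.col_pct.loc[s, t],
                })
        return pd.DataFrame(recs)


def transition_flows(matrix: StateMatrix, t_from, t_to) -> TransitionSummary:
    """Category flow matrix between two time points; total flow = total bins."""
    a = matrix.category_codes[:, matrix.col(t_from)]
    b = matrix.category_codes[:, matrix.col(t_to)]
    nC = len(CATEGORIES)
    counts = np.bincount(a * nC + b, minlength=nC * nC).reshape(nC, nC)
    cdf = pd.DataFrame(counts, index=list(CATEGORIES), columns=list(CATEGORIES))
    with np.errstate(invalid="ignore", divide="ignore"):
        row = cdf.div(cdf.sum(axis=1), axis=0) * 100.0
        col = cdf.div(cdf.sum(axis=0), axis=1) * 100.0
    return TransitionSummary(str(t_from), str(t_to), cdf, row, col)


def origin_fractions(matrix: StateMatrix, target_timepoint, target_category: str,
                     reference_timepoint) -> pd.Series:
    """Where did a category's bins come from?

    Among bins in ``target_category`` at ``target_timepoint``, the fraction
    that carried each category at ``reference_timepoint``. Sums to 1. This is
    the normalized target-category column of the reference->target flow matrix.
    """
    if target_category not in CATEGORIES:
        raise ValueError(f"unknown category {target_category!r}")
    tgt = matrix.category_codes[:, matrix.col(target_timepoint)]
    ref = matrix.category_codes[:, matrix.col(reference_timepoint)]
    sel = tgt == _CAT_INDEX[target_category]
    n = int(sel.sum())
    if n == 0:
        raise ValueError(
            f"no bins in category {target_category!r} at {target_timepoint!r} "
            "(zero denominator)")
    counts = np.bincount(ref[sel], minlength=len(CATEGORIES))
    return pd.Series(counts / n, index=list(CATEGORIES), name=target_category)


def dominant_gene_state(matrix: StateMatrix, genes: pd.DataFrame,
                        flank_bp: int = 2000) -> pd.DataFrame:
    """Dominant (modal) chromatin category per gene and time point.

    A gene's window is its body extended by ``flank_bp`` on both sides,
    strand-independent; every bin overlapping the window counts fully. The
    modal category wins; ties break by the fixed priority
    promoter > enhancer > heterochromatin > repressed > quiescent.
    Genes overlapping zero bins are reported as NaN rows and logged.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    nC = len(CATEGORIES)
    out = {}
    missing = []
    for _, g in genes.iterrows():
        name = g["name"]
        if g["chrom"] not in matrix.grid.chroms:
            missing.append(name)
            out[name] = [np.nan] * len(matrix.timepoints)
            continue
        lo, hi = matrix.grid.interval_bins(
            g["chrom"], g["start"] - flank_bp, g["end"] + flank_bp)
        if hi <= lo:
            missing.append(name)
            out[name] = [np.nan] * len(matrix.timepoints)
            continue
        row = []
        for j in range(len(matrix.timepoints)):
            counts = np.bincount(matrix.category_codes[lo:hi, j], minlength=nC)
            # argmax over priority-ordered categories: first max wins the tie
            row.append(CATEGORIES[int(np.argmax(counts))])
        out[name] = row
    if missing:
        logger.warning("dominant_gene_state: %d genes overlap no bins: %s",
                       len(missing), missing[:5])
    tab = pd.DataFrame.from_dict(out, orient="index",
                                 columns=list(matrix.timepoints))
    tab.index.name = "gene"
    return tab
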