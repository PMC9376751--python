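"""Coverage binning and input-adjusted Poisson binarization of histone marks.

A mark's binned counts are reduced to per-bin presence/absence calls by an
upper-tail Poisson test against a background rate derived from the matched
input (whole-cell extract) track: for each bin the expected rate is

    lambda = max(global mark mean, input count x library-size ratio, 1e-6)

and the bin is called present iff ``P(X >= observed | lambda) <= pvalue_cutoff``
(default 1e-4, the ChromHMM convention). The resulting bins x marks binary
matrix is the observation sequence for the chromatin-state HMM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import poisson

from .grid import BinGrid, BinnedTrack, pool_tracks

logger = logging.getLogger(__name__)

LAMBDA_FLOOR = 1e-6


def _parse_source(source, columns: int):
    """Yield (line_number, fields) from a path or iterate a DataFrame."""
    import pandas as pd

    if isinstance(source, pd.DataFrame):
        return source
    rows = []
    with open(source) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < columns:
                raise ValueError(f"malformed record at line {ln}: {line!r}")
            try:
                if columns == 4:
                    rows.append((parts[0], int(parts[1]), int(parts[2]),
                                 float(parts[3])))
                else:
                    rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"malformed record at line {ln}: {line!r}") from exc
    import pandas as pd

    names = ["chrom", "start", "end", "value"][:columns]
    return pd.DataFrame(rows, columns=names)


def bin_coverage(source, grid: BinGrid, mode: str = "bedgraph") -> BinnedTrack:
    """Aggregate coverage onto a bin grid.

    Parameters
    ----------
    source
        Path to a bedGraph / interval file, or an equivalent DataFrame with
        columns ``chrom, start, end[, value]``.
    mode
        ``"bedgraph"``: each record contributes ``value x overlap_bp / bin_size``
        to every bin it overlaps (i.e. records are per-position depth, so a
        record exactly covering a bin adds its value once).
        ``"reads"``: each interval is one read assigned to the bin holding its
        midpoint.

    Records on chromosomes absent from the grid are skipped with a logged
    warning and counted; malformed lines raise with their line number.
    """
    if mode not in ("bedgraph", "reads"):
        raise ValueError(f"unknown mode {mode!r}")
    ncol = 4 if mode == "bedgraph" else 3
    recs = _parse_source(source, ncol)

    values = np.zeros(grid.total_bins, dtype=np.float64)
    known = recs["chrom"].isin(grid.chroms).to_numpy()
    n_skip = int((~known).sum())
    if n_skip:
        logger.warning("bin_coverage: skipped %d records on unknown chromosomes",
                       n_skip)
    recs = recs[known]
    bs = grid.bin_size
    library = 0.0

    for chrom, sub in recs.groupby("chrom", sort=False):
        off = grid._offsets[chrom]
        clen = grid.chrom_length(chrom)
        start = np.clip(sub["start"].to_numpy(dtype=np.int64), 0, clen)
        end = np.clip(sub["end"].to_numpy(dtype=np.int64), 0, clen)
        ok = end > start
        start, end = start[ok], end[ok]
        if mode == "reads":
            mid = (start + end) // 2
            idx = off + np.minimum(mid // bs, grid.n_bins(chrom) - 1)
            np.add.at(values, idx, 1.0)
            library += len(idx)
            continue
        val = sub["value"].to_numpy(dtype=np.float64)[ok]
        lo = start // bs
        hi = (end - 1) // bs
        single = lo == hi
        # fast path: record within one bin
        np.add.at(values, off + lo[single],
                  val[single] * (end[single] - start[single]) / bs)
        # general path: split across bins
        for s, e, v, l, h in zip(start[~single], end[~single], val[~single],
                                 lo[~single], hi[~single]):
            for b in range(l, h + 1):
                bin_lo = b * bs
                bin_hi = bin_lo + bs
                ov = min(e, bin_hi) - max(s, bin_lo)
                values[off + b] += v * ov / bs

    if mode == "bedgraph":
        library = float(values.sum())
    return BinnedTrack(grid, values, float(library))


def poisson_tail_pvalue(observed, lam):
    """Upper-tail Poisson p-value ``P(X >= observed | lam)``, vectorized."""
    observed = np.asarray(observed)
    return poisson.sf(observed - 1, np.asarray(lam, dtype=np.float64))


def poisson_binarize(mark: BinnedTrack, control: BinnedTrack,
                     pvalue_cutoff: float = 1e-4) -> np.ndarray:
    """Call per-bin mark presence against the input-derived Poisson background.

    Returns a uint8 vector over the grid. Raises on mismatched grids or a
    zero-library control.
    """
    if mark.grid != control.grid:
        raise ValueError("mark and control tracks are on different grids")
    if control.library_size <= 0:
        raise ValueError("control track has zero library size")
    ratio = mark.library_size / control.library_size
    lam = np.maximum(mark.values.mean(), control.values * ratio)
    lam = np.maximum(lam, LAMBDA_FLOOR)
    obs = np.floor(mark.values)
    pvals = poisson_tail_pvalue(obs, lam)
    return ((pvals <= pvalue_cutoff) & (obs > 0)).astype(np.uint8)


@dataclass
class BinarizedTrackSet:
    """Bins x marks presence matrices, one per (timepoint[, replicate]).

    ``presence`` maps a timepoint label (pooled mode) or a
    ``(timepoint, replicate)`` pair (per-replicate mode) to a uint8 matrix of
    shape ``(grid.total_bins, len(marks))``. Mark column order is fixed.
    """

    grid: BinGrid
    marks: tuple
    presence: dict

    def __post_init__(self):
        self.marks = tuple(self.marks)
        for key, mat in self.presence.items():
            if mat.shape != (self.grid.total_bins, len(self.marks)):
                raise ValueError(f"presence matrix for {key!r} has wrong shape")
            if not np.isin(mat, (0, 1)).all():
                raise ValueError(f"presence matrix for {key!r} is not binary")

    def sequences(self, key) -> list[np.ndarray]:
        """One observation sequence per chromosome (HMM never crosses them)."""
        mat = self.presence[key]
        return [mat[self.grid.chrom_slice(c)] for c in self.grid.chroms]

    def grouped_sequences(self, keys: Sequence) -> list[np.ndarray]:
        """Per chromosome, stack several samples (replicates sharing one
        hidden state path) into an (R, T, M) observation array."""
        mats = [self.presence[k] for k in keys]
        return [np.stack([m[self.grid.chrom_slice(c)] for m in mats])
                for c in self.grid.chroms]


def binarize_samples(
    mark_tracks: Mapping[str, Mapping[str, Sequence[BinnedTrack]]],
    control_tracks: Mapping[str, Sequence[BinnedTrack]],
    marks: Sequence[str],
    pvalue_cutoff: float = 1e-4,
    pool_replicates: bool = True,
) -> BinarizedTrackSet:
    """Binarize every (timepoint, mark) against the matched input.

    Parameters
    ----------
    mark_tracks
        ``{timepoint: {mark: [replicate tracks...]}}``.
    control_tracks
        ``{timepoint: [replicate input tracks...]}``.
    pool_replicates
        If True (default) replicate counts are summed per timepoint before
        binarization — one observation sequence per timepoint. Otherwise each
        replicate is binarized against its own input and keyed
        ``(timepoint, replicate_index)``.
    """
    first_tp = next(iter(mark_tracks))
    grid = mark_tracks[first_tp][marks[0]][0].grid
    presence: dict = {}
    for tp, per_mark in mark_tracks.items():
        controls = list(control_tracks[tp])
        if pool_replicates:
            ctl = pool_tracks(controls)
            cols = [poisson_binarize(pool_tracks(list(per_mark[m])), ctl,
                                     pvalue_cutoff) for m in marks]
            presence[tp] = np.column_stack(cols)
        else:
            n_rep = len(controls)
            for r in range(n_rep):
                cols = [poisson_binarize(per_mark[m][r], controls[r],
                                         pvalue_cutoff) for m in marks]
                presence[(tp, r)] = np.column_stack(cols)
    return BinarizedTrackSet(grid=grid, marks=tuple(marks), presence=presence)
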