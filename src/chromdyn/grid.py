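"""Fixed-width genome binning.

All coordinates are 0-based, half-open (BED convention). A :class:`BinGrid`
tiles every chromosome with non-overlapping bins of ``bin_size`` bp; the last,
possibly partial, bin of each chromosome is kept. Bins carry a single global
index so per-bin vectors span the whole genome, and the grid is the coordinate
authority for every track, binarization and segmentation built on top of it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class BinGrid:
    """Non-overlapping tiling of a genome into fixed-size bins.

    Parameters
    ----------
    chrom_sizes
        Iterable of ``(chrom_name, length_bp)`` pairs, in the order bins are
        laid out globally.
    bin_size
        Bin width in bp (default 200).
    """

    def __init__(self, chrom_sizes: Iterable[tuple[str, int]], bin_size: int = 200):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.chrom_sizes: tuple[tuple[str, int], ...] = tuple(
            (str(c), int(n)) for c, n in chrom_sizes
        )
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must be non-empty")
        for c, n in self.chrom_sizes:
            if n <= 0:
                raise ValueError(f"chromosome {c} has non-positive length {n}")
        self.bin_size = int(bin_size)
        self._n_bins = {
            c: -(-n // self.bin_size) for c, n in self.chrom_sizes  # ceil div
        }
        self._offsets: dict[str, int] = {}
        off = 0
        for c, _ in self.chrom_sizes:
            self._offsets[c] = off
            off += self._n_bins[c]
        self.total_bins: int = off  # the "m" of the m x n state matrix

    # ------------------------------------------------------------------ #

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinGrid)
            and self.chrom_sizes == other.chrom_sizes
            and self.bin_size == other.bin_size
        )

    def __repr__(self) -> str:
        return (
            f"BinGrid({len(self.chrom_sizes)} chroms, bin_size={self.bin_size}, "
            f"m={self.total_bins})"
        )

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chrom_sizes)

    def chrom_length(self, chrom: str) -> int:
        for c, n in self.chrom_sizes:
            if c == chrom:
                return n
        raise KeyError(chrom)

    def n_bins(self, chrom: str) -> int:
        return self._n_bins[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        """Global index slice covering one chromosome."""
        off = self._offsets[chrom]
        return slice(off, off + self._n_bins[chrom])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of a single position."""
        if pos < 0 or pos >= self.chrom_length(chrom):
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        return self._offsets[chrom] + pos // self.bin_size

    def interval_bins(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global half-open bin range ``[lo, hi)`` overlapped by an interval.

        The interval is clipped to the chromosome; a fully out-of-range
        interval yields an empty range.
        """
        length = self.chrom_length(chrom)
        start = max(0, int(start))
        end = min(length, int(end))
        if end <= start:
            off = self._offsets[chrom]
            return off, off
        off = self._offsets[chrom]
        lo = off + start // self.bin_size
        hi = off + (end - 1) // self.bin_size + 1
        return lo, hi

    def bin_table(self) -> pd.DataFrame:
        """All bins as a (chrom, start, end) frame in global order."""
        rows = []
        for c, n in self.chrom_sizes:
            nb = self._n_bins[c]
            starts = np.arange(nb, dtype=np.int64) * self.bin_size
            ends = np.minimum(starts + self.bin_size, n)
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    # -- serialization -------------------------------------------------- #

    def to_dict(self) -> dict:
        return {"chrom_sizes": [list(t) for t in self.chrom_sizes],
                "bin_size": self.bin_size}

    @classmethod
    def from_dict(cls, d: dict) -> "BinGrid":
        return cls([(c, n) for c, n in d["chrom_sizes"]], d["bin_size"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BinGrid":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class BinnedTrack:
    """Per-bin non-negative counts on a :class:`BinGrid`.

    ``library_size`` is the total mapped signal the track represents; by
    default the sum of the binned values, so totals are conserved between a
    track and its manifest.
    """

    grid: BinGrid
    values: np.ndarray
    library_size: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.grid.total_bins,):
            raise ValueError(
                f"track length {self.values.shape} != grid bins {self.grid.total_bins}"
            )
        if np.any(self.values < 0):
            raise ValueError("binned values must be non-negative")
        if self.library_size is None:
            self.library_size = float(self.values.sum())

    def pooled_with(self, others: Sequence["BinnedTrack"]) -> "BinnedTrack":
        """Sum this track with replicate tracks on the same grid."""
        vals = self.values.copy()
        lib = self.library_size
        for t in others:
            if t.grid != self.grid:
                raise ValueError("cannot pool tracks on different grids")
            vals += t.values
            lib += t.library_size
        return BinnedTrack(self.grid, vals, lib)


def pool_tracks(tracks: Sequence[BinnedTrack]) -> BinnedTrack:
    """Pool replicate tracks by summing counts and library sizes."""
    if not tracks:
        raise ValueError("no tracks to pool")
    return tracks[0].pooled_with(list(tracks[1:]))
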