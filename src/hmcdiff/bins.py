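"""Fixed-width genome binning and fragment counting.

The genome is tiled with non-overlapping bins of a fixed width (2 kb by
default, the resolution at which hMe-seal pulldown libraries are compared).
Fragments are assigned to the unique bin containing their midpoint, so one
fragment contributes exactly one count — the sampling model a negative
binomial count test assumes.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["BinGrid", "make_bins", "count_fragments", "signal_profile", "signal_at_regions"]


@dataclass(frozen=True)
class BinGrid:
    """Tiling of chromosomes into fixed-width bins.

    Chromosomes are ordered lexicographically; within a chromosome bins are
    ordered by start.  The final bin of a chromosome may be shorter than
    ``binsize`` (it is retained so that in-bounds fragments are conserved).
    """

    binsize: int
    chrom_sizes: dict[str, int]
    _chroms: tuple[str, ...] = field(init=False, repr=False)
    _offsets: dict[str, int] = field(init=False, repr=False)
    _nbins: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.binsize <= 0:
            raise ValueError("binsize must be positive")
        for c, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {c} has non-positive size {size}")
        chroms = tuple(sorted(self.chrom_sizes))
        nbins = {c: -(-self.chrom_sizes[c] // self.binsize) for c in chroms}
        offsets, acc = {}, 0
        for c in chroms:
            offsets[c] = acc
            acc += nbins[c]
        object.__setattr__(self, "_chroms", chroms)
        object.__setattr__(self, "_offsets", offsets)
        object.__setattr__(self, "_nbins", nbins)

    @property
    def chroms(self) -> tuple[str, ...]:
        return self._chroms

    def __len__(self) -> int:
        return sum(self._nbins.values())

    def n_bins(self, chrom: str) -> int:
        return self._nbins[chrom]

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing position ``pos``."""
        if chrom not in self._offsets:
            raise KeyError(chrom)
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offsets[chrom] + pos // self.binsize

    def bin_interval(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of the bin with global index ``index``."""
        for c in self._chroms:
            if index < self._nbins[c]:
                start = index * self.binsize
                return c, start, min(start + self.binsize, self.chrom_sizes[c])
            index -= self._nbins[c]
        raise IndexError("bin index out of range")

    def intervals(self) -> pd.DataFrame:
        """All bins as a DataFrame (chrom, start, end) in grid order."""
        rows = []
        for c in self._chroms:
            size = self.chrom_sizes[c]
            starts = np.arange(self._nbins[c]) * self.binsize
            ends = np.minimum(starts + self.binsize, size)
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def feature_ids(self) -> list[str]:
        iv = self.intervals()
        return [f"{c}:{s}-{e}" for c, s, e in zip(iv.chrom, iv.start, iv.end)]

    def overlapping_bins(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of every bin overlapping [start, end) by >= 1 bp."""
        if chrom not in self._offsets:
            raise KeyError(chrom)
        start = max(start, 0)
        end = min(end, self.chrom_sizes[chrom])
        if end <= start:
            return np.array([], dtype=int)
        first = start // self.binsize
        last = (end - 1) // self.binsize
        return self._offsets[chrom] + np.arange(first, last + 1)


def make_bins(chrom_sizes: dict[str, int], binsize: int = 2000) -> BinGrid:
    """Tile each chromosome with ``binsize`` bins, keeping the final partial bin."""
    return BinGrid(binsize=binsize, chrom_sizes=dict(chrom_sizes))


def count_fragments(
    fragments: dict[str, pd.DataFrame], grid: BinGrid, dedup: bool = True
) -> pd.DataFrame:
    """Count fragments per bin per sample by fragment midpoint.

    ``fragments`` maps sample id to a BED-like DataFrame (chrom, start, end,
    optionally strand).  A fragment lands in the unique bin containing
    ``floor((start + end) / 2)``.  With ``dedup`` on, fragments identical in
    (chrom, start, end, strand) are counted once, emulating PCR-duplicate
    removal.  Fragments on chromosomes absent from the grid are skipped with
    a logged count.
    """
    counts = np.zeros((len(grid), len(fragments)), dtype=np.int64)
    for j, (sample, frags) in enumerate(fragments.items()):
        if len(frags) == 0:
            continue
        df = frags
        if dedup:
            keys = ["chrom", "start", "end"] + (["strand"] if "strand" in df.columns else [])
            df = df.drop_duplicates(subset=keys)
        known = df["chrom"].isin(grid.chroms)
        n_skip = int((~known).sum())
        if n_skip:
            logger.warning("%s: skipped %d fragments on unknown chromosomes", sample, n_skip)
        df = df[known]
        for chrom, sub in df.groupby("chrom", sort=False):
            mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
            size = grid.chrom_sizes[chrom]
            inb = (mids >= 0) & (mids < size)
            n_out = int((~inb).sum())
            if n_out:
                logger.warning("%s: skipped %d out-of-bounds fragments on %s", sample, n_out, chrom)
            idx = grid.bin_index(chrom, 0) + mids[inb] // grid.binsize
            np.add.at(counts[:, j], idx, 1)
    return pd.DataFrame(counts, index=grid.feature_ids(), columns=list(fragments))


def signal_profile(
    signal: np.ndarray, grid: BinGrid, anchors: pd.DataFrame, flank_bins: int
) -> np.ndarray:
    """Mean per-bin signal around anchor regions, by bin offset.

    Position 0 is the bin containing each anchor's midpoint; the returned
    vector has length ``2 * flank_bins + 1``.  Offsets that run off the
    chromosome contribute nothing at that position (the mean is taken over
    the anchors whose window covers it).
    """
    if len(anchors) == 0:
        raise ValueError("no anchor regions")
    signal = np.asarray(signal, dtype=float)
    width = 2 * flank_bins + 1
    total = np.zeros(width)
    n = np.zeros(width)
    for chrom, start, end in zip(anchors["chrom"], anchors["start"], anchors["end"]):
        if chrom not in grid.chroms:
            continue
        mid = (int(start) + int(end)) // 2
        center = grid.bin_index(chrom, min(max(mid, 0), grid.chrom_sizes[chrom] - 1))
        local = center - grid.bin_index(chrom, 0)
        for off in range(-flank_bins, flank_bins + 1):
            b = local + off
            if 0 <= b < grid.n_bins(chrom):
                total[off + flank_bins] += signal[center + off]
                n[off + flank_bins] += 1
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, total / np.maximum(n, 1), np.nan)


def signal_at_regions(signal: np.ndarray, grid: BinGrid, regions: pd.DataFrame) -> np.ndarray:
    """Per-region mean of the per-bin signal, weighted by overlap width."""
    signal = np.asarray(signal, dtype=float)
    out = np.empty(len(regions))
    for i, (chrom, start, end) in enumerate(
        zip(regions["chrom"], regions["start"], regions["end"])
    ):
        if chrom not in grid.chroms:
            raise KeyError(f"region chromosome {chrom} not in grid")
        idx = grid.overlapping_bins(chrom, int(start), int(end))
        if idx.size == 0:
            out[i] = np.nan
            continue
        w = np.empty(idx.size)
        for k, b in enumerate(idx):
            _, bs, be = grid.bin_interval(int(b))
            w[k] = min(be, int(end)) - max(bs, int(start))
        out[i] = float((signal[idx] * w).sum() / w.sum())
    return out
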