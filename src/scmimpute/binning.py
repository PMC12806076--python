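"""Fixed-length genome tiling and NA-aware cell-by-region matrix construction.

The genome is tiled into non-overlapping windows of a fixed length (100 kbp
and 10 kbp are the standard choices).  For each cell and window the average
methylation level of the captured sites is computed; windows in which a cell
captured no site get an explicit NA (mask) entry, which is distinct from an
observed level of zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import CellCallSet, ChromSizes, ValidationError

__all__ = [
    "BinGrid", "RegionMatrix",
    "make_bins", "assign_bin", "aggregate_cell", "build_matrix",
    "drop_all_missing_regions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinGrid:
    """A fixed-length tiling of the genome with a contiguous global region index.

    Regions are 0-based half-open intervals.  Every chromosome contributes
    ``ceil(length / window_length)`` bins; the last bin of a chromosome may
    be shorter than ``window_length``.  Global region indices run
    0..R-1 in chromosome order, then position order.
    """

    window_length: int
    chrom_order: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bins_per_chrom: tuple[int, ...]
    # global index of each chromosome's first bin
    chrom_offsets: tuple[int, ...] = field(default=(), repr=False)

    @property
    def n_regions(self) -> int:
        return sum(self.bins_per_chrom)

    def offset_of(self, chrom: str) -> int:
        try:
            return self.chrom_offsets[self.chrom_order.index(chrom)]
        except ValueError:
            raise ValidationError(f"chromosome {chrom!r} not in grid") from None

    def global_index(self, chrom: str, ordinal: int) -> int:
        i = self.chrom_order.index(chrom)
        if not 0 <= ordinal < self.bins_per_chrom[i]:
            raise ValidationError(
                f"bin ordinal {ordinal} out of range for {chrom!r} "
                f"({self.bins_per_chrom[i]} bins)"
            )
        return self.chrom_offsets[i] + ordinal

    def region_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-region (chrom, start, end) arrays in global index order."""
        chroms = np.empty(self.n_regions, dtype=object)
        starts = np.empty(self.n_regions, dtype=np.int64)
        ends = np.empty(self.n_regions, dtype=np.int64)
        for name, length, nbins, off in zip(
            self.chrom_order, self.chrom_lengths, self.bins_per_chrom, self.chrom_offsets
        ):
            idx = np.arange(nbins)
            chroms[off : off + nbins] = name
            starts[off : off + nbins] = idx * self.window_length
            ends[off : off + nbins] = np.minimum((idx + 1) * self.window_length, length)
        return chroms, starts, ends


@dataclass
class RegionMatrix:
    """Cells x regions average-methylation values with an explicit missingness mask.

    ``mask[i, j]`` is True exactly when cell i captured no site in region j;
    ``values`` is NaN there and lies in [0, 1] everywhere else.
    """

    cell_ids: list[str]
    region_chrom: np.ndarray
    region_start: np.ndarray
    region_end: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    context: str
    window_length: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, r = self.values.shape
        if self.mask.shape != (n, r):
            raise ValidationError("values and mask shapes differ")
        if len(self.cell_ids) != n:
            raise ValidationError("cell_ids length does not match values")
        if not (len(self.region_chrom) == len(self.region_start) == len(self.region_end) == r):
            raise ValidationError("region coordinate arrays do not match values")
        avail = self.values[~self.mask]
        if avail.size and (np.isnan(avail).any() or avail.min() < 0 or avail.max() > 1):
            raise ValidationError("unmasked values must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def na_rate(self) -> float:
        """Fraction of (cell, region) entries that are missing."""
        return float(self.mask.mean()) if self.mask.size else 0.0

    def region_names(self) -> list[str]:
        return [
            f"{c}:{s}-{e}"
            for c, s, e in zip(self.region_chrom, self.region_start, self.region_end)
        ]


def make_bins(sizes: ChromSizes, window_length: int) -> BinGrid:
    """Tile every chromosome into ``window_length`` bp windows.

    The trailing partial bin of each chromosome is kept, so every base is
    covered exactly once.
    """
    if window_length <= 0:
        raise ValidationError(f"window_length must be positive, got {window_length}")
    names = sizes.names
    lengths = tuple(sizes[c] for c in names)
    nbins = tuple(-(-length // window_length) for length in lengths)  # ceil div
    offsets = tuple(int(x) for x in np.concatenate([[0], np.cumsum(nbins)[:-1]]))
    return BinGrid(
        window_length=int(window_length),
        chrom_order=names,
        chrom_lengths=lengths,
        bins_per_chrom=nbins,
        chrom_offsets=offsets,
    )


def assign_bin(chrom: str, pos: int, grid: BinGrid) -> int:
    """Global region index of the unique bin containing (chrom, pos)."""
    try:
        i = grid.chrom_order.index(chrom)
    except ValueError:
        raise ValidationError(f"chromosome {chrom!r} not in grid") from None
    if not 0 <= pos < grid.chrom_lengths[i]:
        raise ValidationError(
            f"position {pos} outside chromosome {chrom!r} "
            f"(length {grid.chrom_lengths[i]})"
        )
    return grid.chrom_offsets[i] + pos // grid.window_length


def aggregate_cell(
    calls: CellCallSet,
    grid: BinGrid,
    *,
    weighted_mean: bool = False,
    min_sites: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """One matrix row: the per-region average methylation level of one cell.

    For each region with k >= ``min_sites`` captured sites the value is the
    unweighted mean of the per-site ratios mc/total (each site weight 1);
    with ``weighted_mean`` the read-weighted ratio sum(mc)/sum(total) is
    used instead (identical for binary single-read calls).  Regions below
    ``min_sites`` are masked.
    """
    r = grid.n_regions
    counts = np.zeros(r, dtype=np.int64)
    values = np.full(r, np.nan)
    if calls.n_calls:
        region_idx = np.empty(calls.n_calls, dtype=np.int64)
        chrom_arr = calls.chrom.astype(str)
        for name, length, off in zip(grid.chrom_order, grid.chrom_lengths, grid.chrom_offsets):
            sel = chrom_arr == name
            if not sel.any():
                continue
            p = calls.pos[sel]
            if p.min() < 0 or p.max() >= length:
                raise ValidationError(
                    f"call position outside chromosome {name!r} (length {length})"
                )
            region_idx[sel] = off + p // grid.window_length
        known = np.isin(chrom_arr, grid.chrom_order)
        if not known.all():
            missing = sorted(set(chrom_arr[~known]))
            raise ValidationError(f"call(s) on chromosome(s) absent from grid: {missing}")
        counts = np.bincount(region_idx, minlength=r)
        if weighted_mean:
            mc_sum = np.bincount(region_idx, weights=calls.mc, minlength=r)
            tot_sum = np.bincount(region_idx, weights=calls.total, minlength=r)
            with np.errstate(invalid="ignore", divide="ignore"):
                values = mc_sum / tot_sum
        else:
            level_sum = np.bincount(region_idx, weights=calls.levels, minlength=r)
            with np.errstate(invalid="ignore", divide="ignore"):
                values = level_sum / counts
    mask = counts < max(1, int(min_sites))
    values[mask] = np.nan
    return values, mask


def build_matrix(
    cells: list[CellCallSet],
    grid: BinGrid,
    context: str = "CG",
    *,
    weighted_mean: bool = False,
    min_sites: int = 1,
) -> RegionMatrix:
    """Stack :func:`aggregate_cell` rows into a :class:`RegionMatrix`.

    Rows follow the input cell order; the context tag is recorded but the
    calls are assumed to be already context-filtered (see
    :func:`scmimpute.io.read_cell_calls`).
    """
    ids = [c.cell_id for c in cells]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate cell ids: {dupes}")
    n, r = len(cells), grid.n_regions
    values = np.full((n, r), np.nan)
    mask = np.ones((n, r), dtype=bool)
    for i, cell in enumerate(cells):
        values[i], mask[i] = aggregate_cell(
            cell, grid, weighted_mean=weighted_mean, min_sites=min_sites
        )
    chroms, starts, ends = grid.region_coords()
    return RegionMatrix(
        cell_ids=ids,
        region_chrom=chroms,
        region_start=starts,
        region_end=ends,
        values=values,
        mask=mask,
        context=context,
        window_length=grid.window_length,
    )


def drop_all_missing_regions(matrix: RegionMatrix) -> RegionMatrix:
    """Remove regions that are NA in every cell (they carry no statistic).

    Idempotent; surviving regions keep their genomic coordinates.
    """
    keep = ~matrix.mask.all(axis=0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d all-missing region(s) of %d", dropped, matrix.n_regions)
    if not dropped:
        return matrix
    return RegionMatrix(
        cell_ids=list(matrix.cell_ids),
        region_chrom=matrix.region_chrom[keep],
        region_start=matrix.region_start[keep],
        region_end=matrix.region_end[keep],
        values=matrix.values[:, keep],
        mask=matrix.mask[:, keep],
        context=matrix.context,
        window_length=matrix.window_length,
    )
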