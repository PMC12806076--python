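"""The four NA-imputation strategies for cell-by-region methylation matrices.

Missing entries are filled with a constant 0, a constant 1, the per-region
mean of the available values across cells, or the per-region median.  The
column statistics use only observed entries (single pass, never previously
imputed ones) and observed entries are carried through bit-identically.

Zeros treat a missing region as unmethylated, ones as fully methylated
(motivated by the high CG baseline), means follow the EpiScanpy convention,
and medians are robust to the minority of hypo-methylated DMR cells that
drag a column mean down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import RegionMatrix
from .io import ValidationError

__all__ = [
    "STRATEGIES", "ImputedMatrix",
    "column_available_mean", "column_available_median", "impute",
]

STRATEGIES = ("zeros", "ones", "means", "medians")


@dataclass
class ImputedMatrix:
    """A fully defined cells x regions matrix plus the original missingness mask."""

    cell_ids: list[str]
    region_chrom: np.ndarray
    region_start: np.ndarray
    region_end: np.ndarray
    values: np.ndarray
    strategy: str
    source_mask: np.ndarray
    context: str
    window_length: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ValidationError("imputed matrix contains NaN entries")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValidationError("imputed values must lie in [0, 1]")
        if self.strategy not in STRATEGIES:
            raise ValidationError(
                f"unknown strategy {self.strategy!r}; valid: {list(STRATEGIES)}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


def _available_column(matrix: RegionMatrix, region: int) -> np.ndarray:
    col = matrix.values[:, region]
    avail = col[~matrix.mask[:, region]]
    if avail.size == 0:
        raise ValidationError(
            f"region {region} is missing in every cell; "
            "drop all-missing regions before imputing (drop_all_missing_regions)"
        )
    return avail


def column_available_mean(matrix: RegionMatrix, region: int) -> float:
    """Arithmetic mean of the observed entries of one region across cells."""
    return float(_available_column(matrix, region).mean())


def column_available_median(matrix: RegionMatrix, region: int) -> float:
    """Median of the observed entries of one region across cells.

    Even counts use the mean of the two central order statistics.
    """
    return float(np.median(_available_column(matrix, region)))


def impute(matrix: RegionMatrix, strategy: str) -> ImputedMatrix:
    """Fill every masked entry of ``matrix`` according to ``strategy``.

    ``zeros`` and ``ones`` fill with the constants; ``means`` and
    ``medians`` fill each region's missing entries with the mean/median of
    that region's available values across cells.  Requires that no region
    is missing in every cell.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(
            f"unknown strategy {strategy!r}; valid: {list(STRATEGIES)}"
        )
    all_missing = matrix.mask.all(axis=0) if matrix.n_cells else np.ones(matrix.n_regions, bool)
    if matrix.n_regions and all_missing.any():
        raise ValidationError(
            f"{int(all_missing.sum())} region(s) are missing in every cell; "
            "apply drop_all_missing_regions first"
        )
    values = matrix.values.copy()
    if strategy == "zeros":
        fill = np.zeros(matrix.n_regions)
    elif strategy == "ones":
        fill = np.ones(matrix.n_regions)
    else:
        masked = np.ma.masked_array(matrix.values, mask=matrix.mask)
        if strategy == "means":
            fill = np.asarray(masked.mean(axis=0))
        else:  # medians
            fill = np.asarray(np.ma.median(masked, axis=0))
    values[matrix.mask] = np.broadcast_to(fill, matrix.values.shape)[matrix.mask]
    return ImputedMatrix(
        cell_ids=list(matrix.cell_ids),
        region_chrom=matrix.region_chrom,
        region_start=matrix.region_start,
        region_end=matrix.region_end,
        values=values,
        strategy=strategy,
        source_mask=matrix.mask.copy(),
        context=matrix.context,
        window_length=matrix.window_length,
    )
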