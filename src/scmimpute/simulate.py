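"""Synthetic single-cell methylome generator with known cell types and DMRs.

The generative model mirrors the statistical structure of real single-cell
bisulfite data:

* each region j has a latent methylation propensity per cell type t,
  ``p[t, j]``;
* non-DMR regions share one Beta-distributed propensity across all types
  (high baseline in CG context, near-zero in CH);
* a fraction of regions are differentially methylated: the affected cell
  types draw their propensity from a separate Beta whose mean (~0.16) lies
  below the CG baseline and above the CH baseline, so DMRs come out
  hypo-methylated in CG mode and hyper-methylated in CH mode from the same
  rule;
* site capture is Poisson per (cell, region) with mean ``lambda``
  proportional to the window length, so shrinking the window mechanically
  raises the NA rate (a region with zero captured sites becomes an NA
  entry downstream);
* each captured site is a binary single-read call: methylated with
  probability ``p[type, region]``, read counts in {0, 1} with
  total_reads = 1, positions uniform without replacement within the
  region, all on one synthetic chromosome.

The whole dataset is a pure function of :class:`SimConfig` (all randomness
derives from ``config.seed``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import CellCallSet, ChromSizes, Partition, ValidationError

__all__ = [
    "SimConfig", "GroundTruth",
    "sample_ground_truth", "simulate_cell_calls", "simulate_dataset",
    "perturb_composition",
]

logger = logging.getLogger(__name__)

# default Beta(alpha, beta) baselines: CG methylation is high (mean 0.8),
# CH methylation nearly absent (mean ~0.03)
BASELINE_BETA = {"CG": (8.0, 2.0), "CH": (0.4, 12.0)}
DEFAULT_LAMBDA_AT_100KB = 8.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic methylome.

    ``sites_per_region_mean`` defaults to 8 at 100 kbp windows and scales
    linearly with ``window_length`` (0.8 at 10 kbp), encoding that shorter
    tiles capture proportionally fewer sites and hence have more missing
    entries.  ``dmr_fraction`` of the regions are DMRs, each carrying
    ``dmr_types_affected`` affected cell types.
    """

    seed: int = 0
    n_cell_types: int = 3
    cells_per_type: tuple[int, ...] = (60, 60, 60)
    n_regions: int = 2000
    window_length: int = 100_000
    context_mode: str = "CG"
    baseline_beta: tuple[float, float] | None = None
    dmr_fraction: float = 0.1
    dmr_beta: tuple[float, float] = (1.5, 8.0)
    dmr_types_affected: int = 1
    sites_per_region_mean: float | None = None
    chrom_name: str = "chrS"

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells_per_type", tuple(int(c) for c in self.cells_per_type))
        if self.context_mode not in ("CG", "CH"):
            raise ValidationError(f"context_mode must be CG or CH, got {self.context_mode!r}")
        if len(self.cells_per_type) != self.n_cell_types:
            raise ValidationError(
                f"cells_per_type has {len(self.cells_per_type)} entries "
                f"for {self.n_cell_types} cell types"
            )
        if any(c < 0 for c in self.cells_per_type):
            raise ValidationError("cell counts must be non-negative")
        if self.n_regions < 1 or self.window_length < 1:
            raise ValidationError("n_regions and window_length must be positive")
        if not 0.0 <= self.dmr_fraction <= 1.0:
            raise ValidationError("dmr_fraction must lie in [0, 1]")
        for pair in (self.resolved_baseline_beta(), self.dmr_beta):
            if pair[0] <= 0 or pair[1] <= 0:
                raise ValidationError("Beta parameters must be positive")
        if not 1 <= self.dmr_types_affected <= max(1, self.n_cell_types):
            raise ValidationError("dmr_types_affected out of range")
        if self.resolved_lambda() <= 0:
            raise ValidationError("sites_per_region_mean must be positive")

    def resolved_baseline_beta(self) -> tuple[float, float]:
        if self.baseline_beta is not None:
            return self.baseline_beta
        return BASELINE_BETA[self.context_mode]

    def resolved_lambda(self) -> float:
        if self.sites_per_region_mean is not None:
            return float(self.sites_per_region_mean)
        return DEFAULT_LAMBDA_AT_100KB * self.window_length / 100_000.0

    @property
    def n_cells(self) -> int:
        return sum(self.cells_per_type)

    def chrom_sizes(self) -> ChromSizes:
        return ChromSizes({self.chrom_name: self.n_regions * self.window_length})

    def context_string(self) -> str:
        return "CG" if self.context_mode == "CG" else "CHH"


@dataclass
class GroundTruth:
    """Latent state behind a simulated dataset.

    ``propensity[t, j]`` is the methylation probability of cell type t in
    region j; non-DMR regions have identical propensities across types.
    """

    labels: Partition
    propensity: np.ndarray
    dmr_flags: np.ndarray
    affected_types: tuple[tuple[int, ...], ...]
    type_names: tuple[str, ...]

    def type_of_cell(self, cell_index: int) -> int:
        return self.type_names.index(self.labels.labels[cell_index])


def _truth_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), 0])


def _cell_rng(config: SimConfig, cell_index: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), 1, int(cell_index)])


def sample_ground_truth(config: SimConfig) -> GroundTruth:
    """Draw cell-type labels, region propensities and DMR placement.

    floor(dmr_fraction * G) regions are flagged as DMRs; each draws its
    affected types uniformly without replacement.  Deterministic for a
    given config.
    """
    k, g = config.n_cell_types, config.n_regions
    n_dmr = int(np.floor(config.dmr_fraction * g))
    if n_dmr > 0 and k < 2:
        raise ValidationError("DMRs require at least 2 cell types (no heterogeneity otherwise)")
    rng = _truth_rng(config)
    a0, b0 = config.resolved_baseline_beta()
    a1, b1 = config.dmr_beta

    base = rng.beta(a0, b0, size=g)
    propensity = np.tile(base, (max(k, 1), 1))
    dmr_flags = np.zeros(g, dtype=bool)
    affected: list[tuple[int, ...]] = [()] * g
    if n_dmr:
        dmr_regions = np.sort(rng.choice(g, size=n_dmr, replace=False))
        dmr_flags[dmr_regions] = True
        for j in dmr_regions:
            types = rng.choice(k, size=config.dmr_types_affected, replace=False)
            p_dmr = rng.beta(a1, b1)
            propensity[types, j] = p_dmr
            affected[j] = tuple(int(t) for t in np.sort(types))

    type_names = tuple(f"type{t}" for t in range(k))
    cell_ids, labels = [], []
    for t, count in enumerate(config.cells_per_type):
        for i in range(count):
            cell_ids.append(f"cell{len(cell_ids):04d}")
            labels.append(type_names[t])
    return GroundTruth(
        labels=Partition(tuple(cell_ids), tuple(labels)),
        propensity=propensity,
        dmr_flags=dmr_flags,
        affected_types=tuple(affected),
        type_names=type_names,
    )


def simulate_cell_calls(
    truth: GroundTruth, config: SimConfig, cell_index: int
) -> CellCallSet:
    """Simulate one cell's binary site calls.

    Per region, the number of captured sites is Poisson(lambda); site
    positions are uniform without replacement within the region, and each
    site is methylated (mc=1, total=1) with the cell type's propensity.
    Regions with zero captured sites contribute no calls and become the NA
    entries downstream.
    """
    n = truth.labels.n
    if not 0 <= cell_index < n:
        raise ValidationError(f"cell_index {cell_index} out of range (n={n})")
    g, length = config.n_regions, config.window_length
    lam = config.resolved_lambda()
    t = truth.type_of_cell(cell_index)
    p = truth.propensity[t]
    rng = _cell_rng(config, cell_index)

    s = rng.poisson(lam, size=g)
    over = s > length
    if over.any():
        logger.info("capping site count at region length in %d region(s)", int(over.sum()))
        s[over] = length
    region_rep = np.repeat(np.arange(g), s)
    total = region_rep.size
    offs = rng.integers(0, length, size=total)
    pos = region_rep * length + offs
    # resolve within-region collisions so positions are distinct
    while total:
        order = np.argsort(pos, kind="stable")
        dup_sorted = np.concatenate(([False], pos[order][1:] == pos[order][:-1]))
        if not dup_sorted.any():
            break
        redraw = order[dup_sorted]
        offs[redraw] = rng.integers(0, length, size=redraw.size)
        pos = region_rep * length + offs
    order = np.argsort(pos, kind="stable")
    pos, region_rep = pos[order], region_rep[order]
    mc = (rng.random(total) < p[region_rep]).astype(np.int64)

    cell_id = truth.labels.cell_ids[cell_index]
    ctx = config.context_string()
    return CellCallSet(
        cell_id,
        np.full(total, config.chrom_name, dtype=object),
        pos,
        np.full(total, "+", dtype="<U1"),
        np.full(total, ctx, dtype="<U3"),
        mc,
        np.ones(total, dtype=np.int64),
        validate=False,
        presorted=True,
    )


def simulate_dataset(config: SimConfig) -> tuple[list[CellCallSet], GroundTruth]:
    """All cells of one synthetic dataset, plus the latent ground truth."""
    truth = sample_ground_truth(config)
    cells = [simulate_cell_calls(truth, config, i) for i in range(truth.labels.n)]
    return cells, truth


def perturb_composition(
    cells: list[CellCallSet],
    labels: Partition,
    target_proportions,
    seed: int = 0,
) -> tuple[list[CellCallSet], Partition]:
    """Subsample cells without replacement to match target type proportions.

    ``target_proportions`` is either a mapping label -> proportion or a
    sequence aligned with the distinct labels in order of first appearance.
    The subsample is the largest feasible: with available counts c_t, the
    notional total is T = min over p_t > 0 of floor(c_t / p_t) and each
    type contributes floor(T * p_t) cells (rounded down consistently).
    Deterministic for a given seed; original cell order is preserved.
    """
    if len(cells) != labels.n:
        raise ValidationError("cells and labels have different lengths")
    distinct: list = []
    for lab in labels.labels:
        if lab not in distinct:
            distinct.append(lab)
    if isinstance(target_proportions, dict):
        props = {lab: float(target_proportions.get(lab, 0.0)) for lab in distinct}
        unknown = set(target_proportions) - set(distinct)
        if unknown:
            raise ValidationError(f"proportions given for unknown label(s): {sorted(unknown)}")
    else:
        target_proportions = list(target_proportions)
        if len(target_proportions) != len(distinct):
            raise ValidationError(
                f"{len(target_proportions)} proportions for {len(distinct)} labels"
            )
        props = dict(zip(distinct, (float(p) for p in target_proportions)))
    if any(p < 0 for p in props.values()) or sum(props.values()) <= 0:
        raise ValidationError("proportions must be non-negative and sum to > 0")
    total_p = sum(props.values())
    props = {lab: p / total_p for lab, p in props.items()}

    avail = {lab: sum(1 for x in labels.labels if x == lab) for lab in distinct}
    t_max = None
    for lab, p in props.items():
        if p == 0.0:
            continue
        if avail[lab] == 0:
            raise ValidationError(
                f"type {lab!r} requested at proportion {p:.3g} but no cells are available"
            )
        bound = int(np.floor(avail[lab] / p))
        t_max = bound if t_max is None else min(t_max, bound)
    take = {lab: int(np.floor(t_max * p)) for lab, p in props.items()}

    rng = np.random.default_rng([int(seed), 2])
    keep_idx: set[int] = set()
    for lab in distinct:
        idx = [i for i, x in enumerate(labels.labels) if x == lab]
        chosen = rng.choice(len(idx), size=take[lab], replace=False)
        keep_idx.update(idx[c] for c in chosen)
    kept = sorted(keep_idx)
    sub_cells = [cells[i] for i in kept]
    sub_labels = Partition(
        tuple(labels.cell_ids[i] for i in kept),
        tuple(labels.labels[i] for i in kept),
    )
    return sub_cells, sub_labels
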