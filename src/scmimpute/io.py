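"""Readers and writers for methylation call files, chromosome sizes, labels and matrices.

File dialects
-------------
* allc-style call file: six tab-separated columns per cytosine —
  chromosome, position (1-based), strand, context (CG/CHG/CHH),
  methylated read count, total read count.  Positions are converted to
  0-based on read; all internal intervals are 0-based half-open.
* chrom.sizes: two tab-separated columns, chromosome name and length.
* label file: two tab-separated columns, cell id and label.
* region matrix: a dense TSV (cells as rows, regions as columns headed by
  ``chrom:start-end``) with the literal token ``NA`` for missing entries,
  plus region and cell metadata sidecar TSVs.

Gzip input is handled transparently (by file extension).
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MethylationCall", "CellCallSet", "ChromSizes", "Partition",
    "read_chrom_sizes", "read_cell_calls", "write_cell_calls",
    "read_labels", "write_labels",
    "write_region_matrix", "read_region_matrix",
    "ValidationError", "ParseError",
]

VALID_CONTEXTS = ("CG", "CHG", "CHH")
VALID_STRANDS = ("+", "-")

ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc_reads", "total_reads"]


class ValidationError(ValueError):
    """An input violates a domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class MethylationCall:
    """A single cytosine observation in one cell.

    ``pos`` is the 0-based genomic coordinate.  In single-cell data
    ``total_reads`` is typically 1 and ``mc_reads`` is 0 or 1, but counts
    above 1 are admitted.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    mc_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"negative position {self.pos}")
        if self.context not in VALID_CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"unknown strand {self.strand!r}")
        if self.total_reads < 1:
            raise ValidationError("total_reads must be >= 1")
        if not 0 <= self.mc_reads <= self.total_reads:
            raise ValidationError(
                f"mc_reads={self.mc_reads} outside [0, total_reads={self.total_reads}]"
            )

    @property
    def level(self) -> float:
        return self.mc_reads / self.total_reads


class CellCallSet:
    """All retained methylation calls of one cell, sorted by (chrom, pos).

    Calls are stored column-wise in numpy arrays for fast aggregation.
    Duplicate (chrom, pos, strand) entries are rejected.
    """

    __slots__ = ("cell_id", "chrom", "pos", "strand", "context", "mc", "total")

    def __init__(
        self,
        cell_id: str,
        chrom: np.ndarray,
        pos: np.ndarray,
        strand: np.ndarray,
        context: np.ndarray,
        mc: np.ndarray,
        total: np.ndarray,
        *,
        validate: bool = True,
        presorted: bool = False,
    ) -> None:
        self.cell_id = str(cell_id)
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        strand = np.asarray(strand, dtype="<U1")
        context = np.asarray(context, dtype="<U3")
        mc = np.asarray(mc, dtype=np.int64)
        total = np.asarray(total, dtype=np.int64)
        n = len(pos)
        if not (len(chrom) == len(strand) == len(context) == len(mc) == len(total) == n):
            raise ValidationError("call columns have unequal lengths")
        if not presorted and n:
            order = np.lexsort((pos, chrom.astype(str)))
            chrom, pos, strand = chrom[order], pos[order], strand[order]
            context, mc, total = context[order], mc[order], total[order]
        if validate and n:
            if pos.min() < 0:
                raise ValidationError("negative position in call set")
            if total.min() < 1:
                raise ValidationError("total_reads must be >= 1")
            bad = (mc < 0) | (mc > total)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"mc_reads > total_reads at {chrom[i]}:{pos[i]} "
                    f"({mc[i]} > {total[i]})"
                )
            unknown = ~np.isin(context, VALID_CONTEXTS)
            if unknown.any():
                bad_ctx = sorted(set(context[unknown]))
                raise ValidationError(f"unknown context string(s): {bad_ctx}")
            key = np.char.add(
                np.char.add(chrom.astype(str), np.char.mod(":%d:", pos)), strand
            )
            if len(np.unique(key)) != n:
                raise ValidationError(
                    f"duplicate (chrom, pos, strand) entries in cell {cell_id!r}"
                )
        self.chrom, self.pos, self.strand = chrom, pos, strand
        self.context, self.mc, self.total = context, mc, total

    @property
    def n_calls(self) -> int:
        return len(self.pos)

    @property
    def levels(self) -> np.ndarray:
        """Per-site methylation ratio mc/total."""
        return self.mc / self.total

    @classmethod
    def from_calls(cls, cell_id: str, calls: Iterable[MethylationCall]) -> "CellCallSet":
        calls = list(calls)
        return cls(
            cell_id,
            np.array([c.chrom for c in calls], dtype=object),
            np.array([c.pos for c in calls], dtype=np.int64),
            np.array([c.strand for c in calls], dtype="<U1"),
            np.array([c.context for c in calls], dtype="<U3"),
            np.array([c.mc_reads for c in calls], dtype=np.int64),
            np.array([c.total_reads for c in calls], dtype=np.int64),
        )

    def __len__(self) -> int:
        return self.n_calls

    def __repr__(self) -> str:
        return f"CellCallSet({self.cell_id!r}, n_calls={self.n_calls})"


@dataclass(frozen=True)
class ChromSizes:
    """Ordered chromosome name -> length (bp) mapping."""

    sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.sizes:
            raise ValidationError("no chromosomes")
        for name, length in self.sizes.items():
            if int(length) <= 0:
                raise ValidationError(f"non-positive length {length} for {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.sizes.keys())

    def __getitem__(self, name: str) -> int:
        return int(self.sizes[name])

    def __contains__(self, name: str) -> bool:
        return name in self.sizes

    def items(self):
        return self.sizes.items()


@dataclass(frozen=True)
class Partition:
    """A categorical labelling of an ordered list of cells."""

    cell_ids: tuple[str, ...]
    labels: tuple = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids but {len(self.labels)} labels"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids in partition")

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    def label_array(self) -> np.ndarray:
        """Labels encoded as contiguous integers 0..K-1 (order of first appearance)."""
        codes: dict = {}
        out = np.empty(self.n, dtype=np.int64)
        for i, lab in enumerate(self.labels):
            out[i] = codes.setdefault(lab, len(codes))
        return out


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return _io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column (name, length) chrom.sizes file, order preserved."""
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            name, raw_len = parts
            try:
                length = int(raw_len)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer length {raw_len!r}") from None
            if length <= 0:
                raise ValidationError(f"{path}: line {lineno}: non-positive length {length}")
            if name in sizes:
                raise ValidationError(f"{path}: line {lineno}: duplicate chromosome {name!r}")
            sizes[name] = length
    if not sizes:
        raise ValidationError(f"{path}: no chromosomes")
    return ChromSizes(sizes)


def _apply_context_filter(context: np.ndarray, context_filter: str) -> np.ndarray:
    if context_filter == "all":
        return np.ones(len(context), dtype=bool)
    if context_filter == "CG":
        return context == "CG"
    if context_filter == "CH":
        return (context == "CHG") | (context == "CHH")
    raise ValidationError(
        f"unknown context filter {context_filter!r}; expected one of 'CG', 'CH', 'all'"
    )


def read_cell_calls(
    path: str | Path,
    context_filter: str = "all",
    cell_id: str | None = None,
) -> CellCallSet:
    """Read an allc-style call file into a :class:`CellCallSet`.

    Positions are 1-based in the file and converted to 0-based.  ``CH``
    keeps CHG and CHH contexts; ``CG`` keeps CG only.  The cell id
    defaults to the file name stem.
    """
    path = Path(path)
    if cell_id is None:
        cell_id = path.name
        for suffix in (".gz", ".tsv", ".txt", ".allc"):
            if cell_id.endswith(suffix):
                cell_id = cell_id[: -len(suffix)]
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=ALLC_COLUMNS, comment="#",
            dtype={"chrom": str, "pos": np.int64, "strand": str, "context": str,
                   "mc_reads": np.int64, "total_reads": np.int64},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: malformed allc file: {exc}") from exc
    if (df["pos"] < 1).any():
        raise ValidationError(f"{path}: positions must be >= 1 (1-based file coordinates)")
    unknown = ~df["context"].isin(VALID_CONTEXTS)
    if unknown.any():
        bad = sorted(df.loc[unknown, "context"].unique())
        raise ValidationError(f"{path}: unknown context string(s): {bad}")
    if (df["mc_reads"] > df["total_reads"]).any():
        i = int((df["mc_reads"] > df["total_reads"]).idxmax())
        raise ValidationError(
            f"{path}: mc_reads > total_reads at row {i + 1} "
            f"({df['mc_reads'][i]} > {df['total_reads'][i]})"
        )
    keep = _apply_context_filter(df["context"].to_numpy(dtype="<U3"), context_filter)
    df = df.loc[keep]
    return CellCallSet(
        cell_id,
        df["chrom"].to_numpy(dtype=object),
        df["pos"].to_numpy(dtype=np.int64) - 1,  # to 0-based
        df["strand"].to_numpy(dtype="<U1"),
        df["context"].to_numpy(dtype="<U3"),
        df["mc_reads"].to_numpy(dtype=np.int64),
        df["total_reads"].to_numpy(dtype=np.int64),
    )


def write_cell_calls(calls: CellCallSet, path: str | Path) -> None:
    """Write a :class:`CellCallSet` as an allc-style file (positions 1-based)."""
    df = pd.DataFrame(
        {
            "chrom": calls.chrom,
            "pos": calls.pos + 1,
            "strand": calls.strand,
            "context": calls.context,
            "mc_reads": calls.mc,
            "total_reads": calls.total,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_labels(path: str | Path) -> Partition:
    """Read a two-column (cell_id, label) TSV into a :class:`Partition`."""
    cell_ids: list[str] = []
    labels: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            cell_ids.append(parts[0])
            labels.append(parts[1])
    return Partition(tuple(cell_ids), tuple(labels))


def write_labels(partition: Partition, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for cid, lab in zip(partition.cell_ids, partition.labels):
            fh.write(f"{cid}\t{lab}\n")


# -- region matrix round trip -------------------------------------------------
# Values are serialized with Python float repr (shortest round-trip form), so a
# write/read cycle is bit-exact.  Missing entries are the literal token "NA".

def _matrix_paths(path_prefix: str | Path) -> tuple[Path, Path, Path]:
    prefix = Path(path_prefix)
    return (
        prefix.with_name(prefix.name + ".matrix.tsv"),
        prefix.with_name(prefix.name + ".regions.tsv"),
        prefix.with_name(prefix.name + ".cells.tsv"),
    )


def write_region_matrix(matrix, path_prefix: str | Path) -> None:
    """Write a RegionMatrix as ``<prefix>.matrix.tsv`` plus metadata sidecars.

    The dense TSV has cells as rows and regions as columns headed by
    ``chrom:start-end``; masked entries are written as ``NA``.  The regions
    sidecar records coordinates, context and window length; the cells
    sidecar records cell ids.
    """
    mat_path, reg_path, cell_path = _matrix_paths(path_prefix)
    headers = [
        f"{c}:{s}-{e}"
        for c, s, e in zip(matrix.region_chrom, matrix.region_start, matrix.region_end)
    ]
    with open(mat_path, "wt", encoding="utf-8") as fh:
        fh.write("cell_id\t" + "\t".join(headers) + "\n")
        for i, cid in enumerate(matrix.cell_ids):
            row = [
                "NA" if matrix.mask[i, j] else repr(float(matrix.values[i, j]))
                for j in range(matrix.n_regions)
            ]
            fh.write(cid + "\t" + "\t".join(row) + "\n")
    with open(reg_path, "wt", encoding="utf-8") as fh:
        fh.write("chrom\tstart\tend\tcontext\twindow_length\n")
        for c, s, e in zip(matrix.region_chrom, matrix.region_start, matrix.region_end):
            fh.write(f"{c}\t{s}\t{e}\t{matrix.context}\t{matrix.window_length}\n")
    with open(cell_path, "wt", encoding="utf-8") as fh:
        fh.write("cell_id\n")
        for cid in matrix.cell_ids:
            fh.write(cid + "\n")


def read_region_matrix(path_prefix: str | Path):
    """Read back a matrix written by :func:`write_region_matrix`."""
    from .binning import RegionMatrix  # local import avoids a cycle

    mat_path, reg_path, cell_path = _matrix_paths(path_prefix)
    reg = pd.read_csv(reg_path, sep="\t", dtype={"chrom": str})
    cells = pd.read_csv(cell_path, sep="\t", dtype=str)
    cell_ids = [] if cells.empty else list(cells["cell_id"])
    context = str(reg["context"].iloc[0]) if len(reg) else "CG"
    window_length = int(reg["window_length"].iloc[0]) if len(reg) else 0
    n, r = len(cell_ids), len(reg)
    values = np.full((n, r), np.nan)
    mask = np.ones((n, r), dtype=bool)
    with open(mat_path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise ParseError(f"{mat_path}: empty matrix file")
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != r + 1:
                raise ParseError(f"{mat_path}: line {i + 2}: expected {r + 1} columns")
            for j, tok in enumerate(parts[1:]):
                if tok == "NA":
                    continue
                v = float(tok)
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(
                        f"{mat_path}: line {i + 2}: value {tok} outside [0, 1]"
                    )
                values[i, j] = v
                mask[i, j] = False
    return RegionMatrix(
        cell_ids=list(cell_ids),
        region_chrom=reg["chrom"].to_numpy(dtype=object),
        region_start=reg["start"].to_numpy(dtype=np.int64),
        region_end=reg["end"].to_numpy(dtype=np.int64),
        values=values,
        mask=mask,
        context=context,
        window_length=window_length,
    )
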