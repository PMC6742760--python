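"""Shared genomic data model and readers/writers for every on-disk format the
pipeline touches.

Conventions
-----------
* Coordinates are 0-based half-open everywhere in memory; BED/BEDPE are native.
* Contact matrices use the HiC-Pro sparse triplet dialect: a whitespace
  separated ``bin_i  bin_j  count`` file with **1-based** bin ids, plus a
  companion bin BED whose 4th column carries the same ids.  Bin id <->
  coordinate mapping always follows the companion BED, never arithmetic on
  chromosome sizes.
* Matrices are symmetric and stored as the upper triangle (``row <= col``);
  lower-triangle input entries are mirrored and duplicates summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval; the unit of every BED-derived entity."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_length: int

    def __post_init__(self) -> None:
        if self.gene_length <= 0:
            raise ValueError("gene_length must be > 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


class BinTable:
    """Fixed-resolution bins tiling each chromosome without gaps; the last
    bin of a chromosome may be short."""

    def __init__(self, chrom_sizes: Mapping[str, int], resolution: int):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.resolution = int(resolution)
        self.chrom_sizes: dict[str, int] = {str(c): int(s) for c, s in chrom_sizes.items()}
        self._offset: dict[str, int] = {}
        self._nbins: dict[str, int] = {}
        off = 0
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive size")
            n = -(-size // self.resolution)
            self._offset[chrom] = off
            self._nbins[chrom] = n
            off += n
        self.n_bins = off

    # -- lookups ---------------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_bins_chrom(self, chrom: str) -> int:
        return self._nbins[chrom]

    def offset(self, chrom: str) -> int:
        return self._offset[chrom]

    def bin_range(self, chrom: str) -> tuple[int, int]:
        """Half-open global bin id range of a chromosome."""
        off = self._offset[chrom]
        return off, off + self._nbins[chrom]

    def bin_id(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offset[chrom] + pos // self.resolution

    def coords(self, bin_id: int) -> tuple[str, int, int]:
        if not 0 <= bin_id < self.n_bins:
            raise ValueError(f"bin id {bin_id} out of range")
        for chrom in self.chroms:
            lo, hi = self.bin_range(chrom)
            if lo <= bin_id < hi:
                start = (bin_id - lo) * self.resolution
                return chrom, start, min(start + self.resolution, self.chrom_sizes[chrom])
        raise AssertionError("unreachable")

    def chrom_of(self, bin_ids: np.ndarray) -> np.ndarray:
        edges = np.array([self.bin_range(c)[1] for c in self.chroms])
        idx = np.searchsorted(edges, np.asarray(bin_ids), side="right")
        return np.array(self.chroms, dtype=object)[idx]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chroms:
            n = self._nbins[chrom]
            starts = np.arange(n, dtype=np.int64) * self.resolution
            ends = np.minimum(starts + self.resolution, self.chrom_sizes[chrom])
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        df = pd.concat(rows, ignore_index=True)
        df["bin_id"] = np.arange(len(df), dtype=np.int64)
        return df

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BinTable)
            and self.resolution == other.resolution
            and self.chrom_sizes == other.chrom_sizes
        )

    # -- IO --------------------------------------------------------------
    def to_bed(self, path) -> None:
        df = self.to_frame()
        df["name"] = df["bin_id"] + 1  # HiC-Pro ids are 1-based
        df[["chrom", "start", "end", "name"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_bed(cls, path) -> "BinTable":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], dtype={0: str},
        )
        widths = df["end"] - df["start"]
        resolution = int(widths.max())
        chrom_sizes: dict[str, int] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            expect = np.arange(len(sub)) * resolution
            if not np.array_equal(starts, expect) or not np.array_equal(
                ends[:-1], starts[1:]
            ):
                raise ValueError(f"bins do not tile chromosome {chrom} without gaps")
            chrom_sizes[str(chrom)] = int(ends[-1])
        return cls(chrom_sizes, resolution)


@dataclass
class ContactMatrix:
    """Binned symmetric sparse contact counts (upper triangle stored)."""

    bins: BinTable
    row: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    col: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    count: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))
    bias: np.ndarray | None = None

    @classmethod
    def from_entries(
        cls,
        bins: BinTable,
        i: Iterable[int],
        j: Iterable[int],
        count: Iterable[float],
        bias: np.ndarray | None = None,
    ) -> "ContactMatrix":
        i = np.asarray(list(i) if not isinstance(i, np.ndarray) else i, dtype=np.int64)
        j = np.asarray(list(j) if not isinstance(j, np.ndarray) else j, dtype=np.int64)
        c = np.asarray(
            list(count) if not isinstance(count, np.ndarray) else count, dtype=np.float64
        )
        if len(i) and (i.min() < 0 or j.min() < 0 or max(i.max(), j.max()) >= bins.n_bins):
            raise ValueError("bin id out of range")
        if len(c) and c.min() < 0:
            raise ValueError("negative contact count")
        r = np.minimum(i, j)
        s = np.maximum(i, j)
        m = sp.coo_matrix((c, (r, s)), shape=(bins.n_bins, bins.n_bins))
        m.sum_duplicates()
        keep = m.data > 0
        order = np.lexsort((m.col[keep], m.row[keep]))
        return cls(
            bins,
            m.row[keep][order].astype(np.int64),
            m.col[keep][order].astype(np.int64),
            m.data[keep][order].astype(np.float64),
            bias=bias,
        )

    # -- basic queries ---------------------------------------------------
    def total(self) -> float:
        return float(self.count.sum())

    def get(self, i: int, j: int) -> float:
        r, c = min(i, j), max(i, j)
        hit = (self.row == r) & (self.col == c)
        return float(self.count[hit].sum())

    def to_symmetric_csr(self) -> sp.csr_matrix:
        n = self.bins.n_bins
        upper = sp.coo_matrix((self.count, (self.row, self.col)), shape=(n, n))
        off = self.row != self.col
        lower = sp.coo_matrix(
            (self.count[off], (self.col[off], self.row[off])), shape=(n, n)
        )
        return (upper + lower).tocsr()

    def marginals(self) -> np.ndarray:
        """Symmetric row sums (diagonal counted once)."""
        return np.asarray(self.to_symmetric_csr().sum(axis=1)).ravel()

    def chrom_entries(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Intra-chromosomal entries with chromosome-local bin ids."""
        lo, hi = self.bins.bin_range(chrom)
        sel = (self.row >= lo) & (self.row < hi) & (self.col >= lo) & (self.col < hi)
        return self.row[sel] - lo, self.col[sel] - lo, self.count[sel]

    def dense_chrom(self, chrom: str) -> np.ndarray:
        lo, hi = self.bins.bin_range(chrom)
        n = hi - lo
        r, c, v = self.chrom_entries(chrom)
        a = np.zeros((n, n))
        a[r, c] = v
        a[c, r] = v
        return a

    def valid_bins(self) -> np.ndarray:
        """Bins usable downstream: unmasked bias (when present) and, for raw
        matrices, any bin (masking happens at normalization)."""
        ok = np.ones(self.bins.n_bins, dtype=bool)
        if self.bias is not None:
            ok &= np.isfinite(self.bias)
        return ok


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Parse a 3-6 column BED into intervals, preserving input order and the
    score column when present.  Malformed lines raise with their line number."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >=3 tab-separated fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: {exc}") from None
            try:
                out.append(GenomicInterval(chrom, start, end, name=name, score=score))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
    return out


def write_bed(intervals: Sequence[GenomicInterval] | pd.DataFrame, path) -> None:
    if isinstance(intervals, pd.DataFrame):
        intervals = frame_to_intervals(intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(repr(iv.score))
            fh.write("\t".join(fields) + "\n")


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "name": [iv.name for iv in intervals],
            "score": [iv.score for iv in intervals],
        }
    )


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    names = df["name"] if "name" in df else [None] * len(df)
    scores = df["score"] if "score" in df else [None] * len(df)
    return [
        GenomicInterval(
            str(c), int(s), int(e),
            name=None if n is None or (isinstance(n, float) and np.isnan(n)) else str(n),
            score=None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v),
        )
        for c, s, e, n, v in zip(df["chrom"], df["start"], df["end"], names, scores)
    ]


# ---------------------------------------------------------------------------
# Contact matrices (HiC-Pro triplet dialect)
# ---------------------------------------------------------------------------

def read_contact_matrix(matrix_path, bins_path) -> ContactMatrix:
    bins = BinTable.from_bed(bins_path)
    try:
        trip = pd.read_csv(
            matrix_path, sep=r"\s+", header=None, names=["i", "j", "count"],
            dtype={"i": np.int64, "j": np.int64, "count": np.float64},
        )
    except pd.errors.EmptyDataError:
        return ContactMatrix(bins)
    i = trip["i"].to_numpy() - 1  # file ids are 1-based
    j = trip["j"].to_numpy() - 1
    c = trip["count"].to_numpy()
    if len(i) and (i.min() < 0 or j.min() < 0 or max(i.max(), j.max()) >= bins.n_bins):
        raise ValueError("triplet bin id out of range of the bin table")
    if len(c) and c.min() < 0:
        raise ValueError("negative contact count in triplet file")
    return ContactMatrix.from_entries(bins, i, j, c)


def write_contact_matrix(matrix: ContactMatrix, matrix_path, bins_path) -> None:
    matrix.bins.to_bed(bins_path)
    pd.DataFrame(
        {"i": matrix.row + 1, "j": matrix.col + 1, "count": matrix.count}
    ).to_csv(matrix_path, sep="\t", header=False, index=False, float_format="%.10g")


def write_bias_vector(bias: np.ndarray, path) -> None:
    pd.DataFrame({"bin_id": np.arange(len(bias)), "bias": bias}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# Loops (BEDPE)
# ---------------------------------------------------------------------------

_BEDPE_EXTRAS = ["count", "p", "q", "category"]


def write_loops_bedpe(loops: pd.DataFrame, path) -> None:
    """Write loops as 10-column BEDPE plus raw count, p, q, category columns.
    Only intra-chromosomal loops are representable."""
    req = {"chrom", "start1", "end1", "start2", "end2"}
    if not req.issubset(loops.columns):
        missing = req - set(loops.columns)
        raise ValueError(f"unresolvable anchors, missing columns: {sorted(missing)}")
    if "chrom2" in loops.columns and not (loops["chrom2"] == loops["chrom"]).all():
        raise ValueError("inter-chromosomal loop cannot be written (intra only)")
    df = loops.copy()
    out = pd.DataFrame(
        {
            "chrom1": df["chrom"],
            "start1": df["start1"].astype(int),
            "end1": df["end1"].astype(int),
            "chrom2": df["chrom"],
            "start2": df["start2"].astype(int),
            "end2": df["end2"].astype(int),
            "name": df["name"] if "name" in df else ".",
            "score": df["score"] if "score" in df else ".",
            "strand1": ".",
            "strand2": ".",
        }
    )
    for extra in _BEDPE_EXTRAS:
        out[extra] = df[extra] if extra in df else "."
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.10g")


def read_loops_bedpe(path) -> pd.DataFrame:
    cols = [
        "chrom", "start1", "end1", "chrom2", "start2", "end2",
        "name", "score", "strand1", "strand2",
    ] + _BEDPE_EXTRAS
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=cols, dtype={0: str, 3: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=cols)
    if not (df["chrom2"] == df["chrom"]).all():
        raise ValueError("inter-chromosomal loop in BEDPE (intra only)")
    for c in ("count", "p", "q"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df.drop(columns=["strand1", "strand2"])


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

_GENE_COLS = ["gene_id", "chrom", "strand", "tss", "length"]


def read_gene_table(path) -> pd.DataFrame:
    """Gene TSV: gene_id, chrom, strand, tss, length plus any number of
    numeric expression columns (one per condition x replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in _GENE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if (df["length"] <= 0).any():
        raise ValueError("gene_length must be > 0")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be + or -")
    return df


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False, float_format="%.10g")


def expression_columns(genes: pd.DataFrame) -> list[str]:
    return [c for c in genes.columns if c not in _GENE_COLS and c not in ("expressed", "upregulated")]
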