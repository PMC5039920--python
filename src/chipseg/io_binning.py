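"""Read ingestion, PCR-duplicate removal and midpoint binning.

Mapped reads (BED or SAM/BAM) are collapsed to at most one read per
(chromosome, 5'-position, strand) key and binned by their midpoint into
fixed-step windows (default 300 bp) tiling each chromosome.  The result
is a window-by-profile integer count matrix with columns tagged as
negative controls or ChIP experiments.

Coordinates are 0-based half-open throughout; SAM/BAM records are
converted on input by pysam.  Gzip-compressed BED files are decompressed
transparently.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "MappedRead",
    "WindowGrid",
    "CountMatrix",
    "read_mapped_reads",
    "deduplicate",
    "bin_reads",
    "build_count_matrix",
]

DEFAULT_WINDOW_SIZE = 300


class MappedRead(NamedTuple):
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "+"

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def five_prime(self) -> int:
        """5'-most coordinate: start on '+', end on '-'."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class WindowGrid:
    """Fixed-step windows tiling a set of chromosomes.

    Windows have width ``window_size`` except possibly the last one per
    chromosome, tile each chromosome without gaps or overlaps, and are
    ordered by chromosome (insertion order of ``chrom_lengths``) then
    start.
    """

    window_size: int
    chrom_lengths: dict
    _n_per_chrom: dict = field(init=False, repr=False)
    _offsets: dict = field(init=False, repr=False)

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        npc, offs, off = {}, {}, 0
        for chrom, length in self.chrom_lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
            nw = -(-length // self.window_size)  # ceil
            npc[chrom] = nw
            offs[chrom] = off
            off += nw
        object.__setattr__(self, "_n_per_chrom", npc)
        object.__setattr__(self, "_offsets", offs)

    @property
    def n(self) -> int:
        return sum(self._n_per_chrom.values())

    @property
    def blocks(self) -> list:
        """Per-chromosome window-index slices, in grid order."""
        return [
            slice(self._offsets[c], self._offsets[c] + self._n_per_chrom[c])
            for c in self.chrom_lengths
        ]

    def window_index(self, chrom: str, pos: int) -> int:
        """Global index of the window containing base ``pos`` of ``chrom``.

        Positions at or beyond the declared chromosome length fall into
        the last window (a warning is the caller's responsibility).
        """
        nw = self._n_per_chrom[chrom]
        return self._offsets[chrom] + min(pos // self.window_size, nw - 1)

    def to_frame(self) -> pd.DataFrame:
        """Window coordinates as a (chrom, start, end) DataFrame."""
        rows = []
        for chrom, length in self.chrom_lengths.items():
            starts = np.arange(self._n_per_chrom[chrom]) * self.window_size
            ends = np.minimum(starts + self.window_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class CountMatrix:
    """Per-window read counts for one or more profiles.

    ``counts`` is an ``(n_windows, n_profiles)`` non-negative integer
    array; ``roles`` tags each column as ``"control"`` or ``"chip"``;
    ``names`` optionally labels the columns.
    """

    grid: WindowGrid
    counts: np.ndarray
    roles: Sequence[str]
    names: Sequence[str] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.grid.n:
            raise ValueError("counts must be (n_windows, n_profiles)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.roles) != self.counts.shape[1]:
            raise ValueError("one role per column required")
        for role in self.roles:
            if role not in ("control", "chip"):
                raise ValueError(f"unknown role {role!r}")
        if self.names is None:
            idx = {}
            names = []
            for role in self.roles:
                idx[role] = idx.get(role, 0) + 1
                names.append(f"{role}{idx[role]}")
            self.names = names

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    @property
    def chip_columns(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == "chip"])

    @property
    def control_columns(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == "control"])

    @property
    def chip_counts(self) -> np.ndarray:
        return self.counts[:, self.chip_columns]

    @property
    def control_counts(self) -> np.ndarray:
        return self.counts[:, self.control_columns]

    @property
    def blocks(self) -> list:
        return self.grid.blocks

    def to_tsv(self, path) -> None:
        frame = self.grid.to_frame()
        for name, role, col in zip(self.names, self.roles, self.counts.T):
            frame[f"{name}:{role}"] = col
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        frame = pd.read_csv(path, sep="\t")
        chrom_lengths = dict(frame.groupby("chrom", sort=False)["end"].max())
        widths = frame["end"] - frame["start"]
        grid = WindowGrid(int(widths.max()), {c: int(v) for c, v in chrom_lengths.items()})
        cols = [c for c in frame.columns if ":" in c]
        names = [c.split(":")[0] for c in cols]
        roles = [c.split(":")[1] for c in cols]
        return cls(grid=grid, counts=frame[cols].to_numpy(), roles=roles, names=names)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _open_text(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_bed(path) -> Iterator[MappedRead]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start must be < end")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "+"
            yield MappedRead(fields[0], start, end, strand)


def _iter_sam(path, mode) -> Iterator[MappedRead]:
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            end = rec.reference_end
            if end is None:
                continue
            yield MappedRead(
                rec.reference_name,
                rec.reference_start,
                end,
                "-" if rec.is_reverse else "+",
            )


def read_mapped_reads(path, format: str = None) -> Iterator[MappedRead]:
    """Stream mapped reads from a BED, SAM or BAM file.

    Unmapped, secondary and supplementary alignments are skipped.  The
    format is inferred from the file suffix when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffixes = [s.lower() for s in path.suffixes]
        stem = suffixes[-2] if suffixes and suffixes[-1] == ".gz" else (
            suffixes[-1] if suffixes else ""
        )
        format = {".bed": "bed", ".sam": "sam", ".bam": "bam"}.get(stem)
        if format is None:
            raise ValueError(f"cannot infer format of {path}; pass format=")
    format = format.lower()
    if format == "bed":
        return _iter_bed(path)
    if format == "sam":
        return _iter_sam(path, "r")
    if format == "bam":
        return _iter_sam(path, "rb")
    raise ValueError(f"unknown format {format!r} (expected bed, sam or bam)")


def deduplicate(reads: Iterable[MappedRead]) -> Iterator[MappedRead]:
    """Drop PCR duplicates: reads at the same location in the same orientation.

    The key is the 5'-most coordinate together with the strand; the
    first read encountered per key is kept and order is preserved.
    """
    seen = set()
    for read in reads:
        key = (read.chrom, read.five_prime, read.strand)
        if key not in seen:
            seen.add(key)
            yield read


def bin_reads(reads: Iterable[MappedRead], grid: WindowGrid):
    """Bin reads by midpoint into the grid; returns (counts, n_skipped).

    Each read increments the window containing ``floor((start+end)/2)``.
    Reads on chromosomes absent from the grid are skipped and counted;
    midpoints beyond the declared chromosome length land in the last
    window of the chromosome.
    """
    counts = np.zeros(grid.n, dtype=np.int64)
    skipped = 0
    overflow = 0
    for read in reads:
        if read.chrom not in grid.chrom_lengths:
            skipped += 1
            continue
        mid = read.midpoint
        if mid >= grid.chrom_lengths[read.chrom]:
            overflow += 1
        counts[grid.window_index(read.chrom, mid)] += 1
    if skipped:
        logger.warning("%d reads on chromosomes absent from the grid were skipped", skipped)
    if overflow:
        warnings.warn(
            f"{overflow} read midpoints beyond the declared chromosome length "
            "were assigned to the last window"
        )
    return counts, skipped


def _infer_chrom_lengths(paths_formats) -> dict:
    lengths = {}
    for path, fmt in paths_formats:
        for read in read_mapped_reads(path, fmt):
            if read.end > lengths.get(read.chrom, 0):
                lengths[read.chrom] = read.end
    return lengths


def build_count_matrix(
    control_paths: Sequence,
    chip_paths: Sequence,
    window_size: int = DEFAULT_WINDOW_SIZE,
    chrom_lengths: dict = None,
    format: str = None,
    infer_lengths: bool = False,
) -> CountMatrix:
    """Read, deduplicate and bin every profile into one CountMatrix.

    Columns are ordered controls first, then ChIP profiles; duplicates
    are removed per profile before binning.  When ``chrom_lengths`` is
    not given, lengths are inferred from the maximal read coordinate
    only if ``infer_lengths`` is set.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if not control_paths or not chip_paths:
        raise ValueError(
            "discretization requires at least one negative control and one "
            "ChIP-seq profile"
        )
    paths = list(control_paths) + list(chip_paths)
    roles = ["control"] * len(control_paths) + ["chip"] * len(chip_paths)
    if chrom_lengths is None:
        if not infer_lengths:
            raise ValueError("chrom_lengths not given; pass infer_lengths=True to infer")
        chrom_lengths = _infer_chrom_lengths((p, format) for p in paths)
    grid = WindowGrid(window_size, dict(chrom_lengths))

    columns = []
    missing = set()
    for path in paths:
        reads = deduplicate(read_mapped_reads(path, format))
        col, _ = bin_reads(
            (r for r in reads if not _track_missing(r, grid, missing)), grid
        )
        columns.append(col)
    if missing:
        logger.warning(
            "reads on chromosomes absent from chrom_lengths were skipped: %s",
            ", ".join(sorted(missing)),
        )
    counts = np.stack(columns, axis=1)
    mean_per_window = counts.mean(axis=0)
    if np.any(mean_per_window < 3):
        warnings.warn(
            "some profiles average fewer than 3 reads per window; consider a "
            "larger window size"
        )
    names = [Path(p).name.split(".")[0] for p in paths]
    if len(set(names)) != len(names):
        names = None
    return CountMatrix(grid=grid, counts=counts, roles=roles, names=names)


def _track_missing(read, grid, missing) -> bool:
    if read.chrom not in grid.chrom_lengths:
        missing.add(read.chrom)
        return True
    return False
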