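"""Core data model: genome bin grid, per-bin profiles, genomic intervals.

Coordinates are 0-based half-open internally.  Report writers render
1-based inclusive coordinates; see :mod:`niptcnv.io`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DEFAULT_BIN_SIZE",
    "GenomeModel",
    "GenomicInterval",
    "BinProfile",
    "ProfileState",
    "bin_reads",
]

DEFAULT_BIN_SIZE = 20_000

#: chromosome names treated as sex chromosomes (everything else is autosomal)
SEX_CHROM_NAMES = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping base pairs (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def to_report_coords(self) -> tuple[str, int, int]:
        """Render as 1-based inclusive (chrom, start, end)."""
        return self.chrom, self.start + 1, self.end


class GenomeModel:
    """Fixed-width bin tiling of a genome with per-bin GC and mappability.

    Bins tile each chromosome left to right without overlap; the last bin
    of a chromosome may be shorter than ``bin_size``.  Per-bin arrays are
    stored concatenated in chromosome order.
    """

    def __init__(
        self,
        names: list[str],
        lengths: list[int],
        bin_size: int = DEFAULT_BIN_SIZE,
        gc: np.ndarray | None = None,
        mappable: np.ndarray | None = None,
    ):
        if len(names) != len(lengths):
            raise ValueError("names and lengths differ in length")
        if len(names) == 0:
            raise ValueError("empty genome")
        if any(l <= 0 for l in lengths):
            raise ValueError("chromosome lengths must be positive")
        if bin_size <= 0:
            raise ValueError("bin size must be positive")
        self.names = list(names)
        self.lengths = dict(zip(self.names, (int(l) for l in lengths)))
        self.bin_size = int(bin_size)
        self._nbins = {
            c: -(-self.lengths[c] // self.bin_size) for c in self.names
        }
        offs = np.concatenate([[0], np.cumsum([self._nbins[c] for c in self.names])])
        self._offsets = {c: int(offs[i]) for i, c in enumerate(self.names)}
        self.n_bins = int(offs[-1])

        if mappable is None:
            mappable = np.ones(self.n_bins, dtype=bool)
        mappable = np.asarray(mappable, dtype=bool).copy()
        if mappable.shape != (self.n_bins,):
            raise ValueError("mappable flag has wrong length")
        # terminal short bins (< bin_size / 2) are kept but flagged unmappable
        for c in self.names:
            tail = self.lengths[c] - (self._nbins[c] - 1) * self.bin_size
            if tail < self.bin_size / 2:
                mappable[self._offsets[c] + self._nbins[c] - 1] = False
        self.mappable = mappable

        if gc is None:
            gc = np.full(self.n_bins, np.nan)
        gc = np.asarray(gc, dtype=float)
        if gc.shape != (self.n_bins,):
            raise ValueError("GC track has wrong length")
        bad = self.mappable & ~((gc >= 0.0) & (gc <= 1.0))
        if bad.any():
            raise ValueError(
                f"GC fraction missing or outside [0, 1] for {int(bad.sum())} mappable bins"
            )
        self.gc = gc

    # -- bin bookkeeping ---------------------------------------------------
    def n_chrom_bins(self, chrom: str) -> int:
        return self._nbins[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        o = self._offsets[chrom]
        return slice(o, o + self._nbins[chrom])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of position ``pos`` (0-based) on ``chrom``."""
        if not (0 <= pos < self.lengths[chrom]):
            raise ValueError(f"position {chrom}:{pos} outside chromosome bounds")
        return self._offsets[chrom] + pos // self.bin_size

    def bin_interval(self, global_bin: int) -> GenomicInterval:
        """Genomic interval covered by a global bin index."""
        chrom = self.bin_chrom(global_bin)
        local = global_bin - self._offsets[chrom]
        start = local * self.bin_size
        end = min(start + self.bin_size, self.lengths[chrom])
        return GenomicInterval(chrom, start, end)

    def bin_chrom(self, global_bin: int) -> str:
        if not (0 <= global_bin < self.n_bins):
            raise IndexError(f"bin {global_bin} out of range")
        for c in self.names:
            if global_bin < self._offsets[c] + self._nbins[c]:
                return c
        raise AssertionError("unreachable")

    def bins_overlapping(self, interval: GenomicInterval) -> np.ndarray:
        """Global indices of bins with any overlap with ``interval``."""
        if interval.chrom not in self.lengths:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        o = self._offsets[interval.chrom]
        first = interval.start // self.bin_size
        last = min((interval.end - 1) // self.bin_size, self._nbins[interval.chrom] - 1)
        return np.arange(o + first, o + last + 1)

    def is_autosome(self, chrom: str) -> bool:
        return chrom not in SEX_CHROM_NAMES

    @property
    def autosome_names(self) -> list[str]:
        return [c for c in self.names if self.is_autosome(c)]

    @property
    def sex_names(self) -> list[str]:
        return [c for c in self.names if not self.is_autosome(c)]

    def autosome_bin_mask(self) -> np.ndarray:
        m = np.zeros(self.n_bins, dtype=bool)
        for c in self.autosome_names:
            m[self.chrom_slice(c)] = True
        return m

    def same_grid(self, other: "GenomeModel") -> bool:
        return (
            self.names == other.names
            and self.lengths == other.lengths
            and self.bin_size == other.bin_size
        )

    def __repr__(self) -> str:  # pragma: no cover
        mb = sum(self.lengths.values()) / 1e6
        return (
            f"GenomeModel({len(self.names)} chroms, {mb:.0f} Mb, "
            f"B={self.bin_size}, {self.n_bins} bins)"
        )


class ProfileState(enum.IntEnum):
    """Processing state of a bin profile; transitions move forward only."""

    RAW = 0
    GC_CORRECTED = 1
    PCA_NORMALIZED = 2
    CENTERED = 3


@dataclass
class BinProfile:
    """Per-bin numeric values on a genome bin grid.

    Raw profiles hold non-negative integer read counts whose sum equals
    ``read_count``; downstream states hold float values (centered profiles
    carry NaN on bins excluded by the normalization filter).
    """

    genome: GenomeModel
    values: np.ndarray
    state: ProfileState = ProfileState.RAW
    read_count: int | None = None
    ff: float | None = None
    sample_id: str | None = None
    incomplete: bool = False
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.genome.n_bins,):
            raise ValueError("value vector length does not match genome bin grid")
        if self.ff is not None and not (0.0 < self.ff <= 1.0):
            raise ValueError(f"fetal fraction {self.ff} outside (0, 1]")
        if self.state == ProfileState.RAW:
            if np.any(self.values < 0) or np.any(self.values != np.floor(self.values)):
                raise ValueError("raw profile values must be non-negative integers")
            total = int(self.values.sum())
            if self.read_count is None:
                self.read_count = total
            elif self.read_count != total:
                raise ValueError(
                    f"read_count {self.read_count} != sum of raw bin values {total}"
                )

    def advanced(self, values: np.ndarray, state: ProfileState) -> "BinProfile":
        """Copy with new values in a strictly later state."""
        if state <= self.state:
            raise ValueError(
                f"state transition {self.state.name} -> {state.name} is not forward"
            )
        return replace(self, values=np.asarray(values, dtype=float), state=state)

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.genome.chrom_slice(chrom)]

    def require_state(self, state: ProfileState) -> None:
        if self.state != state:
            raise ValueError(
                f"profile in state {self.state.name}, expected {state.name}"
            )
        if self.incomplete:
            raise ValueError("profile is incomplete (missing chromosomes)")


def bin_reads(
    read_starts: dict[str, np.ndarray], genome: GenomeModel
) -> BinProfile:
    """Count read start positions into the genome's bin grid.

    A read at position ``p`` falls into bin ``p // bin_size`` of its
    chromosome (half-open bins).  Positions outside chromosome bounds are
    rejected with the offending coordinate reported.
    """
    counts = np.zeros(genome.n_bins, dtype=np.int64)
    total = 0
    for chrom, positions in read_starts.items():
        if chrom not in genome.lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        pos = np.asarray(positions, dtype=np.int64)
        if pos.size == 0:
            continue
        bad = (pos < 0) | (pos >= genome.lengths[chrom])
        if bad.any():
            off = int(pos[bad][0])
            raise ValueError(
                f"read position {chrom}:{off} outside chromosome "
                f"(length {genome.lengths[chrom]})"
            )
        local = np.bincount(pos // genome.bin_size, minlength=genome.n_chrom_bins(chrom))
        counts[genome.chrom_slice(chrom)] += local
        total += pos.size
    return BinProfile(genome, counts, ProfileState.RAW, read_count=total)
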