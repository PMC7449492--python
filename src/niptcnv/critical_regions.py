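"""Syndrome critical-region derivation from labelled deletion records.

The per-base coverage of pathogenic deletions is profiled as a step
function; an initial coverage cutoff (45) defines a candidate region which
is iteratively widened — by lowering the cutoff one step at a time — until
no non-excluded pathogenic deletion lies entirely outside it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenomicInterval

__all__ = [
    "DeletionRecord",
    "CriticalRegion",
    "CoverageProfile",
    "coverage_profile",
    "region_at_cutoff",
    "find_outliers",
    "derive_region",
    "read_deletion_records",
    "write_deletion_records",
    "bundled_deletion_size_table",
    "bundled_syndrome_regions",
    "PUBLISHED_CUTOFFS",
]

PATHOGENIC_CLASSES = frozenset({"pathogenic", "likely_pathogenic"})
BENIGN_CLASSES = frozenset({"benign", "likely_benign"})
_ALL_CLASSES = PATHOGENIC_CLASSES | BENIGN_CLASSES

#: final per-syndrome cutoffs as published; reproducible only against the
#: original database snapshot, shipped as a documented preset.
PUBLISHED_CUTOFFS = {
    "1p36 deletion": 3,
    "Wolf-Hirschhorn": 45,
    "Cri-du-chat": 28,
    "Angelman/Prader-Willi": 25,
    "DiGeorge": 45,
}

DEFAULT_INITIAL_CUTOFF = 45


@dataclass(frozen=True)
class DeletionRecord:
    interval: GenomicInterval
    classification: str
    source_id: str

    def __post_init__(self) -> None:
        if self.classification not in _ALL_CLASSES:
            raise ValueError(
                f"classification {self.classification!r} not in {sorted(_ALL_CLASSES)}"
            )

    @property
    def is_pathogenic(self) -> bool:
        return self.classification in PATHOGENIC_CLASSES


@dataclass
class CriticalRegion:
    interval: GenomicInterval
    cutoff: int
    n_support: int
    excluded_ids: tuple[str, ...]


class CoverageProfile:
    """Piecewise-constant deletion coverage on one chromosome.

    ``breaks`` are sorted positions; ``values[i]`` is the coverage on
    ``[breaks[i], breaks[i+1])``.  Coverage is zero outside the breaks.
    """

    def __init__(self, chrom: str, breaks: np.ndarray, values: np.ndarray):
        self.chrom = chrom
        self.breaks = breaks
        self.values = values

    def value_at(self, pos: int) -> int:
        if self.breaks.size == 0 or pos < self.breaks[0] or pos >= self.breaks[-1]:
            return 0
        i = int(np.searchsorted(self.breaks, pos, side="right")) - 1
        return int(self.values[i])

    def max(self) -> int:
        return int(self.values.max()) if self.values.size else 0

    def argmax_position(self) -> int | None:
        if self.values.size == 0:
            return None
        return int(self.breaks[int(np.argmax(self.values))])

    def integral(self) -> int:
        widths = np.diff(self.breaks)
        return int(np.sum(widths * self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chrom,
                "start": self.breaks[:-1] if self.breaks.size else [],
                "end": self.breaks[1:] if self.breaks.size else [],
                "coverage": self.values,
            }
        )


def coverage_profile(
    records: list[DeletionRecord],
    class_filter: frozenset[str] | set[str] = PATHOGENIC_CLASSES,
) -> CoverageProfile:
    """Sweep-line coverage: value at p = #filtered records with start <= p < end."""
    kept = [r for r in records if r.classification in class_filter]
    chroms = {r.interval.chrom for r in kept}
    if len(chroms) > 1:
        raise ValueError(f"records span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop() if chroms else ""
    if not kept:
        return CoverageProfile(chrom, np.array([], dtype=np.int64), np.array([], dtype=np.int64))
    events = np.concatenate(
        [
            np.array([(r.interval.start, 1) for r in kept], dtype=np.int64),
            np.array([(r.interval.end, -1) for r in kept], dtype=np.int64),
        ]
    )
    order = np.lexsort((events[:, 1], events[:, 0]))
    events = events[order]
    breaks_all = events[:, 0]
    uniq, first_idx = np.unique(breaks_all, return_index=True)
    deltas = np.add.reduceat(events[:, 1], first_idx)
    values = np.cumsum(deltas)[:-1]
    return CoverageProfile(chrom, uniq, values)


def region_at_cutoff(coverage: CoverageProfile, c: int) -> list[GenomicInterval]:
    """Maximal intervals where coverage >= c, in genomic order."""
    if c < 1:
        raise ValueError("cutoff must be >= 1")
    out: list[GenomicInterval] = []
    above = coverage.values >= c
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            out.append(
                GenomicInterval(
                    coverage.chrom,
                    int(coverage.breaks[i]),
                    int(coverage.breaks[j + 1]),
                )
            )
            i = j + 1
        else:
            i += 1
    return out


def find_outliers(
    records: list[DeletionRecord],
    region: GenomicInterval,
    min_overlap: int = 0,
) -> list[DeletionRecord]:
    """Pathogenic records whose overlap with the region is <= min_overlap bp.

    With ``min_overlap = 0`` this is exactly "entirely outside the region";
    the published distal-deletion exclusion used 20,000 bp.
    """
    if min_overlap < 0:
        raise ValueError("min_overlap must be >= 0")
    return [
        r
        for r in records
        if r.is_pathogenic and r.interval.overlap(region) <= min_overlap
    ]


def derive_region(
    records: list[DeletionRecord],
    initial_cutoff: int = DEFAULT_INITIAL_CUTOFF,
    exclusions: set[str] | frozenset[str] = frozenset(),
    min_overlap: int = 0,
) -> CriticalRegion:
    """Iteratively lower the coverage cutoff until no pathogenic outlier remains.

    Starting at ``initial_cutoff`` (or the maximal coverage if smaller), the
    candidate region — the superlevel interval containing the coverage
    maximum — is widened one cutoff step at a time.  Raises when the cutoff
    reaches zero with outliers remaining (manual exclusions needed).
    """
    used = [r for r in records if r.is_pathogenic and r.source_id not in exclusions]
    if not used:
        raise ValueError("no pathogenic records left after exclusions")
    cov = coverage_profile(used)
    peak = cov.argmax_position()
    c = min(initial_cutoff, cov.max())
    while c >= 1:
        intervals = region_at_cutoff(cov, c)
        region = next(
            (iv for iv in intervals if iv.start <= peak < iv.end), intervals[0]
        )
        outliers = find_outliers(used, region, min_overlap)
        if not outliers:
            return CriticalRegion(
                interval=region,
                cutoff=c,
                n_support=len(used) - len(outliers),
                excluded_ids=tuple(sorted(exclusions)),
            )
        c -= 1
    raise ValueError(
        "cutoff reached zero with pathogenic outliers remaining; "
        "consider excluding outlier records explicitly"
    )


# -- record I/O ------------------------------------------------------------


def read_deletion_records(path: str | Path) -> list[DeletionRecord]:
    """TSV/BED with columns chrom, start, end, classification[, source_id]."""
    out: list[DeletionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 fields")
            source = fields[4] if len(fields) > 4 else f"record_{lineno}"
            try:
                out.append(
                    DeletionRecord(
                        GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                        fields[3],
                        source,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return out


def write_deletion_records(records: list[DeletionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tclassification\tsource_id\n")
        for r in records:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.classification}\t{r.source_id}\n"
            )


def write_region_report(
    regions: dict[str, CriticalRegion] | dict[str, GenomicInterval],
    path: str | Path,
) -> None:
    """1-based inclusive TSV report (Syndrome, Chromosome, Start, End)."""
    with open(path, "w") as fh:
        fh.write("Syndrome\tChromosome\tStart position\tEnd position\n")
        for name, reg in regions.items():
            iv = reg.interval if isinstance(reg, CriticalRegion) else reg
            chrom, start, end = iv.to_report_coords()
            fh.write(f"{name}\t{chrom}\t{start}\t{end}\n")


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("niptcnv") / "data" / name)


def bundled_deletion_size_table() -> pd.DataFrame:
    """Counts of evaluation microdeletions per syndrome and size class."""
    return pd.read_csv(_data_path("deletion_size_counts.tsv"), sep="\t", index_col=0)


def bundled_syndrome_regions() -> dict[str, GenomicInterval]:
    """Published critical regions (hg19), stored 1-based inclusive on disk."""
    df = pd.read_csv(_data_path("syndrome_regions.tsv"), sep="\t")
    return {
        row["Syndrome"]: GenomicInterval(
            str(row["Chromosome"]), int(row["Start position"]) - 1, int(row["End position"])
        )
        for _, row in df.iterrows()
    }
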