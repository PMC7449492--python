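"""Readers and writers for the on-disk formats.

Bin tables and genome tables are plain TSV; regions can be read from BED
(0-based) or written as 1-based inclusive TSV reports.  An optional BAM
binning entry point is provided behind a lazy pysam import.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .core import BinProfile, GenomeModel, GenomicInterval, ProfileState, bin_reads

log = logging.getLogger(__name__)

__all__ = [
    "read_bin_table",
    "write_bin_table",
    "read_genome_table",
    "write_genome_table",
    "read_region_bed",
    "write_region_bed",
    "bin_bam",
]


class ParseError(ValueError):
    """Raised for malformed input files; message names the line number."""


def write_bin_table(profile: BinProfile, path: str | Path) -> None:
    """Write a profile as TSV (chromosome, bin_start, bin_end, value).

    Metadata (state, read count, fetal fraction, sample id) goes into
    ``#``-prefixed header lines so that write-then-read is the identity.
    """
    g = profile.genome
    with open(path, "w") as fh:
        fh.write("# niptcnv bin table v1\n")
        fh.write(f"# state={profile.state.name.lower()}\n")
        if profile.read_count is not None:
            fh.write(f"# read_count={profile.read_count}\n")
        if profile.ff is not None:
            fh.write(f"# ff={profile.ff}\n")
        if profile.sample_id is not None:
            fh.write(f"# sample_id={profile.sample_id}\n")
        fh.write("chromosome\tbin_start\tbin_end\tvalue\n")
        is_int = profile.state == ProfileState.RAW
        for chrom in g.names:
            vals = profile.chrom_values(chrom)
            B = g.bin_size
            L = g.lengths[chrom]
            for i, v in enumerate(vals):
                end = min((i + 1) * B, L)
                if is_int:
                    fh.write(f"{chrom}\t{i * B}\t{end}\t{int(v)}\n")
                else:
                    fh.write(f"{chrom}\t{i * B}\t{end}\t{float(v)!r}\n")


def read_bin_table(path: str | Path, genome: GenomeModel) -> BinProfile:
    """Read a TSV bin table; validates bin boundaries against ``genome``.

    Chromosomes present in the genome but absent from the file leave the
    profile flagged incomplete; downstream operations refuse such profiles.
    """
    meta: dict[str, str] = {}
    values = np.full(genome.n_bins, np.nan)
    seen: set[str] = set()
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields[:4] != ["chromosome", "bin_start", "bin_end", "value"]:
                    raise ParseError(
                        f"{path}:{lineno}: missing or malformed header row"
                    )
                header_seen = True
                continue
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            chrom, s_start, s_end, s_val = fields
            if chrom not in genome.lengths:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end = int(s_start), int(s_end)
                val = float(s_val)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            B = genome.bin_size
            if start % B != 0:
                raise ParseError(
                    f"{path}:{lineno}: bin_start {start} not a multiple of bin size {B}"
                )
            expected_end = min(start + B, genome.lengths[chrom])
            if end != expected_end:
                raise ParseError(
                    f"{path}:{lineno}: bin [{start}, {end}) inconsistent with "
                    f"genome model (expected end {expected_end})"
                )
            idx = genome.bin_index(chrom, start)
            values[idx] = val
            seen.add(chrom)
    if not header_seen:
        raise ParseError(f"{path}: no header row found")
    missing = [c for c in genome.names if c not in seen]
    incomplete = bool(missing)
    nan_left = ~np.isfinite(values)
    state = ProfileState[meta.get("state", "raw").upper()]
    if state != ProfileState.CENTERED:
        for c in missing:
            values[genome.chrom_slice(c)] = 0.0
        if nan_left.any() and not incomplete:
            raise ParseError(f"{path}: {int(nan_left.sum())} bins missing from table")
    if state == ProfileState.RAW and incomplete:
        # sum check would fail against stored read_count; construct manually
        prof = BinProfile(
            genome,
            values,
            ProfileState.RAW,
            read_count=int(values[np.isfinite(values)].sum()),
        )
    else:
        prof = BinProfile(
            genome,
            values,
            state,
            read_count=int(meta["read_count"]) if "read_count" in meta else None,
            ff=float(meta["ff"]) if "ff" in meta else None,
            sample_id=meta.get("sample_id"),
        )
    prof.incomplete = incomplete
    prof.sample_id = meta.get("sample_id", prof.sample_id)
    if incomplete:
        log.warning("%s: missing chromosomes %s; profile marked incomplete", path, missing)
    return prof


def write_genome_table(genome: GenomeModel, path: str | Path) -> None:
    """TSV with chrom, bin_start, bin_end, gc, mappable for every bin."""
    with open(path, "w") as fh:
        fh.write(f"# niptcnv genome v1 bin_size={genome.bin_size}\n")
        fh.write("chromosome\tbin_start\tbin_end\tgc\tmappable\n")
        for chrom in genome.names:
            B, L = genome.bin_size, genome.lengths[chrom]
            sl = genome.chrom_slice(chrom)
            for i in range(genome.n_chrom_bins(chrom)):
                end = min((i + 1) * B, L)
                gc = float(genome.gc[sl.start + i])
                mp = int(genome.mappable[sl.start + i])
                fh.write(f"{chrom}\t{i * B}\t{end}\t{gc!r}\t{mp}\n")


def read_genome_table(path: str | Path) -> GenomeModel:
    names: list[str] = []
    lengths: dict[str, int] = {}
    gc: list[float] = []
    mappable: list[bool] = []
    bin_size = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("# ").split():
                    if tok.startswith("bin_size="):
                        bin_size = int(tok.split("=", 1)[1])
                continue
            fields = line.split("\t")
            if fields[0] == "chromosome":
                continue
            if len(fields) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 fields")
            chrom, _, s_end, s_gc, s_mp = fields
            if chrom not in lengths:
                names.append(chrom)
                lengths[chrom] = 0
            lengths[chrom] = max(lengths[chrom], int(s_end))
            gc.append(float(s_gc))
            mappable.append(bool(int(s_mp)))
    if bin_size is None:
        raise ParseError(f"{path}: header with bin_size missing")
    return GenomeModel(
        names,
        [lengths[c] for c in names],
        bin_size=bin_size,
        gc=np.array(gc),
        mappable=np.array(mappable, dtype=bool),
    )


def read_region_bed(path: str | Path) -> list[GenomicInterval]:
    """Read intervals from a BED-like file (0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def write_region_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def bin_bam(bam_path: str | Path, genome: GenomeModel) -> BinProfile:
    """Bin the leftmost position of primary, uniquely mapped reads of a BAM.

    Unmapped, secondary, supplementary and duplicate reads are skipped and
    counted in a log line.  Requires an index.
    """
    import pysam  # local import: optional dependency

    starts: dict[str, list[int]] = {c: [] for c in genome.names}
    skipped = 0
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if not bam.has_index():
            raise ValueError(f"{bam_path}: BAM index required (samtools index)")
        for chrom in genome.names:
            if chrom not in bam.references:
                continue
            for read in bam.fetch(chrom):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                ):
                    skipped += 1
                    continue
                starts[chrom].append(read.reference_start)
    if skipped:
        log.info("%s: skipped %d non-primary/duplicate/unmapped reads", bam_path, skipped)
    return bin_reads({c: np.array(p, dtype=np.int64) for c, p in starts.items()}, genome)
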