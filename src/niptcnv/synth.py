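"""Synthetic data generators: genomes, euploid cohorts, aberrated cases,
and labelled deletion-record sets.

The default mini-genome (three autosomes plus X/Y, ~310 Mb, 20 kb bins)
keeps whole-pipeline studies desk-scale.  Read counts are specified as
full-genome equivalents: a "20M-read" sample on the mini-genome carries
the same per-bin depth as 20M reads spread over a ~3.1 Gb genome, so the
normalization filter thresholds and calling thresholds behave exactly as
at production scale.

Per-bin expected rates follow ``r_i ~ w_i * g(GC_i) * (1 + sum_k lambda_k
u_ik f_k)`` with smooth GC response ``g``, fixed smooth loadings ``u``,
sample factors ``f_k ~ N(0, 1)``, and Poisson (optionally overdispersed)
count sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinProfile, GenomeModel, GenomicInterval, ProfileState
from .critical_regions import DeletionRecord
from .study import SpikeSpec

__all__ = [
    "SynthConfig",
    "MINI_GENOME_LENGTHS",
    "FULL_GENOME_BINS",
    "make_genome",
    "make_cohort",
    "make_case",
    "make_isca_like",
    "equivalent_read_count",
]

#: 3.1 Gb / 20 kb — bin count of the full genome used for depth equivalence
FULL_GENOME_BINS = 155_000

MINI_GENOME_LENGTHS = {
    "chr1": 120_000_000,
    "chr2": 100_000_000,
    "chr3": 60_000_000,
    "chrX": 25_000_000,
    "chrY": 5_000_000,
}


@dataclass
class SynthConfig:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(MINI_GENOME_LENGTHS)
    )
    bin_size: int = 20_000
    reads: int = 20_000_000  # full-genome-equivalent read count per sample
    gc_smooth_bins: int = 25
    gc_center: float = 0.45
    gc_amplitude: float = 0.06
    gc_range: tuple[float, float] = (0.3, 0.6)
    gc_bias_slope: float = 1.5
    gc_bias_curvature: float = -6.0
    noise_magnitudes: tuple[float, ...] = (0.03, 0.02, 0.01)
    gap_fraction: float = 0.05
    low_rate_fraction: float = 0.0  # fraction of bins forced to near-zero rate
    overdispersion: float = 0.0  # gamma CV^2; 0 -> pure Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        for m in self.noise_magnitudes:
            if not np.isfinite(m):
                raise ValueError("noise magnitudes must be finite")


def equivalent_read_count(genome: GenomeModel, nominal_reads: int) -> int:
    """Actual read total on ``genome`` matching a full-genome read count."""
    return int(round(nominal_reads * genome.n_bins / FULL_GENOME_BINS))


def _smooth_noise(rng: np.random.Generator, n: int, width: int) -> np.ndarray:
    """Unit-variance spatially autocorrelated Gaussian noise."""
    z = rng.standard_normal(n + 4 * width)
    k = np.exp(-0.5 * (np.arange(-2 * width, 2 * width + 1) / max(width, 1)) ** 2)
    k /= k.sum()
    sm = np.convolve(z, k, mode="same")[2 * width : 2 * width + n]
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def make_genome(config: SynthConfig) -> GenomeModel:
    """Generate the bin grid: smooth GC track plus centromere-like gaps."""
    if not config.chrom_lengths or sum(config.chrom_lengths.values()) <= 0:
        raise ValueError("zero-length genome")
    rng = np.random.default_rng(config.seed)
    names = list(config.chrom_lengths)
    lengths = [config.chrom_lengths[c] for c in names]
    gc_parts, map_parts = [], []
    for c, L in zip(names, lengths):
        n = -(-L // config.bin_size)
        gc = config.gc_center + config.gc_amplitude * _smooth_noise(
            rng, n, config.gc_smooth_bins
        )
        gc = np.clip(gc, *config.gc_range)
        mappable = np.ones(n, dtype=bool)
        gap = int(round(config.gap_fraction * n))
        if gap > 0:
            mid = n // 2
            mappable[mid - gap // 2 : mid - gap // 2 + gap] = False
        gc_parts.append(gc)
        map_parts.append(mappable)
    return GenomeModel(
        names,
        lengths,
        bin_size=config.bin_size,
        gc=np.concatenate(gc_parts),
        mappable=np.concatenate(map_parts),
    )


def _base_rate(genome: GenomeModel, config: SynthConfig) -> np.ndarray:
    """Fixed per-bin expected-rate shape (mappability x GC response)."""
    d = genome.gc - config.gc_center
    g = np.exp(config.gc_bias_slope * d + config.gc_bias_curvature * d * d)
    rate = np.where(genome.mappable, g, 0.0)
    if config.low_rate_fraction > 0:
        rng = np.random.default_rng(config.seed + 101)
        idx = np.flatnonzero(genome.mappable)
        n_low = int(round(config.low_rate_fraction * idx.size))
        low = rng.choice(idx, size=n_low, replace=False)
        rate[low] *= 0.02
    return rate


def _noise_loadings(genome: GenomeModel, config: SynthConfig) -> np.ndarray:
    """Fixed smooth loadings shared by the whole cohort (K x n_bins)."""
    rng = np.random.default_rng(config.seed + 202)
    K = len(config.noise_magnitudes)
    u = np.zeros((K, genome.n_bins))
    for k in range(K):
        v = _smooth_noise(rng, genome.n_bins, 50)
        v[~genome.mappable] = 0.0
        rms = np.sqrt(np.mean(v[genome.mappable] ** 2)) if genome.mappable.any() else 1.0
        u[k] = v / rms if rms > 0 else v
    return u


def _sample_counts(
    rate: np.ndarray,
    loadings: np.ndarray,
    config: SynthConfig,
    reads: int,
    genome: GenomeModel,
    rng: np.random.Generator,
) -> np.ndarray:
    lam = np.asarray(config.noise_magnitudes)
    factors = rng.standard_normal(lam.size)
    mult = 1.0 + loadings.T @ (lam * factors)
    r = rate * np.clip(mult, 0.05, None)
    total = equivalent_read_count(genome, reads)
    expected = r / r.sum() * total
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        expected = rng.gamma(shape, expected / shape)
    return rng.poisson(expected)


def make_cohort(
    genome: GenomeModel,
    n_samples: int,
    reads: int | None = None,
    config: SynthConfig | None = None,
    seed: int | None = None,
) -> list[BinProfile]:
    """Euploid training cohort of Poisson-sampled raw bin-count profiles."""
    config = config or SynthConfig()
    reads = reads if reads is not None else config.reads
    rng = np.random.default_rng(config.seed + 1_000 if seed is None else seed)
    rate = _base_rate(genome, config)
    loadings = _noise_loadings(genome, config)
    out = []
    for i in range(n_samples):
        counts = _sample_counts(rate, loadings, config, reads, genome, rng)
        out.append(
            BinProfile(
                genome,
                counts,
                ProfileState.RAW,
                read_count=int(counts.sum()),
                sample_id=f"synth_{i:04d}",
            )
        )
    return out


def make_case(
    genome: GenomeModel,
    cnv: SpikeSpec,
    reads: int | None = None,
    config: SynthConfig | None = None,
    seed: int | None = None,
) -> tuple[BinProfile, SpikeSpec]:
    """A single aberrated sample: the CNV enters the expected rates before
    Poisson sampling (in contrast to post-normalization spiking)."""
    config = config or SynthConfig()
    reads = reads if reads is not None else config.reads
    rng = np.random.default_rng(config.seed + 2_000 if seed is None else seed)
    rate = _base_rate(genome, config).copy()
    bins = genome.bins_overlapping(cnv.interval)
    if not genome.mappable[bins].any():
        raise ValueError("CNV region lies entirely within unmappable bins")
    rate[bins] *= cnv.factor
    loadings = _noise_loadings(genome, config)
    counts = _sample_counts(rate, loadings, config, reads, genome, rng)
    profile = BinProfile(
        genome,
        counts,
        ProfileState.RAW,
        read_count=int(counts.sum()),
        ff=cnv.ff,
        sample_id="synth_case",
    )
    return profile, cnv


def make_isca_like(
    true_region: GenomicInterval,
    n_pathogenic: int,
    n_benign: int,
    flank_scale: float,
    seed: int,
    chrom_length: int | None = None,
) -> list[DeletionRecord]:
    """Labelled deletion records around a known core region.

    Every pathogenic record contains the core with exponentially
    distributed flanks; benign records are placed uniformly but never
    contain the core, so the core is recoverable by coverage-cutoff
    derivation.
    """
    rng = np.random.default_rng(seed)
    L = chrom_length if chrom_length is not None else true_region.end + int(50 * max(flank_scale, 1)) + 10_000_000
    records: list[DeletionRecord] = []
    for i in range(n_pathogenic):
        left = rng.exponential(flank_scale) if flank_scale > 0 else 0.0
        right = rng.exponential(flank_scale) if flank_scale > 0 else 0.0
        start = max(0, int(true_region.start - left))
        end = min(L, int(true_region.end + right))
        label = "pathogenic" if rng.random() < 0.7 else "likely_pathogenic"
        records.append(
            DeletionRecord(
                GenomicInterval(true_region.chrom, start, max(end, start + 1)),
                label,
                f"path_{i:04d}",
            )
        )
    for i in range(n_benign):
        for _ in range(100):
            size = int(rng.uniform(50_000, max(true_region.length, 100_000)))
            start = int(rng.uniform(0, max(1, L - size)))
            iv = GenomicInterval(true_region.chrom, start, start + size)
            contains_core = iv.start <= true_region.start and iv.end >= true_region.end
            if not contains_core:
                break
        label = "benign" if rng.random() < 0.7 else "likely_benign"
        records.append(DeletionRecord(iv, label, f"benign_{i:04d}"))
    return records
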