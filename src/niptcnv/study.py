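"""In-silico spike-in evaluation engine.

Artificial aberrated samples are produced by multiplying the bins of a
target region by ``1 - ff/2`` (fetal deletion) or ``1 + ff/2`` (fetal
duplication) after GC and PCA normalization; maternal events use the
``(1 -+ (1 - ff)/2)`` levels.  The engine sweeps (region x background x
fetal-fraction) and (region x background x read-count) grids, calls each
simulated sample and tabulates sensitivity/specificity per size class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import CallerConfig, CnvCall, cbs_segment, classify_segments
from .core import BinProfile, GenomicInterval, ProfileState
from .normalization import NormalizationModel, center, gc_correct, pca_normalize

log = logging.getLogger(__name__)

__all__ = [
    "SpikeSpec",
    "StudyResult",
    "SIZE_CLASSES",
    "DEFAULT_FF_LEVELS",
    "spike_in",
    "downsample",
    "score_detection",
    "run_ff_grid",
    "run_readcount_grid",
    "planned_simulation_count",
    "sensitivity_percent",
    "size_class",
]

#: deletion-size classes in Mb: [low, high) except the last (inclusive)
SIZE_CLASSES = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 10), (10, 40)]
SIZE_CLASS_LABELS = [f"{lo}-{hi}Mb" for lo, hi in SIZE_CLASSES]

DEFAULT_FF_LEVELS = [0.05, 0.075, 0.1, 0.125, 0.15, 0.175, 0.2]
DEFAULT_READ_LEVELS = [r * 1_000_000 for r in range(5, 21)]


@dataclass(frozen=True)
class SpikeSpec:
    """An artificial CNV to inject: where, what, whose, and at which ff."""

    interval: GenomicInterval
    kind: str  # "deletion" | "duplication"
    origin: str  # "fetal" | "maternal"
    ff: float

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "duplication"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.origin not in ("fetal", "maternal"):
            raise ValueError(f"unknown origin {self.origin!r}")
        # ff = 1 is the pure affected-genomic-DNA (hemizygous) limit
        if not (0.0 < self.ff <= 1.0):
            raise ValueError(f"fetal fraction {self.ff} outside (0, 1]")

    @property
    def factor(self) -> float:
        """Multiplicative level applied to in-region bin counts."""
        shift = self.ff / 2.0 if self.origin == "fetal" else (1.0 - self.ff) / 2.0
        return 1.0 - shift if self.kind == "deletion" else 1.0 + shift


def size_class(length_bp: int) -> str:
    mb = length_bp / 1e6
    for (lo, hi), label in zip(SIZE_CLASSES, SIZE_CLASS_LABELS):
        if lo <= mb < hi or (label == SIZE_CLASS_LABELS[-1] and mb <= hi):
            return label
    raise ValueError(f"deletion size {mb:.2f} Mb outside the tabulated classes")


class StudyResult:
    """Per-(size class, axis level) simulation bookkeeping."""

    def __init__(self, axis_name: str, levels: list):
        self.axis_name = axis_name
        self.levels = list(levels)
        shape = (len(SIZE_CLASS_LABELS), len(self.levels))
        self.n_simulations = pd.DataFrame(
            np.zeros(shape, dtype=int), index=SIZE_CLASS_LABELS, columns=self.levels
        )
        self.n_correct = self.n_simulations.copy()
        self.n_fp_free = self.n_simulations.copy()

    def record(self, label: str, level, correct: bool, false_positive: bool) -> None:
        self.n_simulations.loc[label, level] += 1
        if correct:
            self.n_correct.loc[label, level] += 1
        if not false_positive:
            self.n_fp_free.loc[label, level] += 1

    @property
    def total_simulations(self) -> int:
        return int(self.n_simulations.to_numpy().sum())

    @property
    def total_correct(self) -> int:
        return int(self.n_correct.to_numpy().sum())

    def sensitivity(self) -> pd.DataFrame:
        """Fraction of correctly predicted simulations per cell."""
        with np.errstate(invalid="ignore"):
            return self.n_correct / self.n_simulations

    def specificity(self) -> pd.DataFrame:
        """Fraction of simulations without any false-positive call per cell."""
        with np.errstate(invalid="ignore"):
            return self.n_fp_free / self.n_simulations

    def overall_sensitivity_percent(self) -> float:
        return sensitivity_percent(self.total_correct, self.total_simulations)

    def write(self, prefix) -> None:
        self.n_simulations.to_csv(f"{prefix}.n_simulations.tsv", sep="\t")
        self.n_correct.to_csv(f"{prefix}.n_correct.tsv", sep="\t")
        (100 * self.sensitivity()).to_csv(f"{prefix}.sensitivity_pct.tsv", sep="\t")
        (100 * self.specificity()).to_csv(f"{prefix}.specificity_pct.tsv", sep="\t")


def sensitivity_percent(n_correct: int, n_total: int) -> float:
    """Sensitivity as a percentage rounded to one decimal place."""
    if n_total <= 0:
        raise ValueError("no simulations")
    return round(100.0 * n_correct / n_total, 1)


def planned_simulation_count(
    n_regions: int, n_backgrounds: int, n_levels: int
) -> int:
    """One simulation per (region, background, level) combination."""
    return n_regions * n_backgrounds * n_levels


def enlarge_region(
    region: GenomicInterval, genome, flank_bp: int
) -> GenomicInterval:
    """Widen a region by ``flank_bp`` on both sides, clipped to the chromosome."""
    if flank_bp <= 0:
        return region
    return GenomicInterval(
        region.chrom,
        max(0, region.start - flank_bp),
        min(genome.lengths[region.chrom], region.end + flank_bp),
    )


def spike_in(
    profile: BinProfile,
    spec: SpikeSpec,
    model: NormalizationModel | None = None,
) -> BinProfile:
    """Multiply the bins of the target region by the spike factor.

    Operates on PCA-normalized (pre-centering) values, where bin values are
    still on the count scale; equivalently the centered values in the
    region are shifted by ``-+ mb * ff / 2``.
    """
    profile.require_state(ProfileState.PCA_NORMALIZED)
    g = profile.genome
    bins = g.bins_overlapping(spec.interval)
    usable = model.mask[bins] if model is not None else g.mappable[bins]
    if not usable.any():
        raise ValueError(
            f"region {spec.interval.chrom}:{spec.interval.start}-{spec.interval.end} "
            "lies entirely within masked bins; nothing to spike"
        )
    values = profile.values.copy()
    values[bins] *= spec.factor
    out = BinProfile(
        genome=g,
        values=values,
        state=profile.state,
        read_count=profile.read_count,
        ff=spec.ff,
        sample_id=profile.sample_id,
    )
    return out


def downsample(
    profile: BinProfile, target_reads: int, seed: int | np.random.Generator
) -> BinProfile:
    """Binomial thinning of a raw profile to ``target_reads`` expected total."""
    profile.require_state(ProfileState.RAW)
    total = float(profile.values.sum())
    if target_reads > total:
        raise ValueError(f"target {target_reads} exceeds current total {int(total)}")
    if target_reads == total:
        return profile
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = target_reads / total
    thinned = rng.binomial(profile.values.astype(np.int64), p)
    return BinProfile(
        genome=profile.genome,
        values=thinned,
        state=ProfileState.RAW,
        read_count=int(thinned.sum()),
        ff=profile.ff,
        sample_id=profile.sample_id,
    )


def score_detection(
    calls: list[CnvCall], truth: SpikeSpec | list[SpikeSpec]
) -> dict[str, bool]:
    """Score a call list against truth spikes.

    ``correct``: some call of matching kind and origin overlaps a truth
    interval by at least one base.  ``false_positive``: some call overlaps
    no truth interval at all.
    """
    truths = [truth] if isinstance(truth, SpikeSpec) else list(truth)
    correct = any(
        c.kind == t.kind
        and c.origin == t.origin
        and c.interval.overlap(t.interval) > 0
        for c in calls
        for t in truths
    )
    false_positive = any(
        all(c.interval.overlap(t.interval) == 0 for t in truths) for c in calls
    )
    return {"correct": correct, "false_positive": false_positive}


def _normalize_background(bg: BinProfile, model: NormalizationModel):
    norm = pca_normalize(gc_correct(bg, span=model.config.loess_span), model)
    mb = float(np.mean(norm.values[model.mask]))
    return norm, mb


def _simulate_one(
    norm: BinProfile,
    mb: float,
    spec: SpikeSpec,
    model: NormalizationModel,
    config: CallerConfig,
    seed: int,
    chromosomes: list[str] | None,
) -> dict[str, bool]:
    spiked = spike_in(norm, spec, model)
    centered = center(spiked, model)
    cfg = CallerConfig(**{**vars(config), "seed": seed})
    segments = cbs_segment(centered, cfg, chromosomes=chromosomes)
    calls = classify_segments(segments, mb, spec.ff, cfg)
    return score_detection(calls, spec)


def run_ff_grid(
    model: NormalizationModel,
    backgrounds: list[BinProfile] | int,
    regions: list[GenomicInterval] | int,
    ff_levels: list[float] = DEFAULT_FF_LEVELS,
    config: CallerConfig | None = None,
    seed: int = 0,
    kind: str = "deletion",
    origin: str = "fetal",
    count_only: bool = False,
    target_chromosome_only: bool = True,
    enlarge_bp: int = 0,
) -> StudyResult | int:
    """Sweep fetal-fraction levels at fixed read depth.

    One simulation per (region, background, ff level).  With
    ``count_only=True`` only the grid bookkeeping is performed and the
    planned simulation count returned (``backgrounds``/``regions`` may then
    be plain cardinalities).  ``enlarge_bp`` widens every region by that
    many bases on both sides before spiking (off by default).
    """
    n_regions = regions if isinstance(regions, int) else len(regions)
    n_bg = backgrounds if isinstance(backgrounds, int) else len(backgrounds)
    total = planned_simulation_count(n_regions, n_bg, len(ff_levels))
    if count_only:
        return total
    if isinstance(regions, int) or isinstance(backgrounds, int):
        raise ValueError("need actual regions and backgrounds unless count_only=True")
    if not regions:
        raise ValueError("no regions")
    config = config or CallerConfig()
    result = StudyResult("ff", ff_levels)
    sim_no = 0
    for bg in backgrounds:
        norm, mb = _normalize_background(bg, model)
        for region in regions:
            if region.chrom not in model.genome.lengths or region.end > model.genome.lengths[region.chrom]:
                log.warning("region %s outside genome; skipped", region)
                continue
            region = enlarge_region(region, model.genome, enlarge_bp)
            label = size_class(region.length)
            chroms = [region.chrom] if target_chromosome_only else None
            for ff in ff_levels:
                spec = SpikeSpec(region, kind, origin, ff)
                outcome = _simulate_one(
                    norm, mb, spec, model, config, seed + sim_no, chroms
                )
                result.record(label, ff, outcome["correct"], outcome["false_positive"])
                sim_no += 1
    if result.total_simulations != total:
        log.warning(
            "%d of %d planned simulations executed (skipped regions)",
            result.total_simulations,
            total,
        )
    return result


def run_readcount_grid(
    model: NormalizationModel,
    backgrounds: list[BinProfile] | int,
    regions: list[GenomicInterval] | int,
    read_levels: list[int] = DEFAULT_READ_LEVELS,
    ff: float = 0.10,
    config: CallerConfig | None = None,
    seed: int = 0,
    kind: str = "deletion",
    origin: str = "fetal",
    count_only: bool = False,
    target_chromosome_only: bool = True,
    level_labels: list | None = None,
    enlarge_bp: int = 0,
) -> StudyResult | int:
    """Sweep read depths (binomial thinning) at fixed fetal fraction."""
    n_regions = regions if isinstance(regions, int) else len(regions)
    n_bg = backgrounds if isinstance(backgrounds, int) else len(backgrounds)
    total = planned_simulation_count(n_regions, n_bg, len(read_levels))
    if count_only:
        return total
    if isinstance(regions, int) or isinstance(backgrounds, int):
        raise ValueError("need actual regions and backgrounds unless count_only=True")
    if not regions:
        raise ValueError("no regions")
    config = config or CallerConfig()
    labels = level_labels if level_labels is not None else read_levels
    result = StudyResult("reads", labels)
    sim_no = 0
    for bg in backgrounds:
        for level, label_level in zip(read_levels, labels):
            thinned = downsample(bg, level, seed=seed + 977 * sim_no)
            norm, mb = _normalize_background(thinned, model)
            for region in regions:
                if region.chrom not in model.genome.lengths or region.end > model.genome.lengths[region.chrom]:
                    log.warning("region %s outside genome; skipped", region)
                    continue
                region = enlarge_region(region, model.genome, enlarge_bp)
                label = size_class(region.length)
                chroms = [region.chrom] if target_chromosome_only else None
                spec = SpikeSpec(region, kind, origin, ff)
                outcome = _simulate_one(
                    norm, mb, spec, model, config, seed + sim_no, chroms
                )
                result.record(label, label_level, outcome["correct"], outcome["false_positive"])
                sim_no += 1
    return result
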