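"""Segmentation of centered profiles and fetal/maternal CNV classification.

Centered profiles are partitioned per chromosome into equal-level segments
by circular binary segmentation (permutation-tested recursive splitting).
Segments are then classified against fetal-fraction-scaled thresholds: a
heterozygous fetal event shifts the mean bin count by ``mb * ff / 2`` and a
maternal event by ``mb * (1 - ff) / 2``; segments whose absolute mean
oversteps 75% of the respective theoretical level (and satisfy a minimum
length) are called.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._cbs import max_arc_stat, permutation_exceedances
from .core import BinProfile, GenomicInterval, ProfileState
from .normalization import NormalizationModel, center, gc_correct, pca_normalize

log = logging.getLogger(__name__)

__all__ = [
    "CallerConfig",
    "Segment",
    "CnvCall",
    "cbs_segment",
    "classify_segments",
    "call_cnvs",
    "segment_zscore",
    "estimate_ff_y",
]


@dataclass
class CallerConfig:
    """Significance and segmentation parameters of the caller."""

    tau: float = 0.75  # fraction of the theoretical shift a call must overstep
    ff_default: float = 0.05  # used when the fetal fraction is unknown
    min_length_fetal: int = 600_000  # bp
    min_length_maternal: int = 200_000  # bp
    alpha: float = 0.01  # CBS split significance level
    n_permutations: int = 10_000
    seed: int = 0  # base seed for the permutation tests

    def __post_init__(self) -> None:
        if not (0.0 < self.tau <= 1.0):
            raise ValueError(f"tau {self.tau} outside (0, 1]")
        if not (0.0 < self.ff_default < 1.0):
            raise ValueError(f"default fetal fraction {self.ff_default} outside (0, 1)")


@dataclass
class Segment:
    """A constant-level run of retained bins on one chromosome."""

    interval: GenomicInterval
    first_bin: int  # global bin index of the first retained bin
    last_bin: int  # global bin index of the last retained bin (inclusive)
    mean: float
    n_bins: int

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class CnvCall:
    interval: GenomicInterval
    kind: str  # "deletion" | "duplication"
    origin: str  # "fetal" | "maternal"
    mean: float
    zscore: float | None = None
    threshold_fetal: float = math.nan
    threshold_maternal: float = math.nan
    flags: set = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.interval.length


def _segment_indices(x: np.ndarray, config: CallerConfig, seed: int) -> list[tuple[int, int]]:
    """Recursive CBS on a 1-D array; returns half-open index spans."""
    n = x.size
    if n < 2 or np.ptp(x) == 0.0:
        return [(0, n)]
    stop_after = int(config.alpha * config.n_permutations) + 1
    final: list[tuple[int, int]] = []
    stack = [(0, n)]
    test_no = 0
    while stack:
        a, b = stack.pop()
        m = b - a
        if m < 2 or np.ptp(x[a:b]) == 0.0:
            final.append((a, b))
            continue
        stat, i, j = max_arc_stat(np.ascontiguousarray(x[a:b]))
        test_no += 1
        exceed, done = permutation_exceedances(
            np.ascontiguousarray(x[a:b]),
            stat,
            config.n_permutations,
            stop_after,
            (seed + test_no) % (2**31 - 1),
        )
        significant = exceed <= config.alpha * config.n_permutations and done == config.n_permutations
        if not significant:
            final.append((a, b))
            continue
        cuts = [a, a + i, a + j, b]
        for lo, hi in zip(cuts, cuts[1:]):
            if hi > lo:
                stack.append((lo, hi))
    final.sort()
    return final


def cbs_segment(
    profile: BinProfile,
    config: CallerConfig | None = None,
    chromosomes: list[str] | None = None,
) -> list[Segment]:
    """Partition the retained bins of a centered profile into segments.

    Retained bins are the finite entries of the centered profile; each
    chromosome is segmented independently and segments are contiguous over
    its retained bins.  Single-bin chromosomes yield one segment.
    """
    profile.require_state(ProfileState.CENTERED)
    config = config or CallerConfig()
    g = profile.genome
    segments: list[Segment] = []
    for ci, chrom in enumerate(chromosomes if chromosomes is not None else g.names):
        sl = g.chrom_slice(chrom)
        vals = profile.values[sl]
        idx = np.flatnonzero(np.isfinite(vals)) + sl.start
        if idx.size == 0:
            continue
        x = profile.values[idx]
        spans = (
            [(0, idx.size)]
            if idx.size < 2
            else _segment_indices(x, config, seed=config.seed + 7919 * ci)
        )
        for a, b in spans:
            first, last = int(idx[a]), int(idx[b - 1])
            interval = GenomicInterval(
                chrom,
                g.bin_interval(first).start,
                g.bin_interval(last).end,
            )
            segments.append(
                Segment(interval, first, last, float(x[a:b].mean()), b - a)
            )
    return segments


def classify_segments(
    segments: list[Segment],
    mb: float,
    ff: float | None,
    config: CallerConfig | None = None,
    include_intermediate: bool = False,
) -> list[CnvCall]:
    """Classify segments as fetal/maternal deletions/duplications.

    With ``d = |segment mean|``: a maternal call requires
    ``d >= tau * mb * (1 - ff) / 2`` and length >= 200 kb; otherwise a fetal
    call requires ``d >= tau * mb * ff / 2`` and length >= 600 kb.  Ties at
    the threshold count as significant.  When ``ff`` is missing the default
    (5%) is used and every call is flagged ``default_ff``.
    """
    config = config or CallerConfig()
    if mb <= 0:
        raise ValueError(f"mean bin count mb={mb} must be positive")
    default_used = ff is None
    if default_used:
        ff = config.ff_default
    if not (0.0 < ff < 1.0):
        raise ValueError(f"fetal fraction {ff} outside (0, 1)")
    thr_fetal = config.tau * mb * ff / 2.0
    thr_maternal = config.tau * mb * (1.0 - ff) / 2.0
    calls: list[CnvCall] = []
    for seg in segments:
        d = abs(seg.mean)
        kind = "deletion" if seg.mean < 0 else "duplication"
        length = seg.interval.length
        origin = None
        flags: set = set()
        if d >= thr_maternal and length >= config.min_length_maternal:
            origin = "maternal"
        elif d >= thr_fetal and length >= config.min_length_fetal:
            origin = "fetal"
        elif (
            include_intermediate
            and d >= 0.5 * thr_fetal
            and length >= config.min_length_fetal
        ):
            # non-standard annotation for the ambiguous sub-threshold zone
            origin = "fetal"
            flags.add("possible")
        if origin is None:
            continue
        if default_used:
            flags.add("default_ff")
        calls.append(
            CnvCall(
                interval=seg.interval,
                kind=kind,
                origin=origin,
                mean=seg.mean,
                threshold_fetal=thr_fetal,
                threshold_maternal=thr_maternal,
                flags=flags,
            )
        )
    return calls


def segment_zscore(segment: Segment, profile: BinProfile) -> float:
    """Approximate z-score of a segment against the genome-wide noise.

    ``z = mean / (sigma / sqrt(n))`` with sigma the MAD-scaled robust SD of
    centered values outside the segment.  Returns NaN when sigma is zero.
    """
    profile.require_state(ProfileState.CENTERED)
    vals = profile.values
    outside = np.isfinite(vals)
    outside[segment.first_bin : segment.last_bin + 1] = False
    rest = vals[outside]
    if rest.size == 0:
        return math.nan
    sigma = 1.4826 * np.median(np.abs(rest - np.median(rest)))
    if sigma == 0:
        return math.nan
    return float(segment.mean / (sigma / math.sqrt(segment.n_bins)))


def call_cnvs(
    profile: BinProfile,
    model: NormalizationModel,
    ff: float | None = None,
    config: CallerConfig | None = None,
    chromosomes: list[str] | None = None,
    include_intermediate: bool = False,
) -> list[CnvCall]:
    """End-to-end calling: normalize, segment, classify, score.

    ``mb`` (mean bin count at the working scale) is the sample's mean
    retained-bin value after normalization, at its own read depth.
    """
    config = config or CallerConfig()
    normalized = pca_normalize(
        gc_correct(profile, span=model.config.loess_span), model
    )
    mb = float(np.mean(normalized.values[model.mask]))
    centered = center(normalized, model)
    segments = cbs_segment(centered, config, chromosomes=chromosomes)
    calls = classify_segments(
        segments, mb, ff, config, include_intermediate=include_intermediate
    )
    for call in calls:
        seg = next(
            s
            for s in segments
            if s.interval == call.interval and abs(s.mean - call.mean) < 1e-12
        )
        call.zscore = segment_zscore(seg, centered)
    if ff is None:
        log.info("fetal fraction missing; classified with default ff=%g", config.ff_default)
    return calls


def estimate_ff_y(
    profile: BinProfile, male_ref_y: float, female_baseline_y: float
) -> float:
    """Fetal fraction from the chrY read share, by linear interpolation
    between a female background and a pure male reference level."""
    if male_ref_y <= female_baseline_y:
        raise ValueError("male reference chrY fraction must exceed the female baseline")
    g = profile.genome
    total = float(profile.values.sum())
    if total <= 0:
        raise ValueError("profile has no reads")
    y_sum = 0.0
    for chrom in g.sex_names:
        if chrom.lstrip("chr") == "Y":
            y_sum += float(profile.chrom_values(chrom).sum())
    y_frac = y_sum / total
    ff = (y_frac - female_baseline_y) / (male_ref_y - female_baseline_y)
    return float(min(1.0, max(0.0, ff)))
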