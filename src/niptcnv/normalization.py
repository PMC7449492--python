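"""Cohort-trained four-step bin-count normalization.

The pipeline is: LOESS GC correction of each sample against its own
(GC, count) relation; removal of the leading principal components of a
euploid training cohort on autosomal bins; masking of bins with low mean
or high cross-cohort variance at a canonical read scale; and subtraction
of per-bin cohort means so that a healthy profile is centered around zero.

The canonical scale anchors the mean/variance filter thresholds: at
1M reads on a ~3.1 Gb genome the ideal mean bin count for 20 kb bins is
about 6.45 reads, and the thresholds (mean >= 3.0, variance <= 1.5) are
stated at that per-bin depth.  For smaller (synthetic) genomes the scale
is chosen so the ideal per-bin mean is preserved, keeping the thresholds
meaningful regardless of genome size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import statsmodels.api as sm

from .core import BinProfile, GenomeModel, ProfileState

__all__ = [
    "NormalizationConfig",
    "NormalizationModel",
    "gc_correct",
    "fit_reference",
    "pca_normalize",
    "center",
    "retained_fraction",
    "default_scale_total",
]

#: ideal mean reads per 20 kb bin at 1M reads on the full human genome
IDEAL_MEAN_PER_BIN_AT_1M = 1_000_000 / 155_000

_MIN_BINS_FOR_LOESS = 100


def default_scale_total(genome: GenomeModel) -> float:
    """Canonical rescaling target: the equivalent of 1M full-genome reads."""
    return IDEAL_MEAN_PER_BIN_AT_1M * genome.n_bins


@dataclass
class NormalizationConfig:
    n_components: int = 15
    mean_min: float = 3.0
    var_max: float = 1.5
    loess_span: float = 0.3
    scale_total: float | None = None  # None -> default_scale_total(genome)


def _loess_curve(gc: np.ndarray, counts: np.ndarray, span: float):
    """Fit a LOESS curve of counts vs GC; returns (grid_gc, grid_fit)."""
    if gc.max() - gc.min() < 1e-9:  # single GC value: flat smoother
        return np.array([gc[0]]), np.array([counts.mean()])
    delta = 0.005 * (gc.max() - gc.min())
    fitted = sm.nonparametric.lowess(
        counts, gc, frac=span, delta=delta, return_sorted=True
    )
    xs, inv = np.unique(fitted[:, 0], return_inverse=True)
    ys = np.bincount(inv, weights=fitted[:, 1]) / np.bincount(inv)
    return xs, ys


def gc_correct(
    profile: BinProfile, span: float = 0.3
) -> BinProfile:
    """Correct GC bias by the ratio of the global mean to the LOESS fit.

    Each bin value is multiplied by ``mean(counts) / loess(GC_bin)``, where
    the LOESS curve is fitted on the sample's own mappable bins.  Bins with
    GC outside the fitted range use the nearest-edge curve value and are
    flagged in the profile.
    """
    profile.require_state(ProfileState.RAW)
    g = profile.genome
    m = g.mappable
    if int(m.sum()) < _MIN_BINS_FOR_LOESS:
        raise ValueError(
            f"only {int(m.sum())} mappable bins; need >= {_MIN_BINS_FOR_LOESS} "
            "for the GC smoother"
        )
    gc = g.gc[m]
    counts = profile.values[m]
    xs, ys = _loess_curve(gc, counts, span)
    global_mean = counts.mean()
    expected = np.interp(g.gc, xs, ys)  # nearest-edge beyond the fitted range
    floor = max(1e-12, 0.01 * global_mean)
    expected = np.maximum(expected, floor)
    out = profile.values * (global_mean / expected)
    out[~m] = profile.values[~m]
    new = profile.advanced(out, ProfileState.GC_CORRECTED)
    outside = m & ((g.gc < xs[0]) | (g.gc > xs[-1]))
    if outside.any():  # pragma: no cover - cannot happen for self-fitted curve
        new.flags.add("gc_extrapolated")
    return new


@dataclass
class NormalizationModel:
    """Trained cohort artifacts for normalizing query profiles."""

    genome: GenomeModel
    auto_idx: np.ndarray  # global indices of mappable autosomal bins (PCA space)
    components: np.ndarray  # (k, len(auto_idx)) orthonormal rows
    pca_mean: np.ndarray  # training column means in PCA space
    bin_mean: np.ndarray  # per-bin cohort mean at canonical scale (full length)
    bin_var: np.ndarray  # per-bin cohort variance at canonical scale
    mask: np.ndarray  # retained-bin filter (full length, bool)
    scale_total: float
    config: NormalizationConfig = field(default_factory=NormalizationConfig)
    version: int = 1

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def check_genome(self, genome: GenomeModel) -> None:
        if not self.genome.same_grid(genome):
            raise ValueError("profile genome does not match the trained model")

    # -- scaling helpers ---------------------------------------------------
    def _scale_targets(self) -> tuple[float, float]:
        """Rescaling targets (autosomal, sex) at the canonical scale."""
        g = self.genome
        mu = self.scale_total / g.n_bins
        auto = g.autosome_bin_mask()
        n_auto = int((g.mappable & auto).sum())
        n_sex = int((g.mappable & ~auto).sum())
        return mu * n_auto, mu * max(n_sex, 1)

    def scale_factors(self, values: np.ndarray) -> tuple[float, float]:
        """Factors mapping this sample's values to the canonical scale."""
        g = self.genome
        auto = g.autosome_bin_mask()
        t_auto, t_sex = self._scale_targets()
        s_auto = float(values[g.mappable & auto].sum())
        if s_auto <= 0:
            raise ValueError("profile has no autosomal reads")
        sex_sum = float(values[g.mappable & ~auto].sum())
        f_sex = t_sex / sex_sum if sex_sum > 0 else 0.0
        return t_auto / s_auto, f_sex

    def save(self, path: str | Path) -> None:
        meta = {
            "version": self.version,
            "names": self.genome.names,
            "lengths": [self.genome.lengths[c] for c in self.genome.names],
            "bin_size": self.genome.bin_size,
            "scale_total": self.scale_total,
            "config": vars(self.config),
        }
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            gc=self.genome.gc,
            mappable=self.genome.mappable,
            auto_idx=self.auto_idx,
            components=self.components,
            pca_mean=self.pca_mean,
            bin_mean=self.bin_mean,
            bin_var=self.bin_var,
            mask=self.mask,
        )

    @classmethod
    def load(cls, path: str | Path) -> "NormalizationModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            genome = GenomeModel(
                meta["names"],
                meta["lengths"],
                bin_size=meta["bin_size"],
                gc=z["gc"],
                mappable=z["mappable"],
            )
            cfg = NormalizationConfig(**meta["config"])
            return cls(
                genome=genome,
                auto_idx=z["auto_idx"],
                components=z["components"],
                pca_mean=z["pca_mean"],
                bin_mean=z["bin_mean"],
                bin_var=z["bin_var"],
                mask=z["mask"].astype(bool),
                scale_total=meta["scale_total"],
                config=cfg,
                version=meta["version"],
            )


def fit_reference(
    cohort: list[BinProfile],
    config: NormalizationConfig | None = None,
) -> NormalizationModel:
    """Train a normalization model from a euploid cohort of raw profiles.

    Training pipeline per sample: GC correction, rescaling to the canonical
    scale (autosomes and sex chromosomes independently), stacking.  PCA is
    fitted on autosomal bins only and the first ``n_components`` components
    stored; per-bin means/variances are computed on the rescaled stack and
    the filter mask retains mappable bins with mean >= ``mean_min`` and
    variance <= ``var_max``.
    """
    config = config or NormalizationConfig()
    if not cohort:
        raise ValueError("empty training cohort")
    genome = cohort[0].genome
    for p in cohort:
        if not genome.same_grid(p.genome):
            raise ValueError("cohort profiles use differing genome models")
    if len(cohort) < 2 * config.n_components:
        raise ValueError(
            f"need >= {2 * config.n_components} training samples for "
            f"{config.n_components} components, got {len(cohort)}"
        )
    scale_total = (
        config.scale_total
        if config.scale_total is not None
        else default_scale_total(genome)
    )
    auto = genome.autosome_bin_mask()
    auto_idx = np.flatnonzero(genome.mappable & auto)

    model = NormalizationModel(
        genome=genome,
        auto_idx=auto_idx,
        components=np.zeros((config.n_components, auto_idx.size)),
        pca_mean=np.zeros(auto_idx.size),
        bin_mean=np.full(genome.n_bins, np.nan),
        bin_var=np.full(genome.n_bins, np.nan),
        mask=np.zeros(genome.n_bins, dtype=bool),
        scale_total=scale_total,
        config=config,
    )

    stack = np.empty((len(cohort), genome.n_bins))
    for i, p in enumerate(cohort):
        corrected = gc_correct(p, span=config.loess_span) if p.state == ProfileState.RAW else p
        f_auto, f_sex = model.scale_factors(corrected.values)
        v = corrected.values.copy()
        v[auto] *= f_auto
        v[~auto] *= f_sex
        stack[i] = v

    X = stack[:, auto_idx]
    col_mean = X.mean(axis=0)
    Xc = X - col_mean
    # covariance PCA (unstandardized columns) via thin SVD
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(config.n_components, vt.shape[0])
    components = np.zeros((config.n_components, auto_idx.size))
    components[:k] = vt[:k]

    bin_mean = stack.mean(axis=0)
    bin_var = stack.var(axis=0, ddof=1) if len(cohort) > 1 else np.zeros(genome.n_bins)
    mask = genome.mappable & (bin_mean >= config.mean_min) & (bin_var <= config.var_max)

    model.components = components
    model.pca_mean = col_mean
    model.bin_mean = np.where(genome.mappable, bin_mean, np.nan)
    model.bin_var = np.where(genome.mappable, bin_var, np.nan)
    model.mask = mask
    return model


def pca_normalize(profile: BinProfile, model: NormalizationModel) -> BinProfile:
    """Remove the trained principal components from the autosomal signal.

    The sample is rescaled to the canonical scale, mean-offset as during
    training, its projection onto the stored components subtracted, and
    returned to its own scale.  Sex-chromosome bins pass through unchanged.
    """
    profile.require_state(ProfileState.GC_CORRECTED)
    model.check_genome(profile.genome)
    f_auto, _ = model.scale_factors(profile.values)
    v = profile.values[model.auto_idx] * f_auto
    resid = v - model.pca_mean
    proj = model.components.T @ (model.components @ resid)
    out = profile.values.copy()
    out[model.auto_idx] = (v - proj) / f_auto
    return profile.advanced(out, ProfileState.PCA_NORMALIZED)


def center(profile: BinProfile, model: NormalizationModel) -> BinProfile:
    """Subtract per-bin cohort means; non-retained bins become NaN.

    The stored means (canonical scale) are brought to the sample's own
    working scale before subtraction, so centered values stay on the same
    scale as the sample's bin counts.
    """
    profile.require_state(ProfileState.PCA_NORMALIZED)
    model.check_genome(profile.genome)
    g = profile.genome
    f_auto, f_sex = model.scale_factors(profile.values)
    auto = g.autosome_bin_mask()
    expected = np.where(
        auto,
        model.bin_mean / f_auto,
        model.bin_mean / f_sex if f_sex > 0 else np.nan,
    )
    out = profile.values - expected
    out[~model.mask] = np.nan
    return profile.advanced(out, ProfileState.CENTERED)


def retained_fraction(model: NormalizationModel) -> float:
    """Fraction of mappable bins kept by the mean/variance filter."""
    n_mappable = int(model.genome.mappable.sum())
    if n_mappable == 0:
        return 0.0
    return float(model.mask.sum()) / n_mappable
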