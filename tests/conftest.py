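import numpy as np
import pytest

from niptcnv.calling import CallerConfig
from niptcnv.normalization import NormalizationConfig, fit_reference
from niptcnv.synth import SynthConfig, make_cohort, make_genome

# large enough that a few-Mb spike is a small fraction of the autosomal
# read total (at production scale a CNV is negligible vs 3.1 Gb)
TINY_LENGTHS = {"chr1": 16_000_000, "chr2": 12_000_000, "chrX": 4_000_000, "chrY": 2_000_000}
MID_LENGTHS = {"chr1": 60_000_000, "chr2": 40_000_000, "chrX": 10_000_000, "chrY": 4_000_000}


@pytest.fixture(scope="session")
def tiny_config():
    return SynthConfig(chrom_lengths=dict(TINY_LENGTHS), seed=7)


@pytest.fixture(scope="session")
def tiny_genome(tiny_config):
    return make_genome(tiny_config)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config, tiny_genome):
    return make_cohort(tiny_genome, 40, config=tiny_config, seed=100)


@pytest.fixture(scope="session")
def tiny_model(tiny_cohort):
    return fit_reference(tiny_cohort, NormalizationConfig(n_components=5))


@pytest.fixture(scope="session")
def fast_caller_config():
    return CallerConfig(n_permutations=200, seed=17)


@pytest.fixture(scope="session")
def study_env():
    """Mid-scale Poisson-noise environment for the high-signal regime tests."""
    cfg = SynthConfig(chrom_lengths=dict(MID_LENGTHS), seed=29, noise_magnitudes=())
    genome = make_genome(cfg)
    cohort = make_cohort(genome, 60, config=cfg, seed=200)
    model = fit_reference(cohort, NormalizationConfig(n_components=15))
    held = make_cohort(genome, 150, config=cfg, seed=900)
    return {"config": cfg, "genome": genome, "model": model, "held": held}


def flat_centered_profile(genome, values):
    """Construct a centered-state profile directly (test helper)."""
    from niptcnv.core import BinProfile, ProfileState

    vals = np.asarray(values, dtype=float).copy()
    vals[~genome.mappable] = np.nan
    return BinProfile(genome, vals, ProfileState.CENTERED)
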