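import numpy as np
import pytest

from niptcnv._cbs import max_arc_stat
from niptcnv.calling import (
    CallerConfig,
    Segment,
    call_cnvs,
    cbs_segment,
    classify_segments,
    estimate_ff_y,
    segment_zscore,
)
from niptcnv.core import BinProfile, GenomeModel, GenomicInterval
from niptcnv.study import SpikeSpec, score_detection
from niptcnv.synth import make_case, make_cohort

from conftest import flat_centered_profile


def brute_force_max_arc(x):
    """Independent exhaustive search over all circular splits (oracle)."""
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    tot = cs[-1]
    best, bi, bj = -1.0, 0, n
    for i in range(n):
        for j in range(i + 1, n + 1):
            k = j - i
            if k == n:
                continue
            t = abs(cs[j] - cs[i] - k * tot / n) / np.sqrt(k * (n - k) / n)
            if t > best:
                best, bi, bj = t, i, j
    return best, bi, bj


def _flat_genome(n_bins):
    return GenomeModel(["chr1"], [n_bins * 20_000], gc=np.full(n_bins, 0.45))


class TestMaxArcKernel:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 45))
        x = rng.normal(0, 1, n)
        if seed % 2:
            a, b = sorted(rng.integers(0, n, 2))
            x[a:b] += 3.0
        stat, i, j = max_arc_stat(x)
        ostat, oi, oj = brute_force_max_arc(x)
        assert stat == pytest.approx(ostat, rel=1e-12)
        assert (i, j) == (oi, oj)


class TestCbsSegment:
    def test_null_profile_single_segment(self, fast_caller_config):
        g = _flat_genome(300)
        failures = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            prof = flat_centered_profile(g, rng.normal(0, 1, g.n_bins))
            segs = cbs_segment(prof, fast_caller_config)
            if len(segs) != 1:
                failures += 1
            else:
                assert abs(segs[0].mean) < 0.3
        assert failures <= 2  # spurious split rate ~ alpha

    def test_strong_shift_recovers_changepoints(self, fast_caller_config):
        g = _flat_genome(2000)
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, g.n_bins)
        x[800:1000] -= 10.0
        prof = flat_centered_profile(g, x)
        segs = cbs_segment(prof, fast_caller_config)
        assert len(segs) == 3
        bounds = sorted(s.first_bin for s in segs)
        assert abs(bounds[1] - 800) <= 1
        assert abs(bounds[2] - 1000) <= 1
        # and the middle segment mean is near the planted shift
        mid = min(segs, key=lambda s: s.mean)
        assert mid.mean == pytest.approx(-10.0, abs=0.5)

    def test_constant_profile_single_segment(self, fast_caller_config):
        g = _flat_genome(100)
        prof = flat_centered_profile(g, np.full(g.n_bins, 3.3))
        segs = cbs_segment(prof, fast_caller_config)
        assert len(segs) == 1
        assert segs[0].mean == pytest.approx(3.3)

    def test_single_bin_chromosome(self, fast_caller_config):
        g = GenomeModel(["chr1", "chr2"], [20_000, 400_000], gc=np.full(21, 0.45))
        vals = np.ones(21)
        prof = flat_centered_profile(g, vals)
        segs = cbs_segment(prof, fast_caller_config)
        assert {s.chrom for s in segs} == {"chr1", "chr2"}
        chr1 = [s for s in segs if s.chrom == "chr1"][0]
        assert chr1.n_bins == 1

    def test_segments_cover_retained_bins_contiguously(self, fast_caller_config):
        g = _flat_genome(500)
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, g.n_bins)
        x[100:140] += 8.0
        prof = flat_centered_profile(g, x)
        segs = sorted(cbs_segment(prof, fast_caller_config), key=lambda s: s.first_bin)
        assert segs[0].first_bin == 0
        assert segs[-1].last_bin == g.n_bins - 1
        for a, b in zip(segs, segs[1:]):
            assert b.first_bin == a.last_bin + 1
        assert sum(s.n_bins for s in segs) == g.n_bins

    def test_deterministic_given_seed(self, fast_caller_config):
        g = _flat_genome(400)
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, g.n_bins)
        x[50:120] -= 5.0
        prof = flat_centered_profile(g, x)
        a = cbs_segment(prof, fast_caller_config)
        b = cbs_segment(prof, fast_caller_config)
        assert [(s.first_bin, s.last_bin) for s in a] == [
            (s.first_bin, s.last_bin) for s in b
        ]


def _segment(chrom, start, end, mean, n_bins=None):
    n = n_bins if n_bins is not None else max(1, (end - start) // 20_000)
    first = start // 20_000
    return Segment(GenomicInterval(chrom, start, end), first, first + n - 1, mean, n)


class TestClassifySegments:
    CFG = CallerConfig()

    def test_worked_example_fetal_deletion(self):
        # mb=6.45, ff=0.10: fetal threshold 0.2419, maternal 2.1769
        seg = _segment("chr1", 0, 1_000_000, -0.30)
        calls = classify_segments([seg], mb=6.45, ff=0.10, config=self.CFG)
        assert len(calls) == 1
        call = calls[0]
        assert (call.kind, call.origin) == ("deletion", "fetal")
        assert call.threshold_fetal == pytest.approx(0.75 * 6.45 * 0.05)
        assert call.threshold_fetal == pytest.approx(0.2419, abs=1e-4)
        assert call.threshold_maternal == pytest.approx(0.75 * 6.45 * 0.45)
        assert call.threshold_maternal == pytest.approx(2.1769, abs=1e-4)

    def test_fetal_minimum_length_600kb(self):
        seg = _segment("chr1", 0, 400_000, -0.30)
        assert classify_segments([seg], 6.45, 0.10, self.CFG) == []
        seg = _segment("chr1", 0, 600_000, -0.30)
        assert len(classify_segments([seg], 6.45, 0.10, self.CFG)) == 1

    def test_maternal_minimum_length_200kb(self):
        seg = _segment("chr1", 0, 300_000, -2.5)
        calls = classify_segments([seg], 6.45, 0.10, self.CFG)
        assert len(calls) == 1
        assert calls[0].origin == "maternal"
        assert calls[0].kind == "deletion"
        short = _segment("chr1", 0, 180_000, -2.5)
        assert classify_segments([short], 6.45, 0.10, self.CFG) == []

    def test_duplication_sign(self):
        seg = _segment("chr1", 0, 1_000_000, +0.30)
        calls = classify_segments([seg], 6.45, 0.10, self.CFG)
        assert calls[0].kind == "duplication"

    def test_tie_at_threshold_is_called(self):
        thr = 0.75 * 6.45 * 0.05
        seg = _segment("chr1", 0, 1_000_000, -thr)
        assert len(classify_segments([seg], 6.45, 0.10, self.CFG)) == 1

    def test_default_ff_flagged(self):
        seg = _segment("chr1", 0, 1_000_000, -0.30)
        calls = classify_segments([seg], 6.45, None, self.CFG)
        assert calls and all("default_ff" in c.flags for c in calls)
        # default is 5%
        assert calls[0].threshold_fetal == pytest.approx(0.75 * 6.45 * 0.025)

    def test_invalid_inputs(self):
        seg = _segment("chr1", 0, 1_000_000, -0.30)
        with pytest.raises(ValueError):
            classify_segments([seg], mb=0.0, ff=0.1, config=self.CFG)
        with pytest.raises(ValueError):
            classify_segments([seg], mb=6.45, ff=1.0, config=self.CFG)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        segs = [
            _segment("chr1", i * 1_000_000, (i + 1) * 1_000_000, m)
            for i, m in enumerate(rng.normal(0, 2, 20))
        ]
        base = classify_segments(segs, 6.45, 0.1, self.CFG)
        scaled = [
            _segment(s.chrom, s.interval.start, s.interval.end, s.mean * 37.0)
            for s in segs
        ]
        other = classify_segments(scaled, 6.45 * 37.0, 0.1, self.CFG)
        assert [(c.kind, c.origin, c.interval) for c in base] == [
            (c.kind, c.origin, c.interval) for c in other
        ]

    def test_tau_monotonicity(self):
        rng = np.random.default_rng(11)
        segs = [
            _segment("chr1", i * 1_000_000, (i + 1) * 1_000_000, m)
            for i, m in enumerate(rng.normal(0, 1, 30))
        ]
        counts = []
        for tau in (0.25, 0.5, 0.75, 1.0):
            cfg = CallerConfig(tau=tau)
            counts.append(len(classify_segments(segs, 6.45, 0.1, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_ff_monotonicity_by_origin(self):
        # fetal threshold grows with ff, maternal shrinks: fetal calls can
        # only decrease, maternal calls only increase, on a fixed profile
        rng = np.random.default_rng(13)
        segs = [
            _segment("chr1", i * 1_000_000, (i + 1) * 1_000_000, m)
            for i, m in enumerate(rng.normal(0, 2, 40))
        ]
        fetal_counts, maternal_counts = [], []
        for ff in (0.05, 0.1, 0.2, 0.4):
            calls = classify_segments(segs, 6.45, ff, self.CFG)
            fetal_counts.append(sum(c.origin == "fetal" for c in calls))
            maternal_counts.append(sum(c.origin == "maternal" for c in calls))
        assert fetal_counts == sorted(fetal_counts, reverse=True)
        assert maternal_counts == sorted(maternal_counts)

    def test_spike_at_theoretical_level_exceeds_threshold(self):
        # a fetal deletion at exactly mb*ff/2 oversteps tau=0.75 by design
        for mb in (5.0, 6.45, 130.0):
            for ff in (0.05, 0.1, 0.2):
                seg = _segment("chr1", 0, 2_000_000, -mb * ff / 2)
                calls = classify_segments([seg], mb, ff, self.CFG)
                assert calls and calls[0].origin == "fetal"

    def test_intermediate_annotation_flagged(self):
        thr = 0.75 * 6.45 * 0.05
        seg = _segment("chr1", 0, 1_000_000, -0.7 * thr)
        assert classify_segments([seg], 6.45, 0.10, self.CFG) == []
        calls = classify_segments(
            [seg], 6.45, 0.10, self.CFG, include_intermediate=True
        )
        assert calls and "possible" in calls[0].flags


class TestSegmentZscore:
    def _profile_with_noise(self, sigma, n=4000, seed=0):
        g = _flat_genome(n)
        rng = np.random.default_rng(seed)
        return g, flat_centered_profile(g, rng.normal(0, sigma, n))

    def test_zero_mean_gives_zero(self):
        g, prof = self._profile_with_noise(2.0)
        seg = Segment(GenomicInterval("chr1", 0, 2_000_000), 0, 99, 0.0, 100)
        assert segment_zscore(seg, prof) == 0.0

    def test_minus_sigma_over_100_bins(self):
        sigma = 2.0
        g, prof = self._profile_with_noise(sigma, seed=1)
        seg = Segment(GenomicInterval("chr1", 0, 2_000_000), 0, 99, -sigma, 100)
        z = segment_zscore(seg, prof)
        assert z == pytest.approx(-10.0, rel=0.1)

    def test_sqrt_n_scaling(self):
        g, prof = self._profile_with_noise(2.0, seed=2)
        seg1 = Segment(GenomicInterval("chr1", 0, 2_000_000), 0, 99, -1.0, 100)
        seg2 = Segment(GenomicInterval("chr1", 0, 4_000_000), 0, 199, -1.0, 200)
        z1, z2 = segment_zscore(seg1, prof), segment_zscore(seg2, prof)
        assert abs(z2) / abs(z1) == pytest.approx(np.sqrt(2), rel=0.05)

    def test_zero_sigma_reported_undefined(self):
        g = _flat_genome(50)
        prof = flat_centered_profile(g, np.zeros(50))
        seg = Segment(GenomicInterval("chr1", 0, 200_000), 0, 9, 0.5, 10)
        assert np.isnan(segment_zscore(seg, prof))


class TestEstimateFfY:
    def _profile(self, y_frac):
        g = GenomeModel(
            ["chr1", "chrY"], [1_000_000, 200_000], gc=np.full(60, 0.45)
        )
        total = 100_000
        y = int(round(total * y_frac))
        vals = np.zeros(g.n_bins, dtype=int)
        vals[0] = total - y
        vals[g.chrom_slice("chrY").start] = y
        return BinProfile(g, vals)

    def test_endpoints_and_midpoint(self):
        assert estimate_ff_y(self._profile(0.001), 0.005, 0.001) == pytest.approx(0.0)
        assert estimate_ff_y(self._profile(0.005), 0.005, 0.001) == pytest.approx(1.0)
        assert estimate_ff_y(self._profile(0.003), 0.005, 0.001) == pytest.approx(0.5)

    def test_invalid_reference_levels(self):
        with pytest.raises(ValueError, match="must exceed"):
            estimate_ff_y(self._profile(0.003), 0.001, 0.005)


@pytest.fixture(scope="module")
def call_env(tiny_genome, tiny_model, tiny_config):
    return tiny_genome, tiny_model, tiny_config


class TestCallCnvs:
    def test_spiked_fetal_deletion_called(self, call_env, fast_caller_config):
        g, model, cfg = call_env
        region = GenomicInterval("chr1", 1_000_000, 3_500_000)
        spec = SpikeSpec(region, "deletion", "fetal", 0.20)
        case, truth = make_case(g, spec, config=cfg, seed=314)
        calls = call_cnvs(case, model, ff=0.20, config=fast_caller_config)
        fetal_dels = [
            c for c in calls if c.origin == "fetal" and c.kind == "deletion"
        ]
        assert len(fetal_dels) == 1
        assert fetal_dels[0].interval.overlap(region) > 0
        assert fetal_dels[0].zscore < -3

    def test_unspiked_sample_has_no_overlapping_call(
        self, call_env, fast_caller_config
    ):
        g, model, cfg = call_env
        region = GenomicInterval("chr1", 1_000_000, 3_500_000)
        bg = make_cohort(g, 1, config=cfg, seed=2718)[0]
        calls = call_cnvs(bg, model, ff=0.20, config=fast_caller_config)
        spec = SpikeSpec(region, "deletion", "fetal", 0.20)
        assert not score_detection(calls, spec)["correct"]

    def test_missing_ff_uses_default_and_flags(self, call_env, fast_caller_config):
        g, model, cfg = call_env
        spec = SpikeSpec(
            GenomicInterval("chr1", 1_000_000, 3_500_000), "deletion", "fetal", 0.20
        )
        case, _ = make_case(g, spec, config=cfg, seed=99)
        calls = call_cnvs(case, model, ff=None, config=fast_caller_config)
        assert calls
        assert all("default_ff" in c.flags for c in calls)
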