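"""Segment binning and the stochastic pair-subsampling scheme."""

import numpy as np
import pytest

from admixdate.painting import GenomeMap, PaintingSample, PaintingSet, Segment
from admixdate.sampler import (
    SamplerConfig,
    bin_segments,
    draw_pairs_arrays,
    pair_budget,
    sample_null_pairs,
    sample_pairs,
)
from admixdate.simulate import SimScenario, simulate_paintings


def make_sample(midpoints, chrom="chr1", width=0.02, donors=None):
    """A painting sample whose segments have the given midpoints."""
    segs = [
        Segment(chrom, m - width / 2, m + width / 2, donors[i] if donors else "dA")
        for i, m in enumerate(midpoints)
    ]
    return PaintingSample("i1", 1, 1, {chrom: segs})


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(bin_width=0.0)
        with pytest.raises(ValueError):
            SamplerConfig(c=0.5)
        with pytest.raises(ValueError):
            SamplerConfig(min_dist=-1)

    def test_grid(self):
        cfg = SamplerConfig()
        g = cfg.grid_cM
        assert g[0] == pytest.approx(1.1)
        assert g[-1] == pytest.approx(30.0)
        assert len(g) == 290
        fine = SamplerConfig(bin_width=0.05, max_dist=5.0, min_dist=1.0)
        assert fine.grid_cM[0] == pytest.approx(1.05)
        assert fine.grid_cM[-1] == pytest.approx(5.0)


class TestBinning:
    def test_midpoint_rule(self):
        cfg = SamplerConfig()
        sample = PaintingSample(
            "i1", 1, 1,
            {"chr1": [Segment("chr1", 0.0, 0.1, "dA"), Segment("chr1", 0.1, 0.25, "dB")]},
        )
        binned = bin_segments(sample, cfg)
        counts = binned.counts("chr1")
        # midpoints 0.05 and 0.175 -> first and second bin
        assert counts == {0: 1, 1: 1}

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(0)
        mids = np.sort(rng.uniform(0.5, 99.5, 1000))
        cfg = SamplerConfig()
        binned = bin_segments(make_sample(mids), cfg)
        brute = {}
        for m in mids:
            b = int(np.floor(m / cfg.bin_width))
            brute[b] = brute.get(b, 0) + 1
        assert binned.counts("chr1") == brute
        assert binned.n_segments == 1000


class TestPairBudget:
    def test_empty_bin(self):
        rng = np.random.default_rng(0)
        assert pair_budget(0, 5, 10.0, SamplerConfig(), rng) == 0

    def test_exhaustive_limit(self):
        # gamma=0, c=1 reproduces the full N_i*N_j pairing of the
        # non-subsampled algorithm
        rng = np.random.default_rng(0)
        cfg = SamplerConfig(gamma=0.0, c=1.0)
        assert pair_budget(7, 9, 10.0, cfg, rng) == 63

    def test_expectation_matches_formula(self):
        # N_i=10, N_j=20, D=10 cM: E[Y] = 200 * exp(-0.5) / 8 = 15.163
        rng = np.random.default_rng(1)
        cfg = SamplerConfig()
        draws = [pair_budget(10, 20, 10.0, cfg, rng) for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(200 * np.exp(-0.5) / 8, rel=0.02)


def brute_force_pairs(mids, cfg):
    """All (i, j) with bin distance in (min_dist, max_dist], as a set."""
    bins = np.floor(np.asarray(mids) / cfg.bin_width).astype(int)
    out = set()
    for i in range(len(mids)):
        for j in range(i + 1, len(mids)):
            d = abs(bins[j] - bins[i])
            if cfg.min_k < d <= cfg.max_k:
                out.add((min(i, j), max(i, j)))
    return out


class TestSamplePairs:
    def test_two_singleton_bins_forced(self):
        # M forced to 1 via gamma=0, c=1: exactly one pair at 5 cM
        cfg = SamplerConfig(gamma=0.0, c=1.0)
        sample = make_sample([0.05, 5.05])
        draws = list(sample_pairs(bin_segments(sample, cfg), cfg, np.random.default_rng(0)))
        assert len(draws) == 1
        assert draws[0].distance_cM == pytest.approx(5.0)

    def test_distance_cap(self):
        cfg = SamplerConfig(gamma=0.0, c=1.0)
        sample = make_sample([0.05, 31.05])
        draws = list(sample_pairs(bin_segments(sample, cfg), cfg, np.random.default_rng(0)))
        assert draws == []

    def test_min_dist_skips_close_bins(self):
        cfg = SamplerConfig(gamma=0.0, c=1.0)
        sample = make_sample([0.05, 0.95])  # 0.9 cM apart: within min_dist
        draws = list(sample_pairs(bin_segments(sample, cfg), cfg, np.random.default_rng(0)))
        assert draws == []

    def test_exhaustive_oracle_equivalence(self):
        # gamma=0, c=1 must reproduce the exhaustive pairing set exactly
        rng = np.random.default_rng(5)
        mids = np.sort(rng.uniform(0.0, 60.0, 180))
        cfg = SamplerConfig(gamma=0.0, c=1.0)
        sample = make_sample(mids)
        draws = list(sample_pairs(bin_segments(sample, cfg), cfg, np.random.default_rng(0)))
        got = set()
        seg_index = {id(s): i for i, s in enumerate(sample.segments["chr1"])}
        for d in draws:
            i, j = seg_index[id(d.segment_a)], seg_index[id(d.segment_b)]
            got.add((min(i, j), max(i, j)))
        assert got == brute_force_pairs(mids, cfg)

    def test_sampling_fraction_with_defaults(self):
        # uniform segments on a chromosome >> K: drawn / eligible ~ 6.3%
        cfg = SamplerConfig()
        fracs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            mids = np.sort(rng.uniform(0.0, 250.0, 4000))
            gid = np.zeros(len(mids), np.int64)
            bins = np.floor(mids / cfg.bin_width).astype(np.int64)
            from admixdate.sampler import _engine

            pa = _engine(gid, bins, cfg, np.random.default_rng(seed + 100))
            fracs.append(pa.sampling_fraction)
        assert 0.055 <= np.mean(fracs) <= 0.075

    def test_per_distance_draw_probability(self):
        # thinned Bernoulli draws must match M(D) = exp(-gamma D)/c per bin
        cfg = SamplerConfig()
        rng = np.random.default_rng(2)
        mids = np.arange(0.05, 200.0, 0.1)  # every bin occupied once
        gid = np.zeros(len(mids), np.int64)
        bins = np.floor(mids / cfg.bin_width).astype(np.int64)
        from admixdate.sampler import _engine

        counts = np.zeros(cfg.max_k + 1)
        n_rep = 40
        for rep in range(n_rep):
            pa = _engine(gid, bins, cfg, np.random.default_rng(rep))
            np.add.at(counts, pa.separation, 1)
        for delta in (15, 50, 150, 290):
            n_cand = len(mids) - delta
            p_emp = counts[delta] / (n_rep * n_cand)
            p_true = float(cfg.weight(delta * cfg.bin_width))
            se = np.sqrt(p_true * (1 - p_true) / (n_rep * n_cand))
            assert abs(p_emp - p_true) < 4 * se + 1e-12

    def test_determinism(self):
        scn = SimScenario(n_individuals=2, genome=GenomeMap.uniform(2, 100.0), n_samples=2)
        ps, _ = simulate_paintings(scn, np.random.default_rng(0))
        cfg = SamplerConfig()
        a = draw_pairs_arrays(ps, cfg, np.random.default_rng(9))
        b = draw_pairs_arrays(ps, cfg, np.random.default_rng(9))
        assert np.array_equal(a.seg_a, b.seg_a)
        assert np.array_equal(a.seg_b, b.seg_b)
        assert np.array_equal(a.separation, b.separation)


class TestNullPairs:
    def test_single_individual_rejected(self):
        cfg = SamplerConfig()
        binned = {"i1": bin_segments(make_sample([1.0, 5.0]), cfg)}
        with pytest.raises(ValueError, match="at least 2"):
            list(sample_null_pairs(binned, cfg, np.random.default_rng(0)))

    def test_two_individuals_only_cross_pairs(self):
        cfg = SamplerConfig(gamma=0.0, c=1.0)
        binned = {
            "i1": bin_segments(make_sample([0.05, 5.05]), cfg),
            "i2": bin_segments(make_sample([0.05, 5.05]), cfg),
        }
        for seed in range(10):
            draws = list(sample_null_pairs(binned, cfg, np.random.default_rng(seed)))
            # lattice is 2x2 per bin pair; only the 2 cross-individual pairs allowed
            assert len(draws) == 2

    def test_no_same_individual_pairs_at_scale(self):
        scn = SimScenario(n_individuals=6, genome=GenomeMap.uniform(3, 150.0), n_samples=2)
        ps, _ = simulate_paintings(scn, np.random.default_rng(1))
        cfg = SamplerConfig()
        pa = draw_pairs_arrays(ps, cfg, np.random.default_rng(2), mode="null", null_scale=1.0)
        assert pa.n_drawn > 10_000
        assert (ps.ind_code[pa.seg_a] != ps.ind_code[pa.seg_b]).all()
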