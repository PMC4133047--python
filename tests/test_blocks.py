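import itertools

import numpy as np
import pandas as pd
import pytest

import admixpipe as ap
from admixpipe.blocks import Block, BlockSet, build_blocks, interval_rates
from admixpipe.io import MISSING
from conftest import make_genotypes


def snps_at(positions, chrom=1):
    return make_genotypes(np.zeros((2, len(positions)), dtype=np.int8),
                          positions=positions, chromosomes=[chrom] * len(positions)).snps


class TestIntervalRates:
    def test_mean_of_inside_points(self):
        snps = snps_at([100, 1000])
        rmap = pd.DataFrame({"chromosome": [1, 1], "position_bp": [300, 700],
                             "rate_cM_per_Mb": [0.2, 0.4]})
        assert interval_rates(rmap, snps)[0] == pytest.approx(0.3)

    def test_single_inside_point(self):
        snps = snps_at([100, 1000])
        rmap = pd.DataFrame({"chromosome": [1], "position_bp": [500],
                             "rate_cM_per_Mb": [0.7]})
        assert interval_rates(rmap, snps)[0] == pytest.approx(0.7)

    def test_empty_interval_interpolates_flanks(self):
        snps = snps_at([400, 600])
        rmap = pd.DataFrame({"chromosome": [1, 1], "position_bp": [100, 900],
                             "rate_cM_per_Mb": [0.0, 0.8]})
        # midpoint 500 interpolates linearly between (100, 0.0) and (900, 0.8)
        assert interval_rates(rmap, snps)[0] == pytest.approx(0.4)

    def test_outside_span_raises(self):
        snps = snps_at([100, 200])
        rmap = pd.DataFrame({"chromosome": [1], "position_bp": [5000],
                             "rate_cM_per_Mb": [0.5]})
        with pytest.raises(ValueError, match="outside map span"):
            interval_rates(rmap, snps)


class TestBuildBlocks:
    def test_greedy_tiling_twenty_low_snps(self):
        snps = snps_at([(j + 1) * 100 for j in range(20)])
        rates = np.full(19, 0.1)
        bs = build_blocks(rates, snps)
        assert [(b.first, b.last) for b in bs.blocks] == [(0, 14), (15, 19)]

    def test_run_below_min_size_skipped(self):
        snps = snps_at([(j + 1) * 100 for j in range(10)])
        rates = np.full(9, 2.0)
        rates[2:5] = 0.1  # 4-SNP low run: indices 2..5
        assert build_blocks(rates, snps).blocks == []

    def test_above_mode_complementary_rule(self):
        snps = snps_at([(j + 1) * 100 for j in range(12)])
        rates = np.full(11, 2.0)
        bs = build_blocks(rates, snps, mode="above")
        assert [(b.first, b.last) for b in bs.blocks] == [(0, 11)]

    def test_random_mode_matches_reference_lengths(self):
        snps = snps_at([(j + 1) * 100 for j in range(30)])
        ref = BlockSet(blocks=[Block(1, 0, 4), Block(1, 10, 16)], mode="below")
        bs = build_blocks(np.zeros(29), snps, mode="random", seed=0, reference=ref)
        assert sorted(b.size for b in bs.blocks) == [5, 7]
        # disjoint
        used = set()
        for b in bs.blocks:
            span = set(range(b.first, b.last + 1))
            assert not span & used
            used |= span

    def test_random_mode_requires_reference(self):
        with pytest.raises(ValueError):
            build_blocks(np.zeros(5), snps_at([1, 2, 3, 4, 5, 6]), mode="random")

    def test_blocks_respect_size_and_rate_constraints(self, study_fixture):
        """Exhaustive re-check of every emitted block against the rule."""
        g, _, rmap, _ = study_fixture
        rates = interval_rates(rmap.rows, g.snps)
        bs = build_blocks(rates, g.snps)
        assert len(bs.blocks) > 0
        for b in bs.blocks:
            assert 5 <= b.size <= 15
            assert all(rates[j] < 0.5 for j in range(b.first, b.last))
            assert len({g.snps[j].chromosome for j in range(b.first, b.last + 1)}) == 1


class TestEMHaplotypes:
    def test_all_homozygous_equals_direct_counts(self):
        d = np.array([[0, 0, 2], [2, 2, 0], [2, 2, 0], [0, 0, 2]], dtype=np.int8)
        g = make_genotypes(d)
        spec = ap.em_haplotype_frequencies(g, Block(1, 0, 2), "pop1")
        assert spec.frequencies == {"001": pytest.approx(0.5), "110": pytest.approx(0.5)}
        assert len(spec.loglik_trace) == 1

    def test_single_heterozygote_equals_counting(self):
        """Phase is unambiguous with <= 1 heterozygous site per individual."""
        d = np.array([[1, 0], [0, 1], [2, 2], [0, 0]], dtype=np.int8)
        g = make_genotypes(d)
        spec = ap.em_haplotype_frequencies(g, Block(1, 0, 1), "pop1")
        # hand count: 10+00, 00+01, 11+11, 00+00 -> 00:4, 10:1, 01:1, 11:2 of 8
        expected = {"00": 4 / 8, "10": 1 / 8, "01": 1 / 8, "11": 2 / 8}
        for h, f in expected.items():
            assert spec.frequencies[h] == pytest.approx(f, abs=1e-9)

    def test_two_snp_block_matches_likelihood_grid(self):
        """EM solution matches a grid search over the single free phase parameter."""
        # genotype counts: (0,0) x4, (2,2) x4, (1,1) x2
        d = np.array([[0, 0]] * 4 + [[2, 2]] * 4 + [[1, 1]] * 2, dtype=np.int8)
        g = make_genotypes(d)
        spec = ap.em_haplotype_frequencies(g, Block(1, 0, 1), "pop1")

        # free parameter: number t of double heterozygotes phased as 00/11
        # haplotype counts: n00 = 8 + t, n11 = 8 + t, n01 = n10 = 2 - t, total 20
        def loglik(t):
            f = {"00": (8 + t) / 20, "11": (8 + t) / 20,
                 "01": (2 - t) / 20, "10": (2 - t) / 20}
            ll = 4 * np.log(f["00"] ** 2) + 4 * np.log(f["11"] ** 2)
            ll += 2 * np.log(2 * f["00"] * f["11"] + 2 * f["01"] * f["10"])
            return ll

        grid = np.linspace(0, 2, 2001)
        vals = [loglik(t) for t in grid]
        t_best = grid[int(np.argmax(vals))]
        assert spec.frequencies.get("00", 0.0) == pytest.approx((8 + t_best) / 20, abs=1e-3)
        assert spec.frequencies.get("01", 0.0) == pytest.approx((2 - t_best) / 20, abs=1e-3)

    def test_loglik_monotone_nondecreasing(self, study_fixture):
        g, _, rmap, _ = study_fixture
        rates = interval_rates(rmap.rows, g.snps)
        bs = build_blocks(rates, g.snps)
        spec = ap.em_haplotype_frequencies(g, bs.blocks[0], "route00_origin")
        diffs = np.diff(spec.loglik_trace)
        assert np.all(diffs >= -1e-9)

    def test_missing_individuals_excluded(self):
        d = np.array([[0, 0], [MISSING, 1], [2, 2]], dtype=np.int8)
        g = make_genotypes(d)
        spec = ap.em_haplotype_frequencies(g, Block(1, 0, 1), "pop1")
        assert spec.n == 4  # 2 complete individuals


class TestHeterozygosity:
    def test_nei_estimator_values(self):
        from admixpipe.blocks import HaplotypeFrequencySpectrum, block_heterozygosity

        single = HaplotypeFrequencySpectrum({"0": 1.0}, n=10)
        assert block_heterozygosity(single) == 0.0
        two = HaplotypeFrequencySpectrum({"0": 0.5, "1": 0.5}, n=4)
        assert block_heterozygosity(two) == pytest.approx(4 / 3 * 0.5)
        assert block_heterozygosity(two, unbiased=False) == pytest.approx(0.5)
        m = 8
        uniform = HaplotypeFrequencySpectrum({str(i): 1 / m for i in range(m)}, n=10**9)
        assert block_heterozygosity(uniform) == pytest.approx(1 - 1 / m, rel=1e-6)
        with pytest.raises(ValueError):
            block_heterozygosity(HaplotypeFrequencySpectrum({"0": 1.0}, n=1))

    def test_nei_estimator_near_unbiased(self):
        """E[H_hat] over multinomial resampling is close to 1 - sum p^2."""
        from admixpipe.blocks import HaplotypeFrequencySpectrum, block_heterozygosity

        rng = np.random.default_rng(0)
        p = np.array([0.5, 0.3, 0.2])
        truth = 1 - (p**2).sum()
        n = 20
        vals = []
        for _ in range(3000):
            counts = rng.multinomial(n, p)
            spec = HaplotypeFrequencySpectrum(
                {str(i): c / n for i, c in enumerate(counts) if c}, n=n)
            vals.append(block_heterozygosity(spec))
        assert abs(np.mean(vals) - truth) < truth / n

    def test_chromosome_means_hand_arithmetic(self):
        """Two chromosomes with block means 0.4 and 0.6 give mean 0.5."""
        # chromosome 1: two haplotypes 0/1 at 60/40 -> plug-in H = 0.48; use
        # unambiguous all-homozygote data so EM equals counting.
        d1 = np.array([[0] * 5] * 6 + [[2] * 5] * 4, dtype=np.int8)  # chr1 block
        d2 = np.array([[0] * 5] * 5 + [[2] * 5] * 5, dtype=np.int8)  # chr2 block
        d = np.hstack([d1, d2])
        g = make_genotypes(d, chromosomes=[1] * 5 + [2] * 5,
                           positions=list(range(1000, 6000, 1000)) * 2)
        bs = BlockSet(blocks=[Block(1, 0, 4), Block(2, 5, 9)], mode="below")
        het = ap.genomewide_heterozygosity(g, bs, unbiased=False)
        row = het.table.iloc[0]
        h1 = 1 - (0.6**2 + 0.4**2)
        h2 = 1 - 2 * 0.5**2
        assert row["chr1"] == pytest.approx(h1)
        assert row["chr2"] == pytest.approx(h2)
        assert row["mean_H"] == pytest.approx((h1 + h2) / 2)
        assert row["sd_H"] == pytest.approx(np.std([h1, h2], ddof=1))

    def test_admixed_population_heterozygosity_elevated(self):
        """A hybrid of two drifted sources exceeds both sources in block H."""
        cfg = ap.default_config(seed=21, n_snps=300)
        cfg.drift_F_per_step = 0.15  # strong drift so sources lose diversity
        g, pops, rmap, _ = ap.make_study_fixture(cfg)
        rates = interval_rates(rmap.rows, g.snps)
        bs = build_blocks(rates, g.snps)
        het = ap.genomewide_heterozygosity(g, bs)
        t = het.table.set_index("population")["mean_H"]
        parent = t["route09_terminal"]
        for admixed in ("coastalA", "coastalB", "interiorA", "interiorB"):
            assert t[admixed] > parent

    def test_pool_structured_blocks_less_diverse_than_le_blocks(self):
        """With finite haplotype pools inside low-recombination runs, high-LD
        blocks carry fewer haplotypes and hence lower H than blocks built
        from the linkage-equilibrium (above-threshold) regions."""
        cfg = ap.default_config(seed=31, n_snps=400)
        cfg.haplotype_pool_size = 4
        g, _, rmap, _ = ap.make_study_fixture(cfg)
        rates = interval_rates(rmap.rows, g.snps)
        below = build_blocks(rates, g.snps, mode="below")
        above = build_blocks(rates, g.snps, mode="above", min_size=5, max_size=15)
        h_below = ap.genomewide_heterozygosity(g, below, ["route00_origin"]).table
        h_above = ap.genomewide_heterozygosity(g, above, ["route00_origin"]).table
        assert h_below.iloc[0]["mean_H"] < h_above.iloc[0]["mean_H"]
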