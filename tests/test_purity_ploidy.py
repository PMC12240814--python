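"""Purity from LOH BAF bimodality, the absolute-copy-number map, grid-search
ploidy fitting, and allele-specific copy number."""

import math

import numpy as np
import pytest

from svarcall import purity_ploidy as pp
from svarcall.copy_number import CopyNumberSegment
from svarcall.io_formats import GenomicInterval, SnpSite


def brute_force_bimodality(values):
    """Sarle's coefficient from raw moment sums, computed independently."""
    x = np.asarray(values, float)
    n = len(x)
    m = x.mean()
    m2 = ((x - m) ** 2).sum() / n
    m3 = ((x - m) ** 3).sum() / n
    m4 = ((x - m) ** 4).sum() / n
    g1 = (math.sqrt(n * (n - 1)) / (n - 2)) * (m3 / m2 ** 1.5)
    g2_b = m4 / m2 ** 2 - 3
    g2 = ((n - 1) / ((n - 2) * (n - 3))) * ((n + 1) * g2_b + 6)
    return (g1 ** 2 + 1) / (g2 + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3)))


class TestBimodality:
    def test_matches_independent_moment_computation(self):
        values = [0.0] * 5 + [1.0] * 5
        b = pp.bimodality_coefficient(values)
        assert b == pytest.approx(brute_force_bimodality(values), abs=1e-12)
        assert b > 5 / 9  # the classic bimodality benchmark

    def test_degenerate_sample_ineligible(self):
        assert pp.bimodality_coefficient([0.5] * 10) is None
        assert pp.bimodality_coefficient([0.1, 0.9, 0.5]) is None  # n < 4

    def test_bimodal_beats_unimodal(self):
        rng = np.random.default_rng(0)
        unimodal = rng.normal(0.5, 0.05, 200)
        bimodal = np.concatenate([rng.normal(0.2, 0.05, 100), rng.normal(0.8, 0.05, 100)])
        assert pp.bimodality_coefficient(bimodal) > pp.bimodality_coefficient(unimodal)


def _obs(contig, pos, baf, depth=40):
    alt = int(round(baf * depth))
    return pp.SnpBafObservation(SnpSite(contig, pos, "A", "B"), depth - alt, alt)


class TestBlockSelection:
    CONTIGS = {"chr1": 20_000_000}

    def _block_obs(self, block, bafs, depth=40):
        start = block * 1_200_000
        return [_obs("chr1", start + 1000 * (i + 1), b, depth) for i, b in enumerate(bafs)]

    def test_too_few_snps_ineligible(self):
        obs = self._block_obs(0, [0.1, 0.9] * 4)  # 8 SNPs
        obs += self._block_obs(1, [0.1, 0.9] * 10)
        blocks = pp.select_loh_blocks(obs, self.CONTIGS)
        assert len(blocks) == 1
        assert blocks[0].interval.start == 1_200_000

    def test_high_depth_block_excluded(self):
        normal = []
        for b in range(4):
            normal += self._block_obs(b, [0.1, 0.9] * 10, depth=40)
        hot = self._block_obs(8, [0.05, 0.95] * 10, depth=150)  # > 2x mean depth
        blocks = pp.select_loh_blocks(normal + hot, self.CONTIGS)
        assert all(blk.interval.start != 8 * 1_200_000 for blk in blocks)

    def test_top_ten_returned_ranked(self):
        rng = np.random.default_rng(1)
        obs = []
        for b in range(12):
            sep = 0.1 + 0.03 * b  # increasing separation -> increasing bimodality
            bafs = np.concatenate([rng.normal(0.5 - sep, 0.02, 15), rng.normal(0.5 + sep, 0.02, 15)])
            obs += self._block_obs(b, np.clip(bafs, 0.01, 0.99))
        blocks = pp.select_loh_blocks(obs, self.CONTIGS)
        assert len(blocks) == 10
        assert all(blocks[i].bimodality >= blocks[i + 1].bimodality for i in range(9))


class TestEstimatePurity:
    def _block(self, upper, lower):
        return pp.LohBlock(GenomicInterval("chr1", 0, 1_200_000), 50, 30.0, 1.0, upper, lower)

    def test_pure_tumor_limit(self):
        blocks = [self._block(1.0, 0.0)] * 10
        assert pp.estimate_purity(blocks) == pytest.approx(1.0, abs=1e-12)

    def test_half_purity_closed_form(self):
        blocks = [self._block(0.75, 0.25)] * 10
        assert pp.estimate_purity(blocks) == pytest.approx(0.5, abs=1e-12)

    def test_loh_identity_exact_for_any_purity(self):
        for rho in (0.1, 0.3, 0.62, 0.9, 1.0):
            blocks = [self._block(1 - (1 - rho) / 2, (1 - rho) / 2)] * 10
            assert pp.estimate_purity(blocks) == pytest.approx(rho, abs=1e-12)

    def test_block_order_invariant(self):
        blocks = [self._block(0.9, 0.1), self._block(0.7, 0.3), self._block(0.8, 0.2)]
        assert pp.estimate_purity(blocks) == pytest.approx(pp.estimate_purity(blocks[::-1]))

    def test_generative_recovery_with_binomial_noise(self):
        # CN-neutral LOH at rho = 0.7: lower-mode BAF (1-rho)/2 = 0.15
        rng = np.random.default_rng(7)
        rho = 0.7
        obs = []
        contigs = {"chr1": 30_000_000}
        for b in range(10):
            start = b * 1_200_000
            for i in range(200):
                depth = 2000  # deep pseudo-counts keep the mode medians tight
                p = 0.15 if rng.random() < 0.5 else 0.85
                alt = rng.binomial(depth, p)
                obs.append(pp.SnpBafObservation(SnpSite("chr1", start + (i + 1) * 1000, "A", "B"), depth - alt, alt))
        blocks = pp.select_loh_blocks(obs, contigs)
        assert pp.estimate_purity(blocks) == pytest.approx(rho, abs=0.02)

    def test_no_blocks_raises(self):
        with pytest.raises(ValueError):
            pp.estimate_purity([])


class TestAbsoluteCopyNumber:
    def test_neutral_ratio_returns_ploidy(self):
        for rho in (0.2, 0.5, 1.0):
            for psi in (1.5, 2.0, 3.7):
                assert pp.absolute_copy_number(0.0, rho, psi) == pytest.approx(psi, abs=1e-12)

    def test_doubling_in_pure_diploid(self):
        assert pp.absolute_copy_number(1.0, 1.0, 2.0) == pytest.approx(4.0, abs=1e-12)

    def test_half_purity_closed_form(self):
        # ratio 1.5 at rho=0.5, psi=2: CN = 2 + 0.5 * (2 + 4 - 2) = 4
        assert pp.absolute_copy_number(math.log2(1.5), 0.5, 2.0) == pytest.approx(4.0, abs=1e-12)


def _segment(contig, start, size, log2r):
    return CopyNumberSegment(
        interval=GenomicInterval(contig, start, start + size), mean_log2r=log2r, n_bins=max(size // 10_000, 1)
    )


def _noiseless_segments(rho, psi, cns_and_sizes):
    denom = rho * psi + 2 * (1 - rho)
    segs = []
    pos = 0
    for cn_state, size in cns_and_sizes:
        r = (rho * cn_state + 2 * (1 - rho)) / denom
        segs.append(_segment("chr1", pos, size, math.log2(r)))
        pos += size
    return segs


class TestGridSearch:
    def test_noiseless_profile_recovered_exactly(self):
        # integer CNs {1, 2, 3} generated at (0.60, 2.00); truth is on the grid
        segs = _noiseless_segments(0.60, 2.00, [(2, 3_000_000), (1, 1_000_000), (3, 1_000_000)])
        best, grid = pp.grid_search(segs, purity_hat=0.60)
        assert best.purity == pytest.approx(0.60, abs=1e-9)
        assert best.ploidy == pytest.approx(2.00, abs=1e-9)
        assert best.fitness == pytest.approx(0.0, abs=1e-9)

    def test_zero_state_proportion_rejects(self):
        segs = _noiseless_segments(0.60, 2.00, [(0, 1_500_000), (2, 8_500_000)])
        grid_point = pp.absolute_copy_number(np.array([s.mean_log2r for s in segs]), 0.60, 2.00)
        weights = np.array([s.size for s in segs], float)
        _, zero_ok, _, _ = pp._evaluate_grid_point(grid_point, weights, "rmsd")
        assert not zero_ok  # 15% of the genome at CN 0

    def test_state_step_of_two_rejects(self):
        segs = _noiseless_segments(0.60, 2.00, [(2, 5_000_000), (5, 4_000_000), (3, 500_000)])
        cn_vals = pp.absolute_copy_number(np.array([s.mean_log2r for s in segs]), 0.60, 2.00)
        weights = np.array([s.size for s in segs], float)
        _, _, _, step_ok = pp._evaluate_grid_point(cn_vals, weights, "rmsd")
        assert not step_ok  # two most frequent states are CN 2 and CN 5

    def test_all_rejected_raises(self):
        segs = _noiseless_segments(0.60, 2.00, [(0, 9_000_000), (2, 1_000_000)])
        with pytest.raises(ValueError, match="manual"):
            pp.grid_search(segs, purity_hat=0.60)


class TestAlleleSpecific:
    @pytest.mark.parametrize(
        "rho,n_t,baf,expected_minor",
        [
            (1.0, 2, 0.5, 1),  # balanced diploid
            (1.0, 3, 1 / 3, 1),  # 2+1
            (0.5, 2, 0.25, 0),  # LOH at half purity
        ],
    )
    def test_closed_form_inversion(self, rho, n_t, baf, expected_minor):
        seg = _segment("chr1", 0, 1_000_000, 0.0)
        seg.absolute_cn = float(n_t)
        (out,) = pp.allele_specific_cn([seg], [baf], rho)
        assert out.minor_cn == expected_minor

    def test_minor_never_exceeds_half_total(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            seg = _segment("chr1", 0, 1_000_000, 0.0)
            seg.absolute_cn = float(rng.integers(0, 8))
            (out,) = pp.allele_specific_cn([seg], [float(rng.uniform(0, 0.5))], float(rng.uniform(0.1, 1.0)))
            assert 0 <= out.minor_cn <= int(out.absolute_cn) // 2


class TestJointRecovery:
    def test_simulated_cohort_recovery(self):
        """20 genomes over rho x psi grids with noisy log2R and binomial BAF:
        both parameters recovered within tolerance in >= 90% of cases."""
        from svarcall.simulate import CnSegmentSpec, SimulationConfig, profile_for_ploidy, simulate_cn_data
        from svarcall.pipeline import bins_from_table
        from svarcall import copy_number as cn

        rhos = [0.3, 0.45, 0.6, 0.75, 0.9]
        psis = [1.8, 2.0, 3.1, 4.0]
        hits = 0
        total = 0
        for gi, (rho, psi) in enumerate((r, p) for r in rhos for p in psis):
            profile = profile_for_ploidy(psi, "chr1", 10_000_000)
            config = SimulationConfig(
                seed=1000 + gi,
                contigs={"chr1": 10_000_000},
                cn_profile=profile,
                purity=rho,
                snp_depth=30,
                log2r_noise_sd=0.1,
                cn_base_depth=400,
                snp_spacing=2000,
            )
            data = simulate_cn_data(config)
            bins = bins_from_table(data["bins"])
            cn.normalize_log2(bins, mode="paired")
            # segment means over the true boundaries: this test isolates the
            # purity/ploidy fit from the segmentation stage
            segs = []
            for spec in profile:
                vals = [
                    b.log2r
                    for b in bins
                    if not b.excluded and spec.start <= b.interval.start < spec.end
                ]
                segs.append(_segment("chr1", spec.start, spec.end - spec.start, float(np.mean(vals))))
            obs = pp.baf_observations_from_table(data["snps"].itertuples(index=False, name=None))
            blocks = pp.select_loh_blocks(obs, config.contigs, block_size=100_000)
            rho_hat = pp.estimate_purity(blocks)
            best, _ = pp.grid_search(segs, rho_hat)
            total += 1
            if abs(best.purity - rho) <= 0.05 and abs(best.ploidy - psi) <= 0.1:
                hits += 1
        assert total == 20
        assert hits / total >= 0.90
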