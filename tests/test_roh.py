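"""Windowed ROH caller, L-parameter, coverage and density."""

import numpy as np
import pytest
from dataclasses import replace

from autozyg.genome import GenomeSpec
from autozyg.matrix import MISSING, GenotypeMatrix
from autozyg.roh import (
    RRS_PRESET,
    WGS_PRESET,
    ROHParams,
    ROHSegment,
    compute_l_parameter,
    detect_roh,
    mean_heterozygosity,
    meyermans_coverage,
    optimize_parameters,
    snp_density,
)
from conftest import random_matrix
from oracles import brute_force_roh, random_roh_params


def uniform_matrix(gt_column, spacing_bp=10_000, chrom_length=None):
    """Single-individual, single-chromosome matrix with uniform SNP spacing."""
    gt = np.asarray(gt_column, dtype=np.int8)[:, None]
    m = len(gt)
    length = chrom_length or (m + 1) * spacing_bp
    genome = GenomeSpec(("chr1",), (length,))
    return GenotypeMatrix(
        genome,
        np.zeros(m, np.int32),
        (np.arange(m, dtype=np.int64) + 1) * spacing_bp,
        np.full(m, "A", "U1"),
        np.full(m, "G", "U1"),
        ["ind0"],
        gt,
    )


class TestLParameter:
    def test_analytic_unit_case(self):
        assert compute_l_parameter(0.05, 1, 1, 0.95) == 1

    def test_derived_case(self):
        # ln(0.05 / 1e6) / ln(0.7) = 47.13 -> 47
        assert compute_l_parameter(0.05, 10_000, 100, 0.3) == 47

    def test_monotone_in_het_and_size(self):
        base = compute_l_parameter(0.05, 10_000, 100, 0.3)
        assert compute_l_parameter(0.05, 10_000, 100, 0.5) < base
        assert compute_l_parameter(0.05, 100_000, 100, 0.3) > base

    def test_rounding_modes(self):
        assert compute_l_parameter(0.05, 10_000, 100, 0.3, "floor") == 47
        assert compute_l_parameter(0.05, 10_000, 100, 0.3, "ceil") == 48

    @pytest.mark.parametrize("het", [0.0, 1.0, -0.1])
    def test_degenerate_het_rejected(self, het):
        with pytest.raises(ValueError):
            compute_l_parameter(0.05, 100, 10, het)


class TestMeanHeterozygosity:
    def test_all_homozygous(self):
        m = uniform_matrix([0, 2, 0, 2])
        assert mean_heterozygosity(m) == 0.0

    def test_single_site_half_het(self):
        genome = GenomeSpec(("chr1",), (1000,))
        gt = np.array([[1, 1, 0, 2]], dtype=np.int8)
        m = GenotypeMatrix(
            genome, np.zeros(1, np.int32), np.array([10]),
            np.array(["A"]), np.array(["G"]), list("abcd"), gt,
        )
        assert mean_heterozygosity(m) == 0.5

    def test_matches_double_loop(self, small_genome):
        rng = np.random.default_rng(10)
        m = random_matrix(small_genome, 34, 50, rng)
        total, n_used = 0.0, 0
        for i in range(m.n_sites):
            het = called = 0
            for j in range(m.n_samples):
                if m.gt[i, j] != MISSING:
                    called += 1
                    het += m.gt[i, j] == 1
            if called:
                total += het / called
                n_used += 1
        assert mean_heterozygosity(m) == pytest.approx(total / n_used, abs=1e-12)


class TestDetectRoh:
    def test_periodic_hets_with_zero_tolerance_yield_nothing(self):
        gt = np.zeros(200, dtype=np.int8)
        gt[::10] = 1  # every 10th SNP het; every 20-SNP window contains >= 1
        m = uniform_matrix(gt)
        params = ROHParams(
            homozyg_snp=5, homozyg_kb=1, homozyg_density=1000,
            homozyg_gap=1000, homozyg_het=0, window_snp=20,
            window_het=0, window_missing=5,
        )
        assert detect_roh(m, params)["ind0"] == []

    def test_fully_homozygous_chromosome_single_segment(self):
        m = uniform_matrix(np.zeros(500, dtype=np.int8), spacing_bp=10_000,
                           chrom_length=6_000_000)
        segs = detect_roh(m, WGS_PRESET)["ind0"]
        assert len(segs) == 1
        s = segs[0]
        assert s.start == int(m.pos[0]) and s.end == int(m.pos[-1]) + 1
        assert s.n_snps == 500 and s.n_het == 0

    def test_chromosome_shorter_than_window_yields_nothing(self):
        m = uniform_matrix(np.zeros(30, dtype=np.int8))
        assert detect_roh(m, WGS_PRESET)["ind0"] == []  # window needs 50

    def test_fuzz_equals_brute_force(self, small_genome):
        rng = np.random.default_rng(11)
        for rep in range(8):
            m = random_matrix(small_genome, 60, 6, rng,
                              geno_probs=(0.5, 0.12, 0.3, 0.08))
            for _ in range(5):
                params = random_roh_params(rng)
                fast = detect_roh(m, params)
                slow = brute_force_roh(m, params)
                assert fast == slow, params

    def test_segments_never_overlap_within_individual(self, small_genome):
        rng = np.random.default_rng(12)
        m = random_matrix(small_genome, 80, 10, rng)
        params = ROHParams(homozyg_snp=10, homozyg_kb=5, homozyg_density=1000,
                           homozyg_gap=100, homozyg_het=2, window_snp=10,
                           window_het=1, window_missing=1)
        for ind, segs in detect_roh(m, params).items():
            by_chrom: dict = {}
            for s in segs:
                by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
            for ivs in by_chrom.values():
                ivs.sort()
                for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                    assert e1 <= s2

    @pytest.mark.parametrize(
        "relax",
        [
            {"homozyg_snp": 5},
            {"homozyg_kb": 1.0},
            {"homozyg_gap": 2000.0},
            {"homozyg_het": 10},
        ],
    )
    def test_relaxing_one_constraint_never_shrinks_total_length(
        self, small_genome, relax
    ):
        rng = np.random.default_rng(13)
        m = random_matrix(small_genome, 80, 8, rng)
        base = ROHParams(homozyg_snp=15, homozyg_kb=20, homozyg_density=1000,
                         homozyg_gap=500, homozyg_het=2, window_snp=10,
                         window_het=1, window_missing=1)
        relaxed = replace(base, **relax)

        def total(params):
            return sum(
                s.length_bp for v in detect_roh(m, params).values() for s in v
            )

        assert total(relaxed) >= total(base)

    def test_fully_homozygous_union_equals_callable_territory(self):
        # consistency of the caller with the genome-coverage definition
        rng = np.random.default_rng(14)
        genome = GenomeSpec(("chr1", "chr2"), (3_000_000, 2_000_000))
        chrom_idx, pos = [], []
        for ci, length in enumerate(genome.lengths):
            p = np.sort(rng.choice(length, size=260, replace=False))
            chrom_idx.append(np.full(260, ci, np.int32))
            pos.append(p.astype(np.int64))
        m = GenotypeMatrix(
            genome, np.concatenate(chrom_idx), np.concatenate(pos),
            np.full(520, "A", "U1"), np.full(520, "G", "U1"), ["hom"],
            np.zeros((520, 1), dtype=np.int8),
        )
        params = ROHParams(homozyg_snp=20, homozyg_kb=50, homozyg_density=100,
                           homozyg_gap=50, homozyg_het=0, window_snp=30,
                           window_het=0, window_missing=0)
        segs = detect_roh(m, params)["hom"]
        union_bp = sum(s.length_bp for s in segs)
        expected_pct = meyermans_coverage(m, params)
        assert 100.0 * union_bp / genome.autosomal_length == pytest.approx(
            expected_pct, abs=1e-9
        )


class TestCoverageAndDensity:
    def test_empty_matrix_zero_coverage(self, small_genome):
        m = random_matrix(small_genome, 0, 2, np.random.default_rng(0))
        assert meyermans_coverage(m, WGS_PRESET) == 0.0

    def test_dense_uniform_map_near_full_coverage(self):
        m = uniform_matrix(np.zeros(990, dtype=np.int8), spacing_bp=1_000,
                           chrom_length=1_000_000)
        params = ROHParams(homozyg_snp=10, homozyg_kb=10, homozyg_density=50,
                           homozyg_gap=100, window_snp=10)
        assert meyermans_coverage(m, params) > 95.0

    def test_denser_panel_covers_more(self, small_genome):
        rng = np.random.default_rng(15)
        dense = random_matrix(small_genome, 300, 2, rng)
        sparse = dense.take_sites(np.arange(0, dense.n_sites, 12))
        params = ROHParams(homozyg_snp=10, homozyg_kb=10, homozyg_density=30,
                           homozyg_gap=50, window_snp=10)
        assert meyermans_coverage(dense, params) > meyermans_coverage(
            sparse, params
        )

    def test_density_simple_cases(self):
        m = uniform_matrix(np.zeros(1000, dtype=np.int8), spacing_bp=999,
                           chrom_length=1_000_000)
        d = snp_density(m, m.genome)
        assert d.loc[d.chrom == "chr1", "snps_per_mb"].iloc[0] == pytest.approx(1000)

    def test_density_overall_weighted(self):
        genome = GenomeSpec(("c1", "c2"), (1_000_000, 1_000_000))
        pos = np.concatenate([np.arange(10) * 1000 + 1, np.arange(30) * 1000 + 1])
        m = GenotypeMatrix(
            genome, np.repeat([0, 1], [10, 30]).astype(np.int32),
            pos.astype(np.int64), np.full(40, "A", "U1"), np.full(40, "G", "U1"),
            ["i"], np.zeros((40, 1), np.int8),
        )
        d = snp_density(m, genome).set_index("chrom")["snps_per_mb"]
        assert d["c1"] == 10 and d["c2"] == 30 and d["overall"] == 20

    def test_matches_count_loop(self, small_genome):
        rng = np.random.default_rng(16)
        m = random_matrix(small_genome, 57, 3, rng)
        d = snp_density(m, small_genome).set_index("chrom")
        for ci, name in enumerate(small_genome.names):
            n = sum(1 for c in m.chrom_idx if c == ci)
            assert d.loc[name, "snps_per_mb"] == pytest.approx(
                n / (small_genome.lengths[ci] / 1e6)
            )


class TestOptimizeParameters:
    def test_singleton_grid(self, small_genome):
        m = random_matrix(small_genome, 50, 2, np.random.default_rng(17))
        best, table = optimize_parameters(m, [WGS_PRESET])
        assert best == WGS_PRESET and len(table) == 1

    def test_dominating_setting_wins(self, small_genome):
        m = random_matrix(small_genome, 100, 2, np.random.default_rng(18))
        loose = ROHParams(homozyg_snp=5, homozyg_kb=1, homozyg_density=1000,
                          homozyg_gap=1000, window_snp=5)
        strict = replace(loose, homozyg_snp=95, homozyg_kb=500)
        best, _ = optimize_parameters(m, [strict, loose])
        assert best == loose

    def test_argmax_matches_exhaustive(self, small_genome):
        rng = np.random.default_rng(19)
        m = random_matrix(small_genome, 90, 2, rng)
        grid = [random_roh_params(rng) for _ in range(12)]
        best, table = optimize_parameters(m, grid)
        covs = [meyermans_coverage(m, p) for p in grid]
        assert best == grid[int(np.argmax(covs))]
        np.testing.assert_allclose(table["coverage_pct"], covs)

    def test_empty_grid_rejected(self, small_genome):
        m = random_matrix(small_genome, 10, 1, np.random.default_rng(20))
        with pytest.raises(ValueError):
            optimize_parameters(m, [])
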