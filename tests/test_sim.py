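"""Synthetic-data generator: pedigrees, gene dropping, panel degradation,
phenotypes."""

import numpy as np
import pandas as pd
import pytest

from autozyg.genome import GenomeSpec, default_genome
from autozyg.matrix import MISSING
from autozyg.pheno import count_data, egg_volume
from autozyg.sim import (
    Pedigree,
    PhenotypeEffects,
    add_genotype_errors,
    emulate_rrs,
    pedigree_inbreeding,
    simulate_genomes,
    simulate_pedigree,
    simulate_phenotypes,
)

TINY = GenomeSpec(("chr1", "chr2"), (10_000_000, 5_000_000))


class TestPedigree:
    def test_founders_only_have_no_parents(self):
        ped = simulate_pedigree(6, 0, "random", seed=0)
        assert ped.n == 6
        assert (ped.sire == -1).all() and (ped.dam == -1).all()

    def test_fullsib_line_inbreeding_by_path_counting(self):
        # Wright's path-counting values for repeated brother-sister mating
        ped = simulate_pedigree(2, 3, "fullsib_line", seed=0)
        F = pedigree_inbreeding(ped)
        gen = ped.generation
        assert np.allclose(F[gen == 1], 0.0)
        assert np.allclose(F[gen == 2], 0.25)
        assert np.allclose(F[gen == 3], 0.375)

    def test_lek_single_dominant_male_sires_all(self):
        ped = simulate_pedigree(10, 1, "lek", seed=1, n_dominant_males=1)
        g1 = np.flatnonzero(ped.generation == 1)
        assert len(set(ped.sire[g1])) == 1

    def test_single_sex_generation_rejected(self):
        # one offspring per generation -> generation 1 is all-male, so
        # generation 2 has no dams to draw from
        with pytest.raises(ValueError, match="lacks one sex"):
            simulate_pedigree(4, 2, "random", seed=0, offspring_per_generation=1)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            simulate_pedigree(4, 1, "panmixia?", seed=0)


class TestGeneDropping:
    def test_founders_not_autozygous(self):
        ped = simulate_pedigree(4, 2, "random", seed=2)
        _, ibd = simulate_genomes(ped, TINY, snp_density_per_Mb=10, seed=3)
        founders = [ped.ids[i] for i in range(ped.n) if ped.is_founder(i)]
        assert all(ibd.f_true[f] == 0.0 for f in founders)

    def test_selfed_offspring_f_true_half(self):
        # selfing: each replicate's expected autozygosity is 1/2
        vals = []
        for rep in range(200):
            ped = Pedigree(
                ids=["P", "S"],
                sire=np.array([-1, 0]),
                dam=np.array([-1, 0]),
                sex=np.array(["M", "M"]),
                generation=np.array([0, 1]),
            )
            _, ibd = simulate_genomes(ped, TINY, snp_density_per_Mb=2, seed=rep)
            vals.append(ibd.f_true["S"])
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.5) < 3 * se

    def test_no_recombination_gives_whole_chromosome_tracts(self):
        ped = simulate_pedigree(2, 3, "fullsib_line", seed=4)
        _, ibd = simulate_genomes(
            ped, TINY, recomb_rate_cM_per_Mb=0.0, snp_density_per_Mb=5, seed=5
        )
        for ind, per_chrom in ibd.tracts.items():
            for chrom, iv in per_chrom.items():
                length = TINY.length_of(chrom)
                assert iv.size == 0 or (
                    iv.shape[0] == 1 and iv[0, 0] == 0 and iv[0, 1] == length
                )

    def test_f_true_tracks_pedigree_inbreeding(self):
        # groups spanning F_ped 0 .. 0.375 on a 1 Gb genome (large genetic
        # length keeps Mendelian noise well below the group separation)
        genome = default_genome(23, 1000.0)
        f_ped_all, f_true_all = [], []
        for rep in range(25):
            ped = simulate_pedigree(2, 3, "fullsib_line", seed=rep)
            _, ibd = simulate_genomes(ped, genome, snp_density_per_Mb=0.2,
                                      seed=100 + rep)
            F = pedigree_inbreeding(ped)
            for i, ind in enumerate(ped.ids):
                f_ped_all.append(F[i])
                f_true_all.append(ibd.f_true[ind])
        from scipy.stats import spearmanr

        rho = spearmanr(f_ped_all, f_true_all).statistic
        assert rho > 0.9

    def test_zero_length_density_rejected(self):
        ped = simulate_pedigree(2, 0, "random", seed=0)
        with pytest.raises(ValueError):
            simulate_genomes(ped, TINY, snp_density_per_Mb=0, seed=0)


class TestRrsEmulation:
    @pytest.fixture(scope="class")
    @staticmethod
    def dense():
        ped = simulate_pedigree(10, 2, "random", seed=6)
        m, _ = simulate_genomes(ped, TINY, snp_density_per_Mb=7000, seed=7)
        return m

    def test_identity_limit(self, dense):
        src = dense.n_sites / (sum(TINY.lengths) / 1e6)
        out = emulate_rrs(dense, src, clustering=0, extra_missing_rate=0, seed=0)
        np.testing.assert_array_equal(out.gt, dense.gt)
        assert out.n_sites == dense.n_sites

    def test_hundredfold_thinning_count(self, dense):
        src = dense.n_sites / (sum(TINY.lengths) / 1e6)
        out = emulate_rrs(dense, src / 100, seed=8)
        expected = dense.n_sites / 100
        assert abs(out.n_sites - expected) / expected < 0.05

    def test_all_missing_boundary(self, dense):
        src = dense.n_sites / (sum(TINY.lengths) / 1e6)
        out = emulate_rrs(dense, src / 10, extra_missing_rate=1.0, seed=9)
        assert (out.gt == MISSING).all()

    def test_zero_target_rejected(self, dense):
        with pytest.raises(ValueError):
            emulate_rrs(dense, 0.0)

    def test_clustered_sites_are_clumped(self, dense):
        src = dense.n_sites / (sum(TINY.lengths) / 1e6)
        uni = emulate_rrs(dense, src / 50, clustering=0, seed=10)
        clu = emulate_rrs(dense, src / 50, clustering=0.5, seed=10)
        # clustered thinning yields far more sub-kb neighbour gaps
        def frac_close(m):
            sl = m.sites_of("chr1")
            gaps = np.diff(m.pos[sl])
            return (gaps < 1000).mean()

        assert frac_close(clu) > 2 * frac_close(uni)

    def test_ranking_preserved_after_thinning(self):
        from scipy.stats import spearmanr

        ped = simulate_pedigree(12, 3, "halfsib", seed=11)
        m, ibd = simulate_genomes(ped, TINY, snp_density_per_Mb=2000, seed=12)
        src = m.n_sites / (sum(TINY.lengths) / 1e6)
        thin = emulate_rrs(m, src / 20, clustering=0.3, seed=13)

        def hom_fraction(mat):
            called = mat.gt != MISSING
            hom = (mat.gt == 0) | (mat.gt == 2)
            return hom.sum(axis=0) / called.sum(axis=0)

        f = ibd.f_true.to_numpy()
        assert spearmanr(f, hom_fraction(m)).statistic > 0
        assert spearmanr(f, hom_fraction(thin)).statistic > 0


class TestGenotypeErrors:
    @pytest.fixture(scope="class")
    @staticmethod
    def mat():
        ped = simulate_pedigree(10, 2, "random", seed=14)
        m, _ = simulate_genomes(ped, TINY, snp_density_per_Mb=350, seed=15)
        return m

    def test_zero_rates_identity(self, mat):
        out = add_genotype_errors(mat, 0.0, 0.0, seed=0)
        np.testing.assert_array_equal(out.gt, mat.gt)

    def test_full_het_to_hom_leaves_no_hets(self, mat):
        out = add_genotype_errors(mat, het_to_hom_rate=1.0, seed=1)
        assert (out.gt != 1).all()

    def test_planted_rate_within_binomial_bounds(self, mat):
        n_hom = int(((mat.gt == 0) | (mat.gt == 2)).sum())
        assert n_hom > 1e5
        out = add_genotype_errors(mat, hom_to_het_rate=0.01, seed=2)
        flipped = int(((mat.gt != 1) & (out.gt == 1)).sum())
        p = 0.01
        sd = np.sqrt(n_hom * p * (1 - p))
        assert abs(flipped - n_hom * p) < 2.58 * sd  # 99% binomial bounds


class TestPhenotypes:
    @pytest.fixture(scope="class")
    @staticmethod
    def f_series():
        rng = np.random.default_rng(16)
        return pd.Series(rng.uniform(0, 0.5, 49), index=[f"f{i}" for i in range(49)])

    def test_deterministic_given_seed(self, f_series):
        a = simulate_phenotypes(f_series, seed=17)
        b = simulate_phenotypes(f_series, seed=17)
        pd.testing.assert_frame_equal(a, b)

    def test_invariants(self, f_series):
        ph = simulate_phenotypes(f_series, seed=18)
        assert (ph.eggs_hatched <= ph.clutch_size).all()
        assert (ph.egg_volume_ml > 0).all()
        # egg dimensions reproduce the volume through the geometry formula
        np.testing.assert_allclose(
            egg_volume(ph.egg_length_mm, ph.egg_width_mm),
            ph.egg_volume_ml,
            rtol=1e-9,
        )

    def test_zero_betas_zero_sds_equal_rates(self):
        # with no effects and no random variation every female shares one
        # log-rate: realized hatched means differ only by sampling noise
        rng = np.random.default_rng(19)
        f = pd.Series(rng.uniform(0, 0.5, 300), index=[f"f{i}" for i in range(300)])
        eff = PhenotypeEffects(
            beta_froh_clutch=0, beta_froh_hatch=0, beta_froh_volume=0,
            beta_age_clutch=0, beta_age_hatch=0, beta_gen_volume=0,
            clutch_intercept=np.log(30.0),  # large clutches: cap never binds
        )
        ph = simulate_phenotypes(
            f, eff, random_sd_id=0, random_sd_year=0, n_years=2, seed=20
        )
        cd = count_data(ph)
        lo = cd[cd.female_id.isin(f.index[f < f.median()])].eggs_hatched
        hi = cd[cd.female_id.isin(f.index[f >= f.median()])].eggs_hatched
        pooled_se = np.sqrt(lo.var() / len(lo) + hi.var() / len(hi))
        assert abs(lo.mean() - hi.mean()) < 3.5 * pooled_se

    def test_planted_rate_ratio_matches_link_inversion(self):
        # females at +-1 SD of F differ in log-rate by beta: ratio e^-0.44
        n = 4000
        f = pd.Series(
            np.r_[np.full(n, 0.1), np.full(n, 0.3)],
            index=[f"f{i}" for i in range(2 * n)],
        )
        eff = PhenotypeEffects(clutch_intercept=np.log(30.0))
        ph = simulate_phenotypes(
            f, eff, random_sd_id=0, random_sd_year=0, n_years=1, seed=21
        )
        cd = count_data(ph)
        mean_hi_f = cd[cd.female_id.isin(f.index[n:])].eggs_hatched.mean()
        mean_lo_f = cd[cd.female_id.isin(f.index[:n])].eggs_hatched.mean()
        # F spread 0.1/0.3 with SD 0.1: z = -+0.5, log-ratio = beta = -0.44
        assert mean_hi_f / mean_lo_f == pytest.approx(np.exp(-0.44), rel=0.05)

    def test_large_year_variance_dominates(self, f_series):
        ph = simulate_phenotypes(
            f_series, random_sd_id=0.0, random_sd_year=2.0, n_years=8, seed=22
        )
        cd = count_data(ph)
        cd["log1p"] = np.log1p(cd.eggs_hatched)
        by_year = cd.groupby("year")["log1p"].mean()
        within = cd.groupby("year")["log1p"].var().mean()
        assert by_year.var() > within

    def test_negative_sd_rejected(self, f_series):
        with pytest.raises(ValueError):
            simulate_phenotypes(f_series, random_sd_id=-1.0, seed=0)
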