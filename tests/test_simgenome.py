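import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from automixia import simgenome as sg


class TestGenomeMap:
    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            sg.Chromosome("chr1", 0, 1)

    def test_rejects_centromere_outside_chromosome(self):
        for cen in (0, 100, 150):
            with pytest.raises(ValueError):
                sg.Chromosome("chr1", 100, cen)

    def test_rejects_duplicate_names(self):
        with pytest.raises(ValueError):
            sg.GenomeMap((sg.Chromosome("c", 10, 5), sg.Chromosome("c", 20, 5)))

    def test_default_karyotypes(self):
        acro = sg.acrocentric_karyotype()
        meta = sg.metacentric_karyotype()
        assert len(acro) == 23
        for chrom in meta:
            assert chrom.centromere_pos == chrom.length // 2


class TestMaternalGenome:
    def test_zero_density_gives_no_sites(self, small_genome):
        mom = sg.simulate_maternal_genome(small_genome, 0.0, seed=1)
        assert mom.n_sites == 0

    def test_site_count_matches_poisson_mean(self):
        gm = sg.GenomeMap((sg.Chromosome("chr1", 10_000_000, 1_000_000),))
        counts = [
            sg.simulate_maternal_genome(gm, 1e-4, seed=s).n_het_sites for s in range(100)
        ]
        # mean of 100 Poisson(1000) draws, 5 sigma band on the mean
        assert abs(np.mean(counts) - 1000) < 5 * np.sqrt(1000) / 10

    def test_same_seed_reproduces_sites(self, small_genome):
        a = sg.simulate_maternal_genome(small_genome, 1e-3, seed=7, hom_density=1e-3)
        b = sg.simulate_maternal_genome(small_genome, 1e-3, seed=7, hom_density=1e-3)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_positions_sorted_unique_and_in_range(self, mother, small_genome):
        for chrom in small_genome:
            pos = mother.sites[chrom.name].pos
            assert np.all(np.diff(pos) > 0)
            assert pos[0] >= 0 and pos[-1] < chrom.length

    def test_het_flag_matches_alleles(self, mother):
        frame = mother.to_frame()
        assert ((frame["allele1"] != frame["allele2"]) == frame["is_het"]).all()

    def test_paternal_alleles_disjoint_at_het_sites(self, mother, father):
        for name, block in mother.sites.items():
            pblock = father.sites[name]
            het = block.is_het
            assert not np.any(
                (pblock.allele_a[het] == block.allele_a[het])
                | (pblock.allele_a[het] == block.allele_b[het])
                | (pblock.allele_b[het] == block.allele_a[het])
                | (pblock.allele_b[het] == block.allele_b[het])
            )

    def test_negative_density_rejected(self, small_genome):
        with pytest.raises(ValueError):
            sg.simulate_maternal_genome(small_genome, -1e-4, seed=0)


class TestMeiosis:
    def test_no_crossovers_gives_parental_chromatids(self, mother):
        tetrad = sg.simulate_meiosis(mother, 0.0, False, seed=3)
        for ct in tetrad.per_chromosome.values():
            assert len(ct.crossover_positions) == 0
            origins = {tuple(c.origins) for c in ct.chromatids}
            assert origins == {(0,), (1,)}
            egg = ct.role("egg")
            pb2 = ct.role("pb2_sister")
            assert np.array_equal(egg.origins, pb2.origins)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), rate=st.floats(0.0, 6.0))
    def test_homolog_conservation(self, small_genome, seed, rate):
        """At every position exactly two chromatids carry each homolog."""
        tetrad = sg.simulate_meiosis(small_genome, rate, True, seed=seed)
        probe = np.random.default_rng(seed).integers(0, 700_000, 50)
        for ct in tetrad.per_chromosome.values():
            total = sum(c.origin_at(probe).astype(int) for c in ct.chromatids)
            assert np.all(total == 2)

    def test_single_forced_crossover_recombines_two_chromatids(self, one_chrom_genome):
        x = 500_000
        tetrad = sg.simulate_meiosis(
            one_chrom_genome, seed=5, forced_crossovers={"chr1": [x]}
        )
        ct = tetrad.per_chromosome["chr1"]
        probe = np.array([0, 999_999])
        sides = np.array([c.origin_at(probe) for c in ct.chromatids])
        recombinant = sides[:, 0] != sides[:, 1]
        assert recombinant.sum() == 2
        # one recombinant per centromere pair (non-sister exchange)
        assert recombinant[:2].sum() == 1 and recombinant[2:].sum() == 1

    def test_roles_partition_the_tetrad(self, mother):
        tetrad = sg.simulate_meiosis(mother, 2.0, True, seed=11)
        for ct in tetrad.per_chromosome.values():
            idx = sorted(ct.roles.values())
            assert idx == [0, 1, 2, 3]
            egg, pb2 = ct.roles["egg"], ct.roles["pb2_sister"]
            assert {egg, pb2} in ({0, 1}, {2, 3})

    def test_deterministic_under_seed(self, mother):
        a = sg.simulate_meiosis(mother, 2.5, True, seed=9)
        b = sg.simulate_meiosis(mother, 2.5, True, seed=9)
        for name in a.per_chromosome:
            for ca, cb in zip(a.per_chromosome[name].chromatids, b.per_chromosome[name].chromatids):
                assert np.array_equal(ca.bounds, cb.bounds)
                assert np.array_equal(ca.origins, cb.origins)


class TestMakeOffspring:
    def test_mode_validation(self, mother, father):
        tetrad = sg.simulate_meiosis(mother, 2.0, True, seed=1)
        with pytest.raises(ValueError):
            sg.make_offspring(tetrad, "sexual", mother, None, seed=1)
        with pytest.raises(ValueError):
            sg.make_offspring(tetrad, "gamete_duplication", mother, father, seed=1)
        with pytest.raises(ValueError):
            sg.make_offspring(tetrad, "budding", mother, seed=1)

    def test_duplication_fully_homozygous(self, mother):
        tetrad = sg.simulate_meiosis(mother, 3.0, True, seed=2)
        off = sg.make_offspring(tetrad, "gamete_duplication", mother, seed=3)
        assert off.n_het_sites == 0

    def test_no_crossover_limits_of_automixis(self, mother):
        """Sister fusion erases, homolog fusion preserves, all heterozygosity."""
        tetrad = sg.simulate_meiosis(mother, 0.0, False, seed=4)
        terminal = sg.make_offspring(tetrad, "terminal_automixis", mother, seed=5)
        central = sg.make_offspring(tetrad, "central_automixis", mother, seed=6)
        assert terminal.n_het_sites == 0
        assert central.n_het_sites == mother.n_het_sites

    def test_sexual_offspring_heterozygous_at_maternal_het_sites(self, mother, father):
        tetrad = sg.simulate_meiosis(mother, 2.0, True, seed=7)
        off = sg.make_offspring(tetrad, "sexual", mother, father, seed=8)
        assert off.n_het_sites >= mother.n_het_sites  # disjoint paternal alleles

    def test_offspring_sites_match_maternal_grid(self, mother):
        tetrad = sg.simulate_meiosis(mother, 2.0, True, seed=9)
        off = sg.make_offspring(tetrad, "terminal_automixis", mother, seed=10)
        for name, block in mother.sites.items():
            assert np.array_equal(off.sites[name].pos, block.pos)


class TestPileups:
    def test_errorfree_homozygous_site_single_base(self, small_genome):
        mom = sg.simulate_maternal_genome(small_genome, 0.0, hom_density=1e-3, seed=12)
        pile = sg.simulate_pileups(mom, 20.0, 0.0, seed=13)
        counts = pile[list(sg.BASES)].to_numpy()
        assert np.all((counts > 0).sum(axis=1) <= 1)

    def test_mean_coverage_converges(self):
        gm = sg.GenomeMap((sg.Chromosome("chr1", 2_000_000, 100_000),))
        mom = sg.simulate_maternal_genome(gm, 0.1, seed=14)
        pile = sg.simulate_pileups(mom, 18.37, 0.0, seed=15)
        cov = pile[list(sg.BASES)].to_numpy().sum(axis=1)
        assert len(cov) > 100_000
        assert abs(cov.mean() - 18.37) < 0.01 * 18.37

    def test_equal_split_probability_at_fixed_coverage(self):
        """P(10/10 split at coverage 20) is the central binomial term."""
        gm = sg.GenomeMap((sg.Chromosome("chr1", 2_000_000, 100_000),))
        mom = sg.simulate_maternal_genome(gm, 0.1, seed=16)
        pile = sg.simulate_pileups(mom, 20.0, 0.0, seed=17)
        counts = pile[list(sg.BASES)].to_numpy()
        cov = counts.sum(axis=1)
        at20 = counts[cov == 20]
        split = (at20 == 10).sum(axis=1) == 2
        p_expected = 0.17619705200195312  # C(20,10)/2^20
        n = len(at20)
        assert abs(split.mean() - p_expected) < 3 * np.sqrt(p_expected * (1 - p_expected) / n)

    def test_error_rate_validation(self, mother):
        with pytest.raises(ValueError):
            sg.simulate_pileups(mother, 20.0, 0.3, seed=1)
        with pytest.raises(ValueError):
            sg.simulate_pileups(mother, 0.0, 0.0, seed=1)

    def test_deterministic(self, mother):
        a = sg.simulate_pileups(mother, 20.0, 1e-3, seed=18)
        b = sg.simulate_pileups(mother, 20.0, 1e-3, seed=18)
        pd.testing.assert_frame_equal(a, b)


class TestMicrosatellites:
    def test_fp_offspring_homozygous_at_every_locus(self):
        rng = np.random.default_rng(20)
        mom, dad = sg.simulate_ms_parents(8, rng=rng)
        off = sg.simulate_ms_panel(mom, None, "gamete_duplication", 0.0, rng=rng)
        assert all(a == b for a, b in off.genotypes.values())
        assert all(
            off.genotypes[locus][0] in mom.alleles(locus) for locus in off.loci
        )

    def test_sexual_offspring_heterozygous_with_disjoint_parents(self):
        rng = np.random.default_rng(21)
        mom, dad = sg.simulate_ms_parents(8, rng=rng)
        off = sg.simulate_ms_panel(mom, dad, "sexual", 0.0, rng=rng)
        assert all(a != b for a, b in off.genotypes.values())

    def test_fp_sibs_inherit_different_alleles_half_the_time(self):
        """Two FP offspring of a heterozygous mother differ at a locus w.p. 1/2."""
        mom = sg.MSPanel("m", {"MS1": (200, 208)})
        differ = 0
        n = 800
        rng = np.random.default_rng(22)
        for _ in range(n):
            a = sg.simulate_ms_panel(mom, None, "gamete_duplication", 0.0, rng=rng)
            b = sg.simulate_ms_panel(mom, None, "gamete_duplication", 0.0, rng=rng)
            differ += a.genotypes["MS1"] != b.genotypes["MS1"]
        assert abs(differ / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_sexual_mode_requires_father(self):
        mom = sg.MSPanel("m", {"MS1": (200, 208)})
        with pytest.raises(ValueError):
            sg.simulate_ms_panel(mom, None, "sexual", 0.0, seed=1)


class TestColonyAndCells:
    def test_zero_fp_rate(self):
        rec = sg.simulate_colony(200, 0.0, seed=30)
        assert (rec["mode"] == "sexual").all()
        assert rec["father_id"].notna().all()

    def test_fp_count_matches_binomial_mean(self):
        counts = [
            (sg.simulate_colony(832, 8 / 832, seed=s)["mode"] != "sexual").sum()
            for s in range(300)
        ]
        se = np.sqrt(8 * (1 - 8 / 832) / 300)
        assert abs(np.mean(counts) - 8) < 4 * se

    def test_fp_records_have_no_father(self):
        rec = sg.simulate_colony(500, 0.3, seed=31)
        fp = rec["mode"] != "sexual"
        assert rec.loc[fp, "father_id"].isna().all()

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            sg.simulate_colony(10, 1.5, seed=0)
        with pytest.raises(ValueError):
            sg.simulate_colony(10, 0.5, hatch_normal_given_fp=0.7, died_in_ovum_given_fp=0.5, seed=0)
        with pytest.raises(ValueError):
            sg.simulate_cell_sample(100, 0.6, 0.5, seed=0)

    def test_cell_sample_near_expected_classes(self):
        sample = sg.simulate_cell_sample(943_000, 87 / 943, 12 / 943, seed=32)
        assert sample.n_total == 943_000
        assert abs(sample.n_haploid / 943_000 - 87 / 943) < 0.002
        assert abs(sample.n_binucleated / 943_000 - 12 / 943) < 0.001

    def test_colony_from_counts_margins(self):
        rec = sg.colony_from_counts(286, 15, {"hatched_normal": 6, "died_in_ovum": 9})
        assert len(rec) == 286
        assert (rec["mode"] != "sexual").sum() == 15


class TestRadSummaries:
    def test_cohort_mean_and_columns(self):
        table = sg.simulate_rad_summaries({"sp1": 150, "sp2": 171}, seed=40)
        assert len(table) == 321
        pct = 100 * table["n_het"] / table["n_considered"]
        assert abs(pct.mean() - 0.261) < 0.01
        assert set(table.columns) == {"id", "species", "mean_coverage", "n_het", "n_considered"}

    def test_planted_low_individual(self):
        table = sg.simulate_rad_summaries(
            {"deppii": 74}, seed=41, planted_low={"deppii_010": 0.01}
        )
        row = table[table["id"] == "deppii_010"].iloc[0]
        pct = 100 * row["n_het"] / row["n_considered"]
        assert pct < 0.05
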