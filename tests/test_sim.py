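"""Synthetic-population generator: Mendelian structure, noise models, determinism."""

import numpy as np
import pandas as pd
import pytest

import fibermap as fm
from fibermap.sim import draw_parental_sites


class TestSimulateF2:
    def test_mendelian_1_2_1_frequencies(self, tiny_genome):
        """Causal genotype frequencies match 1:2:1 within 3 SE at n=10,000."""
        cfg = fm.CrossConfig(n_f2=10_000, seed=42)
        pop = fm.simulate_f2(tiny_genome, cfg)
        counts = pop.genotype_counts()
        n = len(pop)
        for geno, expected in ((0, 0.25), (1, 0.50), (2, 0.25)):
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(counts[geno] / n - expected) < 3 * se
        # carrier count consistent with Binomial(n, 0.75)
        carriers = counts[1] + counts[2]
        assert abs(carriers - 0.75 * n) < 3 * np.sqrt(n * 0.75 * 0.25)

    def test_zero_genetic_length_means_no_crossovers(self):
        g = fm.GenomeModel(
            chromosomes=(fm.Chromosome("flat", 2_000_000, 0.0),),
            causal_locus=("flat", 1_000_000),
        )
        pop = fm.simulate_f2(g, fm.CrossConfig(n_f2=50, seed=3))
        for ind in pop:
            for gam in ind.gametes["flat"]:
                assert len(gam.breakpoints) == 0

    def test_genotype_consistent_with_haplotypes(self, tiny_genome):
        pop = fm.simulate_f2(tiny_genome, fm.CrossConfig(n_f2=30, seed=5))
        chrom, pos = tiny_genome.causal_locus
        for ind in pop:
            g1, g2 = ind.gametes[chrom]
            derived = int(g1.carries_mutant(np.array([pos]))[0]) + int(
                g2.carries_mutant(np.array([pos]))[0]
            )
            assert derived == ind.causal_genotype

    def test_invalid_genome_rejected(self):
        with pytest.raises(ValueError):
            fm.Chromosome("bad", 0, 1.0)
        with pytest.raises(ValueError):
            fm.GenomeModel(
                chromosomes=(fm.Chromosome("c", 1000, 1.0),),
                causal_locus=("c", 2000),
            )
        with pytest.raises(ValueError):
            fm.GenomeModel(
                chromosomes=(fm.Chromosome("c", 1000, 1.0),),
                variant_density=0.0,
                causal_locus=("c", 500),
            )


class TestPhenotypes:
    def test_noiseless_colors_hit_class_means(self, tiny_genome):
        cfg = fm.CrossConfig(n_f2=200, noise_sd=0.0, seed=8)
        pop = fm.assign_phenotypes(fm.simulate_f2(tiny_genome, cfg), cfg)
        mid = tuple((b + w) / 2 for b, w in zip(fm.BROWN_PARENT_LAB, fm.WHITE_PARENT_LAB))
        expected = {0: fm.WHITE_PARENT_LAB, 1: mid, 2: fm.BROWN_PARENT_LAB}
        for ind in pop:
            assert np.allclose(ind.color, np.tile(expected[ind.causal_genotype], (3, 1)))

    def test_noiseless_groups_match_genotypes(self, tiny_genome):
        """With zero noise the color groups recover the genotype classes exactly."""
        cfg = fm.CrossConfig(n_f2=300, noise_sd=0.0, seed=9)
        pop = fm.assign_phenotypes(fm.simulate_f2(tiny_genome, cfg), cfg)
        label = {0: "white", 1: "cream", 2: "brown"}
        assert all(ind.group == label[ind.causal_genotype] for ind in pop)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            fm.CrossConfig(noise_sd=-1.0)


class TestMakeBulks:
    def test_disjoint_bulks_of_requested_size(self, small_population):
        a, b = fm.make_bulks(small_population, "brown", "white", 12)
        assert len(a) == len(b) == 12
        assert not set(a) & set(b)
        groups = {i.id: i.group for i in small_population}
        assert all(groups[i] == "brown" for i in a)
        assert all(groups[i] == "white" for i in b)

    def test_zero_bulk_size_gives_empty_sets(self, small_population):
        a, b = fm.make_bulks(small_population, "brown", "white", 0)
        assert a == [] and b == []

    def test_infeasible_bulk_size_raises(self, small_population):
        with pytest.raises(ValueError, match="cannot bulk"):
            fm.make_bulks(small_population, "brown", "white", 200)


class TestBulkVariants:
    @pytest.fixture(scope="class")
    def noiseless(self, small_genome):
        cfg = fm.CrossConfig(
            n_f2=120, noise_sd=0.0, genotyping_error=0.0, dropout=0.0, seed=21
        )
        pop = fm.assign_phenotypes(fm.simulate_f2(small_genome, cfg), cfg)
        brown, white = fm.make_bulks(pop, "brown", "white", 12)
        rng = np.random.default_rng(77)
        sites = draw_parental_sites(small_genome, rng)
        chrom, pos = small_genome.causal_locus
        causal_row = pd.DataFrame(
            [[chrom, pos, "A", "G", "SNP"]], columns=sites.columns
        )
        sites = (
            pd.concat([sites, causal_row])
            .drop_duplicates(["chrom", "pos"])
            .sort_values(["chrom", "pos"])
            .reset_index(drop=True)
        )
        sets = fm.simulate_bulk_variants(
            small_genome, pop, {"brown": brown, "white": white}, cfg, sites=sites, rng=rng
        )
        return small_genome, sites, sets

    def test_causal_site_separates_the_bulks(self, noiseless):
        genome, sites, sets = noiseless
        chrom, pos = genome.causal_locus
        key = lambda vs: set(zip(vs.df["chrom"], vs.df["pos"]))
        assert (chrom, pos) in key(sets["brown"])
        assert (chrom, pos) not in key(sets["white"])

    def test_unlinked_sites_cancel_in_subtraction(self, noiseless):
        """Without call noise, sites on other chromosomes are shared by both
        bulks (with 12-member bulks the depletion zone spans the whole causal
        chromosome, so only other chromosomes are genuinely unlinked)."""
        genome, sites, sets = noiseless
        residual = fm.subtract_shared_variants(sets["brown"], sets["white"])
        chrom, _ = genome.causal_locus
        unlinked_total = (sites["chrom"] != chrom).sum()
        off_target = residual.df[residual.df["chrom"] != chrom]
        assert len(off_target) / unlinked_total < 0.01
        # the residual concentrates on the causal chromosome
        assert (residual.df["chrom"] == chrom).mean() > 0.95

    def test_empty_bulk_yields_empty_set(self, small_genome, small_population):
        sets = fm.simulate_bulk_variants(
            small_genome, small_population, {"none": []}, rng=np.random.default_rng(1)
        )
        assert len(sets["none"]) == 0


class TestDeterminism:
    def test_same_seed_reproduces_everything(self, small_genome):
        def run():
            cfg = fm.CrossConfig(n_f2=60, bulk_size=6, seed=123)
            pop = fm.assign_phenotypes(fm.simulate_f2(small_genome, cfg), cfg)
            a, b = fm.make_bulks(pop, "brown", "white", 6)
            sets = fm.simulate_bulk_variants(small_genome, pop, {"a": a, "b": b}, cfg)
            return pop.phenotype_frame(), sets["a"].df, sets["b"].df

        p1, a1, b1 = run()
        p2, a2, b2 = run()
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)


class TestSimulateCounts:
    GROUPS = {"m1": "mut", "m2": "mut", "c1": "ctl", "c2": "ctl"}

    def test_planted_fold_recovered_at_low_dispersion(self):
        counts, design = fm.simulate_counts(
            200, self.GROUPS, [("gene_0001", "mut", 179.0)], dispersion=0.0, seed=2
        )
        m = counts.loc["gene_0001", ["m1", "m2"]].mean()
        c = counts.loc["gene_0001", ["c1", "c2"]].mean()
        # Poisson noise on the n=2 control mean leaves ~10% relative error
        assert m / c == pytest.approx(179.0, rel=0.35)

    def test_null_genes_share_means_across_groups(self):
        """Median per-gene CPM ratio is 1 when nothing is planted."""
        counts, _ = fm.simulate_counts(2000, self.GROUPS, [], dispersion=0.05, seed=3)
        cpm = fm.normalize(counts)
        ratio = (cpm[["m1", "m2"]].mean(axis=1) + 1) / (cpm[["c1", "c2"]].mean(axis=1) + 1)
        assert float(ratio.median()) == pytest.approx(1.0, abs=0.05)

    def test_bad_fold_or_design_rejected(self):
        with pytest.raises(ValueError, match="fold_change"):
            fm.simulate_counts(10, self.GROUPS, [("gene_0001", "mut", 0.0)])
        with pytest.raises(ValueError, match="replicates"):
            fm.simulate_counts(10, {"a": "x", "b": "y"}, [])


class TestLocusSequences:
    def test_structure_matches_requested_lengths(self, locus_seqs):
        assert len(locus_seqs["element"]) == 2877 + 4687 + 2879
        flank = 2000
        assert len(locus_seqs["empty_region"]) == 2 * flank + 5
        assert locus_seqs["element"] in locus_seqs["insertion_region"]
        assert locus_seqs["element"] not in locus_seqs["empty_region"]

    def test_insertion_region_has_tsd_and_empty_region_does_not(self, locus_seqs):
        region = locus_seqs["insertion_region"]
        i = region.index(locus_seqs["element"])
        assert region[i - 5 : i] == region[i + len(locus_seqs["element"]) :][:5]
        empty = locus_seqs["empty_region"]
        ip = 2005
        assert all(
            empty[ip - k : ip] != empty[ip : ip + k] for k in (4, 5, 6)
        )
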