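"""EMS mutagenesis, meiosis and pooled-sequencing simulator."""

import numpy as np
import pytest

from nodmap.effects import annotate_variant
from nodmap.genome import GeneModel, ReferenceGenome
from nodmap.simulate import (
    CrossConfig,
    EmsConfig,
    SequencingConfig,
    draw_ems_mutations,
    haldane_r,
    place_causal_variant,
    random_gene_models,
    random_genome,
    sample_pool_counts,
    select_mutant_pool,
    simulate_f2_plants,
)


def _one_mb_genome(seed=7):
    return random_genome({"c1": 1_000_000}, seed=seed)


class TestDrawEmsMutations:
    def test_rate_zero_gives_no_mutations(self):
        g = _one_mb_genome()
        assert draw_ems_mutations(g, EmsConfig(mutation_rate=0.0)) == []

    def test_full_spectrum_is_gc_to_at(self):
        g = _one_mb_genome()
        variants = draw_ems_mutations(g, EmsConfig(5.0, 1.0, seed=3))
        assert len(variants) > 0
        assert all((v.ref, v.alt) in {("G", "A"), ("C", "T")} for v in variants)
        for v in variants:
            v.validate_against(g)

    def test_expected_count_matches_rate(self):
        # Poisson(rate * Mb): 40 draws on a 1-Mb genome, rate 50
        g = _one_mb_genome()
        counts = [
            len(draw_ems_mutations(g, EmsConfig(50.0, 1.0, seed=s)))
            for s in range(40)
        ]
        mean, sigma = 50.0, np.sqrt(50.0 / 40)
        assert abs(np.mean(counts) - mean) < 3 * sigma

    def test_deterministic_given_seed(self):
        g = _one_mb_genome()
        a = draw_ems_mutations(g, EmsConfig(5.0, 1.0, seed=11))
        b = draw_ems_mutations(g, EmsConfig(5.0, 1.0, seed=11))
        assert a == b
        c = draw_ems_mutations(g, EmsConfig(5.0, 1.0, seed=12))
        assert a != c

    def test_positions_unique(self):
        g = random_genome({"c1": 20_000}, seed=0)
        variants = draw_ems_mutations(g, EmsConfig(500.0, 1.0, seed=0))
        sites = [(v.chromosome, v.position) for v in variants]
        assert len(sites) == len(set(sites))

    def test_gc_free_genome_rejected(self):
        g = ReferenceGenome([("c", "ATATATAT" * 100)])
        with pytest.raises(ValueError, match="no G/C"):
            draw_ems_mutations(g, EmsConfig(5000.0, 1.0, seed=0))


class TestPlaceCausalVariant:
    def test_splice_donor_hits_first_intron_base(self, toy_genome, toy_gene):
        v = place_causal_variant(toy_genome, toy_gene, "splice_donor")
        assert v.position == 17  # first base of the GT donor
        assert (v.ref, v.alt) == ("G", "A")
        assert v.causal

    def test_missense_is_confirmed_by_annotator(self, toy_genome, toy_gene):
        v = place_causal_variant(toy_genome, toy_gene, "missense")
        eff = annotate_variant(v, [toy_gene], toy_genome)[0]
        assert eff.effect_class == "missense"

    def test_gga_middle_g_gives_gly_to_glu(self, toy_genome, toy_gene):
        # CDS ATG GGA GAA TAA: the middle G of GGA (genomic 15) -> GAA, G2E
        from nodmap.genome import EmsVariant

        eff = annotate_variant(EmsVariant("chr1", 15, "G", "A"),
                               [toy_gene], toy_genome)[0]
        assert eff.effect_class == "missense"
        assert eff.protein_change == "G2E"

    def test_donor_without_gc_errors(self):
        genome = ReferenceGenome([("c", "ATGGGA" + "TTTTTTAA" + "GAATAA")])
        gene = GeneModel("g", "c", "+", exons=[(1, 6), (15, 20)],
                         cds=[(1, 6), (15, 20)])
        with pytest.raises(ValueError, match="no G/C"):
            place_causal_variant(genome, gene, "splice_donor")


def _two_site_setup(d_cm: float, length=1_000_000):
    """Genome with two EMS variants d_cm apart on a 100-cM chromosome."""
    from nodmap.genome import EmsVariant

    g = random_genome({"c1": length}, seed=5)
    bp_per_cm = length / 100.0
    p1 = int(0.25 * length)
    p2 = int(p1 + d_cm * bp_per_cm)
    variants = []
    for p in (p1, p2):
        ref = g.base("c1", p)
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        variants.append(EmsVariant("c1", p, ref, alt))
    return g, variants


class TestSimulateF2:
    def test_single_variant_segregates_1_2_1(self):
        g, variants = _two_site_setup(10)
        plants = simulate_f2_plants(variants[:1], g, CrossConfig(seed=2), 4000)
        counts = np.bincount(plants[:, 0], minlength=3)
        for k, p in zip(counts, (0.25, 0.5, 0.25)):
            sigma = np.sqrt(4000 * p * (1 - p))
            assert abs(k - 4000 * p) < 3 * sigma

    def test_zero_cm_apart_is_complete_linkage(self):
        g, variants = _two_site_setup(1)  # physical gap, but cM length ~0
        cfg = CrossConfig(chromosome_genetic_lengths={"c1": 1e-9}, seed=3)
        plants = simulate_f2_plants(variants, g, cfg, 500)
        assert (plants[:, 0] == plants[:, 1]).all()

    def test_haldane_recombinant_fraction_at_50_cm(self):
        # closed form: r = (1 - e^-1)/2 = 0.3161
        g, variants = _two_site_setup(50)
        plants = simulate_f2_plants(variants, g, CrossConfig(seed=4), 6000)
        # a selfed plant's two gametes are i.i.d.; recover per-gamete
        # recombination from the genotype pair is messy, so sample gametes
        from nodmap.simulate import _sample_gametes

        rng = np.random.default_rng(9)
        gametes = _sample_gametes(variants, g, CrossConfig(), 20_000, rng)
        rec = np.mean(gametes[:, 0] != gametes[:, 1])
        r = haldane_r(50.0)
        assert abs(r - 0.3161) < 1e-4
        sigma = np.sqrt(r * (1 - r) / 20_000)
        assert abs(rec - r) < 3 * sigma

    def test_unlinked_chromosomes_segregate_independently(self):
        from nodmap.genome import EmsVariant

        g = random_genome({"c1": 100_000, "c2": 100_000}, seed=6)
        variants = []
        for chrom in ("c1", "c2"):
            p = 50_000
            ref = g.base(chrom, p)
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
            variants.append(EmsVariant(chrom, p, ref, alt))
        from nodmap.simulate import _sample_gametes

        gametes = _sample_gametes(
            variants, g, CrossConfig(), 20_000, np.random.default_rng(10)
        )
        rec = np.mean(gametes[:, 0] != gametes[:, 1])
        assert abs(rec - 0.5) < 3 * np.sqrt(0.25 / 20_000)


class TestSelectMutantPool:
    @pytest.fixture()
    def causal_setup(self):
        from nodmap.genome import EmsVariant

        g = random_genome({"c1": 1_000_000}, seed=8)
        p = 500_000
        ref = g.base("c1", p)
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        return g, [EmsVariant("c1", p, ref, alt, causal=True)]

    def test_recessive_class_is_quarter_of_f2(self, causal_setup):
        g, variants = causal_setup
        plants = simulate_f2_plants(variants, g, CrossConfig(seed=1), 1000)
        eligible = int((plants[:, 0] == 2).sum())
        assert abs(eligible - 250) < 3 * np.sqrt(1000 * 0.25 * 0.75)

    def test_selected_plants_all_homozygous(self, causal_setup):
        g, variants = causal_setup
        plants = simulate_f2_plants(variants, g, CrossConfig(seed=1), 1000)
        pool = select_mutant_pool(plants, variants, 110, rng=0)
        assert pool.shape == (110, 1)
        assert (pool[:, 0] == 2).all()

    def test_undersized_f2_raises(self, causal_setup):
        g, variants = causal_setup
        plants = simulate_f2_plants(variants, g, CrossConfig(seed=1), 40)
        with pytest.raises(ValueError, match="homozygous"):
            select_mutant_pool(plants, variants, 110, rng=0)

    def test_linked_site_frequency_follows_one_minus_r(self):
        """E[pool alt frequency] = 1 - r at r = 0.1, 200 replicates, 3 sigma."""
        from nodmap.genome import EmsVariant

        r = 0.1
        d_cm = -50.0 * np.log(1.0 - 2.0 * r)  # invert Haldane
        length = 1_000_000
        g = random_genome({"c1": length}, seed=12)
        p1 = 200_000
        p2 = int(p1 + d_cm * length / 100.0)
        variants = []
        for p, causal in ((p1, True), (p2, False)):
            ref = g.base("c1", p)
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
            variants.append(EmsVariant("c1", p, ref, alt, causal=causal))
        freqs = []
        for rep in range(200):
            cfg = CrossConfig(seed=100_000 + rep)
            plants = simulate_f2_plants(variants, g, cfg, 600)
            pool = select_mutant_pool(plants, variants, 110, rng=rep)
            freqs.append(pool[:, 1].sum() / 220.0)
        sigma_mean = np.sqrt(r * (1 - r) / (220 * 200))
        assert abs(np.mean(freqs) - (1 - r)) < 3 * sigma_mean


class TestSamplePoolCounts:
    def _pool(self, genotype, n=110):
        return np.full((n, 1), genotype, dtype=np.int8)

    @pytest.fixture()
    def one_variant(self):
        from nodmap.genome import EmsVariant

        return [EmsVariant("c1", 10, "G", "A")]

    def test_all_homozygous_gives_index_one(self, one_variant):
        counts = sample_pool_counts(
            self._pool(2), one_variant, SequencingConfig(50, 0.0, seed=0)
        )
        assert (counts.alt_count == counts.depth).all()

    def test_all_wild_type_gives_zero(self, one_variant):
        counts = sample_pool_counts(
            self._pool(0), one_variant, SequencingConfig(50, 0.0, seed=0)
        )
        assert (counts.alt_count == 0).all()

    def test_depth_is_poisson_mean_depth(self):
        from nodmap.genome import EmsVariant

        variants = [EmsVariant("c1", 10 + i, "G", "A") for i in range(2000)]
        pool = np.ones((10, 2000), dtype=np.int8)
        counts = sample_pool_counts(pool, variants, SequencingConfig(50, 0.0, seed=1))
        assert abs(counts.depth.mean() - 50) < 3 * np.sqrt(50 / 2000)

    def test_error_rate_pulls_fixed_sites_off_one(self, one_variant):
        cfg = SequencingConfig(mean_depth=10_000, error_rate=0.01, seed=2)
        counts = sample_pool_counts(self._pool(2), one_variant, cfg)
        observed = counts.alt_count[0] / counts.depth[0]
        assert 0.985 < observed < 0.995  # ~1 - e


class TestRandomGeneModels:
    def test_gene_bodies_are_valid_coding_models(self):
        g = random_genome({"c1": 200_000}, seed=3)
        g2, models = random_gene_models(g, n_genes_per_chrom=5, seed=4)
        from nodmap.effects import translate_cds
        from nodmap.genome import extract_cds

        assert len(models) == 5
        for m in models:
            cds = extract_cds(g2, m)
            protein = translate_cds(cds)
            assert protein.startswith("M")
            assert protein.endswith("*")
            assert "*" not in protein[:-1]
            for start, end in m.introns():
                intron = g2.slice(m.chromosome, start, end)
                if m.strand == "-":
                    from nodmap.genome import reverse_complement

                    intron = reverse_complement(intron)
                assert intron.startswith("GT") and intron.endswith("AG")
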