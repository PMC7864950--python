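"""Composed simulation scenarios.

`run_mapping_scenario` realizes the full mapping-by-sequencing stated world:
a 10-Mb two-chromosome toy genome with plant-like gene models, genome-wide
EMS SNPs at 5/Mb, one recessive causal splice-donor mutation plus a handful
of tightly linked EMS SNPs (the mutant-haplotype fingerprint around the
lesion), a 1000-plant selfed backcross F2, a 110-plant homozygous-mutant
pool, and Poisson(50) pooled read counts.

`simulate_capture_cohort` emulates the targeted-capture stage: mutants drawn
from screening bulks, some of them siblings sharing an M1 parent's EMS
fingerprint, each explained by a candidate lesion in a panel gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import EmsVariant, GeneModel, GenomicInterval, ReferenceGenome
from .simulate import (
    CrossConfig,
    EmsConfig,
    SequencingConfig,
    add_linked_variants,
    draw_ems_mutations,
    place_causal_variant,
    random_gene_models,
    random_genome,
    sample_pool_counts,
    select_mutant_pool,
    simulate_f2_plants,
)

__all__ = ["MappingScenario", "run_mapping_scenario", "simulate_capture_cohort"]


def _subseeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31 derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


@dataclass
class MappingScenario:
    genome: ReferenceGenome
    gene_models: list[GeneModel]
    causal_gene: GeneModel
    variants: list[EmsVariant]
    causal: EmsVariant
    plants: np.ndarray
    pool: np.ndarray
    counts: pd.DataFrame
    cross_config: CrossConfig = field(repr=False, default=None)


def run_mapping_scenario(
    seed: int,
    chrom_lengths: dict[str, int] | None = None,
    mutation_rate: float = 5.0,
    n_linked: int = 6,
    linked_window_bp: int = 3_000,
    n_plants: int = 1_000,
    pool_size: int = 110,
    mean_depth: float = 50.0,
    error_rate: float = 0.0,
    causal_site_class: str = "splice_donor",
) -> MappingScenario:
    """Simulate the full design and return every intermediate object.

    Defaults are the stated world of the mapping stage: 10 Mb over two
    chromosomes, 5 EMS SNPs/Mb, >= 5 extra EMS SNPs within 2 cM of the
    causal site (here 6 within ±3 kb ≈ ±0.06 cM), 1000 F2 plants, a
    110-plant Nod- pool, depth 50, error 0.
    """
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 5_000_000, "chr2": 5_000_000}
    s_genome, s_genes, s_ems, s_link, s_cross, s_sel, s_seq = _subseeds(seed, 7)

    genome = random_genome(chrom_lengths, seed=s_genome)
    genome, models = random_gene_models(genome, n_genes_per_chrom=10, seed=s_genes)

    # causal gene: a multi-exon model near the middle of the first chromosome
    first_chrom = genome.names[0]
    chrom_models = [m for m in models if m.chromosome == first_chrom]
    causal_gene = min(
        chrom_models, key=lambda m: abs(m.start - chrom_lengths[first_chrom] // 2)
    )
    causal = place_causal_variant(genome, causal_gene, causal_site_class)

    background = draw_ems_mutations(genome, EmsConfig(mutation_rate, 1.0, s_ems))
    background = [
        v for v in background
        if (v.chromosome, v.position) != (causal.chromosome, causal.position)
    ]
    linked = add_linked_variants(
        genome,
        causal,
        n=n_linked,
        max_dist_bp=linked_window_bp,
        seed=s_link,
        exclude={(v.chromosome, v.position) for v in background},
    )
    order = {name: i for i, name in enumerate(genome.names)}
    variants = sorted(
        background + linked + [causal],
        key=lambda v: (order[v.chromosome], v.position),
    )

    cross = CrossConfig(pool_size=pool_size, seed=s_cross)
    plants = simulate_f2_plants(variants, genome, cross, n_plants)
    pool = select_mutant_pool(plants, variants, pool_size, rng=s_sel)
    counts = sample_pool_counts(
        pool, variants, SequencingConfig(mean_depth, error_rate, s_seq)
    )
    return MappingScenario(
        genome=genome,
        gene_models=models,
        causal_gene=causal_gene,
        variants=variants,
        causal=causal,
        plants=plants,
        pool=pool,
        counts=counts,
        cross_config=cross,
    )


def simulate_capture_cohort(
    seed: int,
    panel_genes: list[GeneModel],
    genome: ReferenceGenome,
    n_independent: int = 8,
    sibling_group_sizes: tuple[int, ...] = (2, 3),
    fingerprint_size: int = 12,
    retention: float = 0.75,
    n_bulks: int = 4,
    series_plan: tuple[int, ...] = (3, 3, 2, 1, 1),
) -> tuple[dict[str, list[EmsVariant]], dict[str, str], dict[str, EmsVariant]]:
    """Synthetic targeted-capture calls for a mutant cohort.

    Each M1 founder receives a private fingerprint of EMS SNPs inside panel
    genes plus one candidate lesion (a G/C CDS or splice site in a panel
    gene). Independent mutants are single descendants of distinct founders;
    sibling groups are multiple descendants of one founder, each retaining
    every founder SNP independently with probability 3/4 (a selfed
    heterozygous M1 transmits at least one copy to an M2 line w.p. 3/4),
    which puts expected sibling Jaccard near (9/16)/(15/16) ≈ 0.6.

    ``series_plan`` states how founder lesions distribute over phenotype
    genes — (3, 3, 2, 1, 1) means five distinct genes carry 3, 3, 2, 1 and 1
    independent alleles, emulating an allelic mutant series; its sum must
    equal the number of founders (independents + sibling groups).

    Returns (calls per mutant, bulk assignment, true causal lesion per
    mutant).
    """
    from .effects import annotate_variant

    rng = np.random.default_rng(seed)

    # EMS-mutable sites (G/C) anywhere in a panel gene's span: fingerprints
    # scatter over exons and introns alike, so most are benign
    span_sites: dict[str, list[EmsVariant]] = {}
    severe_sites: dict[str, list[EmsVariant]] = {}
    for m in panel_genes:
        sites = []
        for pos in range(m.start, m.end + 1):
            ref = genome.base(m.chromosome, pos)
            if ref in "GC":
                sites.append(
                    EmsVariant(m.chromosome, pos, ref, "A" if ref == "G" else "T")
                )
        span_sites[m.gene_id] = sites
        severe_sites[m.gene_id] = [
            v for v in sites
            if annotate_variant(v, [m], genome)[0].effect_class
            in ("splice_site", "missense", "nonsense", "start_loss")
        ]

    all_sites = [v for sites in span_sites.values() for v in sites]
    genes = [m.gene_id for m in panel_genes if severe_sites[m.gene_id]]

    calls: dict[str, list[EmsVariant]] = {}
    bulks: dict[str, str] = {}
    truth: dict[str, EmsVariant] = {}
    used: set[EmsVariant] = set()

    def founder_fingerprint() -> list[EmsVariant]:
        free = [v for v in all_sites if v not in used]
        picks = rng.choice(len(free), size=fingerprint_size, replace=False)
        chosen = [free[i] for i in picks]
        used.update(chosen)
        return chosen

    def causal_for(gene_id: str) -> EmsVariant:
        # a phenotype-causing lesion: splice/missense/nonsense, never silent
        free = [v for v in severe_sites[gene_id] if v not in used]
        v = free[rng.integers(len(free))]
        used.add(v)
        return v

    founder_specs = [1] * n_independent + list(sibling_group_sizes)
    if sum(series_plan) != len(founder_specs):
        raise ValueError("series_plan must sum to the number of founders")
    if len(series_plan) > len(genes):
        raise ValueError("panel has too few severe-mutable genes for the plan")
    plan_gene_ids = [
        genes[i] for i in rng.choice(len(genes), size=len(series_plan),
                                     replace=False)
    ]
    lesion_gene_per_founder = [
        g for g, k in zip(plan_gene_ids, series_plan) for _ in range(k)
    ]
    rng.shuffle(lesion_gene_per_founder)

    mutant_counter = 0
    for fi, n_desc in enumerate(founder_specs):
        fingerprint = founder_fingerprint()
        lesion = causal_for(lesion_gene_per_founder[fi])
        bulk = f"bulk{1 + int(rng.integers(n_bulks)):02d}"
        for _ in range(n_desc):
            mutant_counter += 1
            mid = f"M{mutant_counter:03d}"
            retained = [v for v in fingerprint if rng.random() < retention]
            calls[mid] = sorted(
                retained + [lesion], key=lambda v: (v.chromosome, v.position)
            )
            bulks[mid] = bulk
            truth[mid] = lesion
    return calls, bulks, truth
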