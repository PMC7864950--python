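"""Forward simulation of an EMS mutant line, its backcross F2, and pooled
sequencing of phenotype-selected plants.

The model follows the classical mapping-by-sequencing design: a mutagenized
line carries genome-wide G:C→A:T transition SNPs plus one recessive causal
mutation; it is crossed to wild type, the F1 is selfed, and non-nodulating
F2 plants (homozygous mutant at the causal locus) are pooled and sequenced.
At a site a recombination fraction r away from the causal locus, each of a
selected plant's two gametes carries the mutant allele with probability
1 − r, so the expected pool allele frequency is 1 − r (1/2 when unlinked).

Meiosis uses the Haldane model (no interference). Crossovers form a Poisson
process along the genetic map, which makes the gamete haplotype a two-state
Markov chain over ordered loci with flip probability r(d) = (1 − e^(−2d/100))/2
per inter-locus interval of d cM; that equivalent chain is what is sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import EmsVariant, GeneModel, ReferenceGenome, reverse_complement

__all__ = [
    "EmsConfig",
    "CrossConfig",
    "SequencingConfig",
    "haldane_r",
    "draw_ems_mutations",
    "place_causal_variant",
    "add_linked_variants",
    "simulate_f2_plants",
    "select_mutant_pool",
    "sample_pool_counts",
    "random_genome",
    "random_gene_models",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_counts_vcf",
    "read_counts_vcf",
]


@dataclass
class EmsConfig:
    """Mutagenesis parameters.

    mutation_rate is the expected density in mutations per Mb; the real dose
    (0.30% EMS overnight) maps to an unknown per-bp density, so this is an
    explicit knob. spectrum_fraction is the fraction of induced SNPs that
    are canonical G:C→A:T transitions (EMS is near-exclusively this class).
    """

    mutation_rate: float = 5.0
    spectrum_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        if not 0 <= self.spectrum_fraction <= 1:
            raise ValueError("spectrum_fraction must be in [0, 1]")


@dataclass
class CrossConfig:
    """Backcross/selfing design.

    chromosome_genetic_lengths maps chromosome name to its genetic length in
    cM (default 100 cM each); physical positions scale linearly onto the
    map. pool_size defaults to 110, the midpoint of the 100-120 plants
    pooled per mutant in the mapping design.
    """

    chromosome_genetic_lengths: dict[str, float] = field(default_factory=dict)
    default_cm: float = 100.0
    map_function: str = "haldane"
    pool_size: int = 110
    seed: int = 0

    def __post_init__(self) -> None:
        if self.map_function != "haldane":
            raise ValueError("only the Haldane map function is supported")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.default_cm <= 0 or any(
            v <= 0 for v in self.chromosome_genetic_lengths.values()
        ):
            raise ValueError("genetic lengths must be > 0")

    def cm_for(self, chromosome: str) -> float:
        return self.chromosome_genetic_lengths.get(chromosome, self.default_cm)


@dataclass
class SequencingConfig:
    """Pooled short-read sampling at variant sites.

    Depth per site is Poisson(mean_depth); each read is drawn from a
    uniformly chosen chromosome copy of the pool; a sequencing error
    substitutes the read base with one of the three others uniformly.
    """

    mean_depth: float = 50.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SequencingConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def haldane_r(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a genetic distance in cM (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm) / 100.0))


# ---------------------------------------------------------------------------
# Mutagenesis


def draw_ems_mutations(
    genome: ReferenceGenome, config: EmsConfig
) -> list[EmsVariant]:
    """Scatter EMS-induced SNPs over the genome.

    The count is Poisson with mean mutation_rate × genome size in Mb.
    Spectrum-class mutations are G→A or C→T at G/C sites; off-spectrum
    mutations get a uniformly chosen non-reference base at any A/C/G/T site.
    Positions are unique; the list is sorted by (chromosome order, position).
    """
    rng = np.random.default_rng(config.seed)
    n_total = rng.poisson(config.mutation_rate * genome.total_bp() / 1e6)
    n_ems = rng.binomial(n_total, config.spectrum_fraction)

    variants: list[EmsVariant] = []
    taken: set[tuple[str, int]] = set()

    # per-chromosome candidate positions, weighted by chromosome length
    chrom_arrays = {
        name: np.frombuffer(seq.encode(), dtype=np.uint8)
        for name, seq in genome.chromosomes
    }
    gc_positions = {
        name: np.flatnonzero((arr == ord("G")) | (arr == ord("C"))) + 1
        for name, arr in chrom_arrays.items()
    }
    if n_ems > 0 and all(len(p) == 0 for p in gc_positions.values()):
        raise ValueError("genome has no G/C bases to mutate")

    names = genome.names
    lengths = np.array([genome.length(n) for n in names], dtype=float)
    probs = lengths / lengths.sum()

    def draw_one(spectrum: bool) -> EmsVariant | None:
        chrom = names[rng.choice(len(names), p=probs)]
        if spectrum:
            pool = gc_positions[chrom]
            if len(pool) == 0:
                return None
            pos = int(pool[rng.integers(len(pool))])
        else:
            pos = int(rng.integers(1, genome.length(chrom) + 1))
        if (chrom, pos) in taken:
            return None
        ref = genome.base(chrom, pos)
        if ref == "N":
            return None
        if spectrum:
            alt = "A" if ref == "G" else "T"
        else:
            alt = rng.choice([b for b in "ACGT" if b != ref])
        return EmsVariant(chrom, pos, ref, str(alt))

    for spectrum, n in ((True, n_ems), (False, n_total - n_ems)):
        placed = 0
        attempts = 0
        while placed < n and attempts < 50 * max(n, 1):
            attempts += 1
            v = draw_one(spectrum)
            if v is None:
                continue
            taken.add((v.chromosome, v.position))
            variants.append(v)
            placed += 1

    order = {name: i for i, name in enumerate(names)}
    variants.sort(key=lambda v: (order[v.chromosome], v.position))
    return variants


def place_causal_variant(
    genome: ReferenceGenome,
    gene_model: GeneModel,
    site_class: str = "splice_donor",
) -> EmsVariant:
    """Put the recessive causal G:C→A:T SNP at a functional site of a gene.

    splice_donor: the first intron base in transcription order (the G of the
    canonical GT donor; on '-' strand genes the genomic base is the C of the
    AC complement). missense: the first CDS position where a G→A or C→T
    substitution changes the encoded amino acid without creating a stop.
    """
    from .effects import _cds_coordinate_map, translate_cds  # local: avoid cycle

    if site_class == "splice_donor":
        introns = gene_model.introns()
        if not introns:
            raise ValueError("splice_donor requires a gene with >= 2 exons")
        for intron in introns if gene_model.strand == "+" else introns[::-1]:
            pos = intron[0] if gene_model.strand == "+" else intron[1]
            ref = genome.base(gene_model.chromosome, pos)
            if ref == "G":
                return EmsVariant(gene_model.chromosome, pos, "G", "A", causal=True)
            if ref == "C":
                return EmsVariant(gene_model.chromosome, pos, "C", "T", causal=True)
        raise ValueError("no G/C at any intron donor position of this gene")

    if site_class == "missense":
        from .genome import extract_cds

        cds = extract_cds(genome, gene_model)
        protein = translate_cds(cds)
        for cds_idx, (chrom, pos) in enumerate(_cds_coordinate_map(gene_model)):
            ref = genome.base(chrom, pos)
            if ref not in "GC":
                continue
            alt = "A" if ref == "G" else "T"
            # coding-strand base change at this CDS index
            if gene_model.strand == "+":
                coding_alt = alt
            else:
                coding_alt = {"A": "T", "T": "A"}[alt]
            mutant = cds[:cds_idx] + coding_alt + cds[cds_idx + 1 :]
            aa_idx = cds_idx // 3
            if aa_idx == 0:  # start-codon hits are start_loss, not missense
                continue
            new_aa = translate_cds(mutant[3 * aa_idx : 3 * aa_idx + 3])
            if new_aa != protein[aa_idx] and new_aa != "*":
                return EmsVariant(chrom, pos, ref, alt, causal=True)
        raise ValueError("no missense-eligible G/C site in the CDS")

    raise ValueError(f"unknown site_class {site_class!r}")


def add_linked_variants(
    genome: ReferenceGenome,
    causal: EmsVariant,
    n: int,
    max_dist_bp: int,
    seed: int = 0,
    exclude: set[tuple[str, int]] | None = None,
) -> list[EmsVariant]:
    """Inject n EMS-type SNPs at G/C sites within ±max_dist_bp of the causal
    site, emulating the dense mutant-haplotype fingerprint around the lesion.
    """
    rng = np.random.default_rng(seed)
    chrom = causal.chromosome
    lo = max(1, causal.position - max_dist_bp)
    hi = min(genome.length(chrom), causal.position + max_dist_bp)
    window = genome.slice(chrom, lo, hi)
    arr = np.frombuffer(window.encode(), dtype=np.uint8)
    candidates = np.flatnonzero((arr == ord("G")) | (arr == ord("C"))) + lo
    taken = set(exclude or set())
    taken.add((chrom, causal.position))
    candidates = [p for p in candidates if (chrom, int(p)) not in taken]
    if len(candidates) < n:
        raise ValueError("not enough G/C sites in the linked window")
    picks = rng.choice(len(candidates), size=n, replace=False)
    out = []
    for i in sorted(picks):
        pos = int(candidates[i])
        ref = genome.base(chrom, pos)
        out.append(EmsVariant(chrom, pos, ref, "A" if ref == "G" else "T"))
    return out


# ---------------------------------------------------------------------------
# Cross simulation


def _genetic_positions(
    variants: list[EmsVariant], genome: ReferenceGenome, config: CrossConfig
) -> np.ndarray:
    """cM position of each variant: physical position scaled to the
    chromosome's genetic length (no recombination map is available)."""
    out = np.empty(len(variants))
    for i, v in enumerate(variants):
        out[i] = v.position / genome.length(v.chromosome) * config.cm_for(v.chromosome)
    return out


def _sample_gametes(
    variants: list[EmsVariant],
    genome: ReferenceGenome,
    config: CrossConfig,
    n_gametes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """F1 gametes as an (n_gametes, n_variants) 0/1 array (1 = mutant allele).

    Haldane model per chromosome: the first locus is 0/1 with probability
    1/2; consecutive loci flip with the Haldane recombination fraction of
    their cM separation (exact Markov form of Poisson crossovers).
    """
    m = len(variants)
    gametes = np.empty((n_gametes, m), dtype=np.int8)
    gpos = _genetic_positions(variants, genome, config)
    chroms = np.array([v.chromosome for v in variants])
    for chrom in dict.fromkeys(chroms):  # preserve order
        idx = np.flatnonzero(chroms == chrom)
        order = idx[np.argsort(gpos[idx], kind="stable")]
        d = np.diff(gpos[order])
        r_adj = haldane_r(d)
        start = rng.integers(0, 2, size=n_gametes)
        flips = rng.random((n_gametes, len(d))) < r_adj[None, :]
        parity = np.concatenate(
            [np.zeros((n_gametes, 1), dtype=np.int8),
             np.cumsum(flips, axis=1, dtype=np.int64) % 2],
            axis=1,
        )
        hap = (start[:, None] + parity) % 2
        gametes[:, order] = hap.astype(np.int8)
    return gametes


def simulate_f2_plants(
    variants: list[EmsVariant],
    genome: ReferenceGenome,
    config: CrossConfig,
    n_plants: int,
) -> np.ndarray:
    """Selfed-F1 (backcross F2) genotypes, (n_plants, n_variants) in {0,1,2}
    copies of the mutant allele; each plant is two independent F1 gametes.
    """
    rng = np.random.default_rng(config.seed)
    g1 = _sample_gametes(variants, genome, config, n_plants, rng)
    g2 = _sample_gametes(variants, genome, config, n_plants, rng)
    return (g1 + g2).astype(np.int8)


def select_mutant_pool(
    plants: np.ndarray,
    variants: list[EmsVariant],
    pool_size: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Phenotype selection: keep pool_size plants homozygous mutant at the
    causal locus (the recessive Nod- class, ~1/4 of the F2 in expectation).
    """
    causal_idx = [i for i, v in enumerate(variants) if v.causal]
    if len(causal_idx) != 1:
        raise ValueError("exactly one causal variant required")
    eligible = np.flatnonzero(plants[:, causal_idx[0]] == 2)
    if len(eligible) < pool_size:
        raise ValueError(
            f"only {len(eligible)} homozygous-mutant plants; need {pool_size} "
            "(simulate a larger F2)"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    chosen = rng.choice(eligible, size=pool_size, replace=False)
    return plants[np.sort(chosen)]


def sample_pool_counts(
    pool: np.ndarray,
    variants: list[EmsVariant],
    config: SequencingConfig,
) -> pd.DataFrame:
    """Pooled sequencing at variant sites.

    Per site: depth ~ Poisson(mean_depth); each read samples a uniformly
    chosen pool chromosome copy, so the alt-read count is Binomial(depth, p)
    with p = f(1−e) + (1−f)e/3 for pool alt frequency f and error rate e
    (an error substitutes one of the three other bases uniformly).
    """
    if pool.shape[0] == 0:
        raise ValueError("empty pool")
    rng = np.random.default_rng(config.seed)
    f = pool.sum(axis=0) / (2.0 * pool.shape[0])
    e = config.error_rate
    p = f * (1.0 - e) + (1.0 - f) * e / 3.0
    depth = rng.poisson(config.mean_depth, size=len(variants))
    alt = rng.binomial(depth, p)
    return pd.DataFrame(
        {
            "chrom": [v.chromosome for v in variants],
            "pos": [v.position for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
            "causal": [v.causal for v in variants],
            "alt_count": alt,
            "depth": depth,
        }
    )


# ---------------------------------------------------------------------------
# Toy genome / gene-model fixtures


def random_genome(
    chrom_lengths: dict[str, int], seed: int = 0, gc: float = 0.36
) -> ReferenceGenome:
    """Random DNA with a plant-like GC content (~36%)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    chroms = []
    for name, length in chrom_lengths.items():
        seq = rng.choice(bases, size=length, p=p).tobytes().decode()
        chroms.append((name, seq))
    return ReferenceGenome(chroms)


_STOPLESS_CODONS = [
    "GCT", "GCC", "GGA", "GGT", "TGT", "GAT", "GAA", "TTT", "GGC", "CAT",
    "ATT", "AAA", "CTT", "ATG", "AAT", "CCT", "CAA", "CGT", "TCT", "ACT",
    "GTT", "TGG", "TAC",
]


def _gene_sequence(
    rng: np.random.Generator, n_exons: int, exon_codons: int, intron_len: int
) -> tuple[str, list[tuple[int, int]]]:
    """A coding gene sequence: ATG .. exons of in-frame codons .. stop, with
    canonical GT..AG introns between exons. Returns (sequence, exon offsets
    relative to gene start, 0-based inclusive)."""
    exon_seqs = []
    for i in range(n_exons):
        codons = [
            _STOPLESS_CODONS[rng.integers(len(_STOPLESS_CODONS))]
            for _ in range(exon_codons)
        ]
        if i == 0:
            codons[0] = "ATG"
        if i == n_exons - 1:
            codons[-1] = "TAA"
        exon_seqs.append("".join(codons))
    parts = []
    exons = []
    offset = 0
    for i, ex in enumerate(exon_seqs):
        parts.append(ex)
        exons.append((offset, offset + len(ex) - 1))
        offset += len(ex)
        if i < n_exons - 1:
            middle = "".join(
                "ACGT"[rng.integers(4)] for _ in range(intron_len - 4)
            )
            intron = "GT" + middle + "AG"
            parts.append(intron)
            offset += len(intron)
    return "".join(parts), exons


def random_gene_models(
    genome: ReferenceGenome,
    n_genes_per_chrom: int = 10,
    seed: int = 0,
    n_exons: int = 3,
    exon_codons: int = 40,
    intron_len: int = 80,
) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Plant toy gene models spliced into the genome sequence.

    Gene bodies (ATG..TAA with canonical GT/AG introns) overwrite the random
    background at evenly spaced loci; roughly half the genes are placed on
    the '-' strand (the genomic sequence then carries the reverse
    complement). Returns the modified genome and the models.
    """
    rng = np.random.default_rng(seed)
    new_chroms = []
    models = []
    for ci, (name, seq) in enumerate(genome.chromosomes):
        seq_list = list(seq)
        for gi in range(n_genes_per_chrom):
            body, exon_offsets = _gene_sequence(rng, n_exons, exon_codons, intron_len)
            strand = "+" if rng.random() < 0.5 else "-"
            slot = len(seq) // (n_genes_per_chrom + 1)
            start = (gi + 1) * slot - len(body) // 2  # 1-based gene start
            genomic = body if strand == "+" else reverse_complement(body)
            seq_list[start - 1 : start - 1 + len(body)] = genomic
            if strand == "+":
                exons = [(start + s, start + e) for s, e in exon_offsets]
            else:
                gene_end = start + len(body) - 1
                exons = sorted(
                    (gene_end - e, gene_end - s) for s, e in exon_offsets
                )
            models.append(
                GeneModel(
                    gene_id=f"gene{ci + 1:02d}.{gi + 1:02d}",
                    chromosome=name,
                    strand=strand,
                    exons=exons,
                    cds=list(exons),
                )
            )
        new_chroms.append((name, "".join(seq_list)))
    return ReferenceGenome(new_chroms), models


# ---------------------------------------------------------------------------
# Counts I/O


_TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "causal", "alt_count", "depth"]


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False, columns=_TSV_COLUMNS)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts TSV missing columns: {sorted(missing)}")
    return df[_TSV_COLUMNS]


def write_counts_vcf(counts: pd.DataFrame, path: str | Path,
                     genome: ReferenceGenome | None = None) -> None:
    """Minimal VCF 4.2 with INFO DP (site depth) and AD (alt read count)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt read count">\n')
        fh.write('##INFO=<ID=CAUSAL,Number=0,Type=Flag,Description="Simulated causal site">\n')
        if genome is not None:
            for name in genome.names:
                fh.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in counts.itertuples(index=False):
            info = f"DP={row.depth};AD={row.alt_count}"
            if getattr(row, "causal", False):
                info += ";CAUSAL"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t{info}\n"
            )


def read_counts_vcf(path: str | Path) -> pd.DataFrame:
    """Read per-site counts from a VCF.

    Accepts the pipeline's own INFO DP/AD encoding, or a standard
    single-sample VCF with a FORMAT AD field (ref,alt depths), as produced
    by common pooled callers.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            info = dict(rec.info)
            if "AD" in info and "DP" in info:
                alt_count = int(info["AD"])
                depth = int(info["DP"])
            elif rec.samples and "AD" in rec.format:
                ad = rec.samples[0]["AD"]
                alt_count = int(ad[1])
                depth = int(sum(x for x in ad if x is not None))
            else:
                continue
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "causal": bool(info.get("CAUSAL", False)),
                    "alt_count": alt_count,
                    "depth": depth,
                }
            )
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)
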