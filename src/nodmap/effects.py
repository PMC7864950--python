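"""Gene-model-aware annotation of candidate EMS SNPs.

Effect classes, most to least severe: splice_site / nonsense / start_loss,
then missense, synonymous, intronic, intergenic. CDS effects are computed on
the assembled coding sequence (strand-aware base substitution followed by
retranslation), never on genomic triplets, so codons spanning exon junctions
are handled correctly. Protein changes use p.-style notation numbered from
the start codon (e.g. "G354E"); nucleotide changes are CDS-relative
("c.1062G>A").
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .genome import EmsVariant, GeneModel, GenomicInterval, ReferenceGenome

__all__ = [
    "VariantEffect",
    "SEVERITY",
    "translate_cds",
    "classify_splice_site",
    "annotate_variant",
    "rank_candidates",
]

SEVERITY: dict[str, int] = {
    "splice_site": 5,
    "nonsense": 5,
    "start_loss": 5,
    "missense": 4,
    "synonymous": 3,
    "intronic": 2,
    "intergenic": 1,
}

_PROTEIN_CLASSES = {"missense", "nonsense", "start_loss", "synonymous"}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class VariantEffect:
    variant: EmsVariant
    gene_id: str | None
    effect_class: str
    protein_change: str | None = None
    cds_change: str | None = None
    snp_index: float | None = None

    severity_rank: int = field(init=False)

    def __post_init__(self) -> None:
        if self.effect_class not in SEVERITY:
            raise ValueError(f"unknown effect class {self.effect_class!r}")
        has_protein = self.protein_change is not None
        if has_protein != (self.effect_class in _PROTEIN_CLASSES):
            raise ValueError(
                f"protein_change must be present iff effect is one of "
                f"{sorted(_PROTEIN_CLASSES)} (got {self.effect_class})"
            )
        self.severity_rank = SEVERITY[self.effect_class]


def translate_cds(cds: str, to_first_stop: bool = False) -> str:
    """Standard-genetic-code translation; stop codons render as '*'.

    With to_first_stop the translation is truncated at the first stop
    (exclusive); otherwise all codons are translated.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    bad = set(cds) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous bases in CDS: {sorted(bad)}")
    protein = str(Seq(cds).translate())
    if to_first_stop and "*" in protein:
        protein = protein[: protein.index("*")]
    return protein


def _cds_coordinate_map(model: GeneModel) -> list[tuple[str, int]]:
    """Genomic (chrom, pos) of each CDS base in transcription (5'→3') order."""
    coords = [
        (model.chromosome, p)
        for s, e in model.cds
        for p in range(s, e + 1)
    ]
    return coords if model.strand == "+" else coords[::-1]


def classify_splice_site(
    variant: EmsVariant, model: GeneModel, width: int = 2
) -> bool:
    """True iff the variant falls within the first or last `width` bases of
    any intron (the canonical GT donor / AG acceptor dinucleotides at
    width 2). Single-exon genes have no introns and always return False."""
    if variant.chromosome != model.chromosome:
        return False
    for start, end in model.introns():
        if start <= variant.position <= min(end, start + width - 1):
            return True
        if max(start, end - width + 1) <= variant.position <= end:
            return True
    return False


def _in_intervals(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def _annotate_in_gene(
    variant: EmsVariant,
    model: GeneModel,
    genome: ReferenceGenome,
    splice_width: int,
) -> VariantEffect:
    if classify_splice_site(variant, model, width=splice_width):
        return VariantEffect(variant, model.gene_id, "splice_site")

    if model.coding and _in_intervals(variant.position, model.cds):
        coords = _cds_coordinate_map(model)
        cds_idx = coords.index((variant.chromosome, variant.position))
        from .genome import extract_cds

        cds = extract_cds(genome, model)
        if model.strand == "+":
            coding_ref, coding_alt = variant.ref, variant.alt
        else:
            coding_ref = _COMPLEMENT[variant.ref]
            coding_alt = _COMPLEMENT[variant.alt]
        if cds[cds_idx] != coding_ref:
            raise ValueError(
                f"{model.gene_id}: CDS base at c.{cds_idx + 1} is "
                f"{cds[cds_idx]}, variant ref implies {coding_ref}"
            )
        mutant = cds[:cds_idx] + coding_alt + cds[cds_idx + 1 :]
        aa_idx = cds_idx // 3
        ref_aa = translate_cds(cds[3 * aa_idx : 3 * aa_idx + 3])
        alt_aa = translate_cds(mutant[3 * aa_idx : 3 * aa_idx + 3])
        cds_change = f"c.{cds_idx + 1}{coding_ref}>{coding_alt}"
        protein_change = f"{ref_aa}{aa_idx + 1}{alt_aa}"
        if alt_aa == ref_aa:
            klass = "synonymous"
        elif aa_idx == 0 and ref_aa == "M":
            klass = "start_loss"
        elif alt_aa == "*":
            klass = "nonsense"
        else:
            klass = "missense"
        return VariantEffect(
            variant, model.gene_id, klass,
            protein_change=protein_change, cds_change=cds_change,
        )

    # inside the gene span but not CDS or a canonical splice base:
    # introns and any non-coding exon sequence both classify as intronic
    return VariantEffect(variant, model.gene_id, "intronic")


def annotate_variant(
    variant: EmsVariant,
    gene_models: list[GeneModel],
    genome: ReferenceGenome,
    splice_width: int = 2,
) -> list[VariantEffect]:
    """Annotate one variant against every overlapping gene model.

    Returns one VariantEffect per overlapping gene, most severe first (ties
    broken by gene_id); a single intergenic record when no gene overlaps.
    Precedence within a gene: splice_site > CDS effects > intronic.
    """
    variant.validate_against(genome)
    effects = [
        _annotate_in_gene(variant, m, genome, splice_width)
        for m in gene_models
        if m.chromosome == variant.chromosome and m.start <= variant.position <= m.end
    ]
    if not effects:
        return [VariantEffect(variant, None, "intergenic")]
    effects.sort(key=lambda e: (-e.severity_rank, e.gene_id))
    return effects


def rank_candidates(
    effects: list[VariantEffect],
    region: GenomicInterval | None = None,
    index_by_site: dict[tuple[str, int], float] | None = None,
) -> list[VariantEffect]:
    """Order candidate effects for causal-mutation triage.

    Keeps EMS-type variants (G→A / C→T) only, optionally restricted to the
    mapped candidate region; sorts by severity rank, then SNP index
    (descending; looked up from index_by_site when given), then position.
    """
    kept = []
    for e in effects:
        v = e.variant
        if not v.is_ems_type():
            continue
        if region is not None and not region.contains(v.chromosome, v.position):
            continue
        if index_by_site is not None:
            e.snp_index = index_by_site.get((v.chromosome, v.position), e.snp_index)
        kept.append(e)
    kept.sort(
        key=lambda e: (
            -e.severity_rank,
            -(e.snp_index if e.snp_index is not None else 0.0),
            e.variant.chromosome,
            e.variant.position,
        )
    )
    return kept


def effects_to_frame(effects: list[VariantEffect]):
    """Tabular view (TSV-ready) of a list of effects."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chrom": e.variant.chromosome,
                "pos": e.variant.position,
                "ref": e.variant.ref,
                "alt": e.variant.alt,
                "gene": e.gene_id or ".",
                "effect": e.effect_class,
                "protein_change": e.protein_change or ".",
                "cds_change": e.cds_change or ".",
                "snp_index": e.snp_index,
            }
            for e in effects
        ],
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "effect",
            "protein_change", "cds_change", "snp_index",
        ],
    )
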