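"""Genomes, gene models and EMS variants, plus FASTA/GFF3 I/O.

Coordinates are 1-based inclusive everywhere (the GFF3/VCF convention);
conversion to Python's 0-based half-open slices happens only inside the
functions of this module.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")

__all__ = [
    "ReferenceGenome",
    "GeneModel",
    "EmsVariant",
    "GenomicInterval",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "extract_cds",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class ReferenceGenome:
    """An ordered collection of named chromosome sequences.

    Sequences are upper-case DNA over {A, C, G, T, N}; all genomic
    coordinates in the pipeline refer to these sequences, 1-based inclusive.
    """

    chromosomes: list[tuple[str, str]]
    _index: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, seq in self.chromosomes:
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            bad = set(seq.upper()) - _IUPAC_DNA
            if bad:
                raise ValueError(f"non-IUPAC characters in {name!r}: {sorted(bad)}")
        self.chromosomes = [(n, s.upper()) for n, s in self.chromosomes]
        self._index = dict(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def sequence(self, chromosome: str) -> str:
        return self._index[chromosome]

    def length(self, chromosome: str) -> int:
        return len(self._index[chromosome])

    def base(self, chromosome: str, position: int) -> str:
        """Base at a 1-based position."""
        seq = self._index[chromosome]
        if not 1 <= position <= len(seq):
            raise IndexError(f"{chromosome}:{position} outside chromosome")
        return seq[position - 1]

    def slice(self, chromosome: str, start: int, end: int) -> str:
        """Subsequence for a 1-based inclusive interval."""
        seq = self._index[chromosome]
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(f"{chromosome}:{start}-{end} outside chromosome")
        return seq[start - 1 : end]

    def total_bp(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)


@dataclass(frozen=True)
class GenomicInterval:
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, chromosome: str, position: int) -> bool:
        return chromosome == self.chromosome and self.start <= position <= self.end


@dataclass
class GeneModel:
    """One mRNA's exon/CDS structure.

    Exons and CDS intervals are stored sorted by start in genomic
    (ascending) coordinates regardless of strand; ``strand`` records
    transcription direction. ``coding`` is False when the summed CDS length
    is not a multiple of 3 (the model is kept but flagged).
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        for cs, ce in self.cds:
            if cs > ce:
                raise ValueError(f"{self.gene_id}: inverted CDS interval")
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(
                    f"{self.gene_id}: CDS {cs}-{ce} not contained in any exon"
                )
        if self.cds_length() % 3 != 0:
            logger.warning(
                "%s: CDS length %d not a multiple of 3; flagged non-coding",
                self.gene_id,
                self.cds_length(),
            )
            self.coding = False

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        ]

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chromosome, self.start, self.end)


@dataclass(frozen=True)
class EmsVariant:
    """A single induced SNP, the atomic object of the pipeline."""

    chromosome: str
    position: int
    ref: str
    alt: str
    causal: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-base substitutions are supported")

    def is_ems_type(self) -> bool:
        """True for the canonical EMS transitions G→A and C→T."""
        return (self.ref, self.alt) in (("G", "A"), ("C", "T"))

    def validate_against(self, genome: ReferenceGenome) -> None:
        base = genome.base(self.chromosome, self.position)
        if base != self.ref:
            raise ValueError(
                f"{self.chromosome}:{self.position} ref mismatch: "
                f"variant says {self.ref}, genome has {base}"
            )
        if base == "N":
            raise ValueError("variants may not sit on N bases")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a multi-record FASTA as a ReferenceGenome (sequences upper-cased)."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceGenome(records)


def write_fasta(genome: ReferenceGenome, path: str | Path) -> None:
    """Write the genome, wrapped at 60 columns, preserving record order."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.chromosomes
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features of a GFF3 file into GeneModels.

    One GeneModel per mRNA, identified by the mRNA's ID (falling back to the
    parent gene's ID). Stored phases are ignored and recomputed downstream;
    features other than gene/mRNA/exon/CDS are skipped with a logged count.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    kept = {"gene", "mRNA", "exon", "CDS"}
    skipped = sum(1 for f in db.all_features() if f.featuretype not in kept)
    if skipped:
        logger.info("read_gff: skipped %d non gene/mRNA/exon/CDS features", skipped)

    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        name = mrna.id or mrna.attributes.get("Parent", ["?"])[0]
        models.append(
            GeneModel(
                gene_id=name,
                chromosome=mrna.seqid,
                strand=mrna.strand,
                exons=sorted(exons),
                cds=sorted(cds),
            )
        )
    return models


def write_gff(models: list[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS rows, one gene wrapper per model."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gene_id = f"{m.gene_id}.gene"
            row = "{}\tnodmap\t{}\t{}\t{}\t.\t{}\t{}\t{}\n"
            fh.write(
                row.format(m.chromosome, "gene", m.start, m.end, m.strand, ".",
                           f"ID={gene_id}")
            )
            fh.write(
                row.format(m.chromosome, "mRNA", m.start, m.end, m.strand, ".",
                           f"ID={m.gene_id};Parent={gene_id}")
            )
            for s, e in m.exons:
                fh.write(
                    row.format(m.chromosome, "exon", s, e, m.strand, ".",
                               f"Parent={m.gene_id}")
                )
            # phases recomputed from a running CDS length, strand-aware
            cds = m.cds if m.strand == "+" else m.cds[::-1]
            acc = 0
            phased = []
            for s, e in cds:
                phased.append((s, e, (3 - acc % 3) % 3))
                acc += e - s + 1
            for s, e, phase in sorted(phased):
                fh.write(
                    row.format(m.chromosome, "CDS", s, e, m.strand, phase,
                               f"Parent={m.gene_id}")
                )


def extract_cds(genome: ReferenceGenome, model: GeneModel) -> str:
    """Concatenate the model's CDS intervals; reverse-complement for '-' strand.

    Returns the coding-strand sequence read 5'→3' (starts with the start
    codon for a complete model).
    """
    parts = [genome.slice(model.chromosome, s, e) for s, e in model.cds]
    seq = "".join(parts)
    if model.strand == "-":
        seq = reverse_complement(seq)
    return seq
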