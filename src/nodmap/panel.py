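"""Targeted-capture cohort analysis: per-mutant EMS fingerprints over a gene
panel, sibling filtering across screening bulks, candidate-mutation triage,
allelic-series grouping, and Mendelian segregation testing.

Sibling mutants descend from the same mutagenized M1 plant and therefore
share a large fraction of their genome-wide EMS SNPs; independent mutants
share essentially none. Grouping profiles by Jaccard similarity of their
variant sets separates the two regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .effects import VariantEffect
from .genome import EmsVariant, GenomicInterval

__all__ = [
    "MutantProfile",
    "SiblingGroup",
    "AllelicSeries",
    "SegregationResult",
    "PHENOTYPE_CLASSES",
    "build_profiles",
    "jaccard",
    "find_siblings",
    "identify_candidates",
    "group_allelic_series",
    "segregation_test",
]

PHENOTYPE_CLASSES = ("Nod-", "Nod-*", "Inf-", "Fix-", "Nod++")

_CANDIDATE_CLASSES = {"splice_site", "nonsense", "start_loss", "missense"}


@dataclass
class MutantProfile:
    """One mutant's EMS SNP fingerprint over the capture panel."""

    mutant_id: str
    bulk_id: str
    snps: frozenset[EmsVariant]
    phenotype_class: str = "Nod-"

    def __post_init__(self) -> None:
        if self.phenotype_class not in PHENOTYPE_CLASSES:
            raise ValueError(f"unknown phenotype class {self.phenotype_class!r}")
        non_ems = [v for v in self.snps if not v.is_ems_type()]
        if non_ems:
            raise ValueError(f"{self.mutant_id}: non-EMS variants in profile")


@dataclass
class SiblingGroup:
    member_ids: tuple[str, ...]
    shared_snps: int
    similarity: float
    cross_bulk: bool = False


@dataclass
class AllelicSeries:
    gene_id: str
    # mutant_id -> its candidate variant in the gene
    members: dict[str, EmsVariant]
    n_alleles: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_alleles = len(set(self.members.values()))


@dataclass
class SegregationResult:
    n_wild: int
    n_mutant: int
    expected_ratio: tuple[float, float]
    chi_square: float
    p_value: float


def build_profiles(
    calls: dict[str, list[EmsVariant]],
    panel: list[GenomicInterval],
    bulks: dict[str, str],
    phenotypes: dict[str, str] | None = None,
) -> list[MutantProfile]:
    """Per-mutant fingerprints: panel-restricted, EMS-type-only variant sets.

    ``calls`` maps mutant_id to its variant calls; duplicates collapse under
    set semantics. A mutant whose calls leave nothing on the panel gets an
    empty profile (with a warning) rather than being dropped.
    """
    import logging

    profiles = []
    for mutant_id, variants in calls.items():
        kept = frozenset(
            v
            for v in variants
            if v.is_ems_type()
            and any(iv.contains(v.chromosome, v.position) for iv in panel)
        )
        if not kept:
            logging.getLogger(__name__).warning(
                "%s: no EMS-type panel variants; empty profile", mutant_id
            )
        profiles.append(
            MutantProfile(
                mutant_id=mutant_id,
                bulk_id=bulks[mutant_id],
                snps=kept,
                phenotype_class=(phenotypes or {}).get(mutant_id, "Nod-"),
            )
        )
    return profiles


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def find_siblings(
    profiles: list[MutantProfile], min_jaccard: float = 0.5
) -> list[SiblingGroup]:
    """Single-linkage groups over pairs with Jaccard >= min_jaccard.

    Siblings share an M1 parent, so transitive sharing is expected and
    single linkage is the natural closure. Groups spanning more than one
    screening bulk are biologically suspicious: they are kept but flagged
    cross_bulk. Only groups of >= 2 mutants are reported.
    """
    import networkx as nx

    if len(profiles) < 2:
        return []
    g = nx.Graph()
    g.add_nodes_from(p.mutant_id for p in profiles)
    by_id = {p.mutant_id: p for p in profiles}
    ids = sorted(by_id)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if jaccard(by_id[a].snps, by_id[b].snps) >= min_jaccard:
                g.add_edge(a, b)
    groups = []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        members = tuple(sorted(comp))
        shared = frozenset.intersection(*(by_id[m].snps for m in members))
        sims = [
            jaccard(by_id[a].snps, by_id[b].snps)
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        ]
        groups.append(
            SiblingGroup(
                member_ids=members,
                shared_snps=len(shared),
                similarity=float(np.mean(sims)),
                cross_bulk=len({by_id[m].bulk_id for m in members}) > 1,
            )
        )
    groups.sort(key=lambda s: s.member_ids)
    return groups


def identify_candidates(
    profile: MutantProfile, annotations: dict[EmsVariant, VariantEffect]
) -> list[VariantEffect]:
    """Severity filter formalizing the manual candidate search: keep
    splice_site / nonsense / start_loss / missense effects in panel genes,
    ordered by severity then genomic position."""
    missing = [v for v in profile.snps if v not in annotations]
    if missing:
        raise ValueError(
            f"{profile.mutant_id}: {len(missing)} profile SNPs lack annotations"
        )
    kept = [
        annotations[v]
        for v in profile.snps
        if annotations[v].effect_class in _CANDIDATE_CLASSES
        and annotations[v].gene_id is not None
    ]
    kept.sort(
        key=lambda e: (-e.severity_rank, e.variant.chromosome, e.variant.position)
    )
    return kept


def group_allelic_series(
    candidates: dict[str, list[VariantEffect]],
    sibling_groups: list[SiblingGroup],
) -> list[AllelicSeries]:
    """Group candidate mutations by gene into allelic series.

    Sibling mutants carry the same M1 lesion, so each sibling group
    contributes once: only its alphabetically first member with a candidate
    in the gene is counted. The allele count of a series is the number of
    distinct candidate variants among counted members. Output is sorted by
    gene_id; invariant to input order of mutants.
    """
    group_of = {}
    for g in sibling_groups:
        for m in g.member_ids:
            group_of[m] = g.member_ids

    per_gene: dict[str, dict[str, EmsVariant]] = {}
    for mutant_id in sorted(candidates):
        for eff in candidates[mutant_id]:
            per_gene.setdefault(eff.gene_id, {})[mutant_id] = eff.variant

    series = []
    for gene_id in sorted(per_gene):
        members = per_gene[gene_id]
        counted: dict[str, EmsVariant] = {}
        seen_groups: set[tuple[str, ...]] = set()
        for mutant_id in sorted(members):
            grp = group_of.get(mutant_id)
            if grp is not None:
                if grp in seen_groups:
                    continue
                seen_groups.add(grp)
            counted[mutant_id] = members[mutant_id]
        series.append(AllelicSeries(gene_id=gene_id, members=counted))
    return series


def segregation_test(
    n_wild: int,
    n_mutant: int,
    ratio: tuple[float, float] = (3.0, 1.0),
    yates: bool = False,
) -> SegregationResult:
    """Pearson chi-square (1 df) of observed wild:mutant counts against an
    expected Mendelian ratio (3:1 for a single recessive gene).

    Yates continuity correction is off by default; enable with yates=True.
    """
    if n_wild < 0 or n_mutant < 0:
        raise ValueError("counts must be >= 0")
    total = n_wild + n_mutant
    if total == 0:
        raise ValueError("zero total plants")
    exp_wild = total * ratio[0] / (ratio[0] + ratio[1])
    exp_mut = total * ratio[1] / (ratio[0] + ratio[1])
    correction = 0.5 if yates else 0.0
    chi2 = sum(
        (max(abs(obs - exp) - correction, 0.0)) ** 2 / exp
        for obs, exp in ((n_wild, exp_wild), (n_mutant, exp_mut))
    )
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationResult(
        n_wild=n_wild,
        n_mutant=n_mutant,
        expected_ratio=ratio,
        chi_square=float(chi2),
        p_value=p,
    )
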