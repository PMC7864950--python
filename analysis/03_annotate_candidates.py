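"""Effect annotation of candidate SNPs in the mapped region.

Reads the reference FASTA, gene models and SNP-index track written by 01/02,
annotates every EMS SNP in the candidate region (splice site, missense,
nonsense, synonymous, intronic, intergenic) and ranks candidates by effect
severity and SNP index — the step that singles out the causal lesion.
"""

import argparse
from pathlib import Path

import pandas as pd

from nodmap.effects import annotate_variant, effects_to_frame, rank_candidates
from nodmap.genome import EmsVariant, GenomicInterval, read_fasta, read_gff


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    genome = read_fasta(args.outdir / "reference.fa")
    models = read_gff(args.outdir / "genes.gff3")
    track = pd.read_csv(args.outdir / "snp_index_track.tsv", sep="\t")
    clusters = pd.read_csv(args.outdir / "linkage_clusters.tsv", sep="\t")
    if clusters.empty:
        raise SystemExit("no clusters: run 02 first / mapping failed")
    top = clusters.iloc[0]
    region = GenomicInterval(
        top.chrom, max(1, int(top.start) - 50_000), int(top.end) + 50_000
    )

    index_by_site = {(r.chrom, r.pos): r.snp_index
                     for r in track.itertuples(index=False)}
    effects = []
    for r in track.itertuples(index=False):
        if region.contains(r.chrom, r.pos):
            v = EmsVariant(r.chrom, int(r.pos), r.ref, r.alt, bool(r.causal))
            effects.extend(annotate_variant(v, models, genome))
    ranked = rank_candidates(effects, region=region, index_by_site=index_by_site)
    effects_to_frame(ranked).to_csv(
        args.outdir / "candidates.tsv", sep="\t", index=False
    )

    print(f"region {region.chromosome}:{region.start}-{region.end}: "
          f"{len(ranked)} EMS candidate effects")
    for e in ranked[:5]:
        label = e.protein_change or e.effect_class
        print(f"  {e.variant.chromosome}:{e.variant.position} "
              f"{e.variant.ref}>{e.variant.alt}  {e.gene_id or 'intergenic'}  "
              f"{e.effect_class}  {label}  index={e.snp_index}")
    if ranked:
        top_candidate = ranked[0]
        print(f"top candidate: {top_candidate.effect_class} in "
              f"{top_candidate.gene_id} "
              f"(truth: causal={top_candidate.variant.causal})")


if __name__ == "__main__":
    main()
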