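"""Simulate the mapping population and write its artefacts.

Builds the full stated world — a 10-Mb two-chromosome toy genome with gene
models, an EMS mutant line (5 SNPs/Mb, one recessive splice-donor causal
mutation plus a linked fingerprint), 1000 backcross-F2 plants, a 110-plant
non-nodulating pool and Poisson(50) zero-error pooled read counts — and
writes reference FASTA, gene-model GFF3, allele counts (TSV + VCF) and a
truth table for downstream steps.
"""

import argparse
from pathlib import Path

import pandas as pd

from nodmap.genome import write_fasta, write_gff
from nodmap.scenario import run_mapping_scenario
from nodmap.simulate import haldane_r, write_counts_tsv, write_counts_vcf


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sc = run_mapping_scenario(seed=args.seed)
    write_fasta(sc.genome, args.outdir / "reference.fa")
    write_gff(sc.gene_models, args.outdir / "genes.gff3")
    write_counts_tsv(sc.counts, args.outdir / "pool_counts.tsv")
    write_counts_vcf(sc.counts, args.outdir / "pool_counts.vcf", sc.genome)

    # per-variant truth: genetic distance and recombination fraction to the
    # causal site (r = 1/2 for the other chromosome)
    rows = []
    for v in sc.variants:
        if v.chromosome == sc.causal.chromosome:
            cm_per_bp = sc.cross_config.cm_for(v.chromosome) / sc.genome.length(
                v.chromosome
            )
            d = abs(v.position - sc.causal.position) * cm_per_bp
            r = float(haldane_r(d))
        else:
            r = 0.5
        rows.append(
            {"chrom": v.chromosome, "pos": v.position, "ref": v.ref,
             "alt": v.alt, "causal": v.causal, "r_to_causal": r}
        )
    pd.DataFrame(rows).to_csv(args.outdir / "truth.tsv", sep="\t", index=False)

    print(f"genome: {sc.genome.total_bp() / 1e6:.1f} Mb over "
          f"{len(sc.genome.names)} chromosomes, {len(sc.gene_models)} genes")
    print(f"EMS variants: {len(sc.variants)} "
          f"(causal {sc.causal.chromosome}:{sc.causal.position} "
          f"{sc.causal.ref}>{sc.causal.alt}, splice donor of "
          f"{sc.causal_gene.gene_id})")
    print(f"pool: {sc.pool.shape[0]} homozygous-mutant F2 plants of "
          f"{sc.plants.shape[0]} simulated")
    print(f"wrote reference.fa, genes.gff3, pool_counts.tsv/.vcf, truth.tsv "
          f"to {args.outdir}/")


if __name__ == "__main__":
    main()
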