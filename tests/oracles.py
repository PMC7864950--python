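"""Independent brute-force oracles for the test suite.

These deliberately avoid the implementation paths they check: cluster
enumeration walks the raw records; the CDS-effect oracle mutates the genome
sequence itself, re-extracts and retranslates the whole CDS, and diffs the
two proteins.
"""

import numpy as np
import pandas as pd

from nodmap.effects import translate_cds
from nodmap.genome import EmsVariant, ReferenceGenome, extract_cds
from nodmap.mapping import compute_snp_index


def brute_force_clusters(track, threshold, min_snps, max_gap):
    """All maximal qualifying runs, enumerated record by record."""
    recs = list(track.itertuples(index=False))
    runs = []
    i = 0
    while i < len(recs):
        if recs[i].snp_index < threshold:
            i += 1
            continue
        j = i
        while (
            j + 1 < len(recs)
            and recs[j + 1].chrom == recs[j].chrom
            and recs[j + 1].snp_index >= threshold
            and recs[j + 1].pos - recs[j].pos <= max_gap
        ):
            j += 1
        run = recs[i : j + 1]
        if len(run) >= min_snps:
            runs.append(
                (
                    run[0].chrom,
                    run[0].pos,
                    run[-1].pos,
                    len(run),
                    min(r.snp_index for r in run),
                    float(np.mean([r.snp_index for r in run])),
                )
            )
        i = j + 1
    runs.sort(key=lambda r: (-r[3], -r[5], r[0], r[1]))
    return runs


def random_track(rng, max_sites=50):
    """A random small SNP-index track over two chromosomes."""
    n = int(rng.integers(0, max_sites + 1))
    chroms = sorted(rng.choice(["c1", "c2"], size=n))
    pos = []
    seen = set()
    for c in chroms:
        p = int(rng.integers(1, 2_000_000))
        while (c, p) in seen:
            p = int(rng.integers(1, 2_000_000))
        seen.add((c, p))
        pos.append(p)
    depth = rng.integers(10, 60, size=n)
    alt = rng.binomial(depth, rng.choice([0.5, 0.97, 1.0], size=n))
    counts = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "ref": "G", "alt": "A",
         "causal": False, "alt_count": alt, "depth": depth}
    )
    return compute_snp_index(counts)


def mutate_genome(genome: ReferenceGenome, variant: EmsVariant) -> ReferenceGenome:
    chroms = []
    for name, seq in genome.chromosomes:
        if name == variant.chromosome:
            i = variant.position - 1
            assert seq[i] == variant.ref
            seq = seq[:i] + variant.alt + seq[i + 1 :]
        chroms.append((name, seq))
    return ReferenceGenome(chroms)


def cds_effect_oracle(genome, model, variant):
    """Expected (effect_class, protein_change) for a CDS variant, derived by
    rebuilding the whole mutant CDS from a mutated genome and diffing the
    two translations. Returns None when the variant does not touch the CDS.
    """
    cds_ref = extract_cds(genome, model)
    cds_mut = extract_cds(mutate_genome(genome, variant), model)
    if cds_ref == cds_mut:
        return None
    prot_ref = translate_cds(cds_ref)
    prot_mut = translate_cds(cds_mut)
    diffs = [i for i, (a, b) in enumerate(zip(prot_ref, prot_mut)) if a != b]
    if not diffs:
        k = next(i for i, (a, b) in enumerate(zip(cds_ref, cds_mut)) if a != b) // 3
        return "synonymous", f"{prot_ref[k]}{k + 1}{prot_ref[k]}"
    (k,) = diffs
    change = f"{prot_ref[k]}{k + 1}{prot_mut[k]}"
    if k == 0 and prot_ref[0] == "M":
        return "start_loss", change
    if prot_mut[k] == "*":
        return "nonsense", change
    return "missense", change
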