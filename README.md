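# nodmap

Forward-genetics mapping-by-sequencing for EMS nodulation mutants, built as
a fully simulated, testable pipeline.

The package addresses the computational chain of a classical legume forward
screen: an EMS-mutagenized line carries genome-wide G:C→A:T transition SNPs
and one recessive causal mutation abolishing nodulation (Nod⁻). The mutant
is backcrossed to wild type, the F1 selfed, and 100–120 non-nodulating F2
plants — all homozygous mutant at the causal locus — are pooled and
sequenced. At every EMS site the **SNP index**

```
SNP index = alt reads / total reads  ≈  mutant allele frequency in the pool
```

has expectation `1 − r`, where `r` is the recombination fraction to the
causal locus (Haldane: `r = (1 − e^(−2d/100))/2` for `d` cM). Unlinked sites
sit near 0.5; the causal region shows a cluster of SNPs with an index of 1,
which localizes the gene. Candidate mutations in the mapped interval are
then ranked by predicted effect (splice site / nonsense / start loss >
missense > synonymous > intronic > intergenic). A second, targeted-capture
stage fingerprints a mutant collection over a gene panel, filters siblings
(mutants from the same M1 founder, recognized by shared EMS fingerprints),
groups independent alleles per gene into allelic series, and tests 3:1
Mendelian segregation with a χ² goodness-of-fit.

Everything runs on synthetic data generated by the package itself; no
external sequencing data is required.

## Layout

- `src/nodmap/` — the library: `genome` (FASTA/GFF3 I/O, gene models,
  variants), `simulate` (EMS mutagenesis, Haldane meiosis, pool
  sequencing), `mapping` (SNP index, linkage clusters), `effects` (variant
  annotation), `panel` (siblings, allelic series, segregation),
  `scenario` (composed stated-world simulations).
- `analysis/01–04_*.py` — narrative drivers: simulate the population, map
  the locus, annotate candidates, analyse the capture cohort. Outputs go to
  `results/`.
- `scripts/acceptance.py` — recomputes the headline quantities from scratch.

## Worked example

```
$ python analysis/01_simulate_population.py --seed 1
genome: 10.0 Mb over 2 chromosomes, 20 genes
EMS variants: 49 (causal chr1:2727130 G>A, splice donor of gene01.06)
pool: 110 homozygous-mutant F2 plants of 1000 simulated

$ python analysis/02_map_causal_locus.py
track: 49 EMS-type sites at depth >= 10
top cluster: chr1:2681563-2800493 (9 SNPs, min index 1.000, mean 1.000)
candidate region (50 kb margin): chr1:2631563-2850493
causal site inside top cluster: True

$ python analysis/03_annotate_candidates.py
region chr1:2631563-2850493: 9 EMS candidate effects
  chr1:2727130 G>A  gene01.06  splice_site  ...  index=1.0
top candidate: splice_site in gene01.06 (truth: causal=True)
```

The mutant allele frequency reaches exactly 100% at the causal splice-donor
SNP; the top linkage cluster contains it, and severity ranking puts the
splice variant first among the region's candidates. Driver 04 then shows
the capture stage on a 13-mutant cohort: the two simulated sibling groups
are recovered by Jaccard fingerprint clustering, every true lesion appears
among the severity-filtered candidates, and the allelic series at the five
lesion-carrying genes match the simulated allele counts up to fingerprint
noise.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-simulates the zero-error mapping design from scratch and reports, as
JSON: `t1`, the SNP index (in %) at the causal site in the 110-plant pool,
and `t2`, the minimum SNP index among members of the top-ranked linkage
cluster overlapping the causal locus.
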