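# Methods

## Genetic model

The pipeline models a single recessive nodulation mutation induced by EMS
in an inbred line. EMS chemistry alkylates guanine, so induced SNPs are
treated as G:C→A:T transitions (`spectrum_fraction`, default 1.0; values
below 1 scatter uniformly chosen substitutions for robustness tests).
Mutation density is `mutation_rate` per Mb (default 5/Mb). The mutagen dose
used in the emulated screen fixes only the chemistry, not the realized
per-bp density, so the default is an explicit, documented choice in the
range typical of plant EMS populations — not a measured value.

The mutant × WT backcross produces an F1 heterozygous at every mutant SNP;
selfing yields the F2. Meiosis follows the Haldane model (crossovers a
Poisson process on the genetic map, no interference). Because a Poisson
process is Markov, a gamete's haplotype over ordered loci is sampled
exactly as a two-state chain: the first locus is 0/1 with probability 1/2
and consecutive loci flip with `r = (1 − e^(−2d/100))/2` for their cM
separation — distributionally identical to drawing crossover counts and
uniform breakpoints, and fully vectorizable. Physical positions map
linearly onto each chromosome's genetic length (default 100 cM per
chromosome); no recombination map is modelled.

Phenotype selection keeps `pool_size` (default 110, midpoint of the 100–120
plants a mapping bulk contains) F2 plants homozygous for the causal allele
— the recessive Nod⁻ class, ~1/4 of the F2. A selected plant's two gametes
each carry the mutant allele at a linked site with probability `1 − r`, so
the expected pool allele frequency is `1 − r` (1/2 unlinked); this closed
form is the main correctness oracle for the simulator.

Pooled sequencing is modelled at variant sites only: depth per site is
Poisson(`mean_depth`, default 50); each read samples one of the `2 ×
pool_size` chromosome copies uniformly, and a sequencing error
(`error_rate`, default 0) substitutes one of the three other bases
uniformly, giving alt-read probability `f(1 − e) + (1 − f)e/3` at pool
frequency `f`. Read-level simulation, alignment and variant calling are out
of scope: the analysis consumes allele counts, which is the information a
pooled caller distills at these sites. The zero default keeps the
recessive-pool causal index exactly 1, the pattern the mapping stage is
built to detect; error > 0 is exercised in the end-to-end robustness test.

## Mapping stage

The SNP-index track keeps sites with depth ≥ 10 and records
`alt_count/depth` exactly. Only EMS-type transitions (G→A, C→T) enter
cluster detection. A linkage cluster is a maximal run of consecutive track
records with index ≥ 0.95 on one chromosome with adjacent members ≤ 2 Mb
apart and ≥ 3 members; clusters rank by size, then mean index, then
position. The 0.95 threshold (rather than exactly 1.0) tolerates finite
depth and nonzero error; 3/2 Mb are explicit defaults, since the emulated
study reports the qualitative pattern ("clusters of SNPs with an SNP index
of 1") without parameters. The candidate region is the top cluster padded
by 50 kb.

A consequence worth knowing: background EMS SNPs 1–5 cM from the causal
locus have expected pool index 0.90–0.99 and, at depth ~50, a substantial
chance of sampling an index in [0.95, 1). Such sites join the causal run,
so the top cluster usually contains the causal site (100/100 seeds in the
end-to-end test) while its *minimum* member index is exactly 1.0 only in a
minority of realizations. Detection and localization are robust; the
literal "every member at 100%" reading is not, and the test suite reports
that honestly rather than widening the cluster rule.

## Effect annotation

Annotation is per (variant, gene) with total precedence: canonical splice
dinucleotides (first/last 2 intron bases; width configurable) >
CDS effects > intronic > intergenic. CDS effects substitute the base in the
assembled coding sequence (strand-aware complementing), retranslate, and
diff the proteins — never genomic triplets, so junction-spanning codons are
handled. Classes: synonymous, missense, nonsense (new stop), start_loss
(ATG disrupted). Protein changes use p.-style numbering from the start
codon; nucleotide changes are CDS-relative (`c.NNNref>alt`). Stop-loss is
not called: G:C→A:T cannot convert TAA/TGA/TAG to a sense codon.
Candidate ranking keeps EMS-type variants in the mapped region, ordered by
severity class then SNP index.

## Capture stage

Fingerprints are EMS-type variant sets restricted to panel gene intervals.
Sibling similarity is Jaccard on exact variant sets with single-linkage
closure at threshold 0.5 — siblings share an M1 parent, so transitive
sharing is expected; groups spanning bulks are flagged, not dropped. The
emulated study states the goal of sibling filtering but no metric, so both
the metric and the threshold are design choices. The candidate filter keeps
splice_site/nonsense/start_loss/missense effects in panel genes,
formalizing the manual search; an optional min-alt-fraction filter is
deliberately absent from defaults. Allelic series count distinct candidate
variants per gene with each sibling group contributing once
(alphabetically first member). Segregation uses the Pearson χ² with 1 df
against the expected ratio (default 3:1), Yates correction off by default
(switchable); p-values come from the χ² survival function.

## Synthetic worlds

`run_mapping_scenario` composes the stated mapping design: two 5-Mb
chromosomes of random 36%-GC sequence, 10 gene bodies per chromosome
(ATG…TAA, canonical GT/AG introns, half on the minus strand) spliced into
the background, 5 EMS SNPs/Mb, a causal splice-donor G→A in the gene
nearest the middle of chromosome 1, and six additional EMS SNPs within
±3 kb of the causal site. The enrichment is deliberate: a uniform 5/Mb
background yields only ~1 SNP within 2 cM, while the design the analysis
assumes has ≥ 5 — biologically, the mutant haplotype around the lesion is
fully preserved in the pool, and a denser local fingerprint is what real
mutagenized genomes show at this scale. All randomness derives from one
seed via `SeedSequence` spawning.

`simulate_capture_cohort` draws per-founder fingerprints of 12 EMS SNPs
over panel gene spans, with sibling lines retaining each founder SNP
independently with probability 3/4 (a selfed heterozygous M1 transmits at
least one copy with that probability), giving expected sibling Jaccard
≈ 0.63 against ≈ 0 for independents; about 14% of sibling *pairs* fall
below the 0.5 threshold, which single-linkage through larger groups
partially rescues — a known limitation. Founder lesions are verified
severe (splice/missense/nonsense) and distributed over five genes as
3:3:2:1:1 to emulate an allelic series.

What a green test does not establish: the generator draws independent
Poisson depths (no coverage waviness or mapping bias), models no indels or
structural variants, no allele-specific capture bias, no contamination or
mis-phenotyped plants in the pool, and a strictly linear physical↔genetic
map. Numbers measured on this world validate the algebra and the
algorithms, not performance on real libraries.

## Numerical and degenerate-case choices

Coordinates are 1-based inclusive throughout; conversions live only in
readers/writers. Ref=N positions cannot host variants. Gene models with
CDS length not divisible by 3 are kept but flagged non-coding and excluded
from CDS-effect calls. Empty tracks, empty windows (NaN mean), and
zero-cluster outcomes are defined results, not errors; an exhausted
homozygote supply in pool selection raises, signalling an under-sized F2.
Cluster and candidate ties break deterministically (position order) so
outputs are reproducible across runs and platforms.
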