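# Methods

This note describes the models implemented in `tetramap`, the defaults
and why they were chosen, what the simulator does and does not emulate,
and the numerical conventions that make runs reproducible.

## 1. Genetic model

### Genome and genes

A `GenomeModel` is a set of chromosomes (name, length in bp), a list of
single-transcript gene models, and one uniform genetic-map rate in
cM/Mbp. The default desk-scale genome is 3 chromosomes × 4 Mbp with 30
two-exon genes (600 nt CDS each, strands alternating; every second gene
carries a 31-residue transit peptide so mature-protein coordinates are
exercised). Coordinates are 1-based inclusive throughout (VCF
convention). Reference sequence is synthesized as uniform random ACGT
with CDS regions rewritten from uniformly drawn sense codons, so every
gene translates without premature stops.

The map rate defaults to 6 cM/Mbp. With Haldane's function this puts a
locus 2.29 Mbp away at recombination fraction 0.12, matching the
empirical observation that a variant ~2 Mbp from a selected locus
reaches ~88% frequency in phenotype-selected pools. The real
*C. reinhardtii* map is non-uniform and averages roughly this order of
magnitude; a uniform rate is a deliberate simplification.

### Strains and haploidy

A `StrainGenome` is a haploid genotype: a mapping from site keys
(`chrom:pos:ref:alt`) to carried alternate alleles, absent keys meaning
reference. The background wild type carries a private "background SNP"
panel relative to the reference assembly (default 150 sites); the
outcross strain carries that shared panel **plus** a dense private panel
(default 1200 sites ≈ 100/Mbp, uniformly placed — inter-SNP spacings are
then approximately exponential with mean 10 kbp). The two strains
therefore differ at exactly the outcross-panel sites. Mating types are
'+' (background, mutants) and '−' (outcross partner).

Phenotype is identified with carriage of a single causative allele
(penetrance 1, no phenocopies): the clean 2:2 segregation of the trait
in tetrad screens justifies a strict single-locus, full-penetrance
model.

### Mutagenesis

`mutagenize` plants exactly one causative **missense** substitution at a
random codon of a designated gene and scatters the remaining
n_mutations − 1 SNPs uniformly over the genome (default n = 60, the
order of magnitude a UV screen leaves after triage). No mutational
spectrum (UV photoproduct bias) is modelled; positions and alleles are
uniform.

### Meiosis

`meiosis_tetrad` models one meiosis of a (+) × (−) cross on the
four-chromatid bundle:

* Chiasmata per chromosome ~ Poisson(2·d), where d = rate × length is
  the map length in Morgans; positions uniform. (Each gamete then sees
  Poisson(d) crossovers.)
* Each chiasma joins one chromatid from each homolog axis at its
  position — i.e. one strand of each current parental origin — and
  exchanges their distal segments. This is the no-interference,
  no-chromatid-interference model; choosing strands by centromere pairs
  instead would permit effective same-origin exchanges after an earlier
  crossover and measurably deflates two-locus recombination below the
  Haldane closed form (we observed 0.1155 vs the expected 0.1200 at
  c = 0.12 before adopting the axis rule).
* Independent assortment: each bivalent's orientation at meiosis I and
  the order within each sister pair at meiosis II are randomized per
  chromosome.
* Mating type segregates 2:2 per tetrad as an unlinked Mendelian locus
  (random assignment).

Consequences, verified by the test suite: every inter-parental
heterozygous site segregates exactly 2:2 in every tetrad; two-locus
recombination fractions follow c = (1 − e^(−2d))/2; loci on different
chromosomes recombine at 1/2.

Gene conversion, crossover interference, and organellar inheritance are
not modelled.

### Breeding schemes

*Backcross* (`run_backcross_scheme`): per generation, cross the current
phenotype-positive strain to a background-wild-type clone of the
opposite mating type (the background strain is treated as an isogenic
mating-type pair, as lab strain pairs typically are), form one tetrad,
and keep one random causative-carrying product. Unlinked mutations are
retained with probability 2⁻ᵍ after g generations; a variant at
recombination fraction c survives with probability (1−c)ᵍ.

*Outcross pooling* (`run_outcross_pools`): dissect n complete tetrads
(default 25; incomplete tetrads are assumed discarded upstream) and
partition all 4n progenies by phenotype — exactly 2n per pool by the
2:2 law.

## 2. Sequencing and variant-calling noise

`simulate_pool_sequencing` works at the variant level (no reads or
alignment): per site, depth ~ Poisson(mean coverage; default 30 for
pools, 20 for single strains), and alt reads ~ Binomial(depth, f(1−e) +
(1−f)e) with f the pool carrier fraction and e the per-read base error
(default 0.002). A site is reported when depth > 0 and at least
`min_alt_reads` (default 2) reads support the variant — the minimum-
support behaviour of common callers; without it, singleton error reads
in the phenotype-negative pool would spuriously veto the causative
variant under the any-frequency subtraction rule. Frequency values are
rounded to 2 decimals.

Artifact calls are added as a Poisson process along the genome at
`artifact_variant_rate` (default 25/Mbp) with frequencies 100·Beta(8, 8),
concentrating in the 35–65% band. The rate is calibrated so that a
single-strain call set is artifact-dominated — majority of mass
mid-band with a secondary spike at exactly 100% — which is the shape
haploid resequencing shows in practice; the exact generative process of
real artifacts (library chimeras, mapping errors) is unknown and not
modelled mechanistically.

## 3. The filtering cascade

Stage order is cutoff → subtraction → non-synonymous selection:

* **Cutoff**: strictly greater than 80% by default (`keep_at_cutoff`
  exposed for sensitivity analyses).
* **Subtraction** removes any record whose site key appears in any
  reference table at any frequency. Site identity is the exact key
  (chrom, pos, ref, alt); indel left-normalization is not attempted
  because the simulator emits normalized calls.
* **Non-synonymous** keeps missense, nonsense, residue-altering MNPs,
  and any CDS-overlapping indel (frameshift or in-frame); synonymous,
  intronic, and intergenic records are dropped. A broad reading of
  "protein-changing" is used deliberately so loss-of-function candidates
  are never discarded.
* **Intersection** of independent experiments keeps keys present in
  every table, reporting frequencies from the first.

The pooled design (`pool_causal_filter`) applies the cascade to the
phenotype-positive pool, subtracting the phenotype-negative pool and
both wild-type call sets.

## 4. Origin tagging and linkage regions

Trio-style tagging assigns each pool-table record an origin by key
membership: background panel → `background_wt`, outcross panel →
`outcross_wt`, otherwise `novel`. Panels must be disjoint; the pipeline
therefore (a) restricts both wild-type call sets to confident calls
(frequency above the cutoff — single-strain real variants sit near
100%, so this only sheds artifacts whose random positions could
otherwise collide between panels), and (b) keeps only outcross-private
SNPs in the outcross panel, since sites shared with the background
strain do not segregate in the cross and carry no linkage information.

Clean flanks run from a candidate to the nearest outcross-tagged
variant on each side, or to the chromosome boundary (treated as
position 0 / chromosome length, so a chromosome with no outcross SNP
yields a clean region of the full chromosome length). Candidates are
ranked by (clean-region size desc, frequency desc, chromosome,
position): the region criterion formalizes "a large region with only
mutant and background variants", the frequency criterion separates a
100% causative variant from an 88% hitchhiker, and the positional tie
break makes reports deterministic.

## 5. Pipeline designs and problem sizes

Three end-to-end designs are provided, sized to run in seconds each:

* `preliminary`: mutant + background wild type sequenced at coverage 20;
  cascade against the wild type.
* `outcross_pooling`: 25 tetrads → two 50-progeny pools + both wild
  types at coverage 30; pooled cascade, tagging, flank ranking.
* `backcross`: 5 phenotype-selected generations, fifth-generation strain
  and mutant sequenced at coverage 20, cascades intersected.

Statistical acceptance checks use 100 tetrads (2:2 law), 200 replicate
outcrosses × 50 progenies (linked-variant mean 88 ± 1%), 5000 backcross
replicates (retention 2⁻⁵ within 3 binomial SE), 1000 random tables
(filter vs brute-force oracle) and 200 seeded end-to-end runs (top-rank
recovery ≥ 95%). These sizes were chosen so each law is resolved well
inside its tolerance while the whole suite stays interactive.

A run can legitimately end with zero candidates (e.g. two base-error
reads place the causative allele in the phenotype-negative pool table,
whose any-frequency veto then removes it; ~0.2–0.3% of pooled runs at
default noise). The pipeline surfaces this as an explicit error rather
than inventing a candidate; recovery-rate checks count it as a miss.

## 6. Reproducibility and numerics

All stochastic behaviour flows from a single integer seed through one
`numpy` Generator per run, threaded through every stage in a fixed
order; identical (seed, config) pairs reproduce every artifact file
byte for byte (reports carry the seed and a config hash). Frequency
values are compared after 2-decimal rounding; "exactly 100%" means
100.00 after rounding. VCF output is single-sample VCF 4.2 with the
frequency in FORMAT field `VF`; TSV output is a fixed six-column
dialect. Writing is deterministic text emission; parsing goes through
cyvcf2/pandas/gffutils/Biopython.

## 7. What passing tests do and do not show

The simulator reproduces the *statistical skeleton* of a real mapping
experiment — segregation laws, pooled allele frequencies, backcross
decay, artifact frequency structure — so green tests demonstrate that
the pipeline's inferences are correct *given that model*. Real data add
complications the model omits: non-uniform recombination landscapes,
mutational spectra, caller-specific systematic errors correlated across
samples, indel realignment ambiguity, incomplete penetrance and
phenotyping error, and pool-composition imbalance. Absolute variant
counts from real screens depend on caller settings and genome size and
are not reproduced at desk scale; only the scale-free quantities
(frequencies, ratios, segregation proportions, residue arithmetic) are
expected to transfer.

## 8. HGVS subset

Supported coding-change classes are CDS substitutions (`c.479C>T`) and
equal-length delins (`c.2044_2045delCCinsTT`) — the classes a point
mutagenesis screen produces. Splice/UTR offsets, frameshifting indels
in c. notation, and multi-transcript genes raise explicit unsupported
or parse errors. Residue index is ceil(cds_start / 3); the standard
nuclear genetic code (table 1) is used; mature-protein coordinates
subtract the gene's transit-peptide length and refuse changes inside
the transit peptide.
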