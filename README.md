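# tetramap

Causal-mutation identification for haploid forward genetics, built around
the mapping-by-sequencing strategy used in *Chlamydomonas reinhardtii*
mutant screens: mutagenize, cross, pool progeny by phenotype, sequence,
and filter variant tables until one candidate remains. The package pairs
the analysis pipeline with a tetrad-resolved meiosis simulator, so every
stage can be exercised — and its statistical behaviour verified — on
synthetic data of known truth, without any external sequencing data.

## Who this is for

Groups doing UV/EMS mutant screens in haploid microbes or algae who map
causative loci by bulked segregant analysis and backcross purification,
and anyone who wants a compact, fully scriptable model of that workflow
(tetrad dissection, outcrossing to a SNP-dense polymorphic strain,
pooled sequencing, coding-change annotation).

## The model in brief

Every called variant carries a **frequency value** f ∈ [0, 100]: the
percent of mapped reads at the site reporting the variant allele. In a
haploid, a real variant should sit near 100%; library/caller artifacts
form a bulk at mid frequencies. The pipeline composes four ideas:

1. **Frequency triage** — keep calls with f > 80% (strict cutoff,
   tolerating ambiguous base calls in up to 20% of reads).
2. **Subtraction** — a variant present at *any* frequency in a wild-type
   strain or in the phenotype-negative pool cannot be causative.
3. **Bulked segregant signal** — in a pool of n phenotype-selected
   haploid progeny the causative variant is carried by every member
   (f = 100% at allele level); a linked non-causative variant at
   per-meiosis recombination fraction c appears at 100·(1−c)%; unlinked
   variants drift around 50%.
4. **Linkage regions** — tagging each pool variant by origin (background
   wild type / outcross wild type / novel) exposes the causative locus as
   a large region free of outcross-strain SNPs; candidates are ranked by
   clean-region size, then frequency.

Meiosis is simulated on the four-chromatid bundle: chiasmata per
chromosome ~ Poisson(2d) with d the map length in Morgans (uniform
cM/Mbp), each chiasma joining one chromatid from each homolog axis, so
every heterozygous site segregates exactly 2:2 within a tetrad and the
per-gamete recombination fraction follows Haldane's mapping function
c = (1 − e^(−2d))/2. Phenotype-selected backcrossing therefore purges an
unlinked mutation with probability 1/2 per generation (2⁻⁵ ≈ 3.1% after
five generations).

Coding consequences are reported in HGVS-style c. notation restricted to
CDS substitutions and equal-length delins (e.g. `c.479C>T`,
`c.2044_2045delCCinsTT`), translated with the standard genetic code, with
optional mature-protein coordinates after transit-peptide cleavage.

## Worked example

Simulate a pooled outcross experiment (3 × 4 Mbp genome, 60 UV mutations
of which one is a planted causative missense change, 25 tetrads → two
50-progeny pools, coverage 30) and map the mutation:

```sh
$ tetramap run --design outcross_pooling --seed 1 --out-dir demo
outcross_pooling: 1 candidate(s); top chr02:727306:A:G frequency=100.00%

$ cat demo/summary.txt
design: outcross_pooling
candidates: 1
top candidate: chr02:727306:A:G frequency=100.00% clean_region=199759 bp
count trajectory:
  pool:frequency_filter: 1548 -> 172
  pool:subtract: 172 -> 8
  pool:nonsynonymous: 8 -> 1
  pool:linkage_candidates: 1 -> 1
reproducibility:
  seed: 1
  config_hash: 5402d8f4f488e73f
```

Reading the trajectory: of 1548 calls in the phenotype-positive pool,
172 exceed the 80% cutoff (artifacts and ~50% segregating sites drop
out), 8 survive subtraction of the phenotype-negative pool and both
wild types, and a single non-synonymous candidate remains — the planted
causative variant, reported at 100% with its clean linkage region. The
same seed reproduces every output byte for byte.

Tetrad segregation and annotation:

```sh
$ tetramap segregation --config tsp.cfg --tetrads 10
10/10 tetrads segregate 2:2; single-locus consistent: True

$ tetramap annotate --hgvs "c.479C>T" --cds prk_cds.fasta --transit-peptide 31
c.479C>T -> Pro160Leu (missense); mature: Pro129Leu
```

Other subcommands: `simulate` (emit FASTA/GFF3/VCF inputs), `filter`
(triage cascade on existing tables), `pool-map`, `backcross-map`,
`run --design preliminary|backcross`. All accept `--seed` and a flat
key=value `--config` file (see `tetramap.config`).

## Layout

| module | contents |
| --- | --- |
| `tetramap.genome` | chromosomes, gene models, reference synthesis, FASTA/GFF3 |
| `tetramap.variants` | `VariantCall`/`VariantTable`, site keys, VCF 4.2 + TSV IO |
| `tetramap.simulate` | strains, mutagenesis, tetrad meiosis, breeding schemes, pooled sequencing |
| `tetramap.triage` | frequency cutoff, subtraction, non-synonymous selection, intersection |
| `tetramap.pools` | pooled-progeny causal filter, frequency histogram diagnostics |
| `tetramap.linkage` | origin tagging, clean-flank regions, candidate ranking |
| `tetramap.hgvs` | coding-change parsing/application, mature coordinates |
| `tetramap.pipeline` / `tetramap.cli` | experiment designs end to end, CLI |

See `docs/methods.md` for the full model description, parameter defaults,
and known limitations.
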