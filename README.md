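# calluscope

Tools for finding **callus-specific promoters** in allotetraploid peanut
(*Arachis hypogaea*) and for **genotyping cytosine-base-editing (CBE)
outcomes** in the transgenic callus lines those promoters are used to
edit. Plant transformation starts at the callus stage, so confining
Cas9/deaminase expression to callus with a callus-specific promoter
limits off-target mutagenesis in regenerated plants. The package
reimplements the computational stages of that workflow as a tested,
self-contained pipeline:

1. **Expression screen** (`calluscope.expression`) — select the top-N
   genes by FPKM in each RNA-seq replicate of each callus subculture
   stage, form the per-stage consensus as the union of replicate sets,
   intersect across stages, and keep genes that a multi-tissue expression
   atlas shows to be strongly expressed in callus but low or undetectable
   elsewhere.
2. **RT-qPCR** (`calluscope.rtqpcr`) — relative expression by the
   2^−ΔCt method against an internal reference gene (e.g. *AhADH3*),
   averaging technical replicates before taking mean ± SD across
   biological replicates.
3. **Promoter motif scan** (`calluscope.motifs`) — both-strand IUPAC
   consensus scanning of promoter sequences against an editable catalog
   of plant cis-regulatory elements (TATA-box, CAAT-box, light-, hormone-
   and stress-responsive elements).
4. **Amplicon genotyper** (`calluscope.genotyper`) — from Hi-TOM-style
   per-line variant read-count tables: exclude reads below 1% frequency,
   classify variants against the reference amplicon by global alignment
   (wildtype / substitution / indel / complex), sum non-wildtype
   frequencies into a cumulative per-locus **mutation frequency**
   f = edited reads / total reads, and call zygosity:
   - f > 90% → homozygous
   - 20% ≤ f ≤ 90% → heterozygous
   - 0 < f < 20% → chimeric
   A line is *edited* if any locus is heterozygous or homozygous;
   cohort rates are `100 × count / genotyped lines`, one decimal.
5. **Off-target scan** (`calluscope.offtarget`) — enumerate every
   20-mer + PAM (NGG/NAG) within a Hamming-distance budget of the sgRNA
   spacer, score with multiplicative PAM-proximal-weighted penalties, and
   rank the top candidates for validation.
6. **Synthetic data** (`calluscope.simulate`) — seeded generators with
   ground-truth manifests for every stage, so the whole pipeline runs and
   is testable without any external download.

## Worked example

Simulate a 28-line cohort designed with 4 edited lines (2 homozygous,
2 carrying indels) and genotype it:

```sh
calluscope simulate cohort --seed 3 --n-lines 28 --n-edited 4 \
    --n-homozygous 2 --n-indel 2 -o cohort
calluscope genotype --variants cohort/variants.tsv \
    --targets cohort/targets.yaml --amplicons cohort/amplicons.fa -o geno
```

prints

```
cohort: 4/28 edited (14.3%), homozygous 7.1%, indel 7.1%
```

i.e. the genotyper recovered the designed outcome exactly: editing
efficiency 4/28 = 14.3%, homozygous rate 2/28 = 7.1%, indel rate
2/28 = 7.1%. `geno/` also holds per-variant, per-locus and per-line
TSVs with frequencies, mutation classes and zygosity calls.

Other subcommands: `calluscope screen` (expression screen),
`calluscope qpcr` (2^−ΔCt), `calluscope motifs` (cis-element scan),
`calluscope offtarget` (site enumeration and ranking), and
`calluscope simulate {atlas|cohort|promoters|genome}`.

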