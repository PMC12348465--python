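# Methods

## Expression screen

The screen identifies candidate callus-specific genes in four steps.

**Top-N selection.** For each RNA-seq replicate the `top_n` (default 400)
genes with the highest FPKM are selected. Ties at the cutoff are all
included, which makes the selection deterministic and independent of
input order. When the input is raw fragment counts, FPKM is computed as
`fragments × 10⁹ / (library_size × transcript_length)` with the library
size defaulting to the column sum; a gene with nonzero counts but no
length is a hard error.

**Per-stage consensus.** The consensus of a stage's replicates is the
*union* of the per-replicate top-N sets. A union is the only consensus
consistent with per-stage highly-expressed lists larger than N (three
top-400 replicate sets yielding ~487 genes); an intersection could never
exceed N.

**Cross-stage intersection.** Genes in every stage's consensus.

**Atlas specificity filter.** A gene is callus-specific when its mean
callus FPKM ≥ `min_callus_expr` (default 10), its maximum mean FPKM over
all other tissues ≤ `max_other_expr` (default 1), and
`(callus + ε)/(max_other + ε) ≥ min_ratio` (default 10, ε = 0.01 to guard
zero denominators). These thresholds are explicit parameters rather than
a reproduction of any particular published shortlist, which may have
involved manual inspection; replicates are averaged per tissue before
thresholding. An optional precomputed differential-expression table
(gene, log2FC, FDR) annotates the candidate report but plays no role in
selection — differential-expression testing itself is out of scope.

## RT-qPCR

Relative expression is `2^−(Ct_target − Ct_reference)`. Technical
replicates are averaged to one Ct per biological replicate *before* the
ΔCt and before mean ± sample SD (ddof = 1) across biological replicates;
this matches the usual replicate hierarchy (biological replicates are the
unit of inference, technical replicates only reduce measurement noise)
and is configurable off (`average_technical_first=False`). Whether
technical averaging preceded ΔCt in the original workflow is not
documented; the order here is this package's convention. A single
replicate reports SD 0 with a logged warning rather than NaN so
downstream plotting never sees missing dispersion.

## Promoter motif scan

Matching is IUPAC-consensus equality: position p matches when every
pattern symbol's IUPAC set contains the sequence base. `N` in the
*sequence* matches nothing (conservative: unknown bases never create
hits); `N` in the *pattern* matches any base. All overlapping and nested
hits are reported — no greedy masking. Both strands are scanned; minus-
strand hits carry forward-strand 1-based inclusive coordinates, with BED6
(0-based half-open) export for interoperability. The shipped catalog
(`calluscope/data/cis_element_catalog.tsv`) holds PLACE/PlantCARE-style
consensi for the core (TATA-box, CAAT-box), light (Box 4, GATA-motif,
AT1-motif), hormone (ABRE, TGACG-motif, TCA-element, P-box) and stress
(as-1, ARE, WUN-motif, TC-rich repeats, STRE) classes; it is
configuration, not code, and no claim is made of reproducing any web
tool's exact hit lists, whose internal consensus definitions differ.
A helper extracts promoters as the ~2000 bp (configurable) upstream of a
start codon given a genome sequence.

## Amplicon genotyper

**Read filter.** Variants with raw frequency (count / pre-filter total)
strictly below 1% are excluded; a variant at exactly 1% is kept.
Frequencies are then recomputed over the retained total, so the reported
per-locus frequencies sum to 1 (the pre-filter denominator is available
via `renormalize=False`). The filter is idempotent. The per-locus
denominator is used; whether upstream platforms filter per locus or per
sample is not documented, so per-locus is this package's choice. A
line/locus where everything is filtered raises a no-call error rather
than silently reporting wildtype.

**Variant classification.** Each retained variant is globally aligned to
the reference amplicon (match +2, mismatch −1, gap open −4, gap
extend −1 — parameters chosen so short indels align as one contiguous
gap; Biopython's `PairwiseAligner` with `open_gap_score=-5`,
`extend_gap_score=-1`, which charges the open score on the first gap
base). When several alignments tie, the first in the aligner's
deterministic iteration order is used. No gaps and no mismatches →
wildtype; mismatches only → substitution; gaps only → indel; both →
complex, which counts as indel-containing. Substitutions inside the
protospacer are reported in protospacer coordinates with position 1 at
the PAM-distal end (the convention of base-editing window reports);
substitutions outside it keep amplicon coordinates and are flagged.

**Zygosity.** The cumulative mutation frequency f sums all non-wildtype
variant frequencies at the locus. f > 0.90 → homozygous ("exceeds 90%" is
strict, so f = 0.90 is heterozygous); 0.20 ≤ f ≤ 0.90 → heterozygous;
0 < f < 0.20 → chimeric; f = 0 → wildtype. The four classes tile [0, 1]
with no gaps or overlaps.

**Line and cohort calls.** A line is *edited* when any locus is
heterozygous or homozygous (chimeric-only lines are not edited), and
*homozygous* when any locus is. "The same classification approach" for
indel lines is implemented as: the cumulative indel-class frequency at
some locus alone reaches the heterozygous threshold (≥ 0.20);
`indel_rule="any"` switches to "any indel variant present". Cohort rates
are `100 × count / genotyped`, rounded to one decimal half away from
zero — this rounding reproduces every published per-construct rate cell
from its count columns (no half-cases actually occur there).

## Off-target scan

Every 20-mer immediately 5′ of a PAM match on either strand with Hamming
distance ≤ `max_mismatches` (default 4) to the spacer is reported once,
including the on-target site at distance 0; windows containing N never
match. The scan is vectorised (byte-encoded sliding windows) and is
verified in tests against a brute-force per-position oracle. Scoring is
`score = Π (1 − w_p)` over mismatched positions with a
PAM-proximal-heavy default profile (w = 0.1 at positions 1–12, 0.3 at
13–20, position 1 PAM-distal): simple, explicit and configurable, since
published web tools do not print their internal formulas. NAG-PAM sites
are multiplied by 0.5, reflecting SpCas9's weak NAG tolerance. Under any
strictly positive weight vector a 1-mismatch site (the typical
homoeologous near-target in an allotetraploid) outranks any 4-mismatch
site. Ranking returns the top-k (default 3) by descending score, ties
broken by (fewer mismatches, seq_id, start, strand), excluding
perfect-match sites by default.

## Synthetic data

All generators are pure functions of their arguments including the seed
(one `numpy` Generator per call) and return JSON-serialisable manifests
sufficient to verify recovery without re-simulation.

**Atlas.** Background genes draw one log-normal baseline (log-mean 1,
log-sd 1.5) shared across tissues, with multiplicative log-normal
replicate noise (log-sd 0.2); sharing the baseline across tissues means
background genes are never tissue-specific, so planted-truth recovery is
exact. Planted callus-specific genes get a sub-threshold non-callus level
(uniform 0.25–0.5 FPKM, i.e. below half the default `max_other_expr`)
and `effect_fold` (default 100) times that level in callus — chosen so
that, at the default thresholds, recovery survives 3-replicate averaging
of the noise with large margin.

**Two-stage top-set construction.** Per-replicate expression columns are
built so each column's top-400 is a designed subset and the per-stage
unions and their intersection have exactly the requested sizes (defaults
487, 453, 419). Designed genes carry large distinct values and
background genes uniform(0,1) values, so the top-N cut is tie-free. This
is a *constructed* consistency check of the set logic — the original
counts cannot be re-derived without the deposited sequencing data.

**Amplicon cohorts.** Per line/locus a design frequency is drawn
uniformly from the designed zygosity class's range (homozygous 0.91–1.0,
heterozygous 0.20–0.90, chimeric 0.01–0.19, wildtype 0) and read counts
are drawn binomially at `depth` (default 5000) over the wildtype and
edited alleles. Because a draw near a class boundary could realise a
frequency in the neighbouring class, the (frequency, counts) pair is
rejection-sampled until the realised post-filter frequency classifies as
designed — the counts remain multinomial draws, the generator remains a
pure function of the seed, and the manifest truth is recoverable at any
seed. Edited alleles are C→T substitutions at protospacer position 5 (a
typical base-editing window position) or 1-bp deletions when the line is
designed to carry indels. Noise variants are single substitutions
outside the protospacer, each capped strictly below 1% of the read
total, so the default filter removes exactly them.

**Promoters / genome.** Promoters are uniform-ACGT with concrete motif
instances written at stated coordinates (minus-strand plantings are
reverse-complemented); overlapping plantings are an error. The off-target
genome plants spacer copies mutated at exactly the designed number of
positions, each followed by an NGG PAM, and is rejection-sampled (seed
substreams, bounded retries) until a full scan finds no accidental site
within the mismatch budget, so the manifest is the complete truth.

**What the simulations do not emulate.** No read-level FASTQ or
quality-score modelling, no PCR/sequencing error profiles beyond the
capped noise variants, no homoeologous cross-amplification, no real
tissue-expression correlation structure, and no genome-scale
base-composition bias. Passing recovery tests therefore demonstrates the
correctness of the pipeline's logic under its stated assumptions, not
its robustness to every artefact of real amplicon or RNA-seq data.

## Problem sizes and numerical choices

Tests and the acceptance script use 2000-gene atlases, 24–28-line
cohorts at depth 5000, 600-bp promoter panels and a 100 kb off-target
genome — sizes at which every planted structure is unambiguous and
brute-force oracles are exact. Floating-point comparisons use relative
tolerance 10⁻⁶ for FPKM conservation and 10⁻¹² for the 2^−ΔCt
multiplicativity property; frequency sums are validated to 10⁻⁶.
Degenerate inputs (empty replicate lists, empty catalogs, all-filtered
loci, sequences shorter than spacer + PAM) raise informative errors
rather than returning empty results, except where the contract says
otherwise (an empty promoter sequence scans to an empty hit list;
fewer genes than N returns all genes).
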