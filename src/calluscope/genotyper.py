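"""Genotyping cytosine-base-editing outcomes from amplicon read tables.

Input is the per-line, per-locus variant read-count table produced by
high-throughput amplicon genotyping (Hi-TOM-shaped: line_id, locus_id,
variant_seq, read_count).  The pipeline:

1. drops variants below a 1% read-frequency floor and renormalises,
2. classifies each retained variant against the reference amplicon by
   global alignment (wildtype / substitution / indel / complex),
3. sums non-wildtype frequencies into a cumulative per-locus mutation
   frequency and calls zygosity from it
   (>90% homozygous, 20-90% heterozygous, <20% chimeric, 0 wildtype),
4. rolls locus calls up to line calls (a line is edited if any locus is
   heterozygous or homozygous) and cohort summaries
   (editing efficiency, homozygous rate and indel rate as percentages of
   genotyped lines).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import Align, SeqIO

__all__ = [
    "TargetSpec",
    "VariantRecord",
    "LocusCall",
    "LineCall",
    "CohortSummary",
    "filter_low_frequency",
    "classify_variant",
    "locus_mutation_frequency",
    "classify_zygosity",
    "call_line",
    "summarize_cohort",
    "genotype_cohort",
    "round_half_away",
    "load_targets",
    "NoCallError",
]

_DNA = set("ACGT")


class NoCallError(ValueError):
    """Raised when every variant at a line/locus falls below the filter."""


@dataclass
class TargetSpec:
    """One editing target: amplicon, spacer and PAM geometry.

    ``protospacer_start`` is the 1-based amplicon position of spacer base 1
    (the PAM-distal end).  On the '-' strand the spacer reads along the
    reverse complement, so spacer base i sits at amplicon position
    ``protospacer_start - (i - 1)``.
    """

    locus_id: str
    reference_amplicon: str
    spacer: str
    protospacer_start: int
    spacer_strand: str = "+"
    pam: str = "NGG"

    def __post_init__(self) -> None:
        self.reference_amplicon = self.reference_amplicon.upper()
        self.spacer = self.spacer.upper()
        if len(self.spacer) != 20:
            raise ValueError("spacer must be 20 nt")
        if self.spacer_strand not in "+-":
            raise ValueError("spacer_strand must be '+' or '-'")
        ref = self.reference_amplicon
        k = len(self.spacer)
        if self.spacer_strand == "+":
            found = ref[self.protospacer_start - 1 : self.protospacer_start - 1 + k]
            if found != self.spacer:
                raise ValueError(
                    f"spacer not found at +{self.protospacer_start} of {self.locus_id}"
                )
        else:
            lo = self.protospacer_start - k
            found = _revcomp(ref[lo : self.protospacer_start])
            if found != self.spacer:
                raise ValueError(
                    f"spacer not found at -{self.protospacer_start} of {self.locus_id}"
                )

    def protospacer_coord(self, amplicon_pos: int) -> int | None:
        """Protospacer coordinate (1 = PAM-distal) of a 1-based amplicon
        position, or None if outside the protospacer."""
        if self.spacer_strand == "+":
            c = amplicon_pos - self.protospacer_start + 1
        else:
            c = self.protospacer_start - amplicon_pos + 1
        return c if 1 <= c <= len(self.spacer) else None


@dataclass
class VariantRecord:
    """One read variant at a line/locus."""

    line_id: str
    locus_id: str
    variant_seq: str
    read_count: int
    frequency: float = float("nan")
    mutation_class: str = ""
    substitutions: list[tuple] = field(default_factory=list)
    length_delta: int = 0


@dataclass
class LocusCall:
    line_id: str
    locus_id: str
    mutation_frequency: float
    zygosity: str
    has_indel_call: bool
    indel_frequency: float


@dataclass
class LineCall:
    line_id: str
    locus_calls: list[LocusCall]
    edited: bool
    homozygous: bool
    indel_line: bool


@dataclass
class CohortSummary:
    construct_id: str
    n_genotyped: int
    n_edited: int
    n_homozygous: int
    n_indel: int
    editing_efficiency: float
    homozygous_rate: float
    indel_rate: float


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (25.05 -> 25.1, not banker's 25.0)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def filter_low_frequency(
    variants: list[VariantRecord],
    min_freq: float = 0.01,
    renormalize: bool = True,
) -> list[VariantRecord]:
    """Drop variants whose raw frequency is strictly below ``min_freq``.

    Raw frequency uses the pre-filter read total; a variant at exactly the
    floor is kept.  Retained variants' frequencies are recomputed over the
    retained total (set ``renormalize=False`` to keep the pre-filter
    denominator).  Idempotent: surviving variants can only gain frequency.
    """
    if any(v.read_count < 0 for v in variants):
        raise ValueError("read counts must be non-negative")
    total = sum(v.read_count for v in variants)
    if total == 0:
        raise NoCallError("no reads at this line/locus")
    kept = [v for v in variants if v.read_count / total >= min_freq]
    if not kept:
        raise NoCallError("all variants below the frequency floor: no-call")
    denom = sum(v.read_count for v in kept) if renormalize else total
    for v in kept:
        v.frequency = v.read_count / denom
    return kept


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 2
_aligner.mismatch_score = -1
# Biopython charges the open score on the first gap base, so open -5 /
# extend -1 realises a gap-length-k penalty of 4 + k.
_aligner.open_gap_score = -5
_aligner.extend_gap_score = -1


def classify_variant(
    target: TargetSpec,
    variant_seq: str,
) -> tuple[str, list[tuple], int]:
    """Align one variant to the reference amplicon and classify it.

    Returns (mutation_class, substitutions, length_delta) where
    mutation_class is one of wildtype / substitution / indel / complex.
    Each substitution is (position, ref_base, alt_base, in_protospacer);
    the position is a protospacer coordinate (1 = PAM-distal) when inside
    the protospacer, otherwise the 1-based amplicon coordinate flagged with
    ``in_protospacer=False``.  'complex' means gaps plus mismatches and is
    counted as indel-containing downstream.
    """
    variant_seq = variant_seq.upper()
    if not variant_seq:
        raise ValueError("empty variant sequence")
    bad = set(variant_seq) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters in variant: {sorted(bad)}")

    ref = target.reference_amplicon
    length_delta = len(variant_seq) - len(ref)
    if variant_seq == ref:
        return "wildtype", [], 0

    aln = next(iter(_aligner.align(ref, variant_seq)))
    ref_aln, var_aln = str(aln[0]), str(aln[1])

    substitutions: list[tuple] = []
    n_gaps = 0
    ref_pos = 0
    for r, v in zip(ref_aln, var_aln):
        if r != "-":
            ref_pos += 1
        if r == "-" or v == "-":
            n_gaps += 1
            continue
        if r != v:
            coord = target.protospacer_coord(ref_pos)
            if coord is None:
                substitutions.append((ref_pos, r, v, False))
            else:
                ref_base = r if target.spacer_strand == "+" else _revcomp(r)
                alt_base = v if target.spacer_strand == "+" else _revcomp(v)
                substitutions.append((coord, ref_base, alt_base, True))

    if n_gaps and substitutions:
        cls = "complex"
    elif n_gaps:
        cls = "indel"
    else:
        cls = "substitution"
    return cls, substitutions, length_delta


def locus_mutation_frequency(variants: list[VariantRecord]) -> tuple[float, float]:
    """Cumulative non-wildtype frequency and indel-class frequency.

    Call after filtering and classification; frequencies must sum to 1.
    """
    total = sum(v.frequency for v in variants)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"variant frequencies sum to {total}, expected 1")
    mut = sum(v.frequency for v in variants if v.mutation_class != "wildtype")
    indel = sum(v.frequency for v in variants if v.mutation_class in ("indel", "complex"))
    return mut, indel


def classify_zygosity(mutation_frequency: float) -> str:
    """Zygosity from cumulative mutation frequency.

    >0.90 homozygous; [0.20, 0.90] heterozygous; (0, 0.20) chimeric;
    exactly 0 wildtype.  'Exceeds 90%' is strict, so 0.90 itself is
    heterozygous.
    """
    f = mutation_frequency
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"mutation frequency {f} outside [0, 1]")
    if f > 0.90:
        return "homozygous"
    if f >= 0.20:
        return "heterozygous"
    if f > 0.0:
        return "chimeric"
    return "wildtype"


def call_locus(
    line_id: str,
    locus_id: str,
    variants: list[VariantRecord],
) -> LocusCall:
    """LocusCall from filtered, classified variants at one line/locus."""
    mut, indel = locus_mutation_frequency(variants)
    return LocusCall(
        line_id=line_id,
        locus_id=locus_id,
        mutation_frequency=mut,
        zygosity=classify_zygosity(mut),
        has_indel_call=indel > 0,
        indel_frequency=indel,
    )


def call_line(
    locus_calls: list[LocusCall],
    indel_threshold: float = 0.20,
    indel_rule: str = "threshold",
) -> LineCall:
    """Roll locus calls up to one line call.

    edited: any locus heterozygous or homozygous (chimeric-only lines are
    not edited).  homozygous: any locus homozygous.  indel_line: under the
    default 'threshold' rule, some locus's cumulative indel-class frequency
    alone reaches ``indel_threshold`` (heterozygous-or-better on the indel
    class); under 'any', any indel-class variant present.
    """
    if not locus_calls:
        raise ValueError("need at least one locus call")
    edited = any(c.zygosity in ("heterozygous", "homozygous") for c in locus_calls)
    homozygous = any(c.zygosity == "homozygous" for c in locus_calls)
    if indel_rule == "threshold":
        indel_line = any(c.indel_frequency >= indel_threshold for c in locus_calls)
    elif indel_rule == "any":
        indel_line = any(c.has_indel_call for c in locus_calls)
    else:
        raise ValueError("indel_rule must be 'threshold' or 'any'")
    return LineCall(
        line_id=locus_calls[0].line_id,
        locus_calls=locus_calls,
        edited=edited,
        homozygous=homozygous,
        indel_line=indel_line,
    )


def summarize_cohort(line_calls: list[LineCall], construct_id: str = "") -> CohortSummary:
    """Cohort rates as percentages of genotyped lines, one decimal,
    rounded half away from zero."""
    if not line_calls:
        raise ValueError("need at least one line call")
    n = len(line_calls)
    n_edited = sum(c.edited for c in line_calls)
    n_homo = sum(c.homozygous for c in line_calls)
    n_indel = sum(c.indel_line for c in line_calls)
    return CohortSummary(
        construct_id=construct_id,
        n_genotyped=n,
        n_edited=n_edited,
        n_homozygous=n_homo,
        n_indel=n_indel,
        editing_efficiency=round_half_away(100.0 * n_edited / n),
        homozygous_rate=round_half_away(100.0 * n_homo / n),
        indel_rate=round_half_away(100.0 * n_indel / n),
    )


def genotype_cohort(
    variant_table: pd.DataFrame,
    targets: dict[str, TargetSpec],
    construct_id: str = "",
    min_freq: float = 0.01,
    indel_rule: str = "threshold",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, CohortSummary]:
    """Run the full genotyping pipeline on one cohort.

    Parameters
    ----------
    variant_table : columns line_id, locus_id, variant_seq, read_count.
    targets : locus_id -> TargetSpec for every locus in the table.

    Returns (per-variant frame, per-locus frame, per-line frame,
    CohortSummary).
    """
    required = {"line_id", "locus_id", "variant_seq", "read_count"}
    if not required <= set(variant_table.columns):
        raise ValueError(f"variant table needs columns {sorted(required)}")
    unknown = set(variant_table["locus_id"]) - set(targets)
    if unknown:
        raise ValueError(f"no TargetSpec for loci: {sorted(unknown)}")

    variant_rows = []
    locus_calls_by_line: dict[str, list[LocusCall]] = {}
    for (line_id, locus_id), grp in variant_table.groupby(
        ["line_id", "locus_id"], sort=True
    ):
        target = targets[locus_id]
        variants = [
            VariantRecord(line_id, locus_id, r.variant_seq, int(r.read_count))
            for r in grp.itertuples()
        ]
        kept = filter_low_frequency(variants, min_freq=min_freq)
        for v in kept:
            v.mutation_class, v.substitutions, v.length_delta = classify_variant(
                target, v.variant_seq
            )
            variant_rows.append(
                {
                    "line_id": v.line_id,
                    "locus_id": v.locus_id,
                    "variant_seq": v.variant_seq,
                    "read_count": v.read_count,
                    "frequency": v.frequency,
                    "mutation_class": v.mutation_class,
                    "substitutions": ";".join(
                        f"{p}{r}>{a}" + ("" if in_ps else "(amplicon)")
                        for p, r, a, in_ps in v.substitutions
                    ),
                    "length_delta": v.length_delta,
                }
            )
        call = call_locus(line_id, locus_id, kept)
        locus_calls_by_line.setdefault(line_id, []).append(call)

    line_calls = [
        call_line(calls, indel_rule=indel_rule)
        for _, calls in sorted(locus_calls_by_line.items())
    ]
    summary = summarize_cohort(line_calls, construct_id)

    locus_frame = pd.DataFrame(
        [
            {
                "line_id": c.line_id,
                "locus_id": c.locus_id,
                "mutation_frequency": c.mutation_frequency,
                "zygosity": c.zygosity,
                "has_indel_call": c.has_indel_call,
                "indel_frequency": c.indel_frequency,
            }
            for lc in line_calls
            for c in lc.locus_calls
        ]
    )
    line_frame = pd.DataFrame(
        [
            {
                "line_id": c.line_id,
                "edited": c.edited,
                "homozygous": c.homozygous,
                "indel_line": c.indel_line,
            }
            for c in line_calls
        ]
    )
    return pd.DataFrame(variant_rows), locus_frame, line_frame, summary


def load_targets(config_path: str | Path, amplicon_fasta: str | Path) -> dict[str, TargetSpec]:
    """TargetSpecs from a YAML config plus an amplicon FASTA.

    YAML: list of mappings with keys locus_id, spacer, protospacer_start,
    optionally spacer_strand and pam; amplicon sequences are looked up in
    the FASTA by locus_id.
    """
    amplicons = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(amplicon_fasta), "fasta")}
    with open(config_path) as fh:
        entries = yaml.safe_load(fh)
    targets = {}
    for e in entries:
        locus = e["locus_id"]
        if locus not in amplicons:
            raise ValueError(f"amplicon for {locus!r} not in FASTA")
        targets[locus] = TargetSpec(
            locus_id=locus,
            reference_amplicon=amplicons[locus],
            spacer=e["spacer"],
            protospacer_start=int(e["protospacer_start"]),
            spacer_strand=e.get("spacer_strand", "+"),
            pam=e.get("pam", "NGG"),
        )
    return targets
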