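"""Seeded synthetic-data generators with ground-truth manifests.

Each generator is a pure function of its arguments (including the seed)
and returns, alongside the data, a JSON-serialisable manifest recording
the planted truth, so recovery tests can verify pipeline output without
re-simulating.

Emulated inputs:

* a multi-tissue expression atlas with planted callus-specific genes,
* two-stage replicated expression matrices whose per-replicate top-N sets
  realise designed union/intersection sizes,
* per-line amplicon read populations with designed zygosity and indel
  outcomes plus sub-filter sequencing noise,
* promoters with motifs planted at known coordinates,
* a genome with off-target sites planted at known mismatch distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from calluscope.expression import ExpressionAtlas
from calluscope.genotyper import TargetSpec, classify_zygosity
from calluscope.motifs import IUPAC
from calluscope.offtarget import GuideSpec, enumerate_sites

__all__ = [
    "LineDesign",
    "simulate_expression_atlas",
    "simulate_staged_topsets",
    "simulate_amplicon_cohort",
    "simulate_promoters",
    "simulate_genome_with_offtargets",
]

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")

DEFAULT_TISSUES = ("callus", "root", "stem", "leaf", "flower", "peg", "kernel")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Expression atlas with planted callus-specific genes

def simulate_expression_atlas(
    n_genes: int = 2000,
    n_tissues: int = 7,
    n_replicates: int = 3,
    n_specific: int = 20,
    effect_fold: float = 100.0,
    seed: int = 0,
) -> tuple[ExpressionAtlas, dict]:
    """Multi-tissue FPKM atlas with ``n_specific`` planted callus genes.

    Background genes share a per-gene baseline drawn log-normally
    (log-mean 1, log-sd 1.5) across all tissues, so they are never
    tissue-specific.  Planted genes get a sub-threshold level in non-callus
    tissues (uniform 0.25-0.5 FPKM) and ``effect_fold`` times that level in
    callus.  Replicate noise is multiplicative log-normal (log-sd 0.2).
    """
    if not 0 <= n_specific <= n_genes:
        raise ValueError("need 0 <= n_specific <= n_genes")
    if n_tissues < 2 or n_replicates < 1:
        raise ValueError("need >= 2 tissues and >= 1 replicate")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    tissues = list(DEFAULT_TISSUES[:n_tissues])
    if len(tissues) < n_tissues:
        tissues += [f"tissue{i}" for i in range(len(tissues), n_tissues)]

    baseline = np.exp(rng.normal(1.0, 1.5, size=n_genes))
    mean_expr = np.tile(baseline[:, None], (1, n_tissues))

    specific_idx = rng.choice(n_genes, size=n_specific, replace=False)
    other_level = rng.uniform(0.25, 0.5, size=n_specific)
    mean_expr[specific_idx, :] = other_level[:, None]
    mean_expr[specific_idx, 0] = other_level * effect_fold  # tissues[0] == callus

    samples, tissue_of = [], {}
    cols = []
    for t in tissues:
        for r in range(1, n_replicates + 1):
            sid = f"{t}_rep{r}"
            samples.append(sid)
            tissue_of[sid] = t
            cols.append(tissues.index(t))
    noise = np.exp(rng.normal(0.0, 0.2, size=(n_genes, len(samples))))
    values = pd.DataFrame(mean_expr[:, cols] * noise, index=genes, columns=samples)

    atlas = ExpressionAtlas(values=values, tissue_of=tissue_of)
    manifest = {
        "seed": int(seed),
        "kind": "expression_atlas",
        "callus_tissue": tissues[0],
        "planted_specific_genes": sorted(genes[i] for i in specific_idx),
        "effect_fold": float(effect_fold),
    }
    return atlas, manifest


# ---------------------------------------------------------------------------
# Two-stage top-N set construction

def simulate_staged_topsets(
    top_n: int = 400,
    stage_union_sizes: tuple[int, int] = (487, 453),
    overlap: int = 419,
    n_replicates: int = 3,
    n_genes: int = 2000,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Two stages of replicated expression with designed top-N set algebra.

    Constructs per-replicate expression columns whose top-``top_n`` sets
    union to exactly ``stage_union_sizes`` genes per stage, with exactly
    ``overlap`` genes shared between the two stage unions.  Designed genes
    carry large distinct values; background genes small distinct values, so
    the top-N cut is tie-free.
    """
    u1, u2 = stage_union_sizes
    if not (top_n <= u1 <= 2 * top_n and top_n <= u2 <= 2 * top_n):
        raise ValueError("union sizes must lie in [top_n, 2*top_n] for this construction")
    if overlap > min(u1, u2):
        raise ValueError("overlap cannot exceed either union size")
    extra2 = u2 - overlap
    if n_genes < u1 + extra2:
        raise ValueError("n_genes too small for the requested sets")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates to realise union size > top_n")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]

    union1 = genes[:u1]
    union2 = genes[:overlap] + genes[u1 : u1 + extra2]

    def replicate_sets(union: list[str]) -> list[list[str]]:
        u = len(union)
        reps = [union[:top_n], union[u - top_n :]]
        while len(reps) < n_replicates:
            reps.append(union[:top_n])
        return reps

    stages = {}
    manifest_sets = {}
    for stage, union in (("t5", union1), ("t11", union2)):
        cols = {}
        for r, top_set in enumerate(replicate_sets(union), start=1):
            vals = pd.Series(rng.uniform(0.0, 1.0, size=n_genes), index=genes)
            # designed genes strictly dominate background; distinct ranks
            vals.loc[top_set] = 1e4 - np.arange(len(top_set))
            cols[f"{stage}_rep{r}"] = vals
        stages[stage] = pd.DataFrame(cols)
        manifest_sets[stage] = sorted(union)

    manifest = {
        "seed": int(seed),
        "kind": "staged_topsets",
        "top_n": int(top_n),
        "stage_unions": manifest_sets,
        "expected_union_sizes": {"t5": u1, "t11": u2},
        "expected_intersection_size": int(overlap),
    }
    return stages, manifest


# ---------------------------------------------------------------------------
# Amplicon cohort with designed editing outcomes

@dataclass
class LineDesign:
    """Designed outcome for one line: zygosity class per locus and whether
    its edits are indels (1-bp deletions) rather than C-to-T substitutions."""

    line_id: str
    zygosity: dict[str, str]  # locus_id -> class
    indel: bool = False

    def __post_init__(self) -> None:
        valid = {"wildtype", "chimeric", "heterozygous", "homozygous"}
        bad = set(self.zygosity.values()) - valid
        if bad:
            raise ValueError(f"unknown zygosity class(es): {sorted(bad)}")


_CLASS_RANGES = {
    "homozygous": (0.91, 1.0),
    "heterozygous": (0.20, 0.90),
    "chimeric": (0.01, 0.19),
}


def _edited_sequence(target: TargetSpec, indel: bool, edit_position: int = 5) -> str:
    """The designed edited allele: C->T at protospacer ``edit_position``
    (falling back to any substitution if the reference base is not C), or a
    1-bp deletion at that position when ``indel``."""
    ref = target.reference_amplicon
    if target.spacer_strand == "+":
        amp_pos = target.protospacer_start + edit_position - 1
    else:
        amp_pos = target.protospacer_start - edit_position + 1
    i = amp_pos - 1
    if indel:
        return ref[:i] + ref[i + 1 :]
    base = ref[i]
    if target.spacer_strand == "+":
        alt = "T" if base == "C" else ("A" if base == "T" else "T")
    else:
        alt = "A" if base == "G" else ("T" if base == "A" else "A")
    return ref[:i] + alt + ref[i + 1 :]


def _noise_variants(
    rng: np.random.Generator,
    target: TargetSpec,
    total_main: int,
    noise_rate: float,
    forbidden: set[str],
) -> list[tuple[str, int]]:
    """Noise variants, each strictly below 1% of the final read total.

    Noise reads make up about ``noise_rate`` of the main read total; each
    variant is a single random substitution outside the protospacer.
    """
    target_reads = int(round(noise_rate * total_main))
    if target_reads == 0:
        return []
    ref = target.reference_amplicon
    proto = {
        (target.protospacer_start + i) if target.spacer_strand == "+" else (target.protospacer_start - i)
        for i in range(20)
    }
    cap = max(1, total_main // 100 - 1)  # < 1% of any total >= total_main
    out: list[tuple[str, int]] = []
    remaining = target_reads
    attempts = 0
    while remaining > 0 and attempts < 1000:
        attempts += 1
        pos = int(rng.integers(1, len(ref) + 1))
        if pos in proto:
            continue
        base = ref[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != base]))
        seq = ref[: pos - 1] + alt + ref[pos:]
        if seq in forbidden:
            continue
        count = int(min(remaining, rng.integers(1, cap + 1)))
        out.append((seq, count))
        forbidden.add(seq)
        remaining -= count
    return out


def simulate_amplicon_cohort(
    targets: list[TargetSpec],
    line_designs: list[LineDesign],
    depth: int = 5000,
    noise_rate: float = 0.0,
    seed: int = 0,
    edit_position: int = 5,
    max_retries: int = 200,
) -> tuple[pd.DataFrame, dict]:
    """Per-line amplicon read tables realising designed outcomes.

    For each line/locus a design frequency is drawn uniformly from the
    designed zygosity class's range (homozygous 0.91-1.0, heterozygous
    0.20-0.90, chimeric 0.01-0.19, wildtype 0) and read counts are drawn
    multinomially over {wildtype allele, edited allele} at ``depth``.
    The draw is rejection-sampled until the realised post-filter frequency
    falls in the designed class, so the manifest truth is recoverable by
    the genotyper at any seed.  Noise variants are single substitutions
    outside the protospacer, each strictly below the 1% filter.

    Returns (variant table, manifest).  The table has columns
    line_id, locus_id, variant_seq, read_count.
    """
    if depth < 100:
        raise ValueError("depth must be >= 100")
    rng = np.random.default_rng(seed)
    target_of = {t.locus_id: t for t in targets}
    rows = []
    truth_lines = []
    for design in line_designs:
        locus_truth = {}
        for locus_id, zyg in design.zygosity.items():
            target = target_of[locus_id]
            ref = target.reference_amplicon
            edited_seq = _edited_sequence(target, design.indel, edit_position)
            if zyg == "wildtype":
                main = [(ref, depth)]
                realized = 0.0
            else:
                lo, hi = _CLASS_RANGES[zyg]
                for _ in range(max_retries):
                    f = float(rng.uniform(lo, hi))
                    n_edit = int(rng.binomial(depth, f))
                    n_wt = depth - n_edit
                    noise = _noise_variants(
                        rng, target, depth, noise_rate, {ref, edited_seq}
                    )
                    total = depth + sum(c for _, c in noise)
                    kept = [c for c in (n_wt, n_edit) if c / total >= 0.01]
                    kept_edit = n_edit if n_edit / total >= 0.01 else 0
                    realized = kept_edit / sum(kept) if kept else 0.0
                    if classify_zygosity(realized) == zyg:
                        break
                else:
                    raise RuntimeError(
                        f"could not realise class {zyg!r} at depth {depth}"
                    )
                main = [(ref, n_wt), (edited_seq, n_edit)]
                main = [(s, c) for s, c in main if c > 0]
                main += noise
            if zyg == "wildtype" and noise_rate > 0:
                noise = _noise_variants(rng, target, depth, noise_rate, {ref})
                main = main + noise
            for seq, count in main:
                rows.append(
                    {
                        "line_id": design.line_id,
                        "locus_id": locus_id,
                        "variant_seq": seq,
                        "read_count": count,
                    }
                )
            locus_truth[locus_id] = {
                "designed_zygosity": zyg,
                "realized_frequency": realized,
            }
        classes = set(design.zygosity.values())
        edited = bool(classes & {"heterozygous", "homozygous"})
        truth_lines.append(
            {
                "line_id": design.line_id,
                "loci": locus_truth,
                "edited": edited,
                "homozygous": "homozygous" in classes,
                "indel_line": design.indel and edited,
            }
        )
    table = pd.DataFrame(rows, columns=["line_id", "locus_id", "variant_seq", "read_count"])
    manifest = {
        "seed": int(seed),
        "kind": "amplicon_cohort",
        "depth": int(depth),
        "noise_rate": float(noise_rate),
        "lines": truth_lines,
        "expected_counts": {
            "n_genotyped": len(truth_lines),
            "n_edited": sum(t["edited"] for t in truth_lines),
            "n_homozygous": sum(t["homozygous"] for t in truth_lines),
            "n_indel": sum(t["indel_line"] for t in truth_lines),
        },
    }
    return table, manifest


def design_cohort_from_counts(
    construct_id: str,
    n_genotyped: int,
    n_edited: int,
    n_homozygous: int,
    n_indel: int,
    loci: tuple[str, ...] = ("AhALS2-A", "AhALS2-B"),
) -> list[LineDesign]:
    """Line designs realising given cohort counts.

    The first ``n_homozygous`` edited lines are homozygous at the first
    locus, the rest heterozygous; the first ``n_indel`` edited lines carry
    their edit as a 1-bp deletion so they count as indel lines.  Requires
    n_indel <= n_edited (an un-edited line cannot reach the indel-line
    threshold).
    """
    if not n_homozygous <= n_edited <= n_genotyped:
        raise ValueError("need n_homozygous <= n_edited <= n_genotyped")
    if n_indel > n_edited:
        raise ValueError("indel lines must be edited lines under the threshold rule")
    designs = []
    for i in range(n_genotyped):
        if i < n_homozygous:
            zyg = "homozygous"
        elif i < n_edited:
            zyg = "heterozygous"
        else:
            zyg = "wildtype"
        zygosity = {loci[0]: zyg}
        for other in loci[1:]:
            zygosity[other] = "wildtype"
        designs.append(
            LineDesign(
                line_id=f"{construct_id}_line{i + 1:03d}",
                zygosity=zygosity,
                indel=i < n_indel and zyg != "wildtype",
            )
        )
    return designs


def make_demo_targets(seed: int = 0) -> list[TargetSpec]:
    """Two synthetic homoeologous amplicon targets (A/B-subgenome style)."""
    rng = np.random.default_rng(seed)
    spacer = "".join(rng.choice(list("ACGT"), size=20))
    # ensure a C at protospacer position 5 so the designed edit is C->T
    spacer = spacer[:4] + "C" + spacer[5:]
    targets = []
    for name in ("AhALS2-A", "AhALS2-B"):
        left = "".join(rng.choice(list("ACGT"), size=60))
        right = "".join(rng.choice(list("ACGT"), size=60))
        amplicon = left + spacer + "AGG" + right
        targets.append(
            TargetSpec(
                locus_id=name,
                reference_amplicon=amplicon,
                spacer=spacer,
                protospacer_start=len(left) + 1,
                spacer_strand="+",
            )
        )
    return targets


# ---------------------------------------------------------------------------
# Promoters with planted motifs

def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    """A concrete DNA realisation of an IUPAC pattern."""
    out = []
    for code in pattern.upper():
        choices = sorted(IUPAC[code])
        out.append(str(rng.choice(choices)))
    return "".join(out)


def simulate_promoters(
    n: int = 10,
    length: int = 2000,
    planted: list[tuple[str, int, str]] | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], dict]:
    """Uniform-ACGT promoters with motifs planted at stated coordinates.

    ``planted`` is a list of (iupac_pattern, 1-based start, strand) applied
    to every promoter; minus-strand plantings write the reverse complement
    of a concrete pattern instance.  Overlapping plantings are an error.

    Returns ({promoter_id: sequence}, manifest).
    """
    planted = planted or []
    rng = np.random.default_rng(seed)
    intervals = []
    for pattern, pos, strand in planted:
        m = len(pattern)
        if pos < 1 or pos + m - 1 > length:
            raise ValueError(f"planted motif {pattern!r} at {pos} does not fit in {length} bp")
        if strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        intervals.append((pos, pos + m - 1))
    intervals.sort()
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            raise ValueError("planted motifs overlap")

    promoters = {}
    truth = []
    for i in range(n):
        pid = f"promoter{i + 1:02d}"
        seq = list("".join(rng.choice(_BASES, size=length)))
        for pattern, pos, strand in planted:
            inst = _instantiate(pattern, rng)
            if strand == "-":
                inst = _revcomp(inst)
            seq[pos - 1 : pos - 1 + len(inst)] = inst
            truth.append(
                {
                    "promoter_id": pid,
                    "pattern": pattern,
                    "start": pos,
                    "end": pos + len(pattern) - 1,
                    "strand": strand,
                }
            )
        promoters[pid] = "".join(seq)
    manifest = {"seed": int(seed), "kind": "promoters", "planted": truth}
    return promoters, manifest


# ---------------------------------------------------------------------------
# Genome with planted off-target sites

def simulate_genome_with_offtargets(
    spacer: str,
    planted_mismatch_counts: list[int] = [0, 1, 2, 3, 4],
    length: int = 100_000,
    seed: int = 0,
    pam: str = "AGG",
    max_mismatches: int = 4,
    max_retries: int = 50,
) -> tuple[dict[str, str], dict]:
    """Random genome containing exactly the designed off-target sites.

    Each planted site is the spacer mutated at exactly the designed number
    of random positions, followed by an NGG PAM, placed at a random
    non-overlapping position on a random strand.  The genome is
    rejection-sampled until a full scan finds no accidental extra site
    within ``max_mismatches``, so the manifest is the complete truth.
    """
    spacer = spacer.upper()
    if len(spacer) != 20:
        raise ValueError("spacer must be 20 nt")
    site_len = len(spacer) + len(pam)
    if length < (site_len + 10) * (len(planted_mismatch_counts) + 1):
        raise ValueError("genome too short for the requested plantings")
    guide = GuideSpec(spacer=spacer, max_mismatches=max_mismatches)

    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        seq = list("".join(rng.choice(_BASES, size=length)))
        placed: list[tuple[int, int]] = []
        truth = []
        for mm in planted_mismatch_counts:
            site = list(spacer)
            pos_mut = rng.choice(20, size=mm, replace=False)
            for p in pos_mut:
                site[p] = str(rng.choice([b for b in "ACGT" if b != site[p]]))
            insert = "".join(site) + pam
            strand = str(rng.choice(["+", "-"]))
            if strand == "-":
                insert = _revcomp(insert)
            for _ in range(200):
                start = int(rng.integers(0, length - site_len))
                if all(start + site_len <= s or start >= e for s, e in placed):
                    break
            else:
                raise RuntimeError("could not place planted site without overlap")
            seq[start : start + site_len] = insert
            placed.append((start, start + site_len))
            if strand == "+":
                s, e = start + 1, start + 20
            else:
                s, e = start + len(pam) + 1, start + site_len
            truth.append(
                {
                    "start": s,
                    "end": e,
                    "strand": strand,
                    "n_mismatches": int(mm),
                }
            )
        genome = {"chr_synth": "".join(seq)}
        found = enumerate_sites(genome, guide)
        # decoys planted beyond the budget must stay invisible to the scan
        expected = {
            (t["start"], t["end"], t["strand"])
            for t in truth
            if t["n_mismatches"] <= max_mismatches
        }
        actual = {(s.start, s.end, s.strand) for s in found}
        if actual == expected and all(
            s.n_mismatches
            == next(
                t["n_mismatches"]
                for t in truth
                if (t["start"], t["end"], t["strand"]) == (s.start, s.end, s.strand)
            )
            for s in found
        ):
            manifest = {
                "seed": int(seed),
                "kind": "offtarget_genome",
                "spacer": spacer,
                "seq_id": "chr_synth",
                "planted": truth,
            }
            return genome, manifest
    raise RuntimeError("could not build a collision-free genome; try another seed")
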