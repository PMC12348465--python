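"""Cis-regulatory element scanning with an IUPAC consensus catalog.

Promoters are scanned on both strands against a catalog of plant
cis-element consensi (TATA-box, CAAT-box, light-, hormone- and
stress-responsive elements).  The catalog is configuration — a TSV of
(name, iupac_pattern, category) — so element definitions can be edited
without touching code.  The shipped default covers the elements commonly
reported for plant promoters.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "IUPAC",
    "MotifCatalog",
    "MotifHit",
    "iupac_matches",
    "scan_promoter",
    "summarize_elements",
    "load_catalog",
    "default_catalog",
    "extract_promoter",
    "hits_to_frame",
    "hits_to_bed",
]

# IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

CATEGORIES = ("core", "light", "hormone", "stress")


@dataclass(frozen=True)
class MotifHit:
    """One cis-element match; coordinates 1-based inclusive, forward strand."""

    promoter_id: str
    motif_name: str
    strand: str
    start: int
    end: int
    matched_seq: str


@dataclass
class MotifCatalog:
    """Catalog of (name, IUPAC pattern, category) cis-element consensi."""

    entries: pd.DataFrame  # columns: name, pattern, category

    def __post_init__(self) -> None:
        required = {"name", "pattern", "category"}
        if not required <= set(self.entries.columns):
            raise ValueError(f"catalog needs columns {sorted(required)}")
        if self.entries["name"].duplicated().any():
            raise ValueError("catalog motif names must be unique")
        for _, row in self.entries.iterrows():
            pat = row["pattern"]
            if not pat:
                raise ValueError(f"empty pattern for motif {row['name']!r}")
            bad = set(pat.upper()) - set(IUPAC)
            if bad:
                raise ValueError(
                    f"invalid IUPAC code(s) {sorted(bad)} in pattern for {row['name']!r}"
                )

    @property
    def category_of(self) -> dict[str, str]:
        return dict(zip(self.entries["name"], self.entries["category"]))

    def __len__(self) -> int:
        return len(self.entries)


def _validate_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC code(s): {sorted(bad)}")
    if not pattern:
        raise ValueError("empty pattern")
    return pattern


def iupac_matches(pattern: str, seq: str) -> list[int]:
    """1-based start positions where ``pattern`` matches ``seq``.

    Overlapping matches are all reported.  An ``N`` in the *sequence* is
    treated as unknown and matches no pattern symbol (conservative), while
    ``N`` in the pattern matches any concrete base.
    """
    pattern = _validate_pattern(pattern)
    seq = seq.upper()
    sets = [IUPAC[c] for c in pattern]
    m, n = len(pattern), len(seq)
    out = []
    for i in range(n - m + 1):
        window = seq[i : i + m]
        if all(base in s for base, s in zip(window, sets)):
            out.append(i + 1)
    return out


def scan_promoter(
    seq: str,
    catalog: MotifCatalog,
    promoter_id: str = "promoter",
) -> list[MotifHit]:
    """Scan both strands of one promoter against the catalog.

    Minus-strand hits are reported with forward-strand coordinates; a hit's
    ``matched_seq`` is the forward-strand slice, which reverse-complements
    to a string satisfying the pattern when strand is '-'.
    Hits are sorted by (start, motif_name, strand).
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    seq = seq.upper()
    L = len(seq)
    if L == 0:
        return []
    rc = str(Seq(seq).reverse_complement())
    hits: list[MotifHit] = []
    for _, row in catalog.entries.iterrows():
        name, pattern = row["name"], row["pattern"].upper()
        m = len(pattern)
        for p in iupac_matches(pattern, seq):
            hits.append(MotifHit(promoter_id, name, "+", p, p + m - 1, seq[p - 1 : p + m - 1]))
        for p in iupac_matches(pattern, rc):
            # map reverse-complement coordinates back to the forward strand
            start = L - (p + m - 1) + 1
            end = L - p + 1
            hits.append(MotifHit(promoter_id, name, "-", start, end, seq[start - 1 : end]))
    hits.sort(key=lambda h: (h.start, h.motif_name, h.strand))
    return hits


def summarize_elements(
    hits: list[MotifHit],
    catalog: MotifCatalog,
) -> pd.DataFrame:
    """Per-promoter, per-category hit counts; one row per promoter."""
    categories = list(dict.fromkeys(catalog.entries["category"]))
    cat_of = catalog.category_of
    promoters = sorted({h.promoter_id for h in hits})
    table = pd.DataFrame(0, index=promoters, columns=categories, dtype=int)
    for h in hits:
        table.loc[h.promoter_id, cat_of[h.motif_name]] += 1
    table.index.name = "promoter_id"
    return table


def load_catalog(path: str | Path) -> MotifCatalog:
    return MotifCatalog(pd.read_csv(path, sep="\t"))


def default_catalog() -> MotifCatalog:
    """The shipped plant cis-element catalog (PLACE/PlantCARE-style consensi)."""
    with resources.files("calluscope.data").joinpath("cis_element_catalog.tsv").open() as fh:
        return MotifCatalog(pd.read_csv(fh, sep="\t"))


def extract_promoter(
    genome_seq: str,
    cds_start: int,
    strand: str = "+",
    length: int = 2000,
) -> str:
    """Sequence upstream of a start codon (default ~2000 bp).

    ``cds_start`` is the 1-based position of the first base of the start
    codon on the given strand.  Truncates at the contig edge.
    """
    if strand == "+":
        lo = max(0, cds_start - 1 - length)
        return genome_seq[lo : cds_start - 1]
    if strand == "-":
        hi = min(len(genome_seq), cds_start + length)
        return str(Seq(genome_seq[cds_start:hi]).reverse_complement())
    raise ValueError("strand must be '+' or '-'")


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "promoter_id": h.promoter_id,
                "motif_name": h.motif_name,
                "strand": h.strand,
                "start": h.start,
                "end": h.end,
                "matched_seq": h.matched_seq,
            }
            for h in hits
        ],
        columns=["promoter_id", "motif_name", "strand", "start", "end", "matched_seq"],
    )


def hits_to_bed(hits: list[MotifHit]) -> pd.DataFrame:
    """BED6: 0-based half-open coordinates."""
    return pd.DataFrame(
        [
            {
                "chrom": h.promoter_id,
                "chromStart": h.start - 1,
                "chromEnd": h.end,
                "name": h.motif_name,
                "score": 0,
                "strand": h.strand,
            }
            for h in hits
        ],
        columns=["chrom", "chromStart", "chromEnd", "name", "score", "strand"],
    )
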