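"""Candidate sgRNA off-target site enumeration and ranking.

Every 20-mer immediately 5' of a PAM match (NGG/NAG for SpCas9), on either
strand, whose Hamming distance to the spacer is within a mismatch budget
is reported.  Sites are scored with multiplicative per-position penalties
weighted toward the PAM-proximal seed region, where mismatches disrupt
Cas9 binding most, and the top-k highest-scoring sites (the ones worth
validating by amplicon sequencing) are returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from calluscope.motifs import IUPAC

logger = logging.getLogger(__name__)

__all__ = [
    "GuideSpec",
    "OffTargetSite",
    "enumerate_sites",
    "score_site",
    "rank_sites",
    "default_weights",
    "sites_to_frame",
]

_BASE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = str.maketrans("ACGTN", "TGCAN")


def default_weights() -> np.ndarray:
    """PAM-proximal-heavy penalty profile.

    Protospacer positions 1-12 (PAM-distal) weigh 0.1, positions 13-20
    (the seed) weigh 0.3: a seed mismatch costs a 0.7x score factor, a
    distal one 0.9x.
    """
    w = np.full(20, 0.1)
    w[12:] = 0.3
    return w


@dataclass
class GuideSpec:
    """Spacer plus the PAMs it tolerates and a mismatch budget."""

    spacer: str
    pam_patterns: tuple[str, ...] = ("NGG", "NAG")
    max_mismatches: int = 4

    def __post_init__(self) -> None:
        self.spacer = self.spacer.upper()
        if len(self.spacer) != 20:
            raise ValueError("spacer must be 20 nt")
        if set(self.spacer) - set("ACGT"):
            raise ValueError("spacer must be unambiguous DNA")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        self.pam_patterns = tuple(p.upper() for p in self.pam_patterns)
        for p in self.pam_patterns:
            bad = set(p) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC in PAM pattern {p!r}: {sorted(bad)}")


@dataclass
class OffTargetSite:
    """A protospacer-like site; coordinates 1-based inclusive on the
    forward strand of ``seq_id`` and covering the 20-mer (PAM excluded)."""

    seq_id: str
    start: int
    end: int
    strand: str
    site_seq: str
    pam_seq: str
    n_mismatches: int
    mismatch_positions: list[int] = field(default_factory=list)
    score: float = float("nan")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _pam_mask(seq_arr: np.ndarray, pam: str) -> np.ndarray:
    """Boolean mask over start positions where ``pam`` matches ``seq``."""
    n, m = len(seq_arr), len(pam)
    if n < m:
        return np.zeros(0, dtype=bool)
    mask = np.ones(n - m + 1, dtype=bool)
    for off, code in enumerate(pam):
        allowed = np.frombuffer("".join(sorted(IUPAC[code])).encode(), dtype=np.uint8)
        mask &= np.isin(seq_arr[off : off + n - m + 1], allowed)
    return mask


def _scan_strand(
    seq: str,
    seq_id: str,
    guide: GuideSpec,
    strand: str,
    forward_len: int,
) -> list[OffTargetSite]:
    """Scan one strand's sequence string (already reverse-complemented for
    '-') and map hits back to forward-strand coordinates."""
    k = len(guide.spacer)
    arr = _encode(seq)
    n = len(arr)
    spacer_arr = _encode(guide.spacer)
    sites: list[OffTargetSite] = []
    pam_len = len(guide.pam_patterns[0])
    if any(len(p) != pam_len for p in guide.pam_patterns):
        raise ValueError("all PAM patterns must share one length")
    if n < k + pam_len:
        return sites

    pam_any = np.zeros(n - pam_len + 1, dtype=bool)
    for p in guide.pam_patterns:
        pam_any |= _pam_mask(arr, p)

    # windows[i] is the 20-mer starting at i; its PAM starts at i + k
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    n_start = n - k - pam_len + 1
    mismatches = (windows[:n_start] != spacer_arr).sum(axis=1)
    valid = (mismatches <= guide.max_mismatches) & pam_any[k : k + n_start]
    # windows containing N never match (N encodes as its own byte, so it
    # always counts as a mismatch against an unambiguous spacer)
    for i in np.nonzero(valid)[0]:
        site_seq = seq[i : i + k]
        pam_seq = seq[i + k : i + k + pam_len]
        mm_pos = [j + 1 for j in range(k) if site_seq[j] != guide.spacer[j]]
        if strand == "+":
            start, end = i + 1, i + k
        else:
            # position i on the reverse complement maps to forward-strand
            # interval [L - i - k + 1, L - i]
            start, end = forward_len - i - k + 1, forward_len - i
        sites.append(
            OffTargetSite(
                seq_id=seq_id,
                start=start,
                end=end,
                strand=strand,
                site_seq=site_seq,
                pam_seq=pam_seq,
                n_mismatches=int(mismatches[i]),
                mismatch_positions=mm_pos,
            )
        )
    return sites


def enumerate_sites(
    sequences: dict[str, str],
    guide: GuideSpec,
    weights: np.ndarray | None = None,
    nag_multiplier: float = 0.5,
) -> list[OffTargetSite]:
    """All candidate sites in a sequence set, scored.

    Parameters
    ----------
    sequences : map seq_id -> DNA string (e.g. parsed from FASTA).
    guide : spacer, PAM set, mismatch budget.
    weights : per-position penalty vector for scoring (default profile
        when None).
    nag_multiplier : score multiplier applied to sites whose PAM is NAG
        rather than NGG (SpCas9 tolerates NAG weakly).

    Sequences shorter than spacer+PAM are skipped with a log message.
    Sites are sorted by (seq_id, start, strand).
    """
    if not sequences:
        raise ValueError("no sequences to scan")
    if weights is None:
        weights = default_weights()
    pam_len = len(guide.pam_patterns[0])
    sites: list[OffTargetSite] = []
    for seq_id, seq in sequences.items():
        seq = seq.upper()
        if len(seq) < len(guide.spacer) + pam_len:
            logger.info("sequence %s shorter than spacer+PAM: skipped", seq_id)
            continue
        rc = seq.translate(_COMP)[::-1]
        sites.extend(_scan_strand(seq, seq_id, guide, "+", len(seq)))
        sites.extend(_scan_strand(rc, seq_id, guide, "-", len(seq)))
    for s in sites:
        s.score = score_site(guide.spacer, s, weights)
        if s.pam_seq[-2:] == "AG":
            s.score *= nag_multiplier
    sites.sort(key=lambda s: (s.seq_id, s.start, s.strand))
    return sites


def score_site(spacer: str, site: OffTargetSite, weights: np.ndarray) -> float:
    """Multiplicative penalty score in [0, 1].

    score = prod over mismatched positions p of (1 - weights[p-1]);
    a perfect match scores 1.0 and every added mismatch can only lower it.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(spacer):
        raise ValueError("weights length must equal spacer length")
    if ((weights < 0) | (weights > 1)).any():
        raise ValueError("weights must lie in [0, 1]")
    score = 1.0
    for p in site.mismatch_positions:
        score *= 1.0 - weights[p - 1]
    return float(score)


def rank_sites(
    sites: list[OffTargetSite],
    k: int = 3,
    exclude_on_target: bool = True,
) -> list[OffTargetSite]:
    """Top-k sites by descending score.

    Ties break by (fewer mismatches, seq_id, start, strand).  Perfect-match
    sites (the intended target) are excluded by default so the list holds
    candidates for off-target validation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pool = [s for s in sites if not (exclude_on_target and s.n_mismatches == 0)]
    pool.sort(key=lambda s: (-s.score, s.n_mismatches, s.seq_id, s.start, s.strand))
    return pool[:k]


def sites_to_frame(sites: list[OffTargetSite]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "seq_id": s.seq_id,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "site_seq": s.site_seq,
                "pam_seq": s.pam_seq,
                "n_mismatches": s.n_mismatches,
                "mismatch_positions": ",".join(map(str, s.mismatch_positions)),
                "score": s.score,
            }
            for s in sites
        ],
        columns=[
            "seq_id",
            "start",
            "end",
            "strand",
            "site_seq",
            "pam_seq",
            "n_mismatches",
            "mismatch_positions",
            "score",
        ],
    )
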