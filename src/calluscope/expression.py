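"""Screening expression data for callus-specific genes.

The screen mirrors how tissue-specific promoter candidates are mined from
bulk RNA-seq: take the top-N most highly expressed genes (FPKM) in each
replicate of each callus stage, form a per-stage consensus as the union of
replicate sets, intersect the consensus sets across stages, and finally
keep only genes that a multi-tissue expression atlas shows to be strongly
expressed in callus yet low or undetectable everywhere else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionAtlas",
    "ScreenConfig",
    "ScreenResult",
    "compute_fpkm",
    "top_n_genes",
    "stage_consensus",
    "cross_stage_intersection",
    "tissue_specificity_filter",
    "run_screen",
    "read_expression_matrix",
    "read_sample_sheet",
    "read_gene_lengths",
]


@dataclass
class ExpressionAtlas:
    """Gene-by-sample expression matrix with tissue labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative matrix, index = gene ids, columns = sample ids.
        Either FPKM or raw fragment counts; counts require ``gene_lengths``.
    tissue_of : dict
        Maps every sample id to a tissue label.
    gene_lengths : pandas.Series, optional
        Transcript lengths in bp, indexed by gene id.  Required only when
        ``values`` holds raw counts.
    is_counts : bool
        Whether ``values`` holds raw fragment counts (True) or FPKM (False).
    """

    values: pd.DataFrame
    tissue_of: dict[str, str]
    gene_lengths: pd.Series | None = None
    is_counts: bool = False

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.tissue_of]
        if missing:
            raise ValueError(f"samples without a tissue label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.tissue_of[s], None)
        return list(seen)

    def fpkm(self) -> pd.DataFrame:
        """Return the matrix as FPKM, converting counts if necessary."""
        if not self.is_counts:
            return self.values
        if self.gene_lengths is None:
            raise ValueError("gene_lengths required to convert counts to FPKM")
        library_sizes = self.values.sum(axis=0)
        return compute_fpkm(self.values, self.gene_lengths, library_sizes)

    def tissue_means(self) -> pd.DataFrame:
        """Mean FPKM per tissue (replicates averaged), genes x tissues."""
        fpkm = self.fpkm()
        groups = pd.Series({s: self.tissue_of[s] for s in fpkm.columns})
        return fpkm.T.groupby(groups).mean().T


@dataclass
class ScreenConfig:
    """Thresholds for the screen.

    ``top_n`` genes are taken per replicate; the atlas filter keeps genes
    with callus FPKM >= ``min_callus_expr``, every other tissue at most
    ``max_other_expr``, and a callus/max-other fold of at least
    ``min_ratio`` (pseudocount ``epsilon`` guards zero denominators).
    """

    top_n: int = 400
    callus_tissue: str = "callus"
    min_callus_expr: float = 10.0
    max_other_expr: float = 1.0
    min_ratio: float = 10.0
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.min_ratio < 1:
            raise ValueError("min_ratio must be >= 1")
        if self.min_callus_expr <= self.max_other_expr:
            raise ValueError("min_callus_expr must exceed max_other_expr")


@dataclass
class ScreenResult:
    """Outputs of each screening step."""

    per_replicate_top: dict[str, set[str]]
    stage_consensus: dict[str, set[str]]
    cross_stage: set[str]
    specific_candidates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> dict:
        return {
            "per_replicate_top_sizes": {s: len(g) for s, g in self.per_replicate_top.items()},
            "stage_consensus_sizes": {s: len(g) for s, g in self.stage_consensus.items()},
            "cross_stage_size": len(self.cross_stage),
            "n_specific_candidates": int(len(self.specific_candidates)),
        }


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = fragments * 1e9 / (library_size * transcript_length).

    Parameters
    ----------
    counts : genes x samples integer (or float) fragment counts.
    gene_lengths : transcript length in bp per gene.
    library_sizes : total fragments per sample; defaults to column sums.

    Raises
    ------
    ValueError
        If a gene with nonzero counts has no length, or any length or
        library size is non-positive.
    """
    lengths = gene_lengths.reindex(counts.index)
    expressed = counts.sum(axis=1) > 0
    missing = lengths.isna() & expressed
    if missing.any():
        raise ValueError(
            f"missing gene length for expressed gene(s): {list(counts.index[missing])[:5]}"
        )
    if (lengths.dropna() <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    # genes with no counts anywhere and no length yield 0 FPKM
    lengths = lengths.fillna(1.0)
    fpkm = counts.div(library_sizes, axis=1).div(lengths, axis=0) * 1e9
    return fpkm


def top_n_genes(expr: pd.Series | dict[str, float], n: int) -> set[str]:
    """Genes with the ``n`` highest values; ties at the cutoff all included.

    Including every gene tied with the n-th value makes the result
    deterministic and independent of input order.  Fewer than ``n`` genes
    returns all of them.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = pd.Series(expr, dtype=float)
    if len(s) <= n:
        return set(s.index)
    cutoff = s.nlargest(n).iloc[-1]
    return set(s.index[s >= cutoff])


def stage_consensus(per_replicate_sets: list[set[str]]) -> set[str]:
    """Consensus of a stage's replicates: the union of per-replicate sets.

    A union (not intersection) is used so that genes strongly expressed in
    any replicate contribute to the stage's highly-expressed list; per-stage
    list sizes therefore exceed the per-replicate top-N.
    """
    if not per_replicate_sets:
        raise ValueError("need at least one replicate set")
    return set().union(*per_replicate_sets)


def cross_stage_intersection(stage_sets: list[set[str]]) -> set[str]:
    """Genes present in every stage's consensus set."""
    if len(stage_sets) < 2:
        raise ValueError("need at least two stage sets to intersect")
    out = set(stage_sets[0])
    for s in stage_sets[1:]:
        out &= s
    return out


def tissue_specificity_filter(
    candidates: set[str],
    atlas: ExpressionAtlas,
    cfg: ScreenConfig,
) -> pd.DataFrame:
    """Keep candidates the atlas shows to be callus-specific.

    A gene passes when callus expression >= ``min_callus_expr``, the maximum
    over all non-callus tissues <= ``max_other_expr``, and
    (callus + eps)/(max_other + eps) >= ``min_ratio``.

    Returns a DataFrame (gene, callus_expr, max_other_expr, ratio) ordered
    by descending callus expression.
    """
    means = atlas.tissue_means()
    if cfg.callus_tissue not in means.columns:
        raise ValueError(
            f"callus tissue {cfg.callus_tissue!r} not in atlas tissues {list(means.columns)}"
        )
    genes = [g for g in candidates if g in means.index]
    sub = means.loc[genes]
    callus = sub[cfg.callus_tissue]
    others = sub.drop(columns=[cfg.callus_tissue])
    max_other = others.max(axis=1) if others.shape[1] else pd.Series(0.0, index=sub.index)
    ratio = (callus + cfg.epsilon) / (max_other + cfg.epsilon)
    keep = (
        (callus >= cfg.min_callus_expr)
        & (max_other <= cfg.max_other_expr)
        & (ratio >= cfg.min_ratio)
    )
    out = pd.DataFrame(
        {
            "gene": sub.index[keep],
            "callus_expr": callus[keep].to_numpy(),
            "max_other_expr": max_other[keep].to_numpy(),
            "ratio": ratio[keep].to_numpy(),
        }
    )
    return out.sort_values("callus_expr", ascending=False, kind="mergesort").reset_index(drop=True)


def run_screen(
    stage_matrices: dict[str, pd.DataFrame],
    cfg: ScreenConfig,
    atlas: ExpressionAtlas | None = None,
    de_table: pd.DataFrame | None = None,
) -> ScreenResult:
    """Run the full screen.

    Parameters
    ----------
    stage_matrices : map stage label -> genes x replicate-samples FPKM frame.
    cfg : thresholds.
    atlas : optional multi-tissue atlas for the specificity filter.
    de_table : optional precomputed differential-expression table
        (columns gene, log2FC, FDR) used only to annotate candidates.
    """
    per_replicate: dict[str, set[str]] = {}
    consensus: dict[str, set[str]] = {}
    for stage, mat in stage_matrices.items():
        rep_sets = []
        for col in mat.columns:
            top = top_n_genes(mat[col], cfg.top_n)
            per_replicate[col] = top
            rep_sets.append(top)
        consensus[stage] = stage_consensus(rep_sets)
    cross = cross_stage_intersection(list(consensus.values()))
    result = ScreenResult(per_replicate, consensus, cross)
    if atlas is not None:
        cand = tissue_specificity_filter(cross, atlas, cfg)
        if de_table is not None and not cand.empty:
            anno = de_table.set_index("gene").reindex(cand["gene"])
            cand = cand.assign(
                log2FC=anno["log2FC"].to_numpy(), FDR=anno["FDR"].to_numpy()
            )
        result.specific_candidates = cand
    return result


# ---------------------------------------------------------------------------
# TSV interfaces

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """First column = gene id, header row = sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Columns: sample_id, tissue, stage (stage optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tissue"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    return df


def read_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "length"])
    return df.set_index("gene")["length"].astype(float)


def write_screen_outputs(result: ScreenResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.specific_candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    with open(outdir / "screen_summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2)
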