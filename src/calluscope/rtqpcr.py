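"""Relative expression from RT-qPCR cycle thresholds (2^-dCt).

Target-gene Ct values are compared against an internal reference gene
(e.g. AhADH3) within each biological replicate; technical replicates are
averaged first, then mean and sample SD are taken across biological
replicates.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["relative_expression", "aggregate_replicates", "relative_expression_table"]


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """2^-(Ct_target - Ct_reference); equal Cts give 1.0."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (-(ct_target - ct_reference))


def aggregate_replicates(values: list[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (ddof=1); SD of one value is 0."""
    if len(values) == 0:
        raise ValueError("cannot aggregate an empty replicate list")
    arr = np.asarray(values, dtype=float)
    if arr.size == 1:
        logger.warning("single replicate: reporting SD 0")
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def relative_expression_table(
    ct: pd.DataFrame,
    reference_gene: str,
    average_technical_first: bool = True,
) -> pd.DataFrame:
    """Mean +/- SD relative expression per (tissue, gene).

    Parameters
    ----------
    ct : long-format frame with columns
        tissue, gene, bio_replicate, tech_replicate, ct.
    reference_gene : internal reference gene name; its rows must be present
        for every (tissue, bio_replicate) analysed.
    average_technical_first : average technical-replicate Cts to one value
        per biological replicate before computing dCt and the across-
        biological-replicate statistics.  When False each technical
        replicate yields its own ratio (paired with the reference mean).

    Returns a tidy frame (tissue, gene, mean_rel_expr, sd_rel_expr, n_bio).
    """
    required = {"tissue", "gene", "bio_replicate", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    if not np.isfinite(ct["ct"].to_numpy(dtype=float)).all():
        raise ValueError("Ct values must be finite")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle counts")

    ref = ct[ct["gene"] == reference_gene]
    targets = ct[ct["gene"] != reference_gene]
    if ref.empty:
        raise ValueError(f"no rows for reference gene {reference_gene!r}")

    ref_ct = ref.groupby(["tissue", "bio_replicate"])["ct"].mean()

    rows = []
    for (tissue, gene), grp in targets.groupby(["tissue", "gene"], sort=True):
        per_bio: list[float] = []
        for bio, bgrp in grp.groupby("bio_replicate", sort=True):
            key = (tissue, bio)
            if key not in ref_ct.index:
                raise ValueError(
                    f"reference gene {reference_gene!r} missing for tissue={tissue!r}, "
                    f"bio_replicate={bio!r}"
                )
            ref_val = float(ref_ct.loc[key])
            if average_technical_first:
                per_bio.append(relative_expression(float(bgrp["ct"].mean()), ref_val))
            else:
                per_bio.extend(relative_expression(float(c), ref_val) for c in bgrp["ct"])
        mean, sd = aggregate_replicates(per_bio)
        rows.append(
            {
                "tissue": tissue,
                "gene": gene,
                "mean_rel_expr": mean,
                "sd_rel_expr": sd,
                "n_bio": grp["bio_replicate"].nunique(),
            }
        )
    return pd.DataFrame(rows)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
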