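"""Differential-expression calling per contrast and intersection across them.

A gene is "dormancy-induced" in one contrast when its linear fold change
(2**log_ratio, dormant over active) clears the threshold — FC ≥ 1.2 by
default, boundary inclusive — optionally gated on per-gene significance.
The seed list is the intersection of the called sets across all contrasts:
the least common denominator of the experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExperimentTable, GeneSet

logger = logging.getLogger("budnet")

__all__ = ["DECriteria", "call_de", "intersect_de", "volcano_table"]

#: smallest significance used when a reported p-value is exactly zero
P_CLAMP = 1e-300


@dataclass(frozen=True)
class DECriteria:
    """Thresholds for calling a gene differentially expressed.

    ``fc_threshold`` is a linear fold change (≥ 1); ``direction`` is "up"
    (induced in dormant buds) or "down"; both thresholds are inclusive.
    """

    fc_threshold: float = 1.2
    direction: str = "up"
    significance_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")


def call_de(table: ExperimentTable, criteria: DECriteria = DECriteria()) -> GeneSet:
    """Genes passing the fold-change (and optional significance) criteria."""
    log_fc_bound = np.log2(criteria.fc_threshold)
    lr = table.log_ratios
    if criteria.direction == "up":
        mask = lr >= log_fc_bound
    else:
        mask = lr <= -log_fc_bound
    if criteria.significance_threshold is not None:
        sig = table.significance
        if sig is None:
            raise ValueError(
                f"{table.experiment_id}: significance_threshold set but table has no significance"
            )
        mask &= sig <= criteria.significance_threshold
    genes = table.frame.loc[mask, "gene"]
    logger.info("call_de[%s]: %d/%d genes pass %s FC>=%g",
                table.experiment_id, int(mask.sum()), len(table),
                criteria.direction, criteria.fc_threshold)
    return GeneSet(table.experiment_id, genes)


def intersect_de(sets: list[GeneSet]) -> GeneSet:
    """Intersection of per-experiment DE calls (the seed gene list)."""
    if len(sets) < 2:
        raise ValueError("intersect_de needs at least 2 sets")
    common = sets[0]
    for s in sets[1:]:
        common = common.intersection(s)
    result = GeneSet("intersection", common.genes)
    for s in sets:
        logger.info("intersect_de: %s has %d genes", s.name, len(s))
    logger.info("intersect_de: intersection has %d genes", len(result))
    return result


def volcano_table(table: ExperimentTable) -> pd.DataFrame:
    """Per-gene (log2 fold change, −log10 significance) records for plotting.

    Zero significance values are clamped to the smallest representable
    p-value and logged.
    """
    sig = table.significance
    if sig is None:
        raise ValueError(f"{table.experiment_id}: volcano plot needs significance")
    n_zero = int((sig == 0).sum())
    if n_zero:
        logger.warning("volcano_table[%s]: clamped %d zero significance value(s) to %g",
                       table.experiment_id, n_zero, P_CLAMP)
    clamped = sig.clip(lower=P_CLAMP)
    return pd.DataFrame(
        {
            "gene": table.frame["gene"],
            "log2_fc": table.log_ratios,
            "neg_log10_significance": -np.log10(clamped),
        }
    ).reset_index(drop=True)
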