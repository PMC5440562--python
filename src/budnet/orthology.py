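"""Cross-species projection of GRNs and time-course/cell-type summaries.

GRN membership is carried into another species through a one-to-many
ortholog map; expression over a dormancy time course is expressed as log2
ratios against a designated "active bud" reference time point, and
cell-type profiles are normalized per gene to the maximum-expressing cell
type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._hcluster import cluster_rows_and_columns
from .coexpression import GRN
from .core_io import OrthologMap, gene_key

logger = logging.getLogger("budnet")

__all__ = [
    "ProjectedGRN",
    "TimecourseMatrix",
    "project_grn",
    "timecourse_logratios",
    "fraction_induced",
    "row_max_normalize",
    "summarize_orthologs",
    "cluster_timecourse",
]

#: default induction threshold, aligned with the FC >= 1.2 validation rule
DEFAULT_INDUCTION_LOG2 = float(np.log2(1.2))


@dataclass
class ProjectedGRN:
    """A GRN carried into another species via an ortholog map."""

    source_grn: GRN
    species: str
    mapped: dict[str, frozenset[str]]   # source gene -> target genes

    @property
    def coverage(self) -> float:
        """Fraction of source genes with at least one ortholog."""
        n = len(self.source_grn.members)
        return len(self.mapped) / n if n else 0.0

    @property
    def target_genes(self) -> list[str]:
        out = {t for targets in self.mapped.values() for t in targets}
        return sorted(out, key=str.casefold)


@dataclass
class TimecourseMatrix:
    """Genes × time points of log2 ratios vs. the reference time point."""

    frame: pd.DataFrame
    reference: str

    def __post_init__(self) -> None:
        ref = self.frame[self.reference].dropna()
        if not np.allclose(ref, 0.0, atol=1e-9):
            raise ValueError("reference column must be identically zero")


def project_grn(grn: GRN, ortholog_map: OrthologMap, species: str) -> ProjectedGRN:
    """Map GRN members into another species; unmapped genes are dropped."""
    if len(ortholog_map) == 0:
        raise ValueError("ortholog map is empty")
    mapped: dict[str, frozenset[str]] = {}
    dropped = 0
    for gene in grn.members.genes:
        targets = ortholog_map.targets(gene)
        if targets:
            mapped[gene] = targets
        else:
            dropped += 1
    logger.info("project_grn[%s→%s]: %d mapped, %d dropped",
                grn.label, species, len(mapped), dropped)
    return ProjectedGRN(source_grn=grn, species=species, mapped=mapped)


def timecourse_logratios(
    expression: pd.DataFrame, reference: str
) -> TimecourseMatrix:
    """Per-time-point log2 ratios against the reference column.

    ``expression`` holds normalized log2 intensities (genes × time
    points); each entry of the result is intensity(t) − intensity(ref), so
    the reference column is identically zero.
    """
    if reference not in expression.columns:
        raise ValueError(f"reference time point {reference!r} not in matrix")
    frame = expression.astype(float)
    out = frame.sub(frame[reference], axis=0)
    return TimecourseMatrix(frame=out, reference=reference)


def fraction_induced(
    tc: TimecourseMatrix, threshold: float = DEFAULT_INDUCTION_LOG2
) -> pd.Series:
    """Per-time-point fraction of genes with log2 ratio ≥ threshold.

    NA entries are excluded from both numerator and denominator.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    frame = tc.frame
    passing = (frame >= threshold).sum(axis=0)
    valid = frame.notna().sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = passing / valid.replace(0, np.nan)
    return frac.fillna(0.0)


def row_max_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene's profile to [0, 1] relative to its maximum cell type.

    All-zero rows are returned unchanged (and flagged in the log);
    negative intensities are rejected.
    """
    frame = matrix.astype(float)
    if (frame < 0).any().any():
        raise ValueError("row_max_normalize expects nonnegative intensities")
    maxima = frame.max(axis=1)
    zero_rows = maxima == 0
    if zero_rows.any():
        logger.warning("row_max_normalize: %d all-zero row(s) left unchanged",
                       int(zero_rows.sum()))
    safe = maxima.where(~zero_rows, 1.0)
    return frame.div(safe, axis=0)


def summarize_orthologs(
    projected: ProjectedGRN,
    expression: pd.DataFrame,
    how: str = "mean",
) -> pd.DataFrame:
    """Collapse one-to-many ortholog expression onto source genes.

    Each source gene's profile is the mean (default) or max over its
    target genes present in the expression matrix.
    """
    if how not in ("mean", "max"):
        raise ValueError("how must be 'mean' or 'max'")
    index_by_key = {gene_key(g): g for g in expression.index}
    rows, kept = [], []
    for source, targets in projected.mapped.items():
        present = [index_by_key[gene_key(t)] for t in targets if gene_key(t) in index_by_key]
        if not present:
            continue
        block = expression.loc[present]
        rows.append(block.mean(axis=0) if how == "mean" else block.max(axis=0))
        kept.append(source)
    return pd.DataFrame(rows, index=kept)


def cluster_timecourse(tc: TimecourseMatrix) -> tuple[pd.DataFrame, str, str]:
    """HCL (Euclidean, average linkage) of the time-course matrix rows/columns."""
    frame = tc.frame
    n_missing = int(frame.isna().to_numpy().sum())
    if n_missing:
        logger.warning("cluster_timecourse: median-imputing %d missing value(s)", n_missing)
        frame = frame.fillna(frame.median(axis=0)).fillna(0.0)
    return cluster_rows_and_columns(frame)
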