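"""Ranked gene-set enrichment: weighted running sum, permutation NES and FDR.

Genes are ranked by their log2 ratio (dormant − active).  For a gene set,
a running sum walks the ranked list: at each set member ("hit") it rises
by that gene's |score|^p share of the total hit weight, at each non-member
it falls by 1/(n − n_hits).  The enrichment score (ES) is the signed
extreme deviation; with weight p = 0 this is exactly the classical
Kolmogorov–Smirnov statistic on the hit indicator.  The default p = 1 is
the "weighted" statistic.

Because the input contrasts are per-gene summaries (no per-replicate
samples), the null is built by gene-label permutation preserving set
size.  When the number of distinct same-size sets is no larger than the
permutation budget, the null is enumerated exhaustively instead of
sampled, so toy examples are exact.  NES divides the ES by the mean
|null ES| of matching sign; the FDR is the standard sign-stratified NES
tail-ratio over the pooled null, clamped to [0, 1].
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._hcluster import cluster_rows_and_columns
from .core_io import ExperimentTable, GeneSet, GeneSetCollection, RankedList

logger = logging.getLogger("budnet")

__all__ = [
    "GseaParams",
    "GseaResult",
    "make_ranked_list",
    "enrichment_score",
    "nes_and_fdr",
    "nes_matrix_cluster",
]


@dataclass(frozen=True)
class GseaParams:
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    min_set_size: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be nonnegative")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    perm_p: float
    fdr: float
    leading_edge: GeneSet
    running_sum: np.ndarray
    n_hits: int


def make_ranked_list(table: ExperimentTable) -> RankedList:
    """Rank genes descending by log2 ratio (ties lexicographic by gene ID)."""
    return RankedList(zip(table.frame["gene"], table.frame["log_ratio"]))


def _es_core(weights: np.ndarray, hits: np.ndarray) -> tuple[float, np.ndarray, int]:
    """Running sum for one hit indicator; returns (ES, running sum, extreme index).

    ``weights`` are |score|^p; a zero total hit weight falls back to
    uniform hit increments so degenerate all-zero rankings stay defined.
    """
    n = len(weights)
    n_hits = int(hits.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("set must hit a proper subset of the ranked list")
    hit_w = weights * hits
    total = hit_w.sum()
    if total == 0:
        hit_w = hits / n_hits
        total = 1.0
    steps = hit_w / total - (~hits) / (n - n_hits)
    running = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(running)))
    return float(running[i_ext]), running, i_ext


def enrichment_score(
    ranked: RankedList, geneset: GeneSet, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, GeneSet]:
    """ES, full running sum and leading edge of a set in a ranked list."""
    keys = ranked.keys
    hit_keys = geneset.keys
    hits = np.array([k in hit_keys for k in keys], dtype=bool)
    if not hits.any():
        raise ValueError(f"set {geneset.name!r} is disjoint from the ranked list")
    weights = np.abs(ranked.scores) ** weight_exponent
    es, running, i_ext = _es_core(weights, hits)
    genes = ranked.genes
    if es >= 0:
        edge = [genes[i] for i in range(i_ext + 1) if hits[i]]
    else:
        edge = [genes[i] for i in range(i_ext, len(genes)) if hits[i]]
    return es, running, GeneSet(f"{geneset.name}_leading_edge", edge)


def _null_es(
    weights: np.ndarray,
    set_size: int,
    params: GseaParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Null ES distribution for random same-size sets (gene-label permutation).

    Enumerates every distinct set exhaustively when there are no more of
    them than the permutation budget; otherwise samples uniformly.
    Returns the null ES values and whether they are exhaustive.
    """
    n = len(weights)
    n_space = math.comb(n, set_size)
    if n_space <= params.n_permutations:
        index_sets = itertools.combinations(range(n), set_size)
        B = n_space
    else:
        index_sets = (
            rng.choice(n, size=set_size, replace=False) for _ in range(params.n_permutations)
        )
        B = params.n_permutations
    hit = np.zeros((B, n), dtype=bool)
    for b, idx in enumerate(index_sets):
        hit[b, list(idx)] = True
    hit_w = hit * weights
    total = hit_w.sum(axis=1)
    degenerate = total == 0
    if degenerate.any():
        hit_w[degenerate] = hit[degenerate] / set_size
        total[degenerate] = 1.0
    steps = hit_w / total[:, None] - (~hit) / (n - set_size)
    running = np.cumsum(steps, axis=1)
    ext = np.argmax(np.abs(running), axis=1)
    return running[np.arange(B), ext], n_space <= params.n_permutations


def _sign_mean(null: np.ndarray, positive: bool) -> float:
    side = null[null > 0] if positive else null[null < 0]
    if len(side) == 0:
        side = np.abs(null[null != 0])
        if len(side) == 0:
            return float("nan")
    return float(np.mean(np.abs(side)))


def nes_and_fdr(
    ranked: RankedList,
    collection: GeneSetCollection,
    params: GseaParams = GseaParams(),
) -> list[GseaResult]:
    """NES, permutation p and FDR for every sufficiently large gene set."""
    ranked_keys = set(ranked.keys)
    kept: list[tuple[GeneSet, int]] = []
    for gs in collection:
        overlap = len(gs.keys & ranked_keys)
        if overlap < params.min_set_size or overlap >= len(ranked):
            logger.warning("gsea: skipping %s (%d gene(s) in the ranked list)",
                           gs.name, overlap)
            continue
        if overlap < 10:
            logger.warning("gsea: set %s has <10 genes in the ranked list; "
                           "significance may be unattainable", gs.name)
        kept.append((gs, overlap))
    if not kept:
        logger.warning("gsea: no sets survive the size filter")
        return []

    weights = np.abs(ranked.scores) ** params.weight_exponent
    rng = np.random.default_rng(np.random.SeedSequence((int(params.rng_seed), 17)))

    null_cache: dict[int, tuple[np.ndarray, bool]] = {}
    observed: list[tuple[GeneSet, float, np.ndarray, GeneSet, int]] = []
    null_nes_pool: list[np.ndarray] = []
    nes_values: list[float] = []
    perm_ps: list[float] = []

    for gs, overlap in kept:
        es, running, edge = enrichment_score(ranked, gs, params.weight_exponent)
        if overlap not in null_cache:
            null_cache[overlap] = _null_es(weights, overlap, params, rng)
        null, exhaustive = null_cache[overlap]

        positive = es >= 0
        same_sign = null[null > 0] if positive else null[null < 0]
        n_extreme = int((np.abs(same_sign) >= abs(es)).sum())
        if exhaustive:
            # the observed configuration is one of the enumerated sets, so
            # no add-one smoothing is needed (n_extreme >= 1 by inclusion)
            perm_p = n_extreme / max(len(same_sign), 1)
        else:
            perm_p = (1 + n_extreme) / (1 + len(same_sign))

        mean_pos = _sign_mean(null, True)
        mean_neg = _sign_mean(null, False)
        denom = mean_pos if positive else mean_neg
        nes = es / denom if denom and not math.isnan(denom) else float("nan")

        null_nes = np.where(
            null >= 0,
            null / mean_pos if mean_pos and not math.isnan(mean_pos) else np.nan,
            -np.abs(null) / mean_neg if mean_neg and not math.isnan(mean_neg) else np.nan,
        )
        null_nes_pool.append(null_nes[np.isfinite(null_nes)])
        observed.append((gs, es, running, edge, overlap))
        nes_values.append(nes)
        perm_ps.append(perm_p)

    pooled = np.concatenate(null_nes_pool)
    obs_nes = np.array(nes_values)
    results: list[GseaResult] = []
    for (gs, es, running, edge, overlap), nes, perm_p in zip(observed, nes_values, perm_ps):
        fdr = _nes_fdr(nes, obs_nes, pooled)
        results.append(
            GseaResult(
                set_name=gs.name, es=es, nes=nes, perm_p=perm_p, fdr=fdr,
                leading_edge=edge, running_sum=running, n_hits=overlap,
            )
        )
    return results


def _nes_fdr(nes: float, obs_nes: np.ndarray, null_nes: np.ndarray) -> float:
    """Sign-stratified NES tail-ratio FDR (clamped to [0, 1])."""
    if math.isnan(nes):
        return float("nan")
    if nes >= 0:
        null_side = null_nes[null_nes >= 0]
        obs_side = obs_nes[obs_nes >= 0]
        null_tail = (null_side >= nes).mean() if len(null_side) else 1.0
        obs_tail = (obs_side >= nes).mean() if len(obs_side) else 1.0
    else:
        null_side = null_nes[null_nes < 0]
        obs_side = obs_nes[obs_nes < 0]
        null_tail = (null_side <= nes).mean() if len(null_side) else 1.0
        obs_tail = (obs_side <= nes).mean() if len(obs_side) else 1.0
    if obs_tail == 0:
        return 0.0 if null_tail == 0 else 1.0
    return float(min(1.0, null_tail / obs_tail))


def nes_matrix_cluster(
    nes: pd.DataFrame,
) -> tuple[pd.DataFrame, str, str]:
    """Cluster a samples × sets NES matrix on both axes (HCL convention).

    Average linkage on Euclidean distance; missing NES values are
    median-imputed per set with a logged count.  Returns the reordered
    matrix and the row/column dendrograms as Newick strings.
    """
    frame = nes.astype(float).copy()
    n_missing = int(frame.isna().to_numpy().sum())
    if n_missing:
        logger.warning("nes_matrix_cluster: median-imputing %d missing value(s)", n_missing)
        frame = frame.fillna(frame.median(axis=0)).fillna(0.0)
    return cluster_rows_and_columns(frame)
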