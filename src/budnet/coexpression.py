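"""Coexpression similarity, seed-list clustering and GRN expansion.

A GRN here is a coregulated gene list: a cluster of the seed genes plus
the genes most coregulated with that cluster across the compendium,
retained only when induced (FC ≥ 1.2) in at least one dormant-vs-active
contrast.

Two coregulation measures are offered.  Pearson r uses pairwise-complete
observations.  Mutual rank (MR) is sqrt(rank_i(j) · rank_j(i)) over each
gene's correlation-ordered partner lists (rank 1 = best partner; lower MR
= more coregulated), the published measure of large coexpression
databases, and the default.  All ties break lexicographically by gene ID
so every stage is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._hcluster import average_linkage_from_distance, cut_to_k, linkage_to_newick
from .core_io import CoexpressionCompendium, ExperimentTable, GeneSet

logger = logging.getLogger("budnet")

__all__ = [
    "CoexprSimilarity",
    "GRN",
    "coexpr_matrix",
    "hcluster_seed",
    "seed_dendrogram_newick",
    "expand_cluster",
    "validate_induction",
    "grn_overlap",
]


@dataclass
class CoexprSimilarity:
    """Symmetric gene × gene similarity: Pearson r or mutual rank."""

    method: str                      # "pearson" | "mutual_rank"
    matrix: np.ndarray               # genes x genes
    keys: list[str]                  # matching keys, lexicographically sorted
    labels: list[str]                # canonical gene IDs, same order

    def __post_init__(self) -> None:
        self._index = {k: i for i, k in enumerate(self.keys)}

    def __contains__(self, gene: str) -> bool:
        return str(gene).strip().casefold() in self._index

    def loc(self, gene: str) -> int:
        return self._index[str(gene).strip().casefold()]

    def distance_matrix(self) -> np.ndarray:
        """Distances for clustering: 1 − r (Pearson) or MR (mutual rank)."""
        if self.method == "pearson":
            d = 1.0 - self.matrix
        else:
            d = self.matrix.copy()
        np.fill_diagonal(d, 0.0)
        return d


def _pairwise_pearson(values: np.ndarray) -> np.ndarray:
    """Pearson correlation; pairwise-complete when NaNs are present."""
    if np.isfinite(values).all():
        return np.corrcoef(values)
    return pd.DataFrame(values).T.corr(min_periods=2).to_numpy()


def coexpr_matrix(
    compendium: CoexpressionCompendium, method: str = "mutual_rank"
) -> CoexprSimilarity:
    """Build the similarity structure over all usable compendium genes.

    Genes with fewer than three finite values or with constant expression
    (undefined correlation) are excluded with a logged count.
    """
    if method not in ("pearson", "mutual_rank"):
        raise ValueError(f"unknown method {method!r}")
    if len(compendium.samples) < 3:
        raise ValueError("compendium needs >= 3 samples")
    frame = compendium.frame.loc[compendium.usable]
    values = frame.to_numpy()
    with np.errstate(invalid="ignore"):
        stds = np.nanstd(values, axis=1)
    constant = stds == 0
    if constant.any():
        logger.warning("coexpr_matrix: excluding %d constant-expression gene(s)",
                       int(constant.sum()))
        frame = frame.loc[~constant]
        values = frame.to_numpy()
    # lexicographic gene order makes every downstream tie-break reproducible
    order = np.argsort(frame.index.to_numpy())
    frame = frame.iloc[order]
    values = values[order]
    keys = list(frame.index)
    labels = [compendium.canonical(k) for k in keys]

    r = _pairwise_pearson(values)
    np.fill_diagonal(r, 1.0)
    if method == "pearson":
        return CoexprSimilarity("pearson", r, keys, labels)

    # mutual rank: stable descending argsort breaks r-ties by gene order
    n = len(keys)
    work = r.copy()
    np.fill_diagonal(work, np.inf)  # self sorts first, partners rank from 1
    order_desc = np.argsort(-work, axis=1, kind="stable")
    ranks = np.empty_like(order_desc)
    rows = np.arange(n)[:, None]
    ranks[rows, order_desc] = np.arange(n)[None, :]
    mr = np.sqrt(ranks * ranks.T).astype(float)
    np.fill_diagonal(mr, 0.0)
    return CoexprSimilarity("mutual_rank", mr, keys, labels)


def _seed_submatrix(seed: GeneSet, sim: CoexprSimilarity) -> tuple[list[int], list[str]]:
    present, dropped = [], []
    for gene in seed.genes:  # already sorted by key
        if gene in sim:
            present.append(sim.loc(gene))
        else:
            dropped.append(gene)
    if dropped:
        logger.warning("hcluster_seed: %d seed gene(s) absent from similarity: %s",
                       len(dropped), ", ".join(dropped[:10]))
    labels = [sim.labels[i] for i in present]
    return present, labels


def hcluster_seed(seed: GeneSet, sim: CoexprSimilarity, k: int = 4) -> list[GeneSet]:
    """Partition the seed list into k coexpression clusters (average linkage)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    idx, labels = _seed_submatrix(seed, sim)
    if k > len(idx):
        raise ValueError(f"k={k} exceeds {len(idx)} retained seed genes")
    dist = sim.distance_matrix()[np.ix_(idx, idx)]
    z = average_linkage_from_distance(dist)
    flat = cut_to_k(z, k)
    clusters: list[GeneSet] = []
    for label in sorted(set(flat)):
        members = [g for g, c in zip(labels, flat) if c == label]
        clusters.append(GeneSet(f"cluster_{label}", members))
    clusters.sort(key=lambda s: (-len(s), s.genes[0].casefold()))
    for i, c in enumerate(clusters, start=1):
        c.name = f"cluster_{i}"
    logger.info("hcluster_seed: cluster sizes %s", [len(c) for c in clusters])
    return clusters


def seed_dendrogram_newick(seed: GeneSet, sim: CoexprSimilarity) -> str:
    """Newick serialization of the seed-list dendrogram."""
    idx, labels = _seed_submatrix(seed, sim)
    dist = sim.distance_matrix()[np.ix_(idx, idx)]
    z = average_linkage_from_distance(dist)
    return linkage_to_newick(z, labels)


def expand_cluster(
    cluster: GeneSet, sim: CoexprSimilarity, top_n: int = 300
) -> list[tuple[str, float]]:
    """The top_n genes most coregulated with a cluster, with their scores.

    Every non-cluster gene is scored by its mean similarity to the cluster
    members: mean r (higher = better) for Pearson, mean MR (lower =
    better) for mutual rank.  Ties break lexicographically.
    """
    if len(cluster) == 0:
        raise ValueError("cluster is empty")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    member_idx = [sim.loc(g) for g in cluster.genes if g in sim]
    if not member_idx:
        raise ValueError("no cluster gene present in the similarity matrix")
    scores = sim.matrix[:, member_idx].mean(axis=1)
    member_set = set(member_idx)
    candidates = [i for i in range(len(sim.keys)) if i not in member_set]
    sign = -1.0 if sim.method == "pearson" else 1.0  # sort ascending on sign*score
    candidates.sort(key=lambda i: (sign * scores[i], sim.keys[i]))
    if top_n > len(candidates):
        logger.warning("expand_cluster: top_n=%d exceeds %d candidates; returning all",
                       top_n, len(candidates))
        top_n = len(candidates)
    return [(sim.labels[i], float(scores[i])) for i in candidates[:top_n]]


@dataclass
class GRN:
    """A bud-dormancy gene regulatory network (seed cluster + validated expansion)."""

    label: str
    seed_cluster: GeneSet
    members: GeneSet
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seed_cluster.keys <= self.members.keys:
            raise ValueError("seed cluster must be contained in the GRN members")

    def __len__(self) -> int:
        return len(self.members)


def validate_induction(
    candidates: list[tuple[str, float]] | list[str],
    experiments: list[ExperimentTable],
    fc_threshold: float = 1.2,
    seed_cluster: GeneSet | None = None,
    label: str = "GRN",
) -> GRN:
    """Keep candidates induced (FC ≥ threshold) in at least one contrast.

    Returns the assembled GRN: the seed cluster (kept unconditionally)
    plus validated candidates, with per-gene provenance of which
    experiments passed.
    """
    if not experiments:
        raise ValueError("need at least one experiment")
    log_bound = np.log2(fc_threshold)
    genes = [c[0] if isinstance(c, tuple) else c for c in candidates]

    def passing(gene: str) -> list[str]:
        key = gene.strip().casefold()
        out = []
        for table in experiments:
            if key in table.frame.index and table.frame.loc[key, "log_ratio"] >= log_bound:
                out.append(table.experiment_id)
        return out

    provenance: dict[str, list[str]] = {}
    validated: list[str] = []
    for gene in genes:
        passed = passing(gene)
        if passed:
            validated.append(gene)
            provenance[gene] = passed
    if seed_cluster is None:
        seed_cluster = GeneSet(f"{label}_seed", [])
    for gene in seed_cluster.genes:
        provenance.setdefault(gene, passing(gene))
    members = GeneSet(label, list(seed_cluster.genes) + validated)
    logger.info("validate_induction[%s]: %d/%d candidates pass FC>=%g in >=1 experiment; GRN size %d",
                label, len(validated), len(genes), fc_threshold, len(members))
    return GRN(label=label, seed_cluster=seed_cluster, members=members,
               provenance=provenance)


def grn_overlap(grns: list[GRN]) -> pd.DataFrame:
    """Pairwise GRN overlaps: count, % of the smaller set, and Jaccard."""
    if len(grns) < 2:
        raise ValueError("need at least 2 GRNs")
    rows = []
    for i in range(len(grns)):
        for j in range(i + 1, len(grns)):
            a, b = grns[i].members, grns[j].members
            count = len(a.keys & b.keys)
            smaller = min(len(a), len(b))
            rows.append(
                {
                    "grn_a": grns[i].label,
                    "grn_b": grns[j].label,
                    "size_a": len(a),
                    "size_b": len(b),
                    "overlap": count,
                    "pct_of_smaller": 100.0 * count / smaller if smaller else 0.0,
                    "jaccard": a.jaccard(b) if (len(a) or len(b)) else 0.0,
                }
            )
    return pd.DataFrame(rows)
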