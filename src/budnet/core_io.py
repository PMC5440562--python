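"""Domain types and readers/writers for the formats the pipeline touches.

Gene identifiers (AGI locus codes such as ``At5g08520``, or any
species-specific ID) are compared case-insensitively after whitespace
trimming; the canonical form preserves the original casing.  All tabular
formats are plain TSV; gene sets are GMT, ranked lists are RNK, promoters
are FASTA, motif matrices are 4-row A/C/G/T PFM text.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("budnet")

__all__ = [
    "gene_key",
    "canonical_gene",
    "GeneSet",
    "GeneSetCollection",
    "ExperimentTable",
    "CoexpressionCompendium",
    "RankedList",
    "MotifMatrix",
    "OrthologMap",
    "PromoterRecord",
    "read_gmt",
    "write_gmt",
    "read_rnk",
    "write_rnk",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_experiment_tsv",
    "write_experiment_tsv",
    "read_fasta",
    "write_fasta",
    "read_ortholog_tsv",
    "write_pfm",
    "ParseError",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def gene_key(gene: str) -> str:
    """Case-insensitive matching key for a gene identifier."""
    key = str(gene).strip().casefold()
    if not key:
        raise ValueError("empty gene identifier")
    return key


def canonical_gene(gene: str) -> str:
    """Trimmed identifier with its original casing preserved."""
    canon = str(gene).strip()
    if not canon:
        raise ValueError("empty gene identifier")
    return canon


# ---------------------------------------------------------------------------
# gene sets


class GeneSet:
    """A named set of genes with case-insensitive membership."""

    __slots__ = ("name", "description", "_by_key")

    def __init__(self, name: str, members: Iterable[str], description: str = ""):
        self.name = str(name)
        self.description = str(description)
        by_key: dict[str, str] = {}
        for m in members:
            canon = canonical_gene(m)
            by_key.setdefault(canon.casefold(), canon)
        self._by_key = by_key

    @property
    def keys(self) -> frozenset[str]:
        return frozenset(self._by_key)

    @property
    def genes(self) -> list[str]:
        """Members in canonical form, sorted by matching key."""
        return [self._by_key[k] for k in sorted(self._by_key)]

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: object) -> bool:
        try:
            return gene_key(str(gene)) in self._by_key
        except ValueError:
            return False

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSet) and self.keys == other.keys

    def __hash__(self) -> int:
        return hash((self.name, self.keys))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"GeneSet({self.name!r}, n={len(self)})"

    def intersection(self, other: "GeneSet") -> "GeneSet":
        common = self.keys & other.keys
        return GeneSet(
            f"{self.name}&{other.name}",
            [self._by_key[k] for k in common],
        )

    def union(self, other: "GeneSet") -> "GeneSet":
        members = list(self.genes) + list(other.genes)
        return GeneSet(f"{self.name}|{other.name}", members)

    def difference(self, other: "GeneSet") -> "GeneSet":
        keep = self.keys - other.keys
        return GeneSet(self.name, [self._by_key[k] for k in keep])

    def jaccard(self, other: "GeneSet") -> float:
        union = self.keys | other.keys
        if not union:
            return float("nan")
        return len(self.keys & other.keys) / len(union)


@dataclass
class GeneSetCollection:
    """Ordered collection of gene sets plus the background universe size."""

    sets: list[GeneSet] = field(default_factory=list)
    universe_size: int | None = None

    def __post_init__(self) -> None:
        if self.universe_size is not None:
            if self.universe_size < max((len(s) for s in self.sets), default=0):
                raise ValueError("universe_size smaller than a member set")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


# ---------------------------------------------------------------------------
# expression tables


class ExperimentTable:
    """One dormant-vs-active contrast: per-gene log2 ratios and significance.

    ``log_ratio`` is log2(dormant) − log2(active); linear fold change is
    ``2**log_ratio``.  When both per-condition intensities are present they
    must be consistent with the stored ratio.
    """

    def __init__(self, experiment_id: str, frame: pd.DataFrame):
        if "gene" not in frame.columns or "log_ratio" not in frame.columns:
            raise ValueError("experiment table needs 'gene' and 'log_ratio' columns")
        frame = frame.copy()
        frame["gene"] = frame["gene"].map(canonical_gene)
        keys = frame["gene"].map(str.casefold)
        dup = keys[keys.duplicated()].unique()
        if len(dup):
            raise ParseError(f"duplicate gene rows: {', '.join(sorted(dup)[:10])}")
        frame.index = pd.Index(keys, name="key")
        if {"intensity_dormant", "intensity_active"} <= set(frame.columns):
            both = frame[["intensity_dormant", "intensity_active"]].notna().all(axis=1)
            implied = frame.loc[both, "intensity_dormant"] - frame.loc[both, "intensity_active"]
            if not np.allclose(implied, frame.loc[both, "log_ratio"], atol=1e-9):
                raise ValueError(
                    f"{experiment_id}: log_ratio inconsistent with intensities"
                )
        if "significance" in frame.columns:
            sig = frame["significance"].dropna()
            if ((sig < 0) | (sig > 1)).any():
                raise ValueError(f"{experiment_id}: significance outside [0, 1]")
        self.experiment_id = str(experiment_id)
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def genes(self) -> list[str]:
        return list(self.frame["gene"])

    @property
    def log_ratios(self) -> pd.Series:
        return self.frame["log_ratio"]

    @property
    def significance(self) -> pd.Series | None:
        if "significance" in self.frame.columns:
            return self.frame["significance"]
        return None


class CoexpressionCompendium:
    """Genes × samples matrix of normalized log2 expression.

    Rows with fewer than three finite values cannot support a correlation
    and are flagged unusable (kept in the matrix, excluded downstream).
    """

    MIN_FINITE = 3

    def __init__(self, frame: pd.DataFrame):
        genes = [canonical_gene(g) for g in frame.index]
        keys = [g.casefold() for g in genes]
        seen: set[str] = set()
        dup = sorted({k for k in keys if k in seen or seen.add(k)})
        if dup:
            raise ParseError(f"duplicate gene rows: {', '.join(dup[:10])}")
        frame = frame.copy()
        frame.index = pd.Index(keys, name="key")
        self.frame = frame.astype(float)
        self._canonical = dict(zip(keys, genes))
        finite = np.isfinite(self.frame.to_numpy()).sum(axis=1)
        self.usable = pd.Series(finite >= self.MIN_FINITE, index=self.frame.index)
        n_bad = int((~self.usable).sum())
        if n_bad:
            logger.warning("compendium: %d gene(s) with <3 finite values flagged unusable", n_bad)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def genes(self) -> list[str]:
        return [self._canonical[k] for k in self.frame.index]

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns)

    def canonical(self, key: str) -> str:
        return self._canonical[key]


class RankedList:
    """Gene list sorted descending by a ranking score; ties lexicographic."""

    def __init__(self, entries: Iterable[tuple[str, float]]):
        cleaned: list[tuple[str, str, float]] = []
        seen: set[str] = set()
        for gene, score in entries:
            canon = canonical_gene(gene)
            key = canon.casefold()
            if key in seen:
                raise ValueError(f"duplicate gene in ranked list: {canon}")
            seen.add(key)
            score = float(score)
            if not math.isfinite(score):
                raise ValueError(f"non-finite score for {canon}")
            cleaned.append((key, canon, score))
        cleaned.sort(key=lambda t: (-t[2], t[0]))
        self._keys = [k for k, _, _ in cleaned]
        self._genes = [g for _, g, _ in cleaned]
        self._scores = np.array([s for _, _, s in cleaned], dtype=float)

    def __len__(self) -> int:
        return len(self._keys)

    @property
    def genes(self) -> list[str]:
        return list(self._genes)

    @property
    def keys(self) -> list[str]:
        return list(self._keys)

    @property
    def scores(self) -> np.ndarray:
        return self._scores.copy()

    @property
    def entries(self) -> list[tuple[str, float]]:
        return list(zip(self._genes, self._scores))


BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class MotifMatrix:
    """Position frequency matrix with a mixed-case consensus.

    Each column is a distribution over A/C/G/T summing to 1; the consensus
    letter is the argmax base, uppercase when its frequency is ≥ 0.5,
    lowercase otherwise (the convention used for motifs like tcTTATCCAc).
    """

    def __init__(self, frequencies: np.ndarray, support: np.ndarray | None = None):
        freq = np.asarray(frequencies, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4:
            raise ValueError("frequency matrix must be L x 4 (A, C, G, T)")
        sums = freq.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each PFM column must sum to 1")
        self.frequencies = freq
        if support is None:
            support = np.ones(len(freq))
        self.support = np.asarray(support, dtype=float)
        if len(self.support) != len(freq):
            raise ValueError("support length must equal matrix width")

    def __len__(self) -> int:
        return len(self.frequencies)

    @property
    def consensus(self) -> str:
        letters = []
        for row in self.frequencies:
            i = int(np.argmax(row))
            base = BASES[i]
            letters.append(base if row[i] >= 0.5 else base.lower())
        return "".join(letters)


class OrthologMap:
    """One-to-many gene mapping between two species."""

    def __init__(self, pairs: Mapping[str, Iterable[str]]):
        fwd: dict[str, frozenset[str]] = {}
        self._canonical: dict[str, str] = {}
        for src, targets in pairs.items():
            src_c = canonical_gene(src)
            tset = frozenset(canonical_gene(t) for t in targets)
            if not tset:
                raise ValueError(f"empty ortholog target set for {src_c}")
            key = src_c.casefold()
            fwd[key] = fwd.get(key, frozenset()) | tset
            self._canonical.setdefault(key, src_c)
        self._fwd = fwd

    def __len__(self) -> int:
        return len(self._fwd)

    def __contains__(self, gene: str) -> bool:
        return gene_key(gene) in self._fwd

    def targets(self, gene: str) -> frozenset[str]:
        return self._fwd.get(gene_key(gene), frozenset())

    @property
    def sources(self) -> list[str]:
        return sorted(self._canonical.values(), key=str.casefold)

    def reverse(self) -> "OrthologMap":
        rev: dict[str, set[str]] = {}
        for src_key, targets in self._fwd.items():
            for t in targets:
                rev.setdefault(t, set()).add(self._canonical[src_key])
        return OrthologMap(rev)


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter sequence, 5'→3' on the gene's strand, uppercase ACGTN."""

    gene: str
    sequence: str


# ---------------------------------------------------------------------------
# readers / writers


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Duplicate member IDs within a line are collapsed; empty member fields
    are dropped.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name, description, *members = fields
            members = [m for m in members if m.strip()]
            sets.append(GeneSet(name, members, description))
    if not sets:
        logger.warning("%s: empty GMT file", path)
    logger.info("read_gmt: %d set(s) from %s", len(sets), path)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_rnk(path: str | Path) -> RankedList:
    """Read a two-column RNK file (gene TAB score); output is sorted."""
    entries: list[tuple[str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 'gene<TAB>score'")
            gene, raw = fields
            try:
                score = float(raw)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric score {raw!r}") from None
            entries.append((gene, score))
    return RankedList(entries)


def write_rnk(ranked: RankedList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, score in ranked.entries:
            fh.write(f"{gene}\t{score:.10g}\n")


def read_expression_tsv(path: str | Path) -> CoexpressionCompendium:
    """Read a genes × samples expression matrix (TSV, header row, gene column first)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns")
    comp = CoexpressionCompendium(frame)
    logger.info("read_expression_tsv: %d genes x %d samples from %s",
                len(comp), len(comp.samples), path)
    return comp


def write_expression_tsv(comp: CoexpressionCompendium, path: str | Path) -> None:
    out = comp.frame.copy()
    out.index = pd.Index(comp.genes, name="gene")
    out.to_csv(path, sep="\t")


_EXPERIMENT_COLUMNS = {
    "gene", "intensity_dormant", "intensity_active", "log_ratio", "significance",
}


def read_experiment_tsv(path: str | Path, experiment_id: str | None = None) -> ExperimentTable:
    """Read a per-gene contrast table (TSV with a header row).

    Requires ``gene`` and ``log_ratio`` columns; ``intensity_dormant``,
    ``intensity_active`` and ``significance`` are optional.
    """
    frame = pd.read_csv(path, sep="\t")
    unknown = set(frame.columns) - _EXPERIMENT_COLUMNS
    if unknown:
        logger.warning("%s: ignoring unknown columns %s", path, sorted(unknown))
        frame = frame[[c for c in frame.columns if c in _EXPERIMENT_COLUMNS]]
    if experiment_id is None:
        experiment_id = Path(path).stem
    return ExperimentTable(experiment_id, frame)


def write_experiment_tsv(table: ExperimentTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list[PromoterRecord]:
    """Read FASTA records; sequences are uppercased and non-ACGT mapped to N."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        seq = "".join(c if c in "ACGT" else "N" for c in seq)
        records.append(PromoterRecord(gene=rec.id, sequence=seq))
    logger.info("read_fasta: %d record(s) from %s", len(records), path)
    return records


def write_fasta(records: Sequence[PromoterRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_ortholog_tsv(path: str | Path) -> OrthologMap:
    """Read a two-column source→target ortholog map (one pair per line)."""
    pairs: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 'source<TAB>target'")
            src, tgt = fields
            pairs.setdefault(canonical_gene(src), set()).add(tgt)
    return OrthologMap(pairs)


def write_pfm(motif: MotifMatrix, path: str | Path) -> None:
    """Write a motif as a 4-row A/C/G/T frequency matrix (whitespace-separated)."""
    with open(path, "w") as fh:
        fh.write(f"; consensus {motif.consensus}\n")
        for i, base in enumerate(BASES):
            row = " ".join(f"{motif.frequencies[j, i]:.4f}" for j in range(len(motif)))
            fh.write(f"{base} | {row}\n")
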