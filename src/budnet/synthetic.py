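"""Synthetic inputs with the statistical structure the meta-analysis assumes.

The generator emulates the study design: a coexpression compendium with
correlated gene modules (the planted "GRNs"), several independent
dormant-vs-active contrasts in which module genes are up-shifted, gene-set
collections that overlap the modules at a controlled rate, and uniform
promoters with a planted 6–8-mer motif.  Everything is reproducible from a
single integer seed via fixed per-stage random streams.

Module genes are drawn from a shared latent factor: for within-module
correlation ρ, each expression value is ``sqrt(ρ)·z_module + sqrt(1−ρ)·ε``
with standard-normal ``z`` (one per sample) and ``ε`` (one per gene and
sample), giving pairwise correlation ρ in expectation.  Per-contrast log2
ratios are Normal(δ, σ) for module genes and Normal(0, σ) for background,
with a two-sided z-test significance against σ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core_io import (
    CoexpressionCompendium,
    ExperimentTable,
    GeneSet,
    GeneSetCollection,
    PromoterRecord,
    write_expression_tsv,
    write_experiment_tsv,
    write_fasta,
    write_gmt,
)

__all__ = [
    "ModuleSpec",
    "SyntheticSpec",
    "SyntheticTruth",
    "gen_compendium",
    "gen_experiments",
    "gen_genesets",
    "gen_promoters",
    "write_bundle",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# fixed stream ids: one seed drives every sub-generator reproducibly
_STREAM_COMPENDIUM = 0
_STREAM_EXPERIMENTS = 1
_STREAM_GENESETS = 2
_STREAM_PROMOTERS = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))


@dataclass
class ModuleSpec:
    """One planted coexpression module."""

    size: int
    rho: float = 0.8          # within-module correlation
    delta: float = 1.5        # dormant-condition log2 up-shift
    motif: str | None = None  # oligo planted in the module's promoters


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults mirror the study conditions.

    Four modules shaped like the seed-list clusters (14, 20, 13 and 31
    genes) are up-shifted by δ=1.5 log2 units over σ=0.3 noise in three
    independent contrasts; the first module's promoters carry the
    TTATCCAC oligo (the sucrose-repressible TATCCA core).
    """

    n_genes: int = 2000
    n_samples: int = 200
    modules: list[ModuleSpec] = field(
        default_factory=lambda: [
            ModuleSpec(size=14, motif="TTATCCAC"),
            ModuleSpec(size=20),
            ModuleSpec(size=13),
            ModuleSpec(size=31),
        ]
    )
    sigma: float = 0.3
    n_experiments: int = 3
    geneset_size: int = 30
    geneset_overlap: float = 0.8
    n_null_sets: int = 3
    promoter_length: int = 1000
    motif_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_genes and n_samples must be positive")
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        for m in self.modules:
            if not (0.0 <= m.rho < 1.0):
                raise ValueError(f"rho must be in [0, 1): {m.rho}")
            if m.motif is not None:
                motif = m.motif.upper()
                if set(motif) - set("ACGT"):
                    raise ValueError(f"motif must be ACGT only: {m.motif}")
                if len(motif) > self.promoter_length:
                    raise ValueError("motif longer than promoter")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0.0 <= self.geneset_overlap <= 1.0):
            raise ValueError("geneset_overlap must be in [0, 1]")
        if self.motif_rate < 0:
            raise ValueError("motif_rate must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating, for recovery tests."""

    spec: SyntheticSpec
    module_membership: dict[str, int]           # gene -> module index
    planted_sets: GeneSetCollection | None = None
    motif_positions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def module_genes(self, index: int) -> list[str]:
        return [g for g, m in self.module_membership.items() if m == index]

    def module_geneset(self, index: int) -> GeneSet:
        return GeneSet(f"module_{index}", self.module_genes(index))


def _module_slices(spec: SyntheticSpec) -> list[slice]:
    out, start = [], 0
    for m in spec.modules:
        out.append(slice(start, start + m.size))
        start += m.size
    return out


def gen_compendium(spec: SyntheticSpec) -> tuple[CoexpressionCompendium, SyntheticTruth]:
    """Genes × samples matrix with compound-symmetric correlation per module."""
    spec.validate()
    rng = _rng(spec.seed, _STREAM_COMPENDIUM)
    values = rng.standard_normal((spec.n_genes, spec.n_samples))
    membership: dict[str, int] = {}
    gene_ids = spec.gene_ids
    for idx, (mod, sl) in enumerate(zip(spec.modules, _module_slices(spec))):
        z = rng.standard_normal(spec.n_samples)
        values[sl] = np.sqrt(mod.rho) * z + np.sqrt(1.0 - mod.rho) * values[sl]
        for g in gene_ids[sl]:
            membership[g] = idx
    frame = pd.DataFrame(
        values,
        index=gene_ids,
        columns=[f"S{j:04d}" for j in range(spec.n_samples)],
    )
    truth = SyntheticTruth(spec=spec, module_membership=membership)
    return CoexpressionCompendium(frame), truth


def gen_experiments(spec: SyntheticSpec, truth: SyntheticTruth) -> list[ExperimentTable]:
    """Independent dormant-vs-active contrasts with module genes up-shifted."""
    spec.validate()
    gene_ids = spec.gene_ids
    delta = np.zeros(spec.n_genes)
    for idx, (mod, sl) in enumerate(zip(spec.modules, _module_slices(spec))):
        delta[sl] = mod.delta
    tables = []
    for e in range(spec.n_experiments):
        rng = _rng(spec.seed, _STREAM_EXPERIMENTS + 100 + e)
        log_ratio = delta + rng.normal(0.0, spec.sigma, size=spec.n_genes)
        significance = 2.0 * norm.sf(np.abs(log_ratio) / spec.sigma)
        frame = pd.DataFrame(
            {
                "gene": gene_ids,
                "intensity_dormant": log_ratio,
                "intensity_active": np.zeros(spec.n_genes),
                "log_ratio": log_ratio,
                "significance": significance,
            }
        )
        tables.append(ExperimentTable(f"experiment_{e + 1}", frame))
    return tables


def gen_genesets(spec: SyntheticSpec, truth: SyntheticTruth) -> GeneSetCollection:
    """Planted sets overlapping each module, plus uniform null sets.

    Each planted set draws ``geneset_overlap · geneset_size`` members from
    its module (capped at the module size) and the rest uniformly from
    outside it; null sets are uniform over all genes.
    """
    spec.validate()
    rng = _rng(spec.seed, _STREAM_GENESETS)
    gene_ids = np.array(spec.gene_ids)
    sets: list[GeneSet] = []
    for idx, sl in enumerate(_module_slices(spec)):
        module_genes = gene_ids[sl]
        n_from_module = min(
            int(round(spec.geneset_overlap * spec.geneset_size)), len(module_genes)
        )
        n_rest = spec.geneset_size - n_from_module
        inside = rng.choice(module_genes, size=n_from_module, replace=False)
        # the remainder is uniform over every gene not yet drawn, so with
        # geneset_overlap=0 the set-module overlap follows the plain
        # hypergeometric expectation |set|·|module|/n_genes
        rest_pool = np.setdiff1d(gene_ids, inside)
        outside = rng.choice(rest_pool, size=n_rest, replace=False)
        sets.append(
            GeneSet(f"planted_{idx}", np.concatenate([inside, outside]),
                    description=f"overlaps module {idx}")
        )
    for j in range(spec.n_null_sets):
        members = rng.choice(gene_ids, size=spec.geneset_size, replace=False)
        sets.append(GeneSet(f"null_{j}", members, description="uniform null set"))
    collection = GeneSetCollection(sets=sets, universe_size=spec.n_genes)
    truth.planted_sets = collection
    return collection


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gen_promoters(
    spec: SyntheticSpec,
    truth: SyntheticTruth,
    genes: Sequence[str] | None = None,
) -> list[PromoterRecord]:
    """Uniform-ACGT promoters with each module's motif planted.

    By default one promoter per module gene is produced; the gene's module
    motif is inserted a Poisson(``motif_rate``) number of times at uniform
    offsets, on a uniformly chosen strand.  Planted (offset, strand) pairs
    are recorded in ``truth.motif_positions``.
    """
    spec.validate()
    rng = _rng(spec.seed, _STREAM_PROMOTERS)
    if genes is None:
        genes = [g for g in spec.gene_ids if g in truth.module_membership]
    records: list[PromoterRecord] = []
    bases = np.array(list("ACGT"))
    for gene in genes:
        seq = rng.choice(bases, size=spec.promoter_length)
        positions: list[tuple[int, str]] = []
        module_idx = truth.module_membership.get(gene)
        motif = spec.modules[module_idx].motif if module_idx is not None else None
        if motif and spec.motif_rate > 0:
            motif = motif.upper()
            n_occ = rng.poisson(spec.motif_rate)
            for _ in range(n_occ):
                offset = int(rng.integers(0, spec.promoter_length - len(motif) + 1))
                strand = "+" if rng.integers(2) == 0 else "-"
                planted = motif if strand == "+" else _revcomp(motif)
                seq[offset : offset + len(motif)] = list(planted)
                positions.append((offset, strand))
        records.append(PromoterRecord(gene=gene, sequence="".join(seq)))
        truth.motif_positions[gene] = positions
    return records


def write_bundle(spec: SyntheticSpec, outdir: str | Path) -> dict[str, str]:
    """Generate the full fixture bundle and write it into a directory.

    Returns a manifest of the files written (compendium TSV, one TSV per
    contrast, GMT, promoter FASTA, ground-truth JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comp, truth = gen_compendium(spec)
    experiments = gen_experiments(spec, truth)
    genesets = gen_genesets(spec, truth)
    promoters = gen_promoters(spec, truth)

    files: dict[str, str] = {}
    write_expression_tsv(comp, outdir / "compendium.tsv")
    files["compendium"] = "compendium.tsv"
    for table in experiments:
        name = f"{table.experiment_id}.tsv"
        write_experiment_tsv(table, outdir / name)
        files[table.experiment_id] = name
    write_gmt(genesets, outdir / "genesets.gmt")
    files["genesets"] = "genesets.gmt"
    write_fasta(promoters, outdir / "promoters.fasta")
    files["promoters"] = "promoters.fasta"

    truth_json = {
        "module_membership": truth.module_membership,
        "planted_sets": {s.name: s.genes for s in (truth.planted_sets or [])},
        "motif_positions": truth.motif_positions,
        "spec": {
            "n_genes": spec.n_genes,
            "n_samples": spec.n_samples,
            "modules": [
                {"size": m.size, "rho": m.rho, "delta": m.delta, "motif": m.motif}
                for m in spec.modules
            ],
            "sigma": spec.sigma,
            "n_experiments": spec.n_experiments,
            "geneset_size": spec.geneset_size,
            "geneset_overlap": spec.geneset_overlap,
            "n_null_sets": spec.n_null_sets,
            "promoter_length": spec.promoter_length,
            "motif_rate": spec.motif_rate,
            "seed": spec.seed,
        },
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)
    files["truth"] = "truth.json"
    return files
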