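"""End-to-end orchestration of the meta-analysis from one YAML config.

Stage order mirrors the analysis: per-contrast DE calls and their
intersection (the seed list) → coexpression clustering and GRN expansion
→ gene-set overrepresentation → GSEA over each contrast's ranked list →
promoter motif discovery per GRN → optional cross-species projection.
Every intermediate artifact is written as a plain file and a JSON
manifest records the config hash, seed and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coexpression import (
    coexpr_matrix,
    expand_cluster,
    grn_overlap,
    hcluster_seed,
    seed_dendrogram_newick,
    validate_induction,
)
from .core_io import (
    GeneSet,
    read_expression_tsv,
    read_experiment_tsv,
    read_fasta,
    read_gmt,
    read_ortholog_tsv,
    write_pfm,
    write_rnk,
)
from .de import DECriteria, call_de, intersect_de
from .enrichment import EnrichmentConfig, enrichment_report
from .gsea import GseaParams, make_ranked_list, nes_and_fdr, nes_matrix_cluster
from .motifs import discover_motifs
from .orthology import (
    cluster_timecourse,
    fraction_induced,
    project_grn,
    summarize_orthologs,
    timecourse_logratios,
)

logger = logging.getLogger("budnet")

__all__ = ["PipelineConfig", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated pipeline parameters (see ``from_yaml``)."""

    compendium: Path
    experiments: list[Path]
    genesets: Path | None = None
    promoters: Path | None = None
    orthologs: dict[str, Path] = field(default_factory=dict)
    timecourses: dict[str, Path] = field(default_factory=dict)
    timecourse_reference: dict[str, str] = field(default_factory=dict)
    outdir: Path = Path("budnet_out")
    seed: int = 0
    de: DECriteria = field(default_factory=DECriteria)
    coexpr_method: str = "mutual_rank"
    k_clusters: int = 4
    top_n: int = 300
    validate_fc: float = 1.2
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    gsea: GseaParams = field(default_factory=GseaParams)
    motif_ks: tuple[int, ...] = (6, 7, 8)
    motif_evalue: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent
        def p(x):  # resolve paths relative to the config file
            return (base / x).resolve() if not Path(x).is_absolute() else Path(x)

        cfg = cls(
            compendium=p(raw["compendium"]),
            experiments=[p(x) for x in raw["experiments"]],
            genesets=p(raw["genesets"]) if raw.get("genesets") else None,
            promoters=p(raw["promoters"]) if raw.get("promoters") else None,
            orthologs={k: p(v) for k, v in (raw.get("orthologs") or {}).items()},
            timecourses={k: p(v) for k, v in (raw.get("timecourses") or {}).items()},
            timecourse_reference=dict(raw.get("timecourse_reference") or {}),
            outdir=Path(raw.get("outdir", "budnet_out")),
            seed=int(raw.get("seed", 0)),
            de=DECriteria(**(raw.get("de") or {})),
            coexpr_method=raw.get("coexpr_method", "mutual_rank"),
            k_clusters=int(raw.get("k_clusters", 4)),
            top_n=int(raw.get("top_n", 300)),
            validate_fc=float(raw.get("validate_fc", 1.2)),
            enrichment=EnrichmentConfig(**(raw.get("enrichment") or {})),
            gsea=GseaParams(rng_seed=int(raw.get("seed", 0)), **(raw.get("gsea") or {})),
            motif_ks=tuple(raw.get("motif_ks", (6, 7, 8))),
            motif_evalue=float(raw.get("motif_evalue", 1.0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        missing = [str(f) for f in self.input_files() if not Path(f).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {', '.join(missing)}")

    def input_files(self) -> list[Path]:
        files = [self.compendium, *self.experiments]
        if self.genesets:
            files.append(self.genesets)
        if self.promoters:
            files.append(self.promoters)
        files.extend(self.orthologs.values())
        files.extend(self.timecourses.values())
        return files

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items(), key=lambda kv: kv[0])},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "stages": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        logger.info("stage %s: %s", stage, counts)

    def fail(stage: str, exc: Exception) -> None:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    # --- DE intersection -------------------------------------------------
    try:
        experiments = [read_experiment_tsv(p) for p in config.experiments]
        de_sets = [call_de(t, config.de) for t in experiments]
        seed_list = intersect_de(de_sets)
        (out / "seed_genes.txt").write_text("\n".join(seed_list.genes) + "\n")
        pd.DataFrame(
            [{"experiment": s.name, "n_called": len(s)} for s in de_sets]
            + [{"experiment": "intersection", "n_called": len(seed_list)}]
        ).to_csv(out / "de_counts.tsv", sep="\t", index=False)
        record("de_intersection", n_experiments=len(experiments), seed_genes=len(seed_list))
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        fail("de_intersection", exc)

    # --- coexpression GRNs ----------------------------------------------
    try:
        compendium = read_expression_tsv(config.compendium)
        sim = coexpr_matrix(compendium, config.coexpr_method)
        clusters = hcluster_seed(seed_list, sim, config.k_clusters)
        (out / "seed_dendrogram.nwk").write_text(seed_dendrogram_newick(seed_list, sim) + "\n")
        grns = []
        rows = []
        for i, cluster in enumerate(clusters, start=1):
            candidates = expand_cluster(cluster, sim, config.top_n)
            grn = validate_induction(
                candidates, experiments, config.validate_fc,
                seed_cluster=cluster, label=f"GRN{i}",
            )
            grns.append(grn)
            for gene in grn.members.genes:
                rows.append(
                    {
                        "grn": grn.label,
                        "gene": gene,
                        "origin": "seed" if gene in cluster else "expanded",
                        "passing_experiments": ",".join(grn.provenance.get(gene, [])),
                    }
                )
        pd.DataFrame(rows).to_csv(out / "grn_members.tsv", sep="\t", index=False)
        grn_overlap(grns).to_csv(out / "grn_overlap.tsv", sep="\t", index=False)
        record("coexpression_grn", clusters=len(clusters),
               grn_sizes=[len(g) for g in grns])
    except Exception as exc:  # noqa: BLE001
        fail("coexpression_grn", exc)

    # --- enrichment ------------------------------------------------------
    genesets = None
    if config.genesets:
        try:
            genesets = read_gmt(config.genesets)
            report = enrichment_report(genesets, grns, config.enrichment)
            report.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            record("enrichment", rows=len(report))
        except Exception as exc:  # noqa: BLE001
            fail("enrichment", exc)

    # --- GSEA ------------------------------------------------------------
    if genesets is not None:
        try:
            nes_rows = {}
            for table in experiments:
                ranked = make_ranked_list(table)
                write_rnk(ranked, out / f"{table.experiment_id}.rnk")
                results = nes_and_fdr(ranked, genesets, config.gsea)
                pd.DataFrame(
                    [
                        {
                            "set_name": r.set_name, "es": r.es, "nes": r.nes,
                            "perm_p": r.perm_p, "fdr": r.fdr, "n_hits": r.n_hits,
                            "leading_edge": ",".join(r.leading_edge.genes),
                        }
                        for r in results
                    ]
                ).to_csv(out / f"gsea_{table.experiment_id}.tsv", sep="\t", index=False)
                nes_rows[table.experiment_id] = {r.set_name: r.nes for r in results}
            nes_matrix = pd.DataFrame(nes_rows).T
            clustered, row_nwk, col_nwk = nes_matrix_cluster(nes_matrix)
            clustered.to_csv(out / "nes_matrix.tsv", sep="\t")
            (out / "nes_rows.nwk").write_text(row_nwk + "\n")
            (out / "nes_cols.nwk").write_text(col_nwk + "\n")
            record("gsea", experiments=len(experiments), sets=nes_matrix.shape[1])
        except Exception as exc:  # noqa: BLE001
            fail("gsea", exc)

    # --- motifs ----------------------------------------------------------
    if config.promoters:
        try:
            promoters = read_fasta(config.promoters)
            by_key = {p.gene.strip().casefold(): p for p in promoters}
            n_matrices = 0
            for grn in grns:
                subset = [by_key[k] for k in sorted(grn.members.keys) if k in by_key]
                if not subset:
                    continue
                stats, matrices = discover_motifs(
                    subset, ks=config.motif_ks, evalue_threshold=config.motif_evalue,
                )
                pd.DataFrame(
                    [
                        {
                            "oligo": s.oligo, "k": s.k, "observed": s.observed,
                            "expected": s.expected, "pval": s.pval,
                            "evalue": s.evalue, "sig": s.sig,
                        }
                        for s in stats
                    ]
                ).to_csv(out / f"oligos_{grn.label}.tsv", sep="\t", index=False)
                for m, matrix in enumerate(matrices, start=1):
                    write_pfm(matrix, out / f"motif_{grn.label}_{m}.pfm")
                n_matrices += len(matrices)
            record("motifs", grns=len(grns), matrices=n_matrices)
        except Exception as exc:  # noqa: BLE001
            fail("motifs", exc)

    # --- projection ------------------------------------------------------
    for species, map_path in config.orthologs.items():
        try:
            omap = read_ortholog_tsv(map_path)
            projections = [project_grn(g, omap, species) for g in grns]
            pd.DataFrame(
                [
                    {"grn": p.source_grn.label, "species": species,
                     "mapped": len(p.mapped), "size": len(p.source_grn.members),
                     "coverage": p.coverage}
                    for p in projections
                ]
            ).to_csv(out / f"projection_{species}.tsv", sep="\t", index=False)
            if species in config.timecourses:
                expr = pd.read_csv(config.timecourses[species], sep="\t", index_col=0)
                reference = config.timecourse_reference.get(species, expr.columns[0])
                tc = timecourse_logratios(expr, reference)
                tc.frame.to_csv(out / f"timecourse_{species}.tsv", sep="\t")
                fraction_induced(tc).to_frame("fraction_induced").to_csv(
                    out / f"induction_{species}.tsv", sep="\t"
                )
                clustered, row_nwk, _ = cluster_timecourse(tc)
                (out / f"timecourse_{species}.nwk").write_text(row_nwk + "\n")
                all_projected = projections[0]
                summarize_orthologs(all_projected, expr).to_csv(
                    out / f"ortholog_summary_{species}_{projections[0].source_grn.label}.tsv",
                    sep="\t",
                )
            record(f"projection_{species}", grns=len(projections))
        except Exception as exc:  # noqa: BLE001
            fail(f"projection_{species}", exc)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
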