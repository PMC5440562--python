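# budnet

Meta-analysis toolkit for deriving **bud-dormancy gene regulatory networks
(GRNs)** from multiple dormant-vs-active bud transcriptome contrasts, and for
testing whether those networks carry a carbon-starvation expression signature.

Axillary and apical buds arrest growth (para-, eco- or endodormancy) in
response to apical dominance, low red:far-red light, short days or seasonal
cues. Comparative transcriptomics across such experiments suggests that a
shared carbon-starvation program — sugar signaling, catabolism, autophagy and
senescence up; ribosomal and cell-cycle genes down — precedes and underlies
the growth-to-dormancy transition. `budnet` reimplements that analysis chain
as a tested, reusable pipeline:

1. **DE intersection** — call dormancy-induced genes per contrast
   (FC ≥ 1.2, boundary inclusive, optional significance gate) and intersect
   across experiments into a seed gene list.
2. **Coexpression GRNs** — cluster the seed list by coregulation over a
   compendium (Pearson r, or mutual rank MR = √(rank_i(j)·rank_j(i)), the
   default), expand each cluster with its most coregulated genes, and keep
   candidates induced in ≥ 1 contrast.
3. **Overrepresentation** — one-sided hypergeometric upper tail
   P(X ≥ k), X ~ Hypergeom(U, N, T), computed in log space so tails below
   1e-200 evaluate exactly; report columns mirror the published table
   (N, Freq(genome)×100, NExp, NObs, Freq(target)×100, p).
4. **GSEA** — weighted running-sum enrichment score (hit step
   |s|^p / Σ|s|^p, miss step −1/(n−n_hits)), gene-label permutation null
   with exhaustive enumeration on small spaces, sign-stratified NES and
   tail-ratio FDR.
5. **Motif discovery** — exhaustive 6–8-mer counting on both strands
   collapsed to canonical oligos, order-0 background, log-space binomial
   significance with per-k E-values, greedy pattern assembly into PFMs and
   mixed-case consensus strings.
6. **Cross-species projection** — ortholog-map projection of GRN membership,
   time-course log2 ratios vs. an "active bud" reference, induced-fraction
   summaries and row-max cell-type normalization.

A first-class **synthetic-data generator** emulates the study design —
correlated coexpression modules, up-shifted contrasts, gene sets overlapping
the modules at a controlled rate, promoters with a planted motif — and
records ground truth so every stage is testable by planted-signal recovery.

## Worked example

Run the whole chain on the default synthetic study (four planted modules of
14, 20, 13 and 31 genes, δ = 1.5 log2 units over σ = 0.3 noise, three
contrasts):

```python
from budnet.synthetic import SyntheticSpec, gen_compendium, gen_experiments, gen_genesets
from budnet.de import DECriteria, call_de, intersect_de
from budnet.coexpression import coexpr_matrix, hcluster_seed, expand_cluster, validate_induction
from budnet.enrichment import EnrichmentConfig, enrichment_report

spec = SyntheticSpec(seed=1)
comp, truth = gen_compendium(spec)
experiments = gen_experiments(spec, truth)
genesets = gen_genesets(spec, truth)

seed = intersect_de([call_de(t, DECriteria(significance_threshold=0.05))
                     for t in experiments])
sim = coexpr_matrix(comp, "mutual_rank")
clusters = hcluster_seed(seed, sim, k=4)
grns = [validate_induction(expand_cluster(c, sim, top_n=6), experiments, 1.2,
                           seed_cluster=c, label=f"GRN{i}")
        for i, c in enumerate(clusters, 1)]
print(len(seed), [len(c) for c in clusters], [len(g) for g in grns])

report = enrichment_report(genesets, grns, EnrichmentConfig(universe_size=spec.n_genes))
print(report[report.grn == "GRN1"]
      [["set_name", "N", "n_exp", "n_obs", "freq_target", "pval"]].to_string(index=False))
```

prints

```
78 [31, 20, 14, 13] [31, 21, 17, 14]
 set_name  N n_exp n_obs freq_target    pval
planted_0 30 0.465     0         0.0 1.0E+00
planted_1 30 0.465     1         3.2 3.8E-01
planted_2 30 0.465     0         0.0 1.0E+00
planted_3 30 0.465    24        77.4 6.5E-44
   null_0 30 0.465     0         0.0 1.0E+00
   ...
```

The three-contrast intersection recovers exactly the 78 planted module genes;
hierarchical clustering splits them into the four planted modules; each GRN
(seed cluster plus validated expansion) matches its module; and the enrichment
report flags only the gene set planted to overlap GRN1's module (24 of 30
members observed vs. 0.465 expected, p = 6.5E-44), while null sets stay at
p = 1.

The same stages are scriptable from the shell:

```bash
budnet synth fixture/                 # emit a synthetic bundle
budnet intersect fixture/experiment_*.tsv > seed.txt
budnet all --config run.yaml          # full pipeline + manifest
```

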