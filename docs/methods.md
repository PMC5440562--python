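# Methods

## Scope and data model

`budnet` operates on already-normalized summary data: per-contrast tables of
log2 ratios (dormant − active) with optional per-gene significance, a
genes × samples coexpression compendium of normalized log2 intensities,
GMT gene-set collections, RNK ranked lists, promoter FASTA (1 kb upstream of
the TSS, 5′→3′ on the gene's strand, supplied by the caller) and two-column
ortholog maps. No probe-level normalization is performed; inputs are treated
as pre-normalized log2 values. Gene identifiers are matched
case-insensitively after whitespace trimming (public sources mix AGI
casings); all internal coordinates are 0-based half-open.

## DE calling and the seed list

A gene is called dormancy-induced when its linear fold change 2^log2ratio is
≥ the threshold (default 1.2, inclusive — a gene at exactly FC 1.2 is kept),
optionally gated on significance ≤ a bound. The seed list is the intersection
across all contrasts; genes absent from a contrast's table count as
not-called there (conservative). The criteria behind the original published
seed list come from prior work and are under-specified, so they are exposed
as configuration rather than hard-coded.

## Coexpression and GRN assembly

Two coregulation measures are available. Pearson r uses pairwise-complete
observations (compendia have gaps); genes with < 3 finite values or constant
expression are excluded with a logged count. Mutual rank,
MR(i,j) = √(rank_i(j)·rank_j(i)) over each gene's descending-r partner list
(rank 1 = best, lower MR = more coregulated), is the default: the
proprietary coregulation score of the public compendium database is not
reproducible from its publication, and MR is that database's documented
measure. Seed clustering is agglomerative average linkage on d = 1 − r or
d = MR, cut to exactly k clusters (default k = 4, as in the source design;
the number is a parameter). Expansion scores every non-cluster gene by its
mean similarity to all cluster members (not best single hit — "most
coregulated with the cluster" read as a cluster-level query, and more
robust); the top-n candidates (default 300) are validated by induction at
FC ≥ 1.2 in ≥ 1 contrast, and the GRN is the seed cluster plus validated
candidates with per-gene provenance. All ties — ranking, clustering input
order, candidate ordering — break lexicographically by gene ID, which makes
every stage deterministic. Pairwise GRN overlap reports both the
smaller-set percentage and Jaccard, since either denominator convention is
defensible.

## Overrepresentation statistics

Enrichment of a gene set (size N) in a target list (size T) within a
universe of U genes is the one-sided hypergeometric upper tail
P(X ≥ k), X ~ Hypergeom(U, N, T), evaluated via the log-survival function
(log-gamma accumulation) so that values far below double underflow remain
exact; the log10 p-value is carried alongside the linear value. Binomial
approximations are not used. The default universe is **33,602** — the
TAIR10 Arabidopsis gene count. This constant was pinned by inverting the
expected-overlap column of the published enrichment table across multiple
independent rows (e.g. 429·295/3.766 and 507·271/4.089 both give ≈ 33,602);
it remains configurable because array-represented-gene universes are also
defensible. Report rendering is fixed to the table's printed precision
(genome frequency 2 d.p., expected overlap 3 d.p., target frequency 1 d.p.,
p-value 2 significant figures) so regression tests can compare strings
byte-for-byte. A Benjamini–Hochberg column is available but off by default
(the published table reports raw p-values). `fold_enrichment` is the generic
observed/expected ratio used for TF-target validation summaries.

## GSEA

Genes are ranked descending by log2 ratio (ties lexicographic). The running
sum increments at a set member by |score|^p / Σ_hits |score|^p and
decrements at a non-member by 1/(n − n_hits); the ES is the signed extreme
deviation. p = 1 ("weighted") is the default; at p = 0 the statistic equals
the classical two-sample Kolmogorov–Smirnov statistic on hit positions,
which the tests verify against an exact KS oracle. When all scores are zero
the hit increment falls back to uniform 1/n_hits.

Because the inputs are per-contrast summaries without per-replicate samples,
the null is **gene-label permutation** preserving set size — the only
feasible scheme here, stated explicitly. When the number of distinct
same-size sets is ≤ the permutation budget the null is enumerated
exhaustively (toy inputs become exact, and no add-one smoothing is applied
since the observed configuration is itself enumerated); otherwise sets are
sampled uniformly and the permutation p uses add-one smoothing,
(1 + #extreme) / (1 + #same-sign). NES = ES / mean(|null ES| of matching
sign); FDR is the standard sign-stratified NES tail ratio over the pooled
null, clamped to [0, 1]. Sets with < min_set_size members in the ranked list
(default 2) are skipped; sets under 10 members trigger a logged warning
(small sets may be unable to reach significance) but are reported rather
than filtered. NES matrices across samples are clustered on both axes by
average linkage on Euclidean distance, with missing values median-imputed
and a logged count; dendrograms serialize to Newick.

## Promoter motif discovery

All overlapping k-mers (k = 6–8) are counted on both strands and collapsed
onto canonical oligos (lexicographic minimum of word and reverse
complement). Each window position contributes a strand pair, so the reported
`observed` is the two-strand sum (+2 per position; palindromes +1, counted
once). Significance is computed on window *events* (observed/2 for
non-palindromes) — testing the doubled count against a per-window binomial
would halve the null variance and flag thousands of unremarkable words. The
background is an order-0 model estimated from the input promoters and
symmetrized over strands (A with T, C with G), which makes a word and its
complement equiprobable and keeps two-strand expectations coherent; a
genome-wide background vector can be supplied instead. Zero background
frequencies are floored at 1e-6 with a warning. The binomial upper tail is
evaluated in log space (log-gamma term summation past the underflow point);
the E-value multiplies by the number of possible canonical oligos at that k
((4^k + 4^(k/2))/2 for even k), i.e. the family is one word length. The
binomial is the standard oligo-counting approximation and is documented as
approximate for self-overlapping words (homopolymers show mild clumping
inflation).

Pattern assembly is greedy: oligos are visited from most significant, and
each joins the first existing matrix it aligns to — ungapped, either
orientation, shift bounded by max_offset (default 2), mismatches ≤
max_mismatch (default 1), alignment chosen by fewest mismatches then
smallest shift — weighted by its observed count, or seeds a new matrix (at
most 20). A matrix never grows wider than its seed oligo plus max_offset on
each side, keeping assemblies motif-sized. Consensus letters are the
per-column argmax base, uppercase when its frequency is ≥ 0.5 (the
mixed-case convention, e.g. tcTTATCCAc-style strings).

## Cross-species projection

GRN members are mapped through a one-to-many ortholog map; unmapped genes
are dropped with a logged count and coverage = mapped/|GRN|. Time-course
expression becomes log2 ratios against a designated "active bud" reference
time point (reference column identically zero; translation-invariant by
construction). One-to-many targets collapse by mean (default) or max — the
source is silent, and the mean is the unbiased heatmap summary. "Induced"
defaults to log2 ratio ≥ log2(1.2), aligned with the validation threshold.
Cell-type profiles are normalized per gene to the maximum-expressing cell
type (row-max = 1.0); all-zero rows pass through unchanged with a flag.

## Synthetic data generator

The generator emulates the study's statistical structure, not its biology:

- **Compendium**: module genes share a latent factor,
  x = √ρ·z_module + √(1−ρ)·ε, giving within-module correlation ρ in
  expectation at O(n) cost; background genes are independent standard
  normals. Defaults: 2,000 genes × 200 samples, four modules of 14, 20, 13
  and 31 genes at ρ = 0.8 (shaped like the published seed-list clusters).
- **Contrasts**: per-experiment log2 ratios are Normal(δ, σ) for module
  genes and Normal(0, σ) for background (δ = 1.5, σ = 0.3, three
  experiments); significance is the two-sided z-test against σ.
- **Gene sets**: each planted set draws overlap·size members from its
  module and the rest uniformly from the remaining genes, so at overlap = 0
  the set-module intersection follows the plain hypergeometric expectation;
  uniform null sets are added for FDR context.
- **Promoters**: i.i.d. uniform ACGT of 1 kb with the module's motif
  (default TTATCCAC, carrying the sucrose-repressible TATCCA core) inserted
  Poisson(rate)-many times at uniform offsets on a uniform strand; planted
  positions are recorded. Later insertions may overwrite earlier ones —
  positions are truth for counting, not a guarantee of disjoint placement.

One integer seed drives fixed per-stage `SeedSequence` streams
(compendium/experiments/genesets/promoters), so the whole bundle is
bit-reproducible and each generator is independently callable.

What the generator does **not** emulate: probe-level artifacts, batch
effects, heavy-tailed expression, correlated background structure, real
promoter composition (GC bias, repeats, CpG structure) or genuine regulatory
grammar. Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the assumed generative model, not performance on
real microarray data.

## Test-fixture problem sizes and analysis settings

The default fixture (2,000 genes × 200 samples, three contrasts) is the
package's desk-scale stand-in for a genome-wide compendium. The end-to-end
recovery test calls the seed list with a significance gate of 0.05 —
without it the three-contrast FC-only intersection admits ≈ 0.7% of
background genes by the closed-form normal tail. Because δ = 1.5 over
σ = 0.3 puts every module gene into all three contrasts, the planted modules
arrive wholly within the seed list, and cluster expansion can only add
background genes (each passing FC ≥ 1.2 in ≥ 1 of 3 contrasts with
probability 1 − (1 − 0.19)³ ≈ 0.47). The expansion budget top_n = 6 follows
from that closed form: recovering the smallest (13-gene) module at
Jaccard ≥ 0.8 tolerates ≈ 3 extra genes, i.e. top_n ≤ 0.25·13/0.47 ≈ 6.
GSEA null calibration uses 1,000 replicate rankings of 300 genes at 199
permutations each; enrichment calibration uses 10,000 hypergeometric draws.

## Numerical choices and degenerate inputs

- Hypergeometric and binomial tails in log space; linear values reported
  alongside log10 values that never underflow.
- Empty gene set or target → degenerate enrichment result (overlap 0,
  p = 1) with a warning, not an error.
- Zero significance in volcano tables clamps to 1e-300 with a warning.
- Constant-expression genes are excluded from correlation with a warning.
- All stochastic stages take explicit seeds; reruns are bit-identical
  (verified by the pipeline tests).

## Known limitations

- The coregulation measure approximates, but cannot reproduce, the source
  database's proprietary score; published GRN membership is therefore not a
  regression target, only the procedure is.
- The binomial oligo statistic is approximate for self-overlapping words;
  a compound-Poisson correction is out of scope.
- Gene-label permutation ignores inter-gene correlation, as all GSEA nulls
  of this kind do; FDRs on strongly coexpressed collections are optimistic.
- Published motif strings depend on the original supplementary promoter
  sets and are illustrative, not reproduction targets.
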