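# Methods

## Model and procedure

`ctsnet` treats cell-type vulnerability to a disease as the presence of
a statistically significant *disease gene module*: a connected
component of disease-associated genes inside a cell type-specific gene
interaction network. The procedure has two halves.

**Cell type-specific networks.** Counts are CPM-normalized per cell
(column sums scaled to 10^6) and averaged within each annotated cell
type; the per-type mean of gene g in type c over N_c cells is the only
expression summary used downstream. The cell type-specificity is the
minimum fold change of that mean against every other type, and the cell
type score standardizes a gene's specificity vector by its own median
and IQR across the k types. Since at most ⌊k/2⌋ of k values can be
strictly above their median, a positive score threshold retains genes
whose specificity in the chosen type exceeds their typical specificity.
The reference interactome — an undirected weighted edge list — is
pruned of its lowest-weight edges (a count-based removal of
⌊fraction·m⌋ edges, default fraction 0.2), restricted to genes present
in the expression data, and then induced per cell type on the genes
passing the score threshold. Isolated qualifying genes stay in the
vertex set: they are legitimate draws for the permutation null and
count toward mapped disease genes.

**Module significance.** Disease genes are intersected with a cell
type-specific network (T = number mapped); the connected components
they induce are candidate modules with sizes S_obs. Under the null that
disease genes do not preferentially interact, T vertices are drawn
uniformly without replacement and the largest connected-component size
S_rand among them is recorded; over n_perm replicates the permutation
p-value is #{S_rand > S_obs}/n_perm (strict inequality). One null is
computed per (cell type, T) and shared by all candidates in that
network, since T is identical for them. Benjamini–Hochberg correction
is applied across all candidates of a run and modules with q below the
FDR cutoff (default 0.1) are called significant. Because the null
survival function is monotone, larger candidates always receive
p-values no larger than smaller ones — in practice only the largest
component is ever significant.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `drop_weight_fraction` | 0.2 | fraction of lowest-ranked edges removed from the reference network |
| `score_threshold` | 0 | strict lower bound on the cell type score; 0, 1, 2 are typical working points |
| `n_perm` | 1000 | permutation replicates; p-values are multiples of 1/n_perm |
| `fdr_cutoff` | 0.1 | BH-adjusted significance level |
| `min_module_size` | 2 | smallest component reported as a candidate (1 counts singletons) |
| `fdr_scope` | global | pool candidates across cell types for BH, or correct per cell type |
| `seed` | 1 | master seed; each cell type's permutation stream is derived from (seed, CRC-32 of the type name) |

## Numerical conventions

- **Zero means.** x/0 with x > 0 yields +∞ (that type can only win the
  min if every reference is silent); 0/0 contributes nothing to the
  min; a gene whose references are all 0/0 gets NA specificity.
- **Quantiles.** Median and IQR use the linear-interpolation convention
  (R type 7). Rows with fewer than two defined specificities, a zero
  IQR, or an infinite median yield NA scores. A +∞ specificity — a
  gene expressed exclusively in one type — maps to a +∞ score and
  passes any finite threshold; when that +∞ makes the row IQR
  infinite, the row's finite entries are NA rather than risking ∞−∞
  arithmetic. At most one entry per row can be +∞, since exclusivity
  in one type forces finite ratios elsewhere.
- **Edge canonicalization.** Edges are stored as (min, max) gene pairs;
  reversed duplicates keep the maximum weight (conservative under the
  subsequent lowest-weight filter); self-loops are dropped. Weight-rank
  ties are broken by the lexicographic edge key, making the 20% filter
  deterministic under heavy ties.
- **p-value estimator.** The plain n/n_perm estimator is the default;
  a `--pvalue-pseudocount` flag switches to (n+1)/(n_perm+1) for users
  who need strictly positive p-values.
- **Determinism.** All randomness flows through numpy Generators seeded
  from explicit arguments; identical inputs and seed give byte-identical
  reports. Deriving each cell type's stream from the type name (not from
  the run's composition) means a single-type run reproduces the matching
  slice of a multi-type run.

## Synthetic data generator

The fixture generator provides ground truth for every stage.
Expression: gamma-Poisson (negative binomial) counts with a lognormal
per-gene base mean shared across types (variance μ(1+αμ); dispersion
α = 0 is the Poisson limit); planted markers have their mean multiplied
by a fold change f in their home type only, so marker specificity
converges to f as sampling noise vanishes. Defaults (k = 5 types,
50 cells/type, f = 4, α = 0.1, 2% markers per type) represent a
moderately noisy droplet-style experiment. Networks: a uniform random
(Erdős–Rényi-style) background of m sampled vertex pairs with
Uniform(0,1] weights, plus a random spanning tree over a designated
subset of disease genes, which guarantees a connected disease component
of at least the planted size; the benchmark conditions are 500
vertices, 1250 edges (density 0.01), 30 disease genes, and a 10-gene
planted module (or none, for calibration).

What the generator does **not** emulate: dropout/zero inflation, batch
effects, library-size gradients, doublets, and scale-free degree
distributions. Passing tests therefore demonstrate correctness of the
statistics under the stated sampling models, not robustness to every
artifact of real snRNA-seq data or real interactomes; no property under
test depends on the degree distribution, which is why a uniform
background suffices.

A distributional note: because the score standardizes each gene by its
own median/IQR, the upper tail of background (non-marker) scores is
invariant to the noise scale — at k = 5 roughly 15% of background
(gene, type) entries exceed score 1, concentrated on each gene's
highest-specificity type. Background genes are therefore *retained* in
cell type-specific networks at an appreciable, k-dependent rate
(bounded by ⌊k/2⌋/k at threshold 0); what separates planted markers is
that they clear the threshold in their home type essentially always.
The module statistics do not rely on background exclusion, only on the
permutation null computed within whatever network the threshold
produces.

## Design choices

- A single disease gene is not a module by default
  (`min_module_size` 2): an isolated vertex carries no interaction
  evidence; singleton counting is available for parity experiments.
- BH pools candidates across cell types within one run by default;
  the per-cell-type alternative is exposed because either scope is
  defensible when few candidates exist per type.
- The largest-component statistic of the null is computed with a
  union-find over the induced edges of each draw, giving O(edges)
  per replicate; observed components use networkx.
- External score tables are accepted through the same TSV schema the
  scorer writes, so any tissue-specificity metric can drive the network
  extraction.
- Gene identifier matching is exact and case-sensitive everywhere;
  silent case folding could merge distinct symbols.
- Upstream QC (cell/gene filtering, cell-cycle or mitochondrial
  removal, clustering/annotation) is out of scope: the tool consumes an
  already-filtered, annotated matrix. Cells present in only one of
  matrix/annotation are dropped with warnings rather than rejected.

## Problem sizes

The test suite and `scripts/acceptance.py` run entirely on simulated
data: scoring checks use 50–10,000 gene tables; null-calibration uses
200 simulated 500-vertex networks at 1000 permutations each; power uses
100 such networks with a planted 10-gene module; the exact-enumeration
oracle for the permutation null uses a 12-vertex graph with all 220
three-vertex draws. The full suite completes in well under a minute on
one CPU.

## Known limitations

- Specificity is computed on linear CPM means; a handful of
  high-expression cells can dominate a type's mean.
- The strict-inequality p-value can be exactly 0; with n_perm = 1000
  the smallest nonzero q is bounded below by 0.001 × m/rank.
- The weight-rank filter is count-based; a value-percentile variant
  would remove a different edge set under heavy ties.
- Very small cell types (the generator never produces them, but real
  atlases do) give noisy means; a warning is logged below 10 cells per
  type but no minimum is enforced.
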