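# ctsnet

Cell type-specific gene interaction networks and disease gene modules
from single-cell / single-nucleus expression data.

Many disease-associated genes are expressed in several cell types, yet
pathology often manifests in only a few of them. `ctsnet` implements an
analytical workflow built on the hypothesis that what makes a cell type
vulnerable is not individual disease genes but the presence of a
*disease gene module* — a connected set of disease-associated genes —
inside that cell type's gene interaction network. Given (a) a gene ×
cell count matrix with cell-type annotations, (b) a referenced
tissue-specific weighted gene interaction network (for example a GIANT
"top edges" download), and (c) a disease gene list, it:

1. normalizes counts to CPM and averages expression per cell type;
2. computes each gene's **cell type-specificity**, the minimum fold
   change against every other type,

   specificity(g, c) = min over r ≠ c of  mean(g, c) / mean(g, r),

   and the **cell type score**, the specificity standardized per gene
   by its own median and interquartile range across the k types,

   score(g, c) = (specificity(g, c) − median_g) / IQR_g ;

3. filters the reference network (dropping the lowest-ranked fraction
   of edges by weight, default 20%), intersects it with the measured
   genes, and induces one **cell type-specific network** per type on
   the genes with score above a threshold (0, 1, or 2 are typical);
4. maps disease genes onto each network; their connected components are
   candidate modules of size S_obs, tested against a permutation null:
   draw T genes at random (T = disease genes present in the network),
   record the largest connected-component size S_rand, repeat 1000
   times; p = #{S_rand > S_obs} / 1000, with Benjamini–Hochberg FDR
   across candidates and significance called at q < 0.1.

Because at most ⌊k/2⌋ of a gene's k scores can be positive, a positive
threshold guarantees the retained genes are more specific to the chosen
type than to the typical one.

## Worked example

All inputs can be simulated with planted ground truth — no downloads:

```
ctsnet fixtures --out-dir fixture --n-genes 400 --k 3 --cells-per-type 40 \
    --marker-frac 0.05 --fold 6 --n-edges 1600 --module-size 10 \
    --n-disease-genes 20 --seed 42
ctsnet run --expression fixture/matrix.mtx \
    --genes-sidecar fixture/genes.txt --cells-sidecar fixture/cells.txt \
    --annotation fixture/annotation.tsv --network fixture/network.tsv \
    --disease-genes fixture/disease_genes.txt \
    --score-threshold=-1000 --drop-weight-fraction 0 \
    --n-perm 1000 --seed 1 --out-dir out
```

which prints `6 candidate modules, 3 significant; report in out`, and
`out/module_report.tsv` contains:

```
cell_type  module_id  size  T   p_perm  q_fdr  significant  genes
type1      type1.1    12    20  0.0     0.0    True         g00007;g00088;g00107;...
type1      type1.2    2     20  0.607   0.609  False        g00016;g00150
type2      type2.1    12    20  0.0     0.0    True         g00007;g00088;g00107;...
...
```

The 10-gene planted module (plus two disease genes that background
edges happened to connect to it) is recovered with permutation p = 0,
while the chance 2-gene component is far from significance — only the
largest component among disease genes beats the largest-component null.
`out/scores.tsv` holds the per-gene specificity and score table; with
the planted 6-fold markers the home-type rows look like

```
gene    cell_type  specificity   score
g00000  type1      5.730060382   1.990288197
g00000  type2      0.1745182308  0
g00000  type3      0.1474094268  -0.009711803292
```

With the default `--score-threshold 0` each cell type keeps only its
score-positive genes, so modules whose genes are not specific to any
one type fragment into smaller components — stricter thresholds always
yield subnetworks (and modules) nested inside the looser ones.

The same stages are available as composable subcommands
(`ctsnet score`, `ctsnet network`, `ctsnet modules`, `ctsnet fixtures`)
and as a Python API (`ctsnet.compute_specificity`,
`ctsnet.identify_modules`, ...). Externally computed score tables (for
example other tissue-specificity metrics) can be supplied via
`--score-table` to bypass the internal scoring.

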