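# Methods

## Model and procedure

`tuba` searches an expression matrix (genes × samples) for biclusters:
groups of genes whose extremes of expression concentrate in the same small
subset of samples.  The pipeline has four stages.

### 1. Extremal sets

For each gene g, the extremal set E(g) is the k most extreme samples, with
k = round(x · N) under round-half-up and a floor of k = 2, where x is the
percentile parameter and N the number of samples.  `direction="high"` takes
the largest values (over-expression, the default), `direction="low"` the
smallest.  Ties in expression are broken deterministically by the stable
sort (value, canonical sample order), so a rerun on the same matrix gives
byte-identical results.  Only ranks enter the analysis from here on; the
expression values themselves are never used again.

### 2. Graph construction

For every gene pair, the overlap m = |E(g₁) ∩ E(g₂)| is scored with the
hypergeometric upper tail P(X ≥ m) given set sizes k₁, k₂ and cohort size
N — equivalently, a one-sided Fisher's exact test on the 2×2 membership
table.  Tails are accumulated in log space (`logpmf` plus a running
`logaddexp`) so that values down to ~1e-300 are representable, and the tail
is exactly 1.0 at or below the support floor.  Since k is constant across
genes at a fixed percentile, the p-value depends only on m and is computed
once per overlap count (a lookup table over m = 0…k).

Pairs whose p-value passes the cut-off become edges carrying their shared
samples.  Two cut-off modes are exposed:

* `cutoff_mode="raw"` thresholds the raw tail probability;
* `cutoff_mode="fdr"` (default) thresholds Benjamini–Hochberg-adjusted
  values, where the BH family is **all** G(G−1)/2 gene pairs, including
  zero-overlap pairs at p = 1.  This makes the adjusted values invariant to
  how many uninformative genes accompany the signal.

### 3. Bicluster extraction

1. **Prune to triangles.**  Edges whose endpoints share no common neighbor
   are removed, iterating to a fixed point; isolated nodes are dropped.
   Chance overlaps rarely close triangles, so this strips singleton edges
   while preserving dense signal.  It also enforces the structural floor:
   every bicluster has ≥ 3 genes.
2. **Seed.**  Maximum cliques are enumerated with Bron–Kerbosch
   (`networkx.find_cliques`).  Among the components containing a largest
   clique, the one holding the canonically smallest gene id is chosen (a
   determinism rule), and the seed is the union of all equal-size maximum
   cliques in that component that pairwise share a vertex.
3. **Trim and repeat.**  All edges incident to seed genes are removed, the
   graph is re-pruned, and steps 2–3 repeat until the graph is empty.
   Seeds are therefore pairwise gene-disjoint.
4. **Expand.**  Each seed gains every gene with ≥ 2 neighbors in the seed,
   evaluated once (single pass) against the *step-1 pruned* graph, so
   expansion sees edges that later trims removed.  Expanded gene sets may
   overlap across biclusters.  The bicluster's samples are the union of the
   shared-sample sets on the edges of its induced subgraph — a sample
   belongs if at least one gene pair co-ranks it extremal.

### 4. Scoring

Each member gene is tested for over-representation of the bicluster's
samples S(B) among its own top-m samples (m = |S(B)|); each member sample s
for over-representation of the bicluster's genes among G(s), the set of
*all* dataset genes ranking s extremal (the dataset-wide universe, so a
sample extremal for many background genes scores worse).  Both families are
BH-adjusted pooled across the whole collection, per axis.  The quality
index is

    Q(B) = min( frac. genes with FDR < 0.05, frac. samples with FDR < 0.05 ).

Genes are also ranked by degree inside the bicluster graph; the top five
are flagged as candidate drivers.

## Tunable parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `percentile` | 0.05 | fraction of samples | Small enough to isolate minority phenotypes, large enough that k ≥ 10 in cohorts of ~200; k is floored at 2. |
| `cutoff` | 1e-8 | probability | Stringent relative to the ~5·10⁵ pairs tested per 1,000 genes; the tuning curve is the principled way to set it per dataset. |
| `cutoff_mode` | `fdr` | — | BH-adjusted by default; `raw` matches the tuning-curve sweep. |
| `direction` | `high` | — | Over-expression; use `low` for silencing/deletion signatures. |
| `fdr_threshold` | 0.05 | FDR | Enters Q(B) only; conventional level. |
| `min_nonzero` | None | count | Optional filter dropping genes expressed in fewer samples. |

**Tuning heuristic** (`suggest_cutoff`): over a decade-spaced grid, pick the
least stringent cut-off whose next decade of leniency grows the edge count
by a factor in [1.4, 1.6].  Below that knee, relaxing the cut-off admits
mostly background pairs.  If no decade falls in the band, the closest to 1.5
is returned flagged `approximate`.  The curve's edge/gene/sample counts are
asserted non-decreasing in the cut-off.

**Permutation null** (`permutation_null`): each iteration independently
shuffles every gene's sample labels and recomputes all pair p-values.  On a
shuffled matrix no pair should survive the cut-off; the returned histogram
over overlap counts m makes the discreteness of the null explicit (raw p
takes only k+1 values).

## Downstream analyses

* **Collection comparison** — gene sets of two runs are matched by
  hypergeometric overlap against a shared gene universe, BH-adjusted,
  significant at FDR < 0.001 by default (stringent because the tables are
  typically scanned for any match at all).
* **Categorical labels** — one-sided Fisher's exact test of bicluster
  membership vs each label level; unlabelled samples are excluded from the
  2×2 table and the exclusion is logged.
* **Copy number** — per member gene, a hypergeometric test of whether the
  bicluster's samples are enriched among that gene's altered samples (gain:
  call ≥ +1; loss: call ≤ −1; the ±1 threshold treats any called alteration
  as an event, leaving amplitude to the caller).  Per-gene p-values are
  combined by Fisher's method, χ² = −2 Σ ln p on 2k df, giving one
  bicluster-level p; these are BH-adjusted across the collection.
* **Proximity** — a bicluster is `proximal` if ≥ 80% of its annotated genes
  fall in a single ≤ 25 Mb window on one chromosome (an amplicon-scale
  neighborhood), `distributed` otherwise, `unannotated` if no loci are
  known.
* **Membership clustering** — the binary bicluster × sample matrix is
  clustered under the Hamming distance in *counts* (scipy's normalized
  hamming × number of samples) with average linkage; the dendrogram is
  exported as Newick via scikit-bio.

## Synthetic benchmark

`default_benchmark` emulates a log-transformed bulk expression cohort:
per-gene means drawn from U(2, 8) with SD 1 on the log2 scale (lognormal in
linear space; a negative-binomial count mode with dispersion 0.3 followed by
log2(x+1) is also provided).  Three disjoint blocks of 20 genes × 10
samples are shifted by +6 SD — a strong, cleanly detectable effect chosen so
the benchmark tests the pipeline's plumbing rather than its power frontier.
The generator reproduces marginal heterogeneity and block structure; it does
**not** emulate gene–gene correlation outside implants, sample covariates,
batch effects, or count noise at low depth.  Ground truth is carried in a
JSON-serializable truth table, and `score_recovery` calls an implant
recovered when its best-matching bicluster reaches Jaccard ≥ 0.8 on both
axes.

Problem sizes used throughout the tests and examples — 200-sample cohorts
with 5% extremal sets (k = 10) — were chosen because a complete overlap then
scores ~4.5e-17, comfortably below any sensible cut-off after multiplicity
adjustment; at 100 samples and k = 5 the best attainable raw p is ~1.3e-8,
too weak to survive BH at 1e-8.

## Numerical and design notes

* All tail probabilities are computed in log space; the tail is exactly 1.0
  at or below the support floor rather than 1 − ε.
* Pairwise overlaps are computed as a single boolean-matrix product
  (int32 Gram matrix), not per-pair loops.
* Maximum-clique search is exact (Bron–Kerbosch) and thus worst-case
  exponential; it is fast on the sparse, pruned graphs this pipeline
  produces, but adversarially dense graphs at lenient cut-offs can be slow —
  tighten the cut-off via the tuning curve in that case.
* Every stage is deterministic given the input and configuration; output
  tables are byte-stable across reruns.
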