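# Methods

## Selection model

The selector asks, per gene, whether its negative Spearman correlations are
in excess of what a pairing-free null produces. The null is built by
sampling up to `null_sample_size` (default 5,000) non-constant genes and
permuting each independently across cells: marginal distributions (and
hence tie structure) are preserved exactly while all gene-gene pairing is
destroyed. All pairwise correlations over the sampled genes' upper triangle
are split at zero into a negative-side and a positive-side null; the two
sides are calibrated separately because the two half-distributions differ —
real co-regulation competes for probability mass on the positive side,
and ties skew the two tails asymmetrically.

Spearman correlations throughout the selection use **dense ranks** (tied
values share one rank, ranks consecutive). Count data is tie-heavy;
mid-ranks put large gaps and atoms into the null distributions, while dense
ranks keep them smooth enough for quantile cutoffs to be meaningful.

With `b` the sorted negative null vector, the cutoff `C_neg = b[⌊N(b)·FPR⌋]`
(1-based; most negative first). A discovery is strictly beyond the cutoff.
When `⌊N·FPR⌋ < 1` the single most extreme null value is used and a warning
emitted. The positive cutoff is mirrored on the descending positive vector
at the same FPR (the configuration has a single FPR governing both sides).

Per gene: `T_i` counts partners with `ρ < 0`, `D_i` counts `ρ < C_neg`,
`FP̂_i = T_i · FPR`, `FDR̂_i = FP̂_i / D_i` (clamped to [0, 1]; genes with
`D_i = 0` get `FDR̂_i = 1` so the rule stays total). Selection is
`FDR̂_i < fdr_threshold` (default 0.066 = 1/15: a 15-fold discovery excess)
**and** more than `min_positive_partners` (default 10, strictly greater, as
the module-membership inequality is written) partners with `ρ > C_pos`.
The second filter encodes that genes separating real populations should be
co-regulated with a module of like-behaving genes; isolated anti-correlated
genes are treated as noise (e.g. dropout artifacts).

### Numerical conventions

- Dense-rank Spearman values are rationals; on continuous data a pair can be
  *mathematically* exactly zero, and float rounding would then arbitrarily
  pick its side of the negative/positive split. Values within
  `ZERO_TOL = 1e-12` of zero belong to neither side.
- Constant genes have degenerate ranks; they are excluded from the null
  sample, assigned `ρ = 0` against every partner (contributing to no tally)
  and flagged in the output.
- Correlation tallies are computed block-wise (default 1,024 genes per
  block) against z-scored rank rows, so the full gene × gene matrix is
  never materialized; memory is O(block_size × n_genes).
- Randomness contract: with `rng = np.random.default_rng(seed)`, the gene
  sample is `rng.choice(candidates, size=m, replace=False)` over
  non-constant genes in original order, followed by `rng.permutation` per
  sampled gene in sampled order. Seeds are therefore portable across
  implementations.
- Fewer genes than `null_sample_size`: all non-constant genes are used
  (sampling stays without replacement); below 500 genes a warning notes the
  null may be unstable.

## Hyperparameters

| parameter | default | meaning |
| --- | --- | --- |
| `fpr` | 0.001 | target fraction of null correlations beyond each cutoff |
| `fdr_threshold` | 0.066 | per-gene estimated-FDR bound (= 1/15 excess) |
| `null_sample_size` | 5000 | genes sampled for the permutation background |
| `min_positive_partners` | 10 | module-membership bound (strict >) |
| `pre_remove_genes` | none | ids to drop before selection; `"default"` uses ribosomal/mitochondrial/hemoglobin symbol patterns |

The defaults are a deliberately conservative operating point: on null data
`D_i` is Poisson-like with mean `T_i·FPR ≈ 2.5` (at 5,000 genes), and
selection would need both `D_i ≳ 38` and an 11-gene positive module —
jointly astronomically unlikely, which is what makes the empty-selection
signal trustworthy.

## Synthetic data

The generators emulate the two standard simulation paradigms at the level
the selector actually sees — marginal count distributions and correlation
structure — not their full generative machinery (no library-size factors,
dropout layers, or dynamical GRN simulation).

- **Null**: each gene i.i.d. negative binomial across cells; gene means
  log-normal(0, 1) (median 1 count/cell, heavy right tail) and shared
  dispersion `r = 2` (variance `μ + μ²/2`), typical of biological
  overdispersion in UMI data.
- **Clustered**: `n_deg` marker genes partitioned round-robin across
  clusters; a marker's NB mean is multiplied by `effect_size` (default 8)
  in its owning cluster only. Mutually exclusive marker blocks induce the
  negative cross-block correlations the selector targets; the remaining
  genes are cluster-independent noise. With `n_deg = 0` the output is
  bit-identical to the null generator at the same seed.
- **Depth normalization of simulations**: `downsample_to_min` draws each
  cell's counts without replacement (multivariate hypergeometric) to
  `⌊0.95 × minimum cell total⌋`, mirroring the benchmark convention.
- **Simpson's-paradox pair**: two genes bivariate-normal with negative
  within-batch correlation; a common upward shift of the second batch makes
  the pooled correlation positive. Demonstrates why feature selection on
  merged batches is hazardous.

What passing tests on these generators does *not* show: robustness to
library-size confounds, ambient RNA, doublets, batch effects, or continuous
(trajectory-like) structure — real data carries all of these.

## Normalizers

- **UMI downsampling**: cells failing the minimum-genes or minimum-total-UMI
  filters are removed (counts of failures logged); each survivor is sampled
  without replacement from its transcript pool to exactly
  `target_umi = ⌊0.95 × min_total_umi⌋` (e.g. cutoff 3162 → depth 3003),
  realized as a per-cell multivariate hypergeometric draw — distributionally
  identical to enumerating the pool.
- **Truncated quantile normalization** (full-length/TPM data): cells need at
  least `g + 1` expressed genes; the `(g+1)`-th highest value is subtracted
  from the whole vector (no artificial gap above zero) and negatives
  clamped; boundary ties are broken uniformly at random under the seed so
  exactly `g` genes are retained; the retained values are quantile
  normalized against the mean-of-sorted-vectors reference (the classical
  convention — the choice of reference is ours). Afterwards every cell has
  the identical positive-value multiset. Degenerate edge: if *every* cell
  ties at the truncation boundary, the smallest reference value is 0 and
  those genes end at 0 rather than positive.

## Clustering

- **Locally weighted Louvain**: cell-cell Spearman matrix S (mid-ranks; cell
  profiles are the observations); similarity `D = (1/d²)/√n_cells` on
  squared Euclidean distances between rows of S, self-entries zero, exact
  duplicates given the row's largest finite value; per row subtract the 95th
  percentile or the 200th-largest value, whichever keeps fewer edges (at
  most min(5% of cells, 200) neighbors), clamp at zero; row-max normalize.
  Louvain modularity (networkx implementation, seeded) on the
  max-symmetrized matrix. Note the resolution behavior this inherits: with
  balanced 2-cluster data the kept-neighbor-to-cluster-size ratio is 10% at
  every n and Louvain tends to fragment the two true clusters (purity
  stays 1); at 4+ clusters the planted structure is recovered exactly.
- **K-means + elbow**: k = 1..k_max on per-gene min-max scaled data; on the
  (k, within-cluster SS) curve with both axes scaled to [0, 1], the k
  nearest the origin wins. 10 restarts per k under the seed.
- **K-means + silhouette**: scan k upward from 2; k is invalid when some
  cluster's maximum per-sample silhouette is below the dataset average. The
  scan *stops at the first invalid k* and returns the last valid one:
  empirically the collapsing average silhouette re-admits large k (2-blob
  data: k=3 invalid but k≥4 "valid" again), so "largest valid k" would
  over-cluster.
- **Affinity propagation + merge**: AP (scikit-learn, precomputed negative
  squared Euclidean affinities of Spearman rows, row-minimum preferences);
  cluster pairs get a z-statistic = half the exemplar distance in affinity
  space over the sum of the two within-cluster SDs (SD of member distances
  to their exemplar; the combination rule "sum" is our choice — pooled SD
  would also be defensible), converted to a transition probability with the
  normal survival function; Louvain on the cluster-level probability matrix
  merges fragments. Edges with probability < 1e-3 (≈ 3 combined SDs) are
  pruned first: on a single-edge graph modularity always merges regardless
  of weight, so two well-separated AP clusters joined by a ~1e-16
  probability would otherwise be fused.

## Recursion harness

Depth 0 is the whole dataset. At each node the selector runs on the subset;
stop reasons: `no_features`, `single_cluster`, `min_size` (a split that
would create any group of ≤ `min_cluster_size` cells, default 5, blocks the
whole split — the conservative reading; per-child closing is available via
`block_whole_split=False`), and an engineering `max_depth` guard (default
20). Leaf cell sets always partition the input.

## Benchmark metrics

Feature selection is scored against *detectable* differential genes: per
gene a one-way ANOVA across the true labels, Benjamini–Hochberg corrected
at α = 0.05 (the correction and threshold are our documented choice; raw
p < α is available). All eleven confusion-table metrics use the convention
metric = 0 (flagged) on empty denominators; MCC = 0 when any marginal is
empty. Purity is the sum over predicted clusters of their best truth-cluster
overlap divided by n; reverse purity swaps the roles. The hyperparameter
sweep computes the permutation background and tallies once per
(dataset, FPR) and re-applies only the selection rule per FDR, which is what
makes grid evaluation affordable.

## Problem sizes used in the shipped checks

Null-specificity runs use 20 replicates of 500 cells × 5,000 genes at the
default operating point; the hyperparameter sweep uses 5 such replicates;
the signal-sensitivity and recursion benchmarks use one 4-cluster dataset
of 2,500 cells × 10,000 genes with 2,000 markers (effect size 8),
downsampled to 95% of the minimum cell total. Oracle-equivalence checks
compare every per-gene quantity against a literal brute-force
transcription of the selection equations on 50-gene × 100-cell matrices.

## Known limitations

- The per-gene FDR estimate applies the pooled null FPR to every gene; a
  permutation check shows this is well calibrated on average (the permuted
  discovery count of a flagged gene matches `FP̂_i` almost exactly), but
  pair-level correlations of one gene are mutually dependent, so the tail of
  `D_i` is heavier than Poisson. At the 500-cell × 5,000-gene scale this
  makes the most permissive grid corner probabilistic: at FDR thresholds
  near 0.5 a single noise gene clears the bar in roughly one replicate in
  ten (usually at FPR = 0.01, where the module filter is no longer
  restrictive). The default operating point (FDR 0.066) is unaffected —
  selection there would need a ~15σ excess. With more cells the pair-rho
  dependence shrinks (cov ∝ 1/n_cells) and the sweep stabilizes.
- Louvain resolution fragments balanced two-population data (see above);
  the harness still halts because sub-fragments of one population select no
  features.
- Spearman-based similarity needs profile *shape* differences; populations
  differing only by a uniform shift across all genes are invisible to it.
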