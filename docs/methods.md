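# Methods

This note documents the statistical models, parameter choices, and numerical
conventions behind `proxirep`, and what the synthetic benchmarks do and do
not establish about behavior on real data.

## Interactome and distances

All analyses run on the largest connected component (LCC) of the input
protein–protein network, treated as undirected and unweighted; hop count is
the distance metric. Restricting to the LCC guarantees every proximity is
finite; nodes outside it are dropped with a logged warning, as are drug
targets or disease genes absent from the network. Gene identifiers are
opaque case-sensitive strings — any symbol normalization must happen
upstream. Distances are computed as multi-source breadth-first searches on a
cached sparse adjacency matrix (`scipy.sparse.csgraph`), which is what makes
tens of thousands of permutations per screen affordable.

## Proximity significance

The proximity `p(T,S)` of a drug-target module to a disease module is
compared against degree-preserving permutations. Nodes are partitioned into
base-2 logarithmic degree bins merged upward until each bin holds at least
100 nodes (configurable; exact per-degree bins are available for small
graphs). A null module replaces each original member with a uniform draw,
without replacement, from that member's bin.

Two design points deserve explanation:

* **Which side is randomized.** The default null (`null_mode="targets"`)
  randomizes only the drug side and holds the disease module fixed. Disease
  modules are connected subgraphs, while degree-matched replacements are
  scattered over the network; a null that also randomizes the disease side
  therefore compares the observed (clustered) module against systematically
  *closer-to-everything* dispersed modules, deflating null proximities and
  costing real power — in the planted benchmark it drives recovery from 7/10
  to 0/10 true drugs. Randomizing both sides, or only the disease side,
  remains available via configuration.
* **Permutation count.** The empirical p-value
  `(1 + #{null ≤ obs}) / (n_perm + 1)` cannot go below `1/(n_perm+1)`. When
  m pairs are screened jointly, Benjamini–Hochberg can only declare
  discoveries if that floor sits below `α·r/m` for the achievable rank r, so
  the pipeline default is `n_perm = 10,000` for screens of hundreds of
  pairs (the single-pair API defaults to 1,000). The vectorized sampler
  makes 10,000 permutations over 500 pairs a ~1 s computation.

Because hop-count proximities are means of small integer vectors, the null
distribution is discrete and heavily tied. With the `≤` tie convention the
empirical p-value is *conservative* (its CDF sits below the diagonal), never
anti-conservative; the self-null calibration test measures a type-I error at
or slightly below the nominal 5%. Ties thin out as the target-module size
grows, so the calibration experiment uses 20-target modules where the
continuous-uniform approximation is adequate.

A degenerate null (all permuted proximities identical) is flagged and
reported with z = 0 rather than a division by zero; its empirical p-value is
still well defined.

## Adjusted similarity and clustering

Similarity is `s = (m − p)/m`, with `m` the maximum proximity over *all*
pairs evaluated in the run (not only significant ones), so `s ∈ [0, 1]`. The
final score is the sigmoid `AS = σ(c·[(1+QC)·s − d_mid])`. Defaults
`c = 30`, `d_mid = 0.5` put the midpoint at half the normalized range and
saturate near the extremes; both are configurable and reported in run
metadata.

Clustering runs on the bipartite graph of significant associations weighted
by `s` (pre-bonus, since the bonus depends on the clusters), using greedy
modularity maximization (Clauset–Newman–Moore, weighted). Determinism is
enforced by inserting nodes and edges in sorted order and labeling clusters
by their lexicographically smallest member. The quality-cluster score QC of
a pair is the mean intra-cluster edge weight of the shared cluster, capped
at 1, and 0 when drug and disease sit in different clusters. Because drugs
and diseases could share names, clustering internally prefixes the two node
namespaces.

## Disease signatures

The expression pipeline runs in a fixed order: per-cohort preprocessing
(optional `log2(x+1)`; probes collapsed to genes by the mean) → merge of
cohorts on the intersection of gene symbols → batch correction → IQR
variance filter → differential expression → thresholding into ordered
up/down lists.

* **Batch correction** is a per-gene location/scale adjustment: standardize
  within batch, then restore the grand gene mean and the pooled
  *within-batch* standard deviation (weighted by batch degrees of freedom).
  Using the total standard deviation instead would re-inject the very batch
  offsets being removed and inflate the case/control contrast by the
  between-batch variance; with the within-batch pool, a planted ±1.5σ effect
  survives correction within a few percent while per-batch gene means agree
  to 1e-8. Genes with zero variance inside a batch skip the scale step
  (location is still adjusted) and are logged.
* **IQR filter**: genes whose Q75 − Q25 (linear-interpolation / type-7
  quantiles) falls strictly below the 10th percentile of the per-gene IQR
  distribution are removed — an expression-independent variance filter that
  discards flat genes before testing.
* **Differential expression**: equal-variance two-sample t test
  (`pooled_t`, df = n₁+n₂−2, two-sided), BH-adjusted across genes. For small
  cohorts, `moderated_t` shrinks per-gene variances toward a scaled
  inverse-chi-square prior whose degrees of freedom and scale are estimated
  from the observed variance distribution by the standard moment-matching
  of log-variances (digamma/trigamma inversion); the prior df is added to
  the t reference distribution. Genes with zero pooled variance get t = 0,
  p = 1 when the means agree and a capped-extreme p otherwise.
* **Thresholding**: mode `adjusted` keeps adj-p < α (default 0.01); mode
  `raw` thresholds unadjusted p-values instead — the fallback for small
  cohorts in which no gene survives adjustment. Up and down lists are each
  ordered by increasing fold change, where fold change is the case−control
  difference of means on the (log) scale.

## Reversal scoring

A drug profile is the complete ranked gene list of one drug in one cell
line, ranked by decreasing differential score (rank 1 = most up-regulated by
the drug; ties broken by gene id). For a tag set with sorted positions
V(1..t) among n genes, the two-sided KS running-sum statistic is
`a = max_j(j/t − V(j)/n)`, `b = max_j(V(j)/n − (j−1)/t)`, returning `a` if
`a > b` else `−b`. Tags missing from a profile are dropped with a log; a
profile containing no tag gene is marked unavailable.

The combined score is `(ES_up − ES_down)/2` when the up- and down-tag
statistics disagree in sign and 0 otherwise: a reverser pushes disease-up
genes toward the bottom (ES_up < 0) and disease-down genes toward the top
(ES_down > 0), giving ES < 0. Per disease signature, cell-line scores are
aggregated by arithmetic mean; the integer score of a drug counts the
signatures with aggregated ES < 0 and so lies in [0, n]. A drug with no
usable profile is `not_available`, which is distinct from an available drug
that reverses nothing (score 0).

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline reads, with planted truth:

* a Barabási–Albert interactome (default 2,000 nodes, mean degree ≈ 6) —
  heavy-tailed degrees and a single component, but none of the clustering,
  motif, or annotation-bias structure of curated interactomes;
* connected disease modules grown by seeded neighbor expansion (default 50
  genes, 5 diseases); "true" drugs draw their targets (default 5) from the
  focus module and its first neighbors — proximity ≤ 1 by construction —
  while decoys draw uniformly;
* expression cohorts with standard-normal baselines, a planted 10% of genes
  shifted by ±1.5σ in cases, optional constant additive batch offsets, and
  several cohorts sharing one planted signal (as real same-disease cohorts
  would). Real microarray data are heteroscedastic, correlated across genes,
  and mean–variance coupled; none of that is modeled;
* drug profiles over the full gene universe in two cell lines: reversers
  score planted-up genes around −3 and planted-down genes around +3 with
  Gaussian noise (σ = 0.25), neutrals score all genes N(0, 1).

Every generator is a pure function of (parameters, seed). Passing benchmarks
therefore demonstrate that the statistics recover structure *of the assumed
form* at realistic sizes — they do not certify performance on real
interactomes or arrays, where identifier mismatch, annotation bias, and
correlated noise dominate. Default problem sizes (2,000-node network, 100
drugs, 3 cohorts of 5,000 genes × 100 samples) keep a full end-to-end run in
seconds on one CPU.

One scale effect is worth knowing: if the interactome is small relative to
the disease module plus its neighbor halo, degree-matched random modules
land next to the module by chance and no association can reach significance.
The network should dwarf the module by roughly two orders of magnitude, as
real interactomes (~16,000 proteins vs ~50-gene modules) do.

## Reproducibility and conventions

The seed is a required pipeline parameter, echoed in every output table and
in the run-metadata JSON together with the full configuration and its hash;
rerunning a configuration reproduces outputs byte for byte. All orderings
that could depend on hash or insertion order (cluster labels, ranked
profiles, tie-broken sorts) are pinned to lexicographic conventions.
Exported formats: TSV tables, GraphML networks, GMT gene sets, and RNK
ranked lists.

## Limitations

* Only the average-to-nearest proximity is implemented; closest/kernel
  variants and closed-form nulls are out of scope.
* QC has no published closed form; the mean intra-cluster weight used here
  is one defensible choice, and printed similarity values depend on it and
  on (c, d_mid).
* The KS reversal score is used only through its sign; no permutation
  p-value is attached to it.
* Identifier mapping (probe→gene, UniProt→symbol) is assumed done upstream.
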