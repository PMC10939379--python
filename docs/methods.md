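# Methods

This note records the models, parameter choices and numerical
conventions behind `semnetphylo`, and what the synthetic experiments do
and do not demonstrate.

## Ontology model and structural metrics

The ontology is a rooted DAG of terms with child → parent `is_a` edges
(`part_of` and other relations can be enabled at load time; by default
only `is_a` is used, the most conservative reading of a process
hierarchy). Exactly one root is required; cycles and multiple roots are
fatal errors. Obsolete terms are excluded at parse time (via `obonet`).

Information content is purely structural:
`IC(t) = −log2((D_t + 1)/N)` with `D_t` the number of distinct
descendants of `t` (self excluded) and `N` the term-universe size. By
default `N` is the size of the loaded namespace graph; an optional
restricted universe (terms with ≥ 1 annotation) is supported for
corpora whose annotation covers only part of the graph — descendant
counts are then taken within that universe. The root has IC 0; leaves
have `log2 N`.

The semantic value sums a logistic weight over a term's strict
ancestors: `SV(t) = Σ_a sw(a)`, `sw(a) = 1/(1 + exp(−1/IC(a)))`. At
IC = 0 the weight is defined by its analytic limit, 1. `sw` is
strictly decreasing in IC and bounded in (0.5, 1], so SV grows roughly
linearly with ancestor count but weights generic ancestors more.
Summation is done in sorted term order so SV values are bit-reproducible.

Both metrics strictly increase from ancestor to descendant (`D` strictly
shrinks and the ancestor set strictly grows along any edge). Two
consequences are used throughout:

* the trimmed set `{IC > q20(IC) and SV > q20(SV)}` (strict
  inequalities, linear-interpolation percentiles) is descendant-closed,
  so the retained set is ancestor-closed and the root always survives;
* the standardized subgraph — retained terms re-wired to their minimal
  retained ancestors — preserves the original ancestor relation
  restricted to retained terms.

Trimmed terms map to their most proximal retained ancestors: ascend
every parent path to the first retained node, then drop any collected
node that is a strict ancestor of another. Mapping sets are therefore
non-empty antichains of ancestors-or-self.

Because IC and SV are graph-relative, re-standardizing the pruned
subgraph with *recomputed* metrics is not a meaningful operation (the
percentiles and `N` shift). Idempotence holds in the fixed-metric sense:
applying the same numeric thresholds to the same metrics trims nothing
further, and `build_standardized_graph` accepts explicit thresholds for
exactly this use.

## Enrichment and prioritization

The universe for a species is its annotated gene set after true-path
propagation (each gene's terms closed under ancestors, root excluded;
propagation is the default and can be bypassed). The per-term p-value is
the exact upper hypergeometric tail `P(X ≥ k)`.

The prioritizing adjustment is an empirical permutation rank: for `R`
uniform same-size gene draws from the universe (default `R = 1000`,
configurable; pipeline-scale runs in this repository use 100–200),
`p_adj = (1 + #{r : p_r ≤ p_obs})/(1 + R)` per term. This is a
deterministic function of the seed, valid (super-uniform) under the
null, and approximately uniform when the hypergeometric support is
fine. Profile selection keeps terms with `p_hyper < 0.05` and
`p_adj < 0.05`; when fewer than 100 terms qualify, selection extends
down the ranking (`p_adj`, then `p_hyper`, then term id) through the
raw-cut candidates to at most 100 terms. Profiles are then mapped onto
the standardized graph, and mapping targets with `IC < 0.1` (on the
standardized subgraph's recomputed metrics) are dropped; terms left
without targets are removed.

## Similarity and distances

The global term-similarity matrix is built over all standardized-graph
terms with IC/SV recomputed on that subgraph. Common-ancestor sets are
inclusive of the terms themselves. The three pairwise measures are each
normalized into [0, 1]:

* Resnik: `IC(MICA) / IC_max` over the standardized graph;
* XGraSM: mean IC of informative (IC > 0) common ancestors divided by
  `max(IC(a), IC(b))`; 0 when no informative common ancestor exists;
* AggregateIC: `2 Σ_{c ∈ CA} sw(c) / (SV⁺(a) + SV⁺(b))` with
  `SV⁺(t) = SV(t) + sw(t)`, which makes self-similarity exactly 1.

The consensus is their arithmetic mean. Resnik and XGraSM
self-similarities can be below 1, so the species distance matrix forces
a zero diagonal rather than reporting `1 − SSim(s, s)`.

Enriched-term similarity is the mean of the matrix over the cross
product of two mapping sets; species similarity is the best-match
average of the two directed sums divided by `|N| + |M|`; distance is
`1 − SSim`, checked to lie in [0, 1].

Ward linkage is applied to the precomputed semantic distances. This is
formally off-model (Ward assumes Euclidean geometry) but is the
method's convention; average and complete linkage are available for
sensitivity checks. Flat partitions cut the dendrogram with `maxclust`.
Metric MDS (SMACOF, 8 restarts, tight tolerance) supplies the 2-D
ordination. Homogeneity uses the Rosenberg–Hirschberg definition with
the degenerate single-class truth defined as 1.0; silhouette is
computed on the precomputed distances and is undefined (NaN, logged)
for single-cluster partitions. Distance-matrix correlation subsamples
at most 80 species per taxonomic group (seeded) and correlates
upper-triangle entries with Pearson's r.

## Components

Within a kingdom, a standardized term is "present" in a species when it
appears among the species' mapping targets. Core terms are present in
strictly more than 90% of species, with ancestors removed when a
qualifying descendant exists. Generic terms sit at shortest-path
distance exactly 2 from the root and aggregate sub-threshold
(≤ 90%) enrichment from strictly more than 50% of species via
descendancy. The association matrix scores each component term per
species as `−log10` of its adjusted p when enriched, else of the
minimum adjusted p over its enriched descendants, else 0; zero p-values
are clamped to the smallest positive double (logged). Scores use log
base 10. An optional reduction groups terms by average-linkage
clustering on consensus semantic distance (default 50 groups, group
score = mean member score).

NMF uses scikit-learn's coordinate descent with the deterministic
`nndsvda` initialization; the seed parameter is forwarded but the
factorization is seed-independent. Species are assigned to the argmax
component of their column of `H`.

## Mechanism evaluation

The reference magnitude for a species is the mean of the 10 lowest
log10 hypergeometric p-values of its reference (proteostasis) analysis.
Annotations under 10 genes are used whole. Otherwise a binary search
over subset sizes (one random draw per probe) finds the largest size
whose `floor(log10(min p))` does not undershoot the reference magnitude
by more than the tolerance (default 1 order of magnitude, configurable);
the search is repeated 30 times to form a sizing distribution, which
absorbs the noise of single probes. Consensus profiles draw sizes from
that distribution (forced to 10 when its mean is below 10), run the full
prioritized enrichment per draw (default 30 draws, configurable), and
keep terms enriched in strictly more than 20% of the outputs.
Component-exclusion analysis removes the component terms from every
profile's mapping targets (dropping enriched terms whose targets empty,
and species whose profiles empty, with a log record) and recomputes the
distance matrix, tree and HS/SS at the same k.

## Synthetic corpora

The generator emulates the study conditions end to end. The ontology is
a balanced-branch DAG: 8 depth-1 branch roots under the root, terms
split nearly evenly across branches and spread over 6 layers of
geometrically growing width (300 terms total by default); each term has
one within-branch parent, plus a second parent with probability 0.25
(80% within-branch, 20% cross-branch) — the sparse-DAG shape that keeps
distinct branches semantically distant, as in real process ontologies.

Modules are planted in distinct branches (one branch for the shared
core module, one per kingdom), each module's terms spread across the
branch's child subtrees so that standardization maps them to several
distinct retained targets. Defaults: core module of 4 terms, kingdom
modules of 8, each module term annotated to a dedicated pool of 5 genes
within each species' private, namespaced universe of 260 genes (each
gene also carries 1–3 background annotations). A species' query list of
70 genes draws `signal = 0.9` of its genes stratified across its module
pools — so every module term accumulates detectable overlap — and the
rest uniformly; every gene–term annotation is independently rewired to
a random term with probability `noise = 0.05`. Three kingdoms of 20
species each (60 species) are the default study condition.

What passing tests on these corpora show: the pipeline recovers planted
kingdom structure through the full standardization → enrichment →
similarity → clustering → NMF stack, thresholds behave as specified,
and signal strength maps monotonically to recovery. What they do not
show: behavior under real GO topology (tens of thousands of terms,
heavier multi-parenting), realistic annotation sparsity and
inter-species gene homology, or the taxonomic idiosyncrasies of real
genomes. Problem sizes in the test suite and reproduction script (300
ontology terms, 60 species, 100–200 permutations) are the package's
chosen demonstration scale; all are configurable upward.

## Numerical conventions and edge cases

* Percentiles: NumPy linear interpolation; trimming strict on both
  metrics.
* All randomness flows through `numpy.random.default_rng` seeds; set
  iteration never feeds a random stream (sorted first), so outputs are
  reproducible across processes.
* Boundary semantics: coverage filter inclusive (≥ 75% of the reference
  list); 90% / 50% / 20% rules strictly greater-than.
* Ties in profile ranking break by (adjusted p, raw p, term id);
  linkage ties follow SciPy's deterministic conventions.
* Degenerate inputs: empty profiles, all-zero association matrices,
  single-root violations and non-finite distances raise typed errors
  naming the offending species or terms; a standardization that retains
  only the root warns but proceeds.

## Known limitations

* The permutation prioritization is this package's concrete reading of
  "score-frequency reordering with permutation resampling"; the original
  tool's exact adjustment is not recoverable from its description.
* Ward on semantic distances is off-model (see above).
* The 50-group term reduction is a declared stand-in for an
  under-specified supplementary procedure; it is optional and off the
  default path.
* Resnik/XGraSM normalization choices (IC_max, max-IC denominator) are
  documented conventions; alternates can be plugged in behind the same
  interface.
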