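# Methods

## Model and procedure

`sigdistill` assumes that tumor samples sharing similar expression over the
genes that truly drive subtype heterogeneity will co-cluster, and that a
large differential-gene panel is largely redundant: groups of co-expressed
genes carry one "vote" each, so one well-chosen representative per group
retains the discriminating information.

The procedure has two steps per gene class *C_r* (a class is one subtype's
candidate panel, or the pooled panel treated as a single class):

1. **How many representatives.**  The class's cohesiveness is the inverse of
   the mean pairwise Euclidean distance between its gene expression vectors,
   `Co(C_r) = 1/d̄(C_r)`.  Under a cohesive strength `K > 0` the class
   contributes `N(C_r) = clamp(round(K·d̄), 1, |C_r|)` representatives.  The
   inverse-mean-distance form is the simplest index that increases with
   within-class similarity while making `N` and `Co` inversely related;
   rounding is half-up (`floor(x + 0.5)`) so the count is a deterministic,
   monotone step function of `K`.  A singleton or zero-diameter class has
   infinite cohesiveness and contributes exactly one gene at any `K`.
2. **Which representatives.**  The class's genes are partitioned into
   `N(C_r)` subclasses by average-linkage hierarchical clustering of their
   expression vectors, and from each subclass the member gene nearest to the
   subclass's arithmetic-mean vector (the fictitious center) is kept.

`K` is shared across classes and chosen by a sweep: for each grid value the
candidate signature (deduplicated union of all representatives) is scored by
re-clustering the samples on it and computing the clustering F-value against
the known subtype labels.  A single shared `K` keeps the search
one-dimensional; per-class strengths would square the grid for every extra
class without a principled way to couple them.  Ties on the maximal F-value
prefer first the smaller signature, then the smaller `K` — the goal is the
most succinct panel.  In `per_subtype` mode each subtype's panel is swept
independently (its own best `K`) and the chosen representatives are unified,
which mirrors reporting per-subtype feature genes alongside a pooled
signature; the two modes need not agree and their overlap is reported.

### Validation indices

Sample clusterings are scored externally against the ground-truth labeling
with the plain (unadjusted) Rand index — the fraction of sample pairs on
which the two partitions agree — and the clustering F-measure: per truth
class, the best `2pr/(p+r)` over clusters (precision `p`, recall `r` from
the class/cluster intersection, 0 for empty intersections), combined as a
class-size-weighted mean.  Both equal 1 exactly for identical partitions.

### Clustering

Average linkage (UPGMA) on Euclidean distances is used throughout, for
genes (subclass partitioning) and samples (evaluation).  The agglomeration
is implemented in-package so the tie-break is fully specified: among cluster
pairs at the minimal mean distance, merge the pair whose smallest original
leaf indices sort lexicographically least.  This makes merge sequences a
pure function of the distances and input order, and cut partitions invariant
to input permutation up to relabeling; SciPy's `linkage` is used only as an
independent cross-check in the tests.  Dendrograms are cut into exactly `k`
clusters by undoing the last `k−1` merges; evaluation cuts at the number of
distinct ground-truth labels (4 for the four-subtype scheme, 2 for ER±).

Before sample-space distances, expression is standardized per gene
(z-score across samples; constant genes map to zero rows) by default, with a
toggle: raw log-expression scales differ across genes and would otherwise
let high-variance genes dominate the distance.  Gene-space distances for
cohesiveness and subclassing use the expression values as given.

## Synthetic data

The generator emulates the *structure* of log-scale expression matrices
grouped into receptor-status subtypes: per subtype, `blocks_per_subtype`
blocks of `block_size` redundant informative genes; per block a shared
per-sample latent factor giving exact pairwise correlation ρ between
members (`x = noise_sd·(√ρ·f + √(1−ρ)·ε) + shift`), with the mean shift
`effect_size · noise_sd` applied only in the block's own subtype; plus
`n_noise_genes` pure-noise genes.  Defaults — 4 subtypes × 15 samples,
2 blocks × 8 genes per subtype, effect size 3, ρ = 0.85, 300 noise genes,
unit noise SD — give a compact analogue of a cohort of ~10² samples with a
moderately sized differential panel embedded in noise, small enough that the
full sweep runs in seconds.

What the generator does **not** emulate: platform-specific artifacts
(bead-chip normalization, RNA-seq count noise), batch effects, unbalanced
or overlapping expression programs, and correlated noise between blocks.
Passing recovery tests therefore show that the procedure finds planted
redundancy structure under Gaussian assumptions, not that it will match any
particular clinical dataset's accuracy.

## Numerical choices

- **Determinism.**  All randomness flows through explicit seeds; the sweep,
  clustering and selection are deterministic given their inputs.  Gene rows
  are sorted by ID before computing sample distances during evaluation, and
  arrays are made contiguous before reductions, so scores do not depend on
  the order classes contributed genes or on a DataFrame's memory layout
  (both can flip exact ties through floating-point summation order).
- **Ties.**  Nearest-to-center ties go to the lexicographically smallest
  gene ID; UPGMA ties as above; K-sweep ties prefer small signatures, then
  small K.
- **K grid.**  40 log-spaced points from `0.5 / max_r d̄_r` (every class at
  `N = 1`) to `max_r |C_r| / min_r d̄_r` (every finite-cohesion class at
  full size), so both limit regimes are always visited.
- **Degenerate inputs.**  Zero-diameter classes hit the infinite-cohesiveness
  sentinel (`N = 1`); constant genes standardize to zero rows; panels with
  genes missing from the matrix are evaluated on the intersection with a
  logged warning (fixed external panels rarely have full probe coverage),
  but fewer than two usable genes is an error.

## Limitations

- The cohesiveness and count formulas are the simplest forms consistent with
  the qualitative constraints they encode; other monotone completions
  (e.g. ceiling instead of rounding) would shift signature sizes slightly.
- F-value-guided selection evaluates on the same labeled samples it
  optimizes; no held-out generalization estimate is attempted.
- With strong separation many K values tie at F = 1 and the succinctness
  tie-break drives the result; with weak separation the chosen signature can
  score below the full panel on individual draws — the sweep maximizes over
  its own candidates, not over all panels.
- Reports deliberately omit wall-clock timestamps so reruns are byte
  identical; the run log records seed, config digest and stage outcomes.
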