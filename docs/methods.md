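# Methods

## Problem and overall procedure

Cell sorting at a flow or mass cytometer executes a *gating strategy*: a
sequence of one-dimensional thresholds ("gates") on chosen markers that
routes each cell to a target subpopulation. Choosing the gating markers,
their order, and the thresholds by hand injects expert bias and is hard to
reproduce. This package derives the full strategy from the data:

1. **Clustering** — identify candidate subpopulations with a
   nonparametric EM mixture model (npEM), deliberately over-specifying the
   component count, or with agglomerative hierarchical clustering.
2. **Silhouette refinement** — iteratively reassign negative-silhouette
   cells to their nearest cluster; emptied clusters disappear, collapsing
   the over-specified fit to the effective number of subpopulations.
3. **Gating tree** — grow a binary conditional-inference tree that
   classifies cells into the refined clusters; internal nodes carry
   (marker, threshold) gates, `value <= threshold` routes left.
4. **Purification** — choose the pruning height `L` and iterate
   "filter contaminants, retrain" until every leaf is pure; removed cells
   are kept in an *extra bin* for inspection.
5. **Stability** — strata bootstrap of the tree for per-node split-point
   ranges and hierarchy reproducibility.

## Input model and transform

Events arrive as FCS 2.0/3.0/3.1 list-mode files or delimited text, one
row per cell, one column per marker. Compensation is assumed done
upstream. Intensities are transformed by `asinh(v / cofactor)`; the
cofactor defaults to 5 (mass cytometry convention) with 150 the usual
fluorescence choice. Negative and zero intensities pass through the
transform untouched — no truncation or jitter of the zero point mass.

## The npEM mixture model

Cell `i` is a vector `x_i` of `r` marker intensities, modeled as a finite
mixture of `m` components; conditional on its component, the coordinates
are independent with completely unspecified univariate densities
`f_jk`. The fit alternates:

* **M-step**: mixing proportions `lambda_j = mean_i p_ij`.
* **KDE-step**: `f_jk(u) = (1 / (n lambda_j h)) sum_i p_ij K((u − x_ik)/h)`
  with standard normal kernel `K` and one pooled bandwidth
  `h = 0.9 min(sigma, IQR/1.34) N^{-1/5}` computed on all `N = n·r`
  pooled values (Silverman-type rule; sigma uses ddof = 1, IQR uses
  linearly interpolated percentiles).
* **E-step**: `p_ij ∝ lambda_j prod_k f_jk(x_ik)`, rows normalized;
  computed in log space with a density floor of 1e-300 so a cell in the
  far tails of every component still receives a valid posterior.

The first iteration is an M-step on a hard k-means partition (single
initialization, fixed seed), making the whole fit deterministic given the
seed. Convergence is declared when the max-absolute change of both the
posteriors and the mixing proportions falls below `tol = 1e-8`
(`max_iter = 500`; non-convergence warns and returns the current fit).
Components whose mixing proportion drops below `1/n` cannot support a
density estimate (the KDE normalizes by `n lambda_j`) and are frozen out
with a warning. Hard labels are the posterior row argmax.

Two practical properties of this estimator matter for interpreting
results. First, because each component's per-marker density is an
arbitrary KDE, a single component can absorb two subpopulations that
differ on *one* marker only: the bimodal marginal costs no likelihood.
Subpopulations separated on two or more markers jointly cannot be
absorbed this way (a product density would put mass on the empty
off-diagonal combinations). Second, duplicate components covering the
same mode receive posteriors proportional to their mixing weights
everywhere, so the argmax collapses them — this is why over-specifying
`m` (default 10) and letting refinement tidy up works.

## Silhouette refinement

For cell `i`, `a_i` is its mean Euclidean distance to its own cluster
(self excluded), `b_i` the smallest mean distance to any other cluster,
and `s_i = (b_i − a_i)/max(a_i, b_i)`. Singleton-cluster cells and exact
duplicates (`a = b = 0`) get `s_i = 0`. Each iteration reassigns *all*
cells with `s_i < 0` simultaneously to the cluster attaining `b_i` (ties
to the lower cluster id), then recomputes. The cost
`|sum of negative s_i|` is tracked; the loop stops when no negatives
remain, the first time the cost would increase (the previous partition is
kept), or at `max_iter = 100`. Input label ids are never renumbered.

## Conditional-inference gating tree

At each node, every marker is tested for association with the cluster
labels via the permutation-framework linear statistic
`t_j = sum_i w_i x_i 1(y_i = j)` with its exact conditional mean and
covariance under permutations (Strasser–Weber moments). The test
statistic is the quadratic form `(t − mu)' Sigma^+ (t − mu)` using a
Moore–Penrose pseudo-inverse, referred to chi-square with
`df = rank(Sigma)`; the quadratic form needs no resampling, unlike a
max-type statistic. Per-node p-values are Bonferroni-adjusted across the
`r` markers; if the smallest adjusted p-value exceeds `alpha`
(default 0.05) the node stops. Otherwise the winning marker is split at
the observed value maximizing the maximum absolute standardized component
of the two-sample linear statistic `t_j = sum_{x_i <= v} 1(y_i = j)`,
subject to at least `minbucket` cells per side
(default `max(20, ceil(0.01 n))`). Ties go to the smallest candidate
value. The stored threshold is the midpoint between the winning
candidate and the next larger observed value: the gate runs through the
middle of the empty interval, as one would draw it at a sorter. Placing
it on the left group's largest observed value instead would make every
split point an extreme order statistic of a cluster tail, and bootstrap
split-point ranges would then systematically fail to contain the split
points of a tree retrained on held-out data (a resample never exceeds
the training maximum; fresh data do, about half the time per node).
Additional stops: pure nodes, nodes smaller than
`2·minbucket`, and the height cap used by purification. The influence
function is the raw marker value, not ranks, so split points are in
intensity units.

## Purification

`L` is the smallest height at which the height-capped tree has every
cluster as the dominant label of at least one leaf (if none works, the
full tree height is used with a warning; a single-leaf tree over more
than one cluster is an error). The loop then repeats: grow at height `L`;
in every leaf below the purity threshold (default exactly 1.0), remove
cells not matching the leaf's dominant label into the extra bin; retrain
on the retained cells. It terminates when all leaves meet the threshold
or a round removes nothing, is guarded at 50 rounds, and aborts with a
diagnostic if a cluster would lose every cell. Because the final tree is
the one grown on the final retained set, re-applying it to those cells
reproduces the pure partition exactly. A single cluster may end up
dominant in several pure leaves; the leaf→cluster map is reported.

## Strata bootstrap

Each of `B` replicates resamples cells with replacement *within each
cluster stratum*, preserving per-cluster counts and total `n`. The full
grow/purify stage is rerun per replicate. Internal nodes are matched
across trees by their path signature — the ordered (marker, branch-side)
steps from the root plus the node's own marker; the side is included
because sibling subtrees may legitimately split on the same marker.
Per-node split points are summarized as empirical (min, max) ranges, not
normal intervals, because split-point bootstrap distributions are
typically multi-modal. The fraction of replicates reproducing the
reference tree's marker hierarchy exactly is reported, as is the count of
replicates whose pipeline failed. Each replicate draws from its own
spawned random stream, so a `B = 10` run is a prefix of a `B = 20` run
with the same seed and widening `B` can only widen ranges.

Containment of independently retrained split points in these ranges is a
diagnostic, not a guarantee. The range of `B` bootstrap draws is centered
on the training-sample estimate, so an estimate retrained on fresh data —
which differs from the training estimate by about `sqrt(2)` sampling
standard deviations — escapes the range at a per-node rate of several
percent even when the bootstrap law is perfectly calibrated, and more
often when a split lies in a sparse intensity region, where the split
point behaves like an order statistic whose variability the bootstrap
understates. On data with wide empty gaps between populations expect
occasional out-of-range flags; dense data around the cuts (the usual
real-data situation) pins the estimates and the ranges agree much
better.

## Synthetic study design

The generator draws per-component, per-marker independent normals on the
arcsinh scale, with qualitative levels `low = (1, 0.3)`,
`low-mid = (2, 0.3)`, `mid = (3, 0.3)`, `high = (5, 0.3)`; a two-part
level such as `"low high"` is an equal mixture of the two named levels,
and explicit `(mean, sd)` pairs are accepted. Sampling is
per-component, so label counts equal the requested component sizes
exactly.

The default design is a five-state, three-marker mixture of 850 cells
(component sizes 100/300/150/100/200) in which marker 3 is "high" for
every component — an always-on lineage marker that carries no gating
information — and markers 1–2 encode the five states. The level pattern on (marker 1, marker 2) is

| component | n   | marker 1 | marker 2 |
|-----------|-----|----------|----------|
| 1         | 100 | low      | low      |
| 2         | 300 | high     | high     |
| 3         | 150 | low      | high     |
| 4         | 100 | high     | low      |
| 5         | 200 | low-mid  | mid      |

four corner states plus an intermediate state between the low/low corner
and the rest. The pattern was chosen, within the level vocabulary, so
that (i) all five components are resolvable by the clustering stage — a
pair of components differing on a *single* marker is absorbed into one
bimodal-KDE mixture component unless the gap is the full low↔high span
(the product-density model fits a bimodal marginal at no likelihood
cost), so close pairs must differ on both markers; (ii) the intermediate
state's tails overlap the low/low corner, so single-marker gates leave
mixed leaves and the purification loop does real work; and (iii) at
every tree node one marker and one cut dominate the split statistic, so
the gating hierarchy is reproducible under resampling.

What the generator does *not* emulate: spillover/compensation artifacts,
the zero-inflated point mass of unstained channels, heavy-tailed debris
and doublets, cross-marker correlation within a subpopulation, and
channel-specific noise scales. Passing the synthetic suite therefore
demonstrates the machinery (clustering, refinement, tree growth,
purification, bootstrap) under clean mixture conditions, not robustness
to instrument artifacts; real data should be inspected with the usual QC
before gating.

## Numerical and design choices

* Density floor 1e-300 inside the E-step product: numerical guard only.
* Silhouettes are computed in-package (the refinement needs the identity
  of each cell's nearest foreign cluster, not just the value); an O(n^2)
  distance matrix is used, sizing the refinement stage to tens of
  thousands of cells.
* Variable-selection ties resolve to the first marker in column order;
  split-candidate ties to the smallest value; dominant-label ties to the
  lower cluster id. All tie-breaks are deterministic.
* The induction statistic between conditions is the difference of mean
  arcsinh intensities per population (cells routed on surface markers
  only); an alternative `abs` mode reports the difference of absolute
  mean values. Populations empty in either condition yield NaN, never 0.
* Problem sizes in the test-suite simulations (850-cell design, 20
  replicate seeds, B = 50 bootstrap) match the synthetic study design
  above; they are the package's reference conditions for the recovery and
  stability guarantees quoted in the README.

## Known limitations

* The npEM stage scales as O(n^2) per marker per iteration in the
  kernel evaluations; subsample (as is standard practice) before
  clustering millions of cells, then gate the full data with the tree.
* Case weights in the tree are 0/1 subset indicators; fractional weights
  are unsupported.
* FCS reading covers list-mode F/D/I data with uniform integer widths;
  doubled-delimiter escapes in TEXT values and analysis segments are not
  parsed. FCS writing is out of scope.
* `hclust` and `npem` may disagree on boundary cells; the tree stage is
  deliberately agnostic to which clusterer produced the labels.
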