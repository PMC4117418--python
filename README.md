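# ccast

Automated, data-driven construction of cell-sorting gating strategies for
flow and mass cytometry.

Sorting a subpopulation at a FACS instrument requires a gating strategy:
which markers to gate on, in what order, and where to draw each
threshold. Choosing these by eye injects expert bias and is hard to
reproduce. `ccast` derives the whole strategy from the data: it clusters
a heterogeneous single-cell population, refines the clusters, and distils
them into a binary decision tree of `(marker, threshold)` gates that an
operator can execute directly at a sorter — typically using only a small
subset of the measured markers.

## Method

Given an events table `x_i ∈ R^r` (cells × arcsinh-transformed markers):

1. **Nonparametric mixture clustering.** Fit a finite mixture with
   density `f(x) = Σ_j λ_j Π_k f_jk(x_k)`, where each `f_jk` is an
   unspecified univariate density estimated as a posterior-weighted
   Gaussian KDE with pooled Silverman bandwidth
   `h = 0.9·min(σ, IQR/1.34)·(nr)^(-1/5)`. An EM-like loop alternates
   the M-step `λ_j = mean_i p_ij`, the KDE update, and the E-step
   `p_ij ∝ λ_j Π_k f_jk(x_ik)`, from a deterministic k-means start with
   a deliberately over-specified component count (default 10).
   Agglomerative hierarchical clustering is a drop-in alternative.
2. **Silhouette refinement.** Cells with negative silhouette
   `s_i = (b_i − a_i)/max(a_i, b_i)` are reassigned to their nearest
   foreign cluster until the cost `|Σ_{s_i<0} s_i|` stops improving;
   emptied clusters vanish, collapsing the fit to the effective number
   of subpopulations.
3. **Conditional-inference gating tree.** At each node, markers are
   tested for association with the cluster labels by the
   permutation-framework linear statistic (quadratic form with exact
   conditional moments, χ² p-value, Bonferroni-adjusted across markers;
   stop at `α = 0.05`); the winning marker is split where the
   standardized two-sample statistic over all admissible cut points is
   maximal. `value ≤ threshold` routes left.
4. **Purification.** Pick the smallest tree height `L` at which every
   cluster dominates some leaf, then iterate *filter* (drop cells not
   matching their leaf's dominant cluster into an "extra bin") and
   *retrain* until every leaf is pure. The final tree is the sortable
   strategy; each leaf's unique root-to-leaf path is the gate sequence
   for that population.
5. **Stability.** A strata bootstrap (resampling within clusters)
   reruns the tree stage `B` times, reporting per-node split-point
   (min, max) ranges and the fraction of replicates reproducing the
   gating hierarchy exactly.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices, and known limitations.

## Worked example

Simulate the built-in five-state, three-marker design (850 cells; marker
3 is an always-on lineage marker carrying no gating information) and run
the full pipeline with a 50-replicate bootstrap:

```sh
ccast simulate --seed 3 --out sim.csv
ccast gate --input sim.csv --format csv --clusterer npem --components 10 \
      --seed 3 --bootstrap-n 50 --out run/
```

The run directory contains the strategy, per-cell labels, bootstrap
summary, and a report. For this seed the report shows

```
"n_cells": 850, "n_clusters": 5, "n_populations": 5,
"markers_used": ["Marker1", "Marker2"], "pruning_level": 3
```

— the pipeline recovered the five simulated states and gates them with
two of the three markers. The exported strategy (`run/strategy.json`)
reads as executable gate sequences, one per sortable population:

```
population leaf=2 cluster=4 n=99:  Marker1 <= 3.583 AND Marker2 <= 1.752
population leaf=4 cluster=8 n=201: Marker1 <= 3.583 AND Marker2 > 1.752 AND Marker2 <= 4.109
population leaf=5 cluster=0 n=150: Marker1 <= 3.583 AND Marker2 > 1.752 AND Marker2 > 4.109
population leaf=7 cluster=3 n=100: Marker1 > 3.583 AND Marker2 <= 2.872
population leaf=8 cluster=1 n=300: Marker1 > 3.583 AND Marker2 > 2.872
```

and the bootstrap summary reports a hierarchy identical in 50/50
replicates with split-point ranges such as `Marker1 ∈ (3.297, 3.777)` at
the root — the gates one would program into a sorter, with their
resampling spread.

Other subcommands: `ccast apply` routes new events through an exported
strategy; `ccast induction` computes per-population signaling changes
between a stimulated and an unstimulated condition (cells routed on
surface markers only); `ccast bootstrap` is `gate` with the bootstrap
always on. The same functionality is available as a library
(`ccast.run_pipeline`, `ccast.npem_fit`, `ccast.grow_tree`,
`ccast.ccast_purify`, ...). FCS 2.0/3.0/3.1 and delimited text are both
accepted via `--input`/`--format`.

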