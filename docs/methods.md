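# Methods

`argbm` implements spatial inference on ancestral recombination graphs
(ARGs) under Brownian motion: maximum-likelihood estimates of the
per-generation dispersal rate and of root locations, and Gaussian location
distributions for arbitrary genetic ancestors.  This note records the model,
the numerical choices, what the synthetic-data engine does and does not
emulate, and the design decisions taken where the design was genuinely open.

## Model

An ARG is a directed graph of haploid genomes: edges point from parent to
child, each annotated with the genomic span transmitted; a recombination
node has two parents over complementary spans and therefore creates a loop
in the graph.  Node times are in generations, increasing into the past.  We
take the ARG (topology and node times) as known and model the movement of
lineages forward in time as Brownian motion with dispersal rate σ²
(variance of offspring displacement around the parent per generation; a
2×2 matrix Σ in two dimensions), so a child's location is normally
distributed around its parent's with variance σ²t for an edge of length t.

On a tree, tip locations are jointly Gaussian with covariance σ² times the
matrix of shared ancestry times — the classic phylogenetic Brownian-motion
model.  On an ARG two complications arise, both caused by loops:

1. a sample below a recombination node has several paths to the root, so
   "the shared time of two samples" is no longer well defined edge-wise;
2. displacements along the two halves of a loop are not independent: they
   must sum to the same total so that the two parental lineages meet at the
   recombination node (the loop-closure constraints).

Both are handled by working with *sample paths*.  Let `Sp` be the matrix of
shared times between sample-to-root paths, `P` the path→sample indicator and
`R` the path→root indicator.  The path-tip vector is Gaussian,
`Lp ~ N(Rμ, σ² Sp)`, and imposing that all paths of a sample end at the same
point yields the sample-location covariance

    S = (Pᵀ Sp⁻ P)⁻¹,

with `Sp⁻` a pseudo-inverse.  Conditioning on loop closure always *shrinks*
variance: a single symmetric loop of arm time t gives the recombination
node variance σ²t/2 (the Brownian-bridge value; a point at time s below the
loop top has variance s(2t−s)/(2t) on a bridge of round-trip duration 2t).
This shrinkage is the source of the dispersal-estimation bias the package
exists to demonstrate: real populations do not become more clustered each
time a recombination event is added to the genealogy, so fitting this model
to data with a fixed set of sample locations makes the dispersal estimate
grow with the number of trees included.

### Minimal path basis

The full path set grows super-linearly with recombination events, but
`ns + n_recomb` paths carry all the information: one *canonical* path per
sample — at every recombination node take the lowest-id parent — plus, for
each recombination node, one path that is canonical below the node for a
designated descendant sample, takes the other parent there, and is
canonical above.  The designated sample is the oldest sample reachable from
the node through canonical edges (ties to the lowest id); if no sample is
reachable through canonical edges alone, any downward route is used.  Any
such choice yields an equivalent basis: each extra path introduces its
non-canonical edge, absent from every other basis path, so the basis is
linearly independent in edge space and spans the full path set (deviations
below a node occur only at strictly more recent recombination nodes, making
the change-of-basis matrix triangular with unit diagonal).  `S` computed
from a minimal basis equals `S` from the full enumeration; this is verified
by tests rather than assumed.  Nodes with k > 2 distinct parents (possible
in simplified ARGs) get k−1 extra paths each.

### Estimates

With the observed sample locations ℓ*, the estimates are the
generalized-least-squares solutions

    μ̂  = (Rᵀ Sp⁻ R)⁻¹ Rᵀ Sp⁻ P ℓ*,
    σ̂² = (P ℓ* − R μ̂)ᵀ Sp⁻ (P ℓ* − R μ̂) / ns,

applied columnwise over habitat dimensions (the quadratic form is the full
2×2 dispersal matrix in 2D, including the cross-covariance).  The σ̂²
denominator is `ns` — the maximum-likelihood convention, with no
degrees-of-freedom correction for the `nr` estimated root locations.  On a
tree both collapse to the classic GLS answers.  In finite samples the `ns`
denominator leaves the usual downward bias of order `(ns − nr)/ns`, which is
visible when an ARG is chopped into many roots; the parameter-recovery
checks therefore use unchopped ARGs, where `nr` is small.

A genetic ancestor — the lineage of a given sample at a given genome
position, followed to a given time — has a Gaussian location with mean

    E[La] = μ̂_ra + saᵀ Sp⁻ (P ℓ* − R μ̂)

and variance `σ̂² V`, where `sa` is the vector of shared times between any
root path of the ancestor and the basis paths, `ta` its time to that root,
and

    V = (ta − saᵀ Sp⁻ sa)  +  (e_ra − Rᵀ Sp⁻ sa)ᵀ (Rᵀ Sp⁻ R)⁻¹ (e_ra − Rᵀ Sp⁻ sa),

the first term due to Brownian motion and the second to root-location
uncertainty; both are non-negative and are reported separately.  The
estimate is invariant to which root path is chosen (tested exhaustively on
small graphs).  For a point mid-edge at time τ, `sa` accrues the partial
overlap `time(parent) − τ` on the entry edge and full overlaps above —
forced by linearity of shared times.  Confidence regions are normal
quantiles in 1D and χ²₂ ellipses in 2D; the dispersal plugged into the
variance defaults to σ̂² but can be overridden with a known rate, so that
location uncertainty can be judged separately from dispersal bias.

### Two likelihood forms

`log_likelihood` reports the density of the *observed sample locations*,
`N(m, σ² S)` with `m = S Pᵀ Sp⁻ R μ` (equal to μ𝟙 for a single root).  This
is the quantity that reduces exactly to the classic tree likelihood and is
maximized by (μ̂, σ̂²) whenever every loop closes under a single root.
`path_log_likelihood` is the path-form singular Gaussian `N(Rμ, σ²Sp)`
evaluated at `Pℓ*` with pseudo-determinant on its support; μ̂ is its exact
maximizer over μ at any fixed dispersal on *any* ARG.  The two differ by a
parameter-free constant unless a chop severs a loop across two different
roots; in that case the printed estimator remains the path-form GLS optimum
while the exact conditional likelihood of the locations acquires a
μ-dependent normalization (the probability that lineages from different
roots meet).  The package follows the printed estimator and exposes both
objectives; the tests pin each against numerical optimization of the
objective it actually maximizes.

### Chopping, windowing, simplification

Because deep history is both poorly resolved and poorly described by
Brownian motion, an ARG can be *chopped* at a past time: every edge
crossing the cutoff is truncated there with a fresh, independent root node
per crossing child→parent adjacency (no merging), and strictly older
material is dropped.  Root locations are treated as fixed and mutually
independent; an optional scalar prior variance on root locations can be
added (in shared-time units, between pairs of paths from the same root).
Note that with freely estimated roots this relaxation provably leaves μ̂ and
σ̂² unchanged — it inflates `Sp` only in directions spanned by the root
means, which GLS projects out — but it does widen ancestor variances `V`.
One subtlety of chopping: when a cut severs a loop, the two paths of a
sample end at *different* roots yet still share the edges below the
recombination node, so their shared time is positive.

*Windowing* restricts the ARG to the local tree at a focal position plus k
trees on each side (fewer at chromosome ends); genomic spans are half-open
`[left, right)` in 0-based coordinates throughout.  *Simplification*
retains only sample nodes and nodes that are coalescent in at least one
local tree, and is used only by the averaging-up baseline, matching how
that method is applied in practice.

## Baselines

* **Single-tree GLS** (`tree_fit`) — the ARG fit applied to a one-tree ARG;
  for a tree the path and sample matrices coincide.
* **Composite dispersal** (`composite_dispersal`) — the unweighted mean of
  per-tree ML dispersal estimates over the first n local trees, each tree
  fit with its own root; between-tree correlations are ignored and no
  importance sampling is performed.
* **Averaging-up** (`averaging_up`) — nodes processed in increasing time
  order, each internal node placed at the unweighted mean of its children's
  locations on the simplified ARG; deterministic, no uncertainty, invariant
  to node times.
* **Midpoint model** (`MidpointModel`) — independent edge displacements
  with each recombination node placed at the exact midpoint (weights ½/½,
  no span weighting) of its two parents' arrival points.  The implied node
  covariance is `σ² W T Wᵀ` with `W` the accumulated weight matrix and `T`
  the diagonal of edge durations; roots and dispersal are estimated by GLS
  under this covariance.  On a single loop the recombination node again has
  variance σ²t/2, but — unlike the main model — the variance of nodes on
  the parental lineages is not reduced.  Its `locate` analogue conditions
  on sample locations with the fitted roots plugged in and does not
  propagate root-location uncertainty.

## Synthetic data

ARG topologies come from the Hudson coalescent with recombination
(msprime, `record_full_arg=True`, haploid samples), which produces exactly
the full-ARG node roles the model expects (coalescent, recombination, and
unary common-ancestor nodes).  Locations are then drawn under three forward
models from fixed root locations (default: all roots at the origin; no
habitat boundary — boundary effects are a property of individual-based
simulations that this engine deliberately does not emulate):

* **conditioned** — edge displacements jointly Gaussian, conditioned on the
  loop-closure constraints.  The constraint rows are built from the
  canonical spanning forest: one row per non-canonical parent edge
  (equivalently, a fundamental cycle basis; when a chop severs a loop
  across two roots the right-hand side carries the root-location offset, so
  parental lineages still meet exactly).  Conditioning uses the standard
  linear-Gaussian projection `D + T Aᵀ (A T Aᵀ)⁻¹ (b − A D)`, which is
  independent of the dispersal and exact — loop closure holds to machine
  precision, and the sample covariance is exactly σ²S (also available in
  closed form via `conditioned_location_covariance`).
* **unconditioned** — independent edge displacements; per-path tip
  locations with covariance σ²Sp (a sample's paths end at different
  points).
* **midpoint** — independent displacements with recombination nodes
  averaged, matching the midpoint model's covariance.

Every draw records true node locations and edge displacements, enabling
parameter-recovery, coverage, and bias experiments against ground truth.
All outputs are reproducible bit-for-bit given the configuration and seed.

What passing tests on these data do **not** show: real populations have
local density regulation, finite habitats with reflecting boundaries, and
non-zero mating distances, none of which the Brownian engine emulates.  The
conditioned sampler shows the estimator is correct *under its own model*;
the midpoint sampler provides a controlled misspecification that isolates
the loop problem.  Biases measured against individual-based simulations in
the wild will differ in magnitude (not in direction).

## Bias experiments

`bias_experiment` fits estimators to the ARG restricted to the first k
trees for a grid of k.  Two designs are exposed: `nested` draws one set of
sample locations on the full (chopped) ARG and refits nested windows — the
misspecified setting in which the ARG dispersal estimate climbs with tree
count while the composite stays flat; `redraw` draws fresh locations on
each windowed ARG, so conditioned data are exactly the assumed process at
every window size (the well-specified control; with nested data a window-k
fit on fully-conditioned locations is *not* correctly specified, because
the full conditioning shrinks the sample covariance below what the window
model expects, producing a mechanical upward trend).  Defaults: nested for
midpoint data, redraw for conditioned data.  On midpoint data the midpoint
estimator is correctly specified and flat, so the ordering
slope(ARG) > slope(midpoint) ≈ 0 realizes the expected "slower rise" of the
midpoint model.

## Numerical choices

* Pseudo-inverses of shared-time matrices use an eigendecomposition with
  relative cutoff 1e−10 on eigenvalues (`Sp` is exactly singular for
  redundant path sets and near-singular for short loops).  A minimal basis
  has full-rank `Sp`, so no information is discarded there.
* Canonical-parent tie-break: lowest node id; deterministic.
* `Rᵀ Sp⁻ R` and the midpoint covariance are solved by Cholesky
  factorization with a diagnostic error naming the usual cause (a root with
  no informative path, or a redundant basis).
* Chopping: a node exactly at the cutoff keeps its identity and becomes a
  root (no zero-length edges are ever created); samples at or above the
  cutoff are an error; a cutoff above the oldest edge warns and is a no-op.
* Degenerate queries: locating a sample at its own time returns its
  observed location with V = 0 exactly; querying beyond the local root is
  an error.
* Monte-Carlo comparisons in the test-suite hold the *family-wise* error of
  a 3-standard-error check across all matrix entries compared (Šidák
  threshold), rather than testing ~10³ entries each at 3 SE.

## Problem sizes

The shipped checks run on deliberately modest problems chosen to make every
quantity recomputable from scratch in one short run: toy graphs with known
closed forms; 20 random ARGs of ≤10 samples and ≤6 recombination nodes with
2×10⁵ conditioned draws each; 20 replicates of 50-sample ARGs (sequence
length 10⁵ bp, recombination rate 10⁻⁸ per bp per generation, population
size 10⁴) for recovery and coverage; and 15 replicates of 30-sample ARGs
over {1, 5, 10, 20}-tree windows for the bias directions.  These sizes are
the package's reference conditions; the machinery itself is dense linear
algebra in the number of paths (ns + recombination events in the window)
and handles hundreds of paths comfortably.

## Known limitations

* The model's loop-induced shrinkage is a genuine misspecification for real
  data; dispersal estimates grow with the number of trees and ancestor
  estimates are pulled toward the sample centroid.  This package
  quantifies that behavior rather than fixing it.
* ARG topology and times are taken as known; there is no integration over
  ARG uncertainty and no inference from sequence data.
* Sample coordinates must be complete (no missing-location imputation) in
  1 or 2 dimensions.
* The averaging-up baseline reproduces point estimates only; it has no
  uncertainty to compare against.
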