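# Methods

## Problem setting

Gene expression and DNA methylation measured on the same samples can be
summarized as two weighted undirected networks over the same gene set: a
co-expression network and a co-methylation network. An *epigenetic
module* is a gene set that is densely interconnected in **both** layers
simultaneously — a common module of the two-layer network. `epjnmf`
discovers such common modules in an arbitrary number of layers M ≥ 1 and
provides the simulation and evaluation machinery needed to validate the
procedure end to end without any external data.

## Quality model for multilayer modules

For a module C in layer m with adjacency W_m, the per-layer quality is
the modularity density

D_m(C) = (L(C,C) − L(C,C̄)) / Σ_{v∈C} d_vm,

where L(A,B) sums w_ijm over ordered pairs (so internal weight counts in
both orientations), C̄ is the complement of C and d_vm is the weighted
degree. Two conventions are deliberate:

* **Both-orientations internal weight.** With L(C,C) = 2 × (internal
  edge weight), the whole vertex set of any layer with positive weight
  scores exactly 1, which gives the measure a fixed, interpretable
  ceiling and anchors several exact tests. Counting each edge once would
  break this self-consistency.
* **Geometric-mean aggregation.** Across layers the module score is
  D(C) = (∏_m D_m(C))^{1/M}, so a module must be good in *every* layer —
  a single weak layer drags the product down, which encodes the
  common-module requirement. When any D_m(C) ≤ 0 the geometric mean is
  undefined; we define the score as 0. This floors "failed" modules at
  the quality of an empty module and keeps the ranking of good modules
  unchanged. A partition's score is the sum of its module scores.

The plain edge density 2|E(C)|/(|C|(|C|−1)) (an edge being any pair with
w > 0) is reported as a diagnostic; weights enter only through D_m.
Betweenness uses hop-count shortest paths on the layer's support, with
unordered vertex pairs counted once.

## Joint tri-factorization

All layers are factorized at once as W_m ≈ B H F_m with B (n×k),
H (k×k) and F_m (k×n) entrywise non-negative, minimizing
e = Σ_m ‖W_m − B H F_m‖²_F. B and H are shared; only F_m is
layer-specific, so the k latent features must explain every layer — this
is what makes the extracted modules common rather than per-layer.
Optimization is by cyclic multiplicative updates (B, then H, then each
F_m); each block update is the standard majorize–minimize rule for a
least-squares factor with the others fixed, so a full sweep never
increases the objective and an exactly factorizable input is a fixed
point. Denominators are floored at 1e−12 to avoid 0/0. Vertex i joins
module argmax_j B_ij (ties to the lowest column; empty columns are
dropped with k reduced accordingly; an all-zero row goes to module 1
with a warning). A bi-factor variant (H pinned to the identity and never
updated, W_m ≈ B F_m) is available via `use_h=False`.

### Initialization

Restarts draw B i.i.d. uniform on (0,1] scaled by mean(W)^{1/3}, set
F_m = Bᵀ, and set H = (I + 0.05·U(0,1])·mean(W)^{1/3}. Three properties
motivated this choice over fully i.i.d. factors:

* **Strict positivity.** A multiplicative update can never revive an
  entry that starts at zero, so every entry starts positive.
* **Symmetry.** The layers are symmetric, and stationary points have
  F_m close to a rescaled Bᵀ; starting on that manifold removes a large
  family of spurious basins. With fully i.i.d. factors, on the standard
  benchmark below (n = 128, Z_out = 1, k = 4) roughly a third to half of
  restarts converged to local optima in which one community is split and
  two merged (NMI ≈ 0.8); with the symmetric start no such trap was
  observed in hundreds of restarts.
* **Near-identity H.** A free i.i.d. H introduces a rotational
  degeneracy between B and H that creates the same traps; starting H
  near the identity (but strictly positive, so it can still move
  anywhere) suppresses it. All three factors carry the same mean(W)^{1/3}
  scale, which makes the entire seeded trajectory exactly equivariant
  under W → cW: the objective trace scales by c² and the extracted
  partition is unchanged (asserted in the tests).

### Termination and restarts

A restart stops when the relative per-sweep decrease
(e_{t−1} − e_t)/e_{t−1} falls below `tol` (default 1e−6) or after
`max_iter` = 1000 sweeps. The relative form is scale invariant. The
default is deliberately tight: the objective trace of multiplicative
updates passes through an early plateau (relative decrease ~1e−3 within
the first few sweeps) *before* the community structure emerges, and a
loose threshold stops there; at 1e−6 single restarts on the standard
benchmark converge in ~50–100 sweeps and none stay under-converged.
`fit` runs `restarts` = 50 independent initializations by default and
returns the one with the lowest final objective. Restart r draws its
RNG stream from (seed, r), so runs are reproducible and mutually
independent. One sweep costs O(k n² M) time and the model O(n² M)
memory; fits at n = 4096 are feasible on a laptop, with n ≤ 1024
exercised routinely in the test suite.

## Choosing the number of modules

k is selected by the instability of the factorization across random
restarts. For each candidate k, `runs` = 50 single-restart fits are
performed under derived seeds (master seed, k, run); the dissimilarity
between two resulting bases is 1 − (Σ_i max_j C_ij + Σ_j max_i C_ij)/2k
with C the matrix of column cosines after L2 normalization — 0 for
bases equal up to column permutation and positive rescaling, 1 for
column-wise orthogonal bases. The instability at k is the mean over all
unordered pairs of runs, and the selected k minimizes it (ties toward
smaller k). At the true module count the basis locks onto the planted
structure and restarts agree; under- or over-specified k forces
arbitrary merges or splits that vary between runs. The statistic uses B
only, since modules are read off B. Instability is computed from fully
converged runs; under-converged runs inflate the instability at the
correct k and can flip the selection, which is the second reason the
default `tol` is tight.

## Benchmark generator

Validation uses planted-partition networks in the classic
four-community style: n vertices (default 128) in q equal communities
(default 4), expected per-vertex degree fixed (default 16), of which
z_out edges on average lead outside the community. Edges are sampled
independently with p_in = (degree − z_out)/(n/q − 1) and
p_out = z_out/(n − n/q), so the expected degree is exactly `degree` at
every noise level (degree is fixed in expectation, not exactly, as in
the classic benchmark). Homogeneous multilayer instances share one
z_out across M independent layers; heterogeneous instances fix layer 1
at z_fixed (4 by convention) and put the remaining layers at z_var. All
layers share the planted partition — without a shared partition there
is no common module to find. Layer m draws from the RNG stream
(seed, m), so layers are independent but individually reproducible.

What the simulations do not emulate: weighted edges (layers are 0/1),
degree heterogeneity, overlapping modules, and the correlation structure
of real expression/methylation profiles. Passing the benchmark suite
shows the optimizer recovers planted block structure under edge noise;
it does not certify performance on real multi-omic data.

## Network construction from profiles

Real profile matrices (genes × samples) are turned into layers by
Pearson correlation followed by a PCIT-style trio filter. For each gene
trio (x,y,z) the first-order partial correlations are computed; the
tolerance for testing edge (x,y) against z is the average ratio of
partial to direct correlation over the two competing edges,
ε = (|r_xz.y/r_xz| + |r_yz.x/r_yz|)/2, and the edge fails the trio when
|r_xy| < ε|r_xz| and |r_xy| < ε|r_yz|. An edge is removed only when it
fails **every** informative trio (trios whose ratio denominators vanish
are uninformative and skipped; with fewer than three genes the test is
vacuous and any nonzero correlation survives). Surviving edges carry
weight |r| — the quality model needs non-negative weights and module
connectivity does not use the correlation sign. Perfectly correlated
pairs (|r| = 1) make the partial-correlation denominators degenerate;
their partials are treated as 0 with a warning. No p-value cutoff is
applied; the trio filter is the sole noise-removal step. The filter
never adds edges and is invariant to positive rescaling of any gene's
profile.

## Evaluation

Partitions are compared by normalized mutual information with
arithmetic-mean normalization,
NMI = −2 Σ_ij N_ij log(N_ij N/(N_i·N_·j)) / [Σ_i N_i· log(N_i·/N) +
Σ_j N_·j log(N_·j/N)], computed from the contingency table N of module
overlaps. Natural logarithms are used (the value is base invariant) and
0·log 0 ≡ 0. When both partitions are the single trivial module the
denominator vanishes; the value is then defined as 1 (the partitions are
equal). The implementation is cross-checked in the tests against an
independent entropy-based oracle and against scikit-learn.

## Degenerate inputs and numerical choices

* Adjacency matrices are accepted as symmetric within a relative 1e−8
  tolerance, symmetrized as (W+Wᵀ)/2, and have self-loops stripped, each
  with a logged warning; harder violations raise.
* Modules of size ≤ 1 have undefined density (returned as 0 with a
  warning); modules isolated in a layer have undefined modularity
  density (returned as 0 with a warning, and the module's multilayer
  score is then 0).
* Non-finite values produced by an update raise immediately, naming the
  offending factor.
* Problem sizes in the test suite (n ≤ 1024, 5–50 restarts, 5 seeds per
  condition) were chosen so the whole suite runs in a couple of minutes
  on one CPU while still exercising every claimed regime; the n = 4096
  scalability point follows the same O(k n² M) cost curve and is left to
  the reader's hardware.

## Known limitations

* The optimization is non-convex; guarantees are monotone descent per
  sweep and stationarity, not global optimality. Multi-restart with
  best-objective selection is the mitigation.
* Instability-based selection compares only the candidates scanned; on
  networks whose true structure is hierarchical, coarser partitions can
  legitimately be the most stable.
* The PCIT trio filter is O(n³) in the number of genes and is intended
  for gene panels of up to a few thousand genes.
* Directed networks, per-layer vertex sets, and overlapping (soft)
  modules are out of scope.
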