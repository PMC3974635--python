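# Methods

This note records the modelling conventions, parameter choices and numerical
details behind `wirecost`, and what the synthetic test networks do and do not
establish about real data.

## Network model

A `SpatialNetwork` is an undirected simple graph: node identifiers in a fixed
order, one 3-D coordinate per node (mm), optional hemisphere and
anatomical-structure labels, and positive real edge weights. Connection
lengths are *always* the Euclidean distance between endpoint coordinates,
recomputed on demand — they are never stored, so no stale geometry can leak
into an analysis. This straight-line approximation ignores the curvature of
real fibre tracts; it underestimates long, curved paths (notably
inter-hemispheric ones), which is why `wiring_statistics` reports
inter-hemispheric fractions and `extract_subnetwork` supports single-
hemisphere re-analysis.

Duplicate edge rows in input tables are collapsed only when their weights
agree exactly; conflicting duplicates raise an error rather than being
averaged, because silently averaging ambiguous input hides upstream bugs.
Aggregation to a coarser parcellation sums the weights of all member-pair
connections crossing two groups and discards intra-group connections; the
coarse node sits at the unweighted centroid of its members (a convention —
any position consistent across networks works, since all compared networks
share coordinates).

## Surrogate generation

All three surrogate types use the same iterative swap: draw two connections
(r₁,r₂), (r₃,r₄) uniformly at random (endpoint labelling randomised, since
connections are unordered), and propose the replacement (r₁,r₃), (r₂,r₄).
Proposals creating self-connections or parallel links are rejected outright.
Acceptance then depends on the surrogate type:

* random: always accept;
* spatial: accept iff after the swap the total connection length of each of
  the four affected regions does not exceed that region's total in the
  *source* network;
* reduced: accept iff every affected region's total strictly decreases
  (`per_region_strict`, the default), or alternatively iff the summed length
  of the two new edges is less than that of the removed pair
  (`total_length`). Both modes make the network total strictly monotone
  decreasing; the per-region reading is the stricter one and is the default
  because the constraint is defined region-wise.

The process stops after `floor(swaps_per_edge · E / 2)` accepted swaps
(each swap rewires two connections), with `swaps_per_edge` defaulting to 20
for random/spatial and 1 for reduced surrogates: reduced acceptance
saturates as length-decreasing swaps run out, so demanding 20 rewirings per
edge would never terminate usefully. A total proposal budget of
`max_attempts_factor × required_swaps` (default factor 1000) bounds the
run; exhausting it is recorded in the per-member provenance (`saturated`),
never fatal, because a partially optimised reduced surrogate is still a
valid length-reduced network.

Replacement edges inherit the weights of the edges they replace —
(r₁,r₃) takes w(r₁,r₂) — so the weight multiset is invariant and only the
degree sequence (not node strength) is preserved exactly. Member i of an
ensemble is generated with seed `base_seed + i`, making results independent
of execution order. The proposal loop is compiled with numba; a
behaviourally identical pure-Python fallback is used when numba is absent,
consuming the same random stream so results agree.

Floating-point note: per-region totals are maintained incrementally during
rewiring (O(1) per swap); over ~10⁵ swaps the drift against a from-scratch
recomputation is below 1e-9 mm, and audits use a 1e-9 tolerance.

## Minimally wired baselines

AM takes the E spatially closest node pairs; DPM walks all pairs from
shortest to longest, adding a pair only while both endpoints are below
their source degree. Distance ties are broken by the lexicographic
(min-index, max-index) pair order, so both constructions are fully
deterministic. Both outputs are unweighted (weight 1) and are compared with
other networks by binary similarity only: there is no principled weight to
assign a constructed edge. DPM can finish with fewer edges than the source
(unfillable degree budget); the deficit is reported, not an error.

## Similarity measures

QSᵇ and QSʷ are intersection-over-union quotients, not the classical
Sørensen `2|∩|/(|A|+|B|)` form (available behind a `classical=True` flag):
the binary quotient is |shared| / |union|; the weighted quotient takes
min(w_A, w_B) over shared edges in the numerator and max(w_A, w_B) plus all
unshared weight in the denominator. This weighted form is pinned to its
required properties rather than to a printed formula: it is symmetric,
bounded in [0,1], equals 1 exactly on identical weighted edge sets, 0 on
disjoint ones, and collapses to the binary quotient whenever all weights
are equal.

Spatial displacement D pairs each region's original neighbours with its
rewired neighbours greedily by ascending distance (ties lexicographic) and
averages d(original, rewired)/d(region, original) per region, then over
regions. The greedy pairing is an approximation to the optimal assignment —
exact matching is factorially expensive at realistic degrees — and tends to
overestimate the optimum slightly; a `rewired_only` flag excludes conserved
(zero-displacement) connections to measure the displacement of the replaced
ones only. Pairs whose original neighbour coincides with the region
(zero-length reference) are excluded with a warning rather than dividing by
zero.

## Metrics

* Efficiency uses edge costs 1/w (strong connections are short), averages
  1/d over ordered pairs excluding self-pairs, and counts unreachable pairs
  as zero — the standard multi-component-safe choice.
* Clustering follows Onnela's geometric-mean form with weights normalised
  by the global maximum weight (the usual convention where the weighted
  triangle intensity is dimensionless and ≤ 1).
* The small-world index multiplies the clustering and efficiency ratios
  against the random-ensemble means; evaluated against its own values a
  network scores exactly 1.
* The hierarchy curve bins nodes by degree (default bin width 5,
  configurable; any fixed binning works since only the shape is
  interpreted) and normalises per-bin mean clustering by the global mean;
  the scalar indicator is the Spearman correlation of (degree, clustering)
  over connected nodes.
* Assortativity is the Pearson-type correlation of endpoint degrees over
  edges; degree-regular graphs have zero variance and return NaN with a
  warning.
* k-core/s-core peeling removes nodes below threshold until stable. The
  s-core profile is computed at the *exact collapse points*: thresholds are
  the attained minimum intra-core strengths, so the "last non-empty core"
  and its fractional collapse threshold are exact and no grid artefacts
  arise; an `s_step` grid is offered purely for plotting. With continuous
  (e.g. log-normal) weights the innermost s-core can legitimately collapse
  to a very small set — one extremely strong dyad can outlast every larger
  core — so s-core size is reported alongside the threshold.
* The weighted rich-club density divides the weight among nodes of degree
  > k by the sum of the E_max largest edge weights in the whole network,
  E_max = |N_{>k}|(|N_{>k}|−1)/2. Thresholds whose club could not be fully
  interconnected by the existing E edges are outside the valid domain and
  reported as excluded, with the bound solved as the largest integer x with
  x(x−1)/2 ≤ E. For E = 17865 this solver gives 189; a published value of
  188 exists for the same E, and the convention producing it (strict
  inequality or different edge bookkeeping) is not recoverable — the
  discrepancy is surfaced here rather than silently matched.

## Module detection and consistency

Modularity uses the weighted matrix B_ij = w_ij − k_i k_j/(2W). Detection
is Newman's recursive leading-eigenvector bipartition with the generalised
(row-sum-corrected) matrix on subgraphs; connected components are split
first, and a split is kept only if ΔQ = sᵀB⁽ᵍ⁾s/(4W) exceeds 1e-12. The
eigendecomposition is a full symmetric `eigh` (deterministic); the
eigenvector's overall sign is fixed by making its first nonzero entry
positive, and zero entries join the positive block. A single-sweep
Kernighan–Lin refinement is available behind `fine_tune=True` but is off by
default. The spectral method is a heuristic: on small graphs its Q is
verified to land within 0.05 of the exhaustive optimum, not to equal it.

Scaled inclusivity scores node consistency as
X(p,q) = |S_p ∩ C_q|²/(|S_p||C_q|) between the node's module in each
ensemble partition and in the reference partition, averaged over members;
it is 1 everywhere iff every member reproduces the reference exactly, and
makes no assumption about module counts or sizes.

## Significance testing

The pipeline tests each metric's ensemble against the source value with a
one-sample t-test (two-sided by default; sidedness is per-metric
configurable, since directional hypotheses are sometimes appropriate), and
annotates stars at p < 0.05/0.01/0.001/0.0001. Zero-variance ensembles are
flagged degenerate rather than tested. Distribution-level comparisons
(per-region connection lengths against a reference network) use the
Wilcoxon rank-sum test.

## The synthetic generator

`wirecost.synthetic` emulates the statistics the analyses assume: nodes
uniform on a sphere surface (or box), edges rejection-sampled with
acceptance exp(−d/λ) until the exact target count is reached (with a
deterministic shortest-remaining-pairs fallback guaranteeing termination),
i.i.d. log-normal or exponential weights, and two optional ingredients that
default to off: a log-normal per-node propensity (right-skewed,
exponential-like degree distributions) and a uniform long-range edge
fraction (the heavy tail of real connection-length distributions). The
`cortical_like_fixture` freezes one calibration — 500 nodes on a 70 mm
sphere, 8900 edges, λ = 8.5 mm, 8% long-range, propensity σ = 0.6,
log-normal(0,1) weights — chosen so the fixture is sparse (~7% density),
essentially fully connected, predominantly local (mean connection length
in the high 20s to low 30s of mm) with a long tail, and right-skew degreed.
`planted_modules` adds well-separated spatial clusters (farthest-point
centre placement, 5 mm scatter against ≥ 50 mm separations) for partition-
recovery tests.

What the generator does *not* emulate: spatially organised weights (weights
are i.i.d., uncorrelated with distance or topology), a cortical sheet's
folded geometry, hemispheric symmetry, or any functionally meaningful
placement of long-range connections. Consequently the synthetic source
network is statistically a *typical member* of its own spatial-surrogate
ensemble — unlike a real cortex, whose specific arrangement of long-range
connections is exactly what the surrogate comparison is designed to expose.
Passing tests therefore establish that the machinery (constraints,
invariants, orderings, estimators) behaves correctly, not that any
particular empirical network is or is not shaped by wiring cost.

## Problem sizes used in validation

Oracle-equivalence checks run on random weighted graphs up to n = 30
against brute-force reimplementations (all-pairs Dijkstra, triangle
enumeration, direct summation), and exhaustive optima are computed up to
n = 8 (set partitions) and E ≤ 12 (edge subsets). Ensemble-level ordering
checks use the 500-node fixture with 20 members per surrogate type; the
acceptance script uses 5 members per type. These sizes make the whole
validation suite run in a couple of minutes while leaving every ordering
well clear of its noise floor.

## Known limitations

* Euclidean lengths underestimate curved fibre paths (see above).
* The reduced surrogate saturates: with `per_region_strict` acceptance the
  attainable length reduction depends strongly on how heavy the source's
  long-range tail is, and the achieved swap count (recorded in provenance)
  can be well below the nominal budget.
* Greedy displacement pairing and spectral modularity are approximations;
  both are validated against small-instance optima, not guaranteed global
  optima.
* Strength (weighted degree) is not preserved by rewiring — only degree —
  matching the constraint set the surrogate definitions specify.
* No overlapping communities, no Louvain/consensus clustering, no
  betweenness or motif statistics: out of scope by design.
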