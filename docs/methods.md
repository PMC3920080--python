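# Methods

## Networks and measures

A connectome is a symmetric, nonnegative, zero-diagonal G×G weight matrix;
weights are streamline-count fractions (each subject normalized so the
upper-triangle sum is 1). Graph distances use the inverse-weight rule
(length = 1/w on present edges; the rule is a configurable callable), and
all shortest paths are Dijkstra over that length matrix.

Conventions that matter downstream:

* **Characteristic path length (λ)** is the mean over *connected* (finite)
  off-diagonal pairs. Lesioning can disconnect a network; averaging over
  finite pairs keeps λ defined, and the number of excluded pairs is reported
  alongside. With this convention the monotonicity guarantee is: after an
  edge lesion, every surviving finite distance is ≥ its intact value, so λ
  restricted to the surviving pairs never decreases.
* **Local efficiency** follows the neighbor-subgraph definition: for node u,
  shortest-path distances are computed *within* the subgraph induced by u's
  neighbors, and the inverse distances (0 where disconnected) are averaged
  over ordered neighbor pairs; nodes with < 2 neighbors score 0. Phrasings
  that average "inverse entries of the connectivity matrix" directly do not
  define a usable quantity; the neighbor-subgraph form is the standard one
  in the brain-network toolboxes this field uses.
* **Degree, density, transitivity, clustering, assortativity** are computed
  on the binary topology (edge present iff weight > 0). Assortativity is the
  Pearson correlation of endpoint degrees over the symmetrized edge list.
* **Degenerate values raise** a typed `UndefinedMetricError` (assortativity
  on a regular graph, transitivity without a connected triple, λ of an
  edgeless graph) instead of returning NaN. The feature vector records such
  components as NaN plus a name; the statistics treat them as missing,
  dropping that subject pairwise and reporting the reduced N.

## Lesion simulation

Node lesions delete one cortical parcel and its incident edges, yielding a
(G−1)-node network; weights are *not* renormalized after lesioning (the
lesioned network is the intact network minus the lesion, not a rescaled
one). Only cortical parcels are lesioned under the anatomical scheme
(148 of 165); subcortex, cerebellum and brainstem remain as nodes. Edge
lesions zero exactly one connection; removing an absent edge is the
identity, which the sweep exploits by copying the intact feature vector for
pairs a subject lacks.

## Paired statistics

Node tests: paired t on healthy − lesioned values per (parcel, metric), two
metrics (λ, mean local efficiency), Bonferroni family m = 148 × 2 by default
(each parcel/metric pair is one hypothesis; the family size is a named
argument). Zero-variance differences (e.g. a constant shift) are reported as
degenerate, never significant.

Edge tests: paired Hotelling T² on the p = 4 feature differences,
F = (N−p)T²/[p(N−1)] with F ~ F₍p,N−p₎, Bonferroni m = G(G−1)/2 regardless
of how many edges exist. Singular difference covariance is expected, not
exceptional: when all subjects share one topology, the binary components
(assortativity, density, transitivity) of the difference vector are constant
across subjects. S is eigendecomposed and directions whose variance is below
1e−10 relative to both the largest variance and the squared mean difference
are treated as constant; the test runs in the remaining subspace with the
effective rank replacing p in the F conversion, and the result is flagged
rank-deficient. An all-constant difference has no sampling variance to test
against and is reported degenerate (p = 1). Edges with nonzero differences
in fewer than p + 2 subjects are non-testable. All tests are two-sided.

The scaffold is the set of testable edges with p < α/m, ranked by descending
F; the stringent core uses α = 0.0001 and is nested in the α = 0.05 set by
construction.

## Decompositions

The lesion-effect correlation matrix R correlates, across subjects, the
post-lesion values (not healthy-minus-lesioned differences — the entry is
defined on the lesioned networks directly) of a global measure for every
pair of lesioned parcels. Rows whose variation across subjects is at
floating-point rounding level relative to their magnitude are treated as
constant and flagged missing rather than correlating numerical noise. PCA is
the eigendecomposition of the covariance of the matrix columns; loadings are
sign-fixed (largest-magnitude entry positive) for deterministic output, and
missing entries are imputed to 0 (counted) before decomposing.

The edge-effect tensor needs a collapse rule across subjects: a 4-way array
(edge endpoints × target node × subject) must become G×G×G. The rule used —
a named, swappable strategy — correlates, across subjects, the per-subject
nodal effect Δmetric(k″) with the per-subject global effect Δλ of the same
edge removal, giving exactly one coefficient per (k, k′, k″). The target
nodal metric defaults to eccentricity (distance-based, hence sensitive to
edge removals); it is configurable. Other collapses (e.g. correlating two
nodal series) are defensible; results of the tensor analysis should be read
as conditional on this choice.

MPCA treats the mode-3 slices as samples (G matrices of size G×G, one per
target region), centers them, initializes the two mode projections from the
per-mode total-scatter eigenvectors (higher-order SVD truncation) and
refines them by alternating partial-projection eigendecompositions until the
captured variation — projected variation over total variation — changes by
less than 1e−8 (200 iterations maximum; non-convergence is flagged, not
raised). Captured variation is non-decreasing across iterations (asserted)
and in the number of components, and the alternating refinement can never do
worse than its initializer. The loadings mapped over regions are the first
column of the mode-1 projection.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes about
tractography cohorts:

* one modular base topology shared by all subjects (gross anatomy is
  shared), drawn from a planted-partition model: `n_modules` contiguous
  blocks, edge probability `p_within` = 0.85 inside and `p_between` = 0.03
  between modules;
* log-normal base weights (`weight_log_sd` = 0.15: locally comparable
  connection strengths), with ordinary between-module weights scaled by
  `between_weight_factor` = 0.2 — long-range fiber counts are weak relative
  to short-range ones;
* planted bridge edges forced present in every subject with their weight
  multiplied by `planted_boost` = 5: a few strong long-range bundles, the
  ground-truth critical connections;
* independent multiplicative log-normal inter-subject noise per edge
  (`subject_noise_sd` = 0.9): streamline counts vary strongly across
  subjects;
* per-subject normalization to unit upper-triangle sum.

These defaults are an instrument design, chosen (via a small simulation
study, before freezing) so that the planted bridges — and essentially only
they — are statistically critical: dense weight-homogeneous modules make
ordinary short-range edges redundant (a 2-hop detour of comparable length
exists, so under large noise their removal has a zero or sign-unstable
effect on λ), and weak ordinary long-range edges sit off shortest paths
because routing through a boosted bridge is cheaper. Two consequences are
worth knowing. First, with a shared topology the binary feature components
carry no across-subject variance, so the edge test effectively runs on the
λ direction with effective rank 1 — exactly what the rank-deduction logic is
for. Second, the optional per-subject `edge_dropout` (off by default) makes
topology vary across subjects; this exercises the absent-edge code paths,
but it also turns the density difference into a scaled Bernoulli of edge
presence, which a paired test flags for *every* sometimes-present edge —
with dropout on, scaffold recovery against the planted truth is not a
meaningful benchmark.

What the generator does not emulate: geometric embedding and
distance-dependent wiring, hemispheric anatomy beyond an optional homotopic
noise correlation (`symmetry_rho`), realistic weight magnitudes or degree
distributions of human connectomes, and subject-level topological
variability (unless dropout is enabled). Passing the recovery benchmark
therefore shows the pipeline correctly identifies edges that are critical
*in the assumed regime*; it does not certify sensitivity/specificity on real
DTI cohorts.

Randomness: the master seed spawns one substream for the base topology and
one per subject, so cohorts are reproducible and independent of subject
iteration order. If the base graph is disconnected, deterministic bridging
edges (median base weight, lowest-index component representatives) are
added; this enforcement can be disabled.

## Problem sizes

The bundled analysis and the acceptance script use G = 40 (4 modules),
N = 30 subjects, 10 planted bridges — the cohort size at which a full edge
sweep (780 pairs × 30 subjects) plus decompositions completes in well under
a minute on one CPU, while leaving the inference genuinely multiple-
comparison limited (Bonferroni threshold 6.4×10⁻⁵). Combinatorial constants
are computed at the full G = 165 anatomical scheme, where no sweep is
needed. Type-I calibration uses 5,000 null replicates at N = 30, p = 4.

## Known limitations

* The Hotelling rank-reduction threshold (relative 1e−10) is a numerical
  tolerance, not an inferential choice; difference components with genuine
  but minuscule variance will be treated as constant.
* Betweenness is delegated to networkx and is the slowest nodal metric;
  the intact-network PCA uses it only on intact networks.
* The tensor collapse rule is one defensible reading of an ambiguous
  construction; MPCA loadings should be compared across collapse strategies
  before interpretation.
* Exact zero weights are treated as absent edges; noisy near-zero weights in
  real data should be thresholded by the user before analysis.
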