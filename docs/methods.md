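# Methods

`omicnet` builds co-occurrence and cross-omics association networks from
feature × sample abundance tables and characterizes their structure.
This note records the statistical model behind each step, the tunable
parameters with their defaults and rationale, what the synthetic
generators do and do not emulate, and the numerical conventions fixed in
`omicnet.config`.

## Correlation screen

Given a table `X` (features on rows, samples on columns), all pairwise
correlations are computed by row-standardizing and taking one matrix
product, optionally tiled into row blocks (`block_size`, default 1024
rows) to bound peak memory; the result is independent of the tiling.
Spearman is Pearson on midranks (ties receive the average rank), so the
same vectorized path serves both methods.

Two-sided p-values come from the exact monotone map between the sample
correlation `r` and Student's t under the null of bivariate independence:

    t = r * sqrt((n - 2) / (1 - r^2)),   df = n - 2.

No permutation is involved; the p-value is analytic and matches
`scipy.stats.pearsonr`/`spearmanr` to ~1e-15 (the test suite checks
1e-10 over a 200 × 50 table). `|r| = 1` (within 1e-12, to absorb the
rounding of the matrix product) is mapped to p = 0; elsewhere `r` is
clipped to `1 - 1e-15` inside the formula so the square root is finite.
`n = 3` (df = 1) is allowed with a warning — the t tail is then extremely
heavy and significance effectively unreachable. Zero-variance features
propagate NaN through `r`, `p` and `p_adj` together.

Missing data: the default is complete-case over the aligned sample set.
`missing="pairwise"` uses pairwise-complete observations with the
per-pair `n` in the t formula; for Pearson this is done with masked
matrix algebra, for Spearman by an explicit per-pair loop, because
per-pair re-ranking has no matrix-product form.

Multiple-testing adjustment (`BH` step-up with running minimum, `holm`
step-down with running maximum, `bonferroni` with cap at 1) covers
exactly the tests the screen performs: the strict upper triangle in
intra-omics mode (mirrored back; the unit diagonal never enters), the
full rows × cols rectangle in inter-omics mode. NaN entries are excluded
from the test count unless `m` is passed explicitly. The implementation
is checked element-wise against `statsmodels.stats.multitest` in the
test suite.

Bray–Curtis-based screens are deliberately not implemented (the analytic
t route does not apply to dissimilarities); requesting `method="bray"`
raises `NotImplementedError`.

## RMT threshold selection

Choosing the hard correlation threshold `t` by eye is the weakest link
of correlation networks. The random-matrix criterion exploits a
universality result: the nearest-neighbor spacing distribution (NNSD) of
the *unfolded* eigenvalues of a noisy correlation matrix follows the
Wigner surmise of the Gaussian orthogonal ensemble,
`P(s) = (pi s / 2) exp(-pi s^2 / 4)`, while a matrix reduced to
independent structural blocks has Poisson spacings `exp(-s)`. Sweeping
`t` upward and zeroing `|r| < t` (unit diagonal kept), the NNSD
transitions from GOE-like to Poisson-like once the noise-level entries
are gone; the smallest such `t` is the data-driven threshold.

Numerical conventions (all in `config`, all overridable per call):

- grid 0.30–0.90 in steps of 0.01;
- eigenvalues closer than 1e-8 collapsed before spacing computation
  (hard-thresholded matrices produce exact-zero blocks and replicated
  eigenvalues);
- unfolding by a cubic smoothing spline (fixed smoothing parameter 0.01)
  fitted to the midrank empirical CDF, after trimming 5% of the spectrum
  at each edge — edge states and isolated outliers otherwise distort the
  smooth density estimate; spacings are renormalized to mean exactly 1.
  Plain rank-difference "unfolding" was rejected: it retains the global
  density profile and makes every spectrum look Poisson-like;
- goodness of fit by chi-square distance on 20 equal bins over [0, 3];
- the call requires Poisson to beat GOE at 2 consecutive grid points
  with at least 20 usable eigenvalues, which stabilizes the transition
  point against grid noise; `chosen = None` when no point qualifies
  (e.g. a structureless identity matrix).

The regime matters: a GOE phase exists only while the retained noise
entries form a dense bulk, i.e. for tables with several hundred features
and a modest sample count. The recovery test therefore uses a
500-feature × 25-sample five-block table (within-block ρ = 0.7), for
which the scan lands at 0.56–0.65 across seeds; at, say, 100 features ×
50 samples the spectrum is Poisson-like over the whole grid and the scan
reports the grid minimum or nothing.

## Network construction and modules

An edge is kept iff `|r| > r_threshold` **and** `p_adj < p_threshold`,
both strict. Edge attributes are `r`, `sign = ±1`, `weight = |r|`, and
`p_adj`; construction parameters are stored as graph attributes.
Duplicate rows in edge-list input collapse to the unordered pair with
the smaller `p_adj` (ties: larger `|r|`).

Module detection is Clauset–Newman–Moore greedy modularity agglomeration
(via networkx) with `|r|` weights; the sign is kept as an edge attribute
but ignored by the null model, which is undefined for negative strengths.
Module ids are 1-based in descending size order, and the reported Q is
verified in the tests against a from-scratch evaluation of
`Q = Σ_c (e_c/m − (d_c/2m)²)`.

Topological roles use the within-module degree z-score and participation
coefficient on *unweighted* link counts:

    Zi = (k_is − mean_s) / sd_s,       Pi = 1 − Σ_m (k_im / k_i)²,

with `sd_s = 0 → Zi = 0` and isolated nodes reported as peripheral with
`Pi = NaN`. Role cutoffs are the Guimerà–Amaral values `Zi ≥ 2.5`,
`Pi ≥ 0.62` (module hub / connector / network hub / peripheral),
exposed in `config`.

Multi-omics assembly unions inter-omics correlation blocks under
per-block thresholds (different omics pairs legitimately warrant
different cutoffs), requires feature ids to be unique across layers, and
reports per-block positive/negative edge tallies.

## Topology, null models, robustness

All topological metrics are computed on the unweighted simple graph —
standard practice for co-occurrence networks, where the edge set rather
than the correlation magnitude carries the ecology. The headline
registry (version 1.0) has 17 entries: node and edge counts, density,
proportion of negative edges, average degree, average path length,
diameter, average local clustering, transitivity, global efficiency,
modularity, natural connectivity, component count, largest-component
fraction, and mean betweenness/closeness/eigenvector centrality;
per-node centrality tables accompany it. Disconnected graphs get path
metrics on the largest component with an explicit flag; efficiency uses
the `1/∞ = 0` convention so it stays global.

Natural connectivity is `ln((1/N) Σ exp(λ_i))` over adjacency
eigenvalues, computed through `logsumexp` for stability and checked
against a matrix-exponential-trace oracle.

The degree power-law fit is the Clauset discrete maximum-likelihood
procedure: for each candidate `xmin`, α̂ maximizes the Hurwitz-zeta
likelihood (bounded search on [1.01, 6]); `xmin` minimizes the KS
distance between the tail ECDF and the fitted model. Candidate tails
smaller than `min_tail = 50` points are not considered — with tiny tails
the KS distance is minimized by chance at large `xmin`, a known artifact
of the procedure — matching the operation's ≥ 50 positive-degrees
precondition. The result is a report (α̂, xmin, KS), never a
scale-freeness verdict.

Null-model comparison supports `er_gnm` (same n, m) and
`degree_preserving` (10·m double-edge swaps rejecting self-loops and
multi-edges); z-scores are `(obs − mean)/sd` with NaN at zero variance.

Robustness curves remove nodes cumulatively (nested sets). Targeted
strategies rank once on the intact network (ties by node id); random
removal uses seeded replicate trajectories (default 20). The
largest-component fraction is relative to the *intact* node count, so
fraction 0 reproduces the intact metrics and fraction 1 gives 0 exactly.

## Layouts

Angular conventions are fixed: circular placements start at 90° and run
counter-clockwise on the unit circle; regular polygons put vertex 1 at
90°. `as_polygon` spaces a side's k nodes at fractions `1/(k+1) …
k/(k+1)` of the open segment; `as_polycircle` uses per-group circles of
radius 0.3 at polygon vertices; circle packing scales inner layouts to
0.8 of the module radius, with radius ∝ sqrt(module size) and greedy
spiral placement (non-overlap is asserted, not assumed). The pseudo-3D
multi-layer map is the affine `(x, y) → (x + y cos α, y sin α + i·dz)`.

Polygon-constrained placement triangulates the polygon by ear clipping —
robust for concave rings, where an unconstrained Delaunay triangulation
of the vertices can spill outside — then samples a triangle with
probability proportional to its area and a uniform barycentric point
within it. The naive rejection sampler exists in the test suite only, as
the distributional oracle. `on_edges` spaces nodes arc-length-uniformly
along the boundary from the first vertex. Classical layouts
(force-directed, tree, random, Kamada–Kawai) delegate to networkx,
wrapped for seed control; every seeded layout is bit-reproducible.

## Synthetic generators

`planted_block_data` draws each block as a shared latent factor plus
independent Gaussian noise; with factor variance v and noise variance
s², the expected pairwise correlation is v/(v + s²), so the target
`within_r` fixes the loading analytically. Factors are standardized to
unit *sample* variance so the realized correlation stays near its target
for every seed. An optional global factor plants `between_r` across all
blocks, giving a controllable inter-module signal for perturbation
experiments. `planted_module_network` is a stochastic block model with
the planted partition attached; `toy_networks` provides the
hand-checkable graphs used throughout the examples.

What the generators do **not** emulate: compositionality (closure),
zero inflation, heavy-tailed abundances, autocorrelated longitudinal
sampling, and batch structure of real sequencing data. Passing tests
demonstrate the correctness of the algorithms under clean Gaussian
latent-factor conditions, not the robustness of correlation networks to
compositional artifacts — for that, compositionality-aware inference
(outside this package's scope) is the appropriate tool.

## Problem sizes in the standard checks

The shipped test suite and `scripts/acceptance.py` use: 200 × 50 tables
for the correlation oracle; 150 features (11 175 pairs) for null
calibration; 500 × 25 for RMT recovery and a 1000 × 1000 GOE matrix for
ensemble separation; 4 × 25-node block models for module recovery;
90 × 80 tables for the perturbation direction-of-effect pipeline; and
100 random graphs with n ≤ 30 for brute-force path-metric equivalence.
These sizes are comfortable for a laptop single core while large enough
for the stochastic checks to be stable across seeds.

## Known limitations

- Correlation networks capture marginal association only; indirect and
  compositional effects are not controlled (no SparCC, partial
  correlation, or mutual information).
- Weighted topological metrics are deferred; everything topological is
  computed on edge presence.
- The RMT call depends on fixed unfolding/binning constants; very small
  matrices (< ~200 features) rarely exhibit a GOE phase on the default
  grid and then yield `None` or the grid minimum.
- Pajek I/O covers the documented subset (id, label, coordinates, edge
  weight) and drops other attributes by design.
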