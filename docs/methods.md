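# Methods

## Scope and model

`heatnet` operates on simple, undirected, unweighted graphs.  The central
quantity is the heatmap centrality

    C_HM(v) = F(v) − (1/deg(v)) Σ_{u ~ v} F(u),

where F(v) is the farness (sum of BFS hop distances to all other nodes).
Farness is finite only on connected graphs, so every farness-based measure
(closeness, heatmap) raises an error on disconnected input rather than
returning infinities; the preprocessing helper (`preprocess_real_world`)
exists precisely to reduce raw data to its largest connected simple
component first.  Betweenness tolerates disconnected graphs (unreachable
pairs contribute nothing).

Two exact identities follow from the definition and are asserted
throughout the test suite as structural invariants:

- **Leaf law.**  A degree-1 node v with neighbor u has
  F(v) = F(u) + N − 2, so C_HM(v) = N − 2 for every leaf of every
  connected graph with N ≥ 3.
- **Degree-weighted zero sum.**  Σ_v deg(v)·C_HM(v) = 0: each farness
  term appears once per incident edge in both the positive and negative
  sums.

## Conventions for the reference centralities

These choices make every number in the package exactly reproducible:

- **Closeness** is the raw reciprocal 1/F(v), with no (N−1)
  normalization.
- **Betweenness** counts each unordered pair once and excludes
  endpoints, with fractional credit σ_jk(v)/σ_jk when a pair has several
  shortest paths.  (Counting ordered pairs would double every value.)
- **Eigenvector centrality** is the dominant adjacency eigenvector
  rescaled so its maximum entry is exactly 1 (not unit Euclidean norm).

## Numerical choices

- **Power iteration** starts from the uniform positive vector,
  max-normalizes each iterate, and stops when the max-norm change is
  ≤ 1e−12 (cap 10 000 iterations; exceeding it raises a convergence
  error that reports the residual).  Iteration runs on the shifted
  operator A + I rather than A: the shift preserves eigenvectors but
  makes the Perron eigenvalue strictly dominant in magnitude, which is
  required on bipartite graphs (paths, trees), where A's spectrum is
  symmetric and plain iteration oscillates between two accumulation
  points forever.  The residual test ‖Ae − λe‖∞ ≤ 1e−8 is enforced in
  the acceptance tests after rescaling.
- **All-pairs distances** (`all_farness`, `diameter`) go through the
  compiled unweighted shortest-path routine in `scipy.sparse.csgraph`;
  the tests pin its agreement with the package's own per-node BFS, so
  the two routes are interchangeable.  Per-node BFS (`bfs_distances`)
  remains pure Python for inspectability.
- **Rounding** for printed-precision table reproduction is half away
  from zero at the column's precision (`decimal.ROUND_HALF_UP` on the
  repr of the float).
- **Ordering.**  Node iteration order is ascending label (numeric when
  all labels are integers, lexicographic otherwise).  Every downstream
  tie-break — tentative ranks, top-k lists, component selection —
  derives from this single ordering, which is what makes whole-pipeline
  outputs bit-reproducible.

## Rank correlation

Ranks are assigned in decreasing order of influence (for heatmap:
increasing value).  Two tie rules are implemented: `"id"` (ties broken
by smaller node label; tentative ranks are final — the default, because
the package's worked reference example is computed this way) and
`"average"` (tied groups share the mean of their tentative ranks, the
textbook mid-rank rule).  Spearman's ρ applies
1 − 6Σd²/(N(N²−1)) to final ranks verbatim.  Kendall's τ divides
N_C − N_D by N_C + N_D, the count of *untied* pairs — deliberately
neither τ-a nor τ-b; the tie-corrected τ-b is exposed separately
(`kendall_tau_b`, via scipy) for comparison and is never the default.
Pair classification is plain O(N²) enumeration, adequate for the
N ≤ ~5000 graphs this package targets.

## SI spreading simulator

The spreading model is a *modified* susceptible–infected process: at each
time step every infected node selects **one** susceptible neighbor
uniformly at random (if any) and infects it with probability β (default
1).  This differs from the standard SI model, where all susceptible
neighbors are exposed; the one-contact rule throttles hubs and is the
regime in which hub and super-spreader rankings can disagree.

The update is synchronous with a one-step latency: susceptibility is
judged against the state at the start of the step, newly infected nodes
transmit from the next step, and collisions (two infectors picking the
same target) yield a single infection — so F(t) is independent of node
iteration order.  Consequences used as test invariants: F is
non-decreasing, F(t+1) − F(t) ≤ I(t), and with β = 1 on a connected
graph every run saturates within N − |seeds| steps.  An infected node
whose neighbors are all infected simply skips its attempt.

Replicates (default 100) each use an independent RNG stream seeded
`rng_seed + replicate`, so any single replicate can be reproduced in
isolation.  Curves report mean and sample standard deviation (ddof = 1;
0 for one replicate) of F(t), with early-saturating replicates held
constant at N.  `t_c` is the first step by which every replicate had no
susceptible nodes (or `t_max`, default 1000, which only binds when
β < 1 stalls the process).  Seed-set comparisons
(`spreading_capability`) run every measure's top-k seed set under the
same base seed on a shared time axis.

## Barabási–Albert generator

Growth starts from a single node (m0 = 1).  The i-th arrival (i ≥ 2)
attaches to min(m, i−1) *distinct* existing nodes, drawn without
replacement with probability proportional to degree at the start of the
arrival (sequential draws with renormalization; uniform fallback at the
very first attachment, when all candidate degrees are 0).  A node's own
half-formed edges never influence its target choice.  These semantics
make the edge count deterministic,

    M = m(N−1) − m(m−1)/2   (N−1 ≥ m),

so mean degree 2M/N is seed-independent, and m = 1 always produces a
connected tree (zero clustering).  The density design rule
m = round(dN/2) follows from d ≈ 2m/N.  Weighted sampling is O(m·N) per
arrival in the worst case, acceptable at N ≤ 5000.

Clustering is reported in two flavors, since the field uses both: the
global transitivity 3·triangles/triples (the default for ensemble
summaries) and the mean local triangle density (degree < 2 nodes
contribute 0).  Ensemble summaries aggregate mean degree, clustering and
diameter over replicates seeded `rng_seed + r`, as mean ± sample sd.

The power-law check is a deliberately simple ordinary least squares of
log P(k) on log k over the degrees present (P(k) > 0), reporting
γ = −slope and the regression R².  It is a descriptive fit in the
log–log plot sense, not a Clauset-style maximum-likelihood tail
estimator, and requires at least 3 distinct positive degrees.

## What the synthetic data does and does not emulate

Generated BA networks reproduce the structural regime the measures are
studied in — heavy-tailed degrees, small diameters (4–5 at N = 1000,
d ≥ 0.01), low clustering — and the toy 15-node fixture exercises every
hand-checkable value.  They do not emulate degree assortativity,
community structure, or the clustering levels of real communication and
flight networks, so passing tests demonstrate correctness of the
algorithms and the deterministic laws above, not field performance on
any particular real dataset.  Real edge lists are processed by the same
pipeline via `heatnet centrality --input ...` after
`preprocess_real_world`-style cleaning.

## Problem sizes and limitations

The test suite and acceptance script run at the scales the algorithms
are designed for: toy N = 15 exhaustively; BA ensembles at N = 1000
(10 replicates for the diameter check) and single realizations at
N = 5000; property checks on hundreds of random graphs with N ≤ 8
against brute-force oracles.  Pure-Python Brandes is O(NM) and practical
to N of a few thousand; beyond that, timings (not correctness) degrade.
Directed or weighted graphs, approximate betweenness, and
continuous-time epidemic variants are out of scope.
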