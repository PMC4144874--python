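# Methods

tractnet implements a weighted structural-connectome analysis of the kind
used to compare white-matter networks between two groups of subjects
scanned with diffusion-weighted imaging: probabilistic tractography yields
a directed matrix of streamline counts between the 90 regions of the AAL
parcellation, those counts become symmetric weighted networks, a sparse
backbone is extracted, graph metrics are computed and compared between
groups against degree-matched random networks. Because no imaging data is
bundled, a synthetic cohort generator stands at the front of the pipeline
and provides inputs with known ground truth.

## From tract counts to networks

**Motion screening.** Each scan carries a log of six rigid-body parameters
per volume (translations in mm, rotations in degrees). A scan is excluded
when its peak absolute translation exceeds 1 mm or its peak absolute
rotation exceeds 1 degree. A bare ">1 mm / >1 degree" rule leaves open
whether it applies per axis, to the Euclidean norm, or to framewise
displacement; `screen_motion` takes the per-axis maximum over volumes —
the most conservative of those readings. The decision records which rule
fired, translation being checked first.

**Connection weights.** For regions i and j with seed-voxel counts v_i,
v_j and directed streamline counts c_ij (seeded in i, reaching j):

    w_ij = c_ij / v_i + c_ji / v_j

Voxel normalisation removes the dependence of raw counts on region size;
summing both seeding directions symmetrises the matrix. Self-connections
are discarded. Repeated scans of a subject are averaged entrywise after
QC, and subjects whose every scan fails QC are dropped with a logged
warning rather than aborting the run.

**Backbone extraction.** The analysed network is the connectivity
backbone: a maximum spanning tree (guaranteeing connectedness) extended
with the remaining edges in descending weight order until the edge count
reaches floor(N·K/2), i.e. average degree K. K = 4 by default, giving 180
edges on 90 nodes. Kept edges retain their weights. The greedy top-up
after a maximum-weight spanning tree is exactly optimal among edge sets of
that size containing a spanning tree (a matroid argument; the test suite
verifies it against exhaustive search on small graphs). Ties in weight are
broken by lexicographic (i, j) order so results are platform-independent;
with continuous weights ties essentially never occur. Odd N·K is rounded
down — irrelevant at N = 90, K = 4, but small test graphs need the rule.

## Graph metrics

All metrics are computed on the weighted backbone, with the distance
between adjacent nodes defined as the inverse weight 1/w_ij.

* **Degree K_i, strength S_i** — count of incident edges; sum of incident
  weights.
* **Generalised clustering C_i** — Onnela's geometric-mean triangle
  intensity, computed on *raw* weights:
  C_i = 2/(K_i(K_i−1)) · Σ_{j<h} (w_ij w_ih w_jh)^{1/3}, zero when
  K_i < 2. Normalising weights by their maximum would make the coefficient
  depend on a single noisy extreme count, so raw weights are used; the
  resulting values are unbounded and meaningful only in comparisons, never
  as absolute quantities. C(G) is the mean over nodes.
* **Path lengths** — all-pairs shortest paths under 1/w distances.
  The nodal L_i is the arithmetic mean distance to all other nodes (and is
  infinite when the node is disconnected from any other). The
  characteristic path length L(G) is the *harmonic* mean,
  L(G) = [ (1/(N(N−1))) Σ_{i≠j} 1/d_ij ]^{−1} with 1/∞ = 0, which stays
  finite on graphs with disconnected pairs. L(G) is exactly
  1/E_glob.
* **Betweenness BC_i** — Σ_{k≠i≠j} σ_kj(i)/σ_kj over *ordered* pairs,
  endpoints excluded, not halved; on undirected graphs this is twice the
  unordered count, a constant convention that cancels in any two-group
  comparison. Path-length ties are detected with relative tolerance 1e-12
  on accumulated distances, so floating-point sums along equally long
  routes count as equal shortest paths.
* **Efficiencies** — E_glob is the mean of 1/d_ij over ordered pairs;
  E_loc averages over nodes the global efficiency of each node's
  neighbour-induced subgraph, kept with its original (un-renormalised)
  weights to match the raw-weight convention used elsewhere, and zero for
  nodes with fewer than two neighbours.

Shortest paths for betweenness/σ counting use a hand-written
Dijkstra/Brandes sweep (the tolerance rule and ordered-pair convention
require it); plain distance matrices go through `scipy.sparse.csgraph`,
and the tiny neighbour subgraphs of E_loc use a dense vectorised
Floyd–Warshall, which is substantially faster there than sparse Dijkstra.
Infinite distances are represented as `inf`, never as a sentinel.

## Null models and the small-world signature

Random references are degree-preserving Maslov–Sneppen rewirings: 10·M
attempted swaps on M edges (the common mixing heuristic), each swap
exchanging the endpoints of two random edges and rejected if it would
create a self-loop or duplicate edge. Weights travel with their edges, so
the degree sequence and the weight multiset are conserved. Connectivity of
rewired networks is *not* enforced (classic formulation); the harmonic /
efficiency conventions absorb any disconnection. Ensemble member k draws
its seed from a (seed, k) stream.

A network is assessed against the ensemble mean (default 100 members):
E_glob(G)/E_glob(G_rand) slightly below 1 together with
E_loc(G)/E_loc(G_rand) above a margin (default 1; "much greater" has no
canonical quantification, so the margin is an explicit parameter)
classifies it as small-world.

## Group statistics

Every nodal metric at every node, and each global feature (C(G), L(G),
E_glob, E_loc and the two small-world ratios), is compared between groups
with a two-sample two-tailed t-test. The default is the pooled-variance
Student form with df = n1 + n2 − 2 (30 for 16 vs 16); Welch's form is
available as an option. P-values are uncorrected by default — appropriate
for a preliminary, hypothesis-generating screen — with Benjamini–Hochberg
adjustment available as an extra column. Rows where a metric is constant
in both groups (betweenness at peripheral nodes, typically) report T = 0,
p = 1 when the means agree. Training-onset ages are related to nodal
features with Pearson correlation.

## The synthetic cohort generator

The generator emulates the *structure* of a two-group repeated-scan
tractography study, not the imaging process itself. Defaults:

| parameter | default | meaning |
|---|---|---|
| n_per_group | 16 | subjects per group |
| n_nodes | 90 | AAL parcellation size |
| n_scans | 3 | repeated acquisitions per subject |
| n_volumes | 21 | volumes per scan (b0 + 20 directions) |
| base_density | 0.3 | fraction of region pairs anatomically connected |
| mean_count | 50 | mean streamline count over present connections |
| dispersion | 5 | negative-binomial size r (var = μ + μ²/r) |
| voxel_range | 150–1500 | uniform seed-voxel count per region |
| spatial_decay | 0.25 | length scale of distance decay of expected counts |
| motion_sd | 0.05 | per-volume random-walk increment (mm / degrees) |
| onset_age_range | 4–16 y | uniform training-onset age, trained group |

Counts are negative-binomial (NB2): probabilistic tractography repeats
many correlated samples per voxel, so counts are strongly overdispersed
relative to Poisson. The connection mask is Erdős–Rényi at `base_density`
(symmetric, shared by the whole cohort as common anatomy). Expected counts
on present connections decay exponentially with the Euclidean distance
between node positions drawn uniformly in a unit cube, rescaled so their
mean over present connections is `mean_count`. This spatial embedding is
what gives synthetic backbones realistic topology: the strongest edges are
short-range and mutually adjacent, so the extracted backbone is locally
clustered and exhibits the small-world efficiency signature that real
white-matter networks show. Without it (``spatial_decay=None``) backbones
are statistically indistinguishable from their own rewired nulls. The
decay scale 0.25 (about a third of the mean inter-node distance) was
chosen once as the weakest embedding that robustly produces that
signature.

Group effects are multiplicative: edges incident to the chosen effect
nodes have their expected counts scaled by `effect_multiplier` in the
second group (applied once, not squared, on edges between two effect
nodes). `expected_weight_matrix` returns the exact analytic expectation of
the resulting symmetric weight matrix — the oracle used by effect-recovery
tests. `calibrate_effect_multiplier` inverts the (approximately linear)
relation between multiplier and realised standardised effect size on
backbone strength via short pilot simulations, so studies can be run at a
stated Cohen's d.

Motion logs are Gaussian random walks; a configurable fraction of scans
receives a sudden 1.5 mm translation jump to exercise the exclusion path.
Onset ages are uniform and independent of network features (the null the
correlation analysis should reproduce). All randomness derives from one
seed through `numpy.random.SeedSequence` streams keyed by (seed, group,
subject, scan), so any subset of a cohort is reproducible in isolation.

**What the generator does not emulate:** tractography geometry and its
distance-dependent false-positive profile, between-region heterogeneity in
count dispersion, hemispheric symmetry, or any correlation between onset
age and connectivity. Passing tests therefore demonstrate that the
*pipeline* recovers known effects from data with realistic marginal
structure — not that it would behave identically on real tractography,
whose biases are richer.

## Validation study sizes

The repeated-simulation checks in the test suite and the acceptance
script run at two scales. Structural and small-world checks use the
full-size design (90 nodes, 16 + 16 subjects, ensemble 100). Calibration
studies that need hundreds of replicate cohorts (type-I error of the nodal
comparison; power against an injected d ≈ 1 strength effect at 4 nodes)
use a 30-node cohort with `base_density 0.5` and `spatial_decay 0.4` —
denser and more weakly decayed than the 90-node defaults so that the
smaller graph keeps the same connectivity margin (at 30 nodes the
full-size settings occasionally leave a region with no surviving positive
connection, which the backbone stage correctly rejects). Type-I error uses
500 cohorts in the tests (300 in the acceptance script), power 200 (150).

## Known limitations

* The backbone requires a connected positive-weight graph; cohorts from
  very sparse generator settings can fail there by design.
* Betweenness on 90-node networks is pure Python (Brandes); it is fast
  enough for cohort-scale work but not for thousands of large networks.
* The pooled t-test is applied to metrics (betweenness, clustering) whose
  distributions can be skewed or zero-inflated at individual nodes;
  simulation shows the type-I error remains within 0.03–0.07, but
  nonparametric alternatives are deliberately out of scope.
* Small-world ratios depend on the rewired ensemble's treatment of
  disconnection; enforcing connected nulls would shift E_loc ratios
  somewhat.
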