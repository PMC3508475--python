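# Methods

## The model

`connmat` treats a brain network as an undirected weighted graph encoded in a
raw connectivity matrix (CM): an n × n real matrix W, assumed symmetric, with
w_ij the connection strength between regions i and j. Functional CMs
typically carry Pearson correlations in [−1, 1]; structural CMs carry fiber
counts spanning several orders of magnitude. The diagonal is meaningless
(self-connection) and is forced to zero on read.

Analysis proceeds raw matrix → thresholded graph → metrics:

1. **Density thresholding.** The k = ⌊(density/100) · n(n−1)/2⌋ strongest
   edges are retained, ranked by *signed* weight descending. Signed rather
   than absolute ranking means strongly negative functional correlations are
   the weakest candidates and are dropped first, which matches the intent of
   keeping "the strongest connections" and yields positive-weight graphs at
   the sparse densities where analysis happens. Zero entries are never edges,
   so a sparse matrix may achieve less than the requested density; the report
   carries both the requested and the achieved ("chosen") density to make the
   discrepancy visible. Ties are broken by lexicographic (i, j) so results are
   bit-reproducible; with this rule edge sets are nested across increasing
   densities.
2. **Weighting.** Binary mode sets retained weights to 1. Weighted mode keeps
   raw weights and requires them positive, because shortest-path distances
   are taken as d_ij = 1/w_ij along edges (the common convention for
   connectivity weights; stronger = closer) and a non-positive weight has no
   distance interpretation — the error message suggests lowering the density
   or using binary mode.

## Metrics

Global: characteristic path length L (mean shortest-path length over
unordered pairs; reported as undefined when the graph is disconnected, never
as a number), mean clustering coefficient C (weighted mode uses the
geometric-mean triangle-intensity generalization with weights scaled by the
maximum weight), number of components, global efficiency (mean 1/d with 1/d=0
for unreachable pairs, hence defined on disconnected graphs), modularity Q,
and the small-world attributes below. Edge-weight and edge Euclidean-length
means and standard deviations are reported for both the raw matrix (over
nonzero pairs) and the thresholded graph (over retained edges); the standard
deviation is the population form (divide by the number of edges).

Nodal: degree (binary) or strength (weighted), clustering, betweenness
centrality normalized by (n−1)(n−2)/2, module membership, regional
efficiency, and participation coefficient P_i = 1 − Σ_s (k_is/k_i)² with
P_i = 0 for isolated nodes. "Regional efficiency" is implemented as *nodal*
efficiency — the mean inverse distance from node i to all others — so that
the node average of the regional vector equals global efficiency exactly,
an identity the test suite asserts. The alternative local-subgraph
efficiency (efficiency of the neighborhood with the node removed) is
available as `local_efficiency` for users who prefer that reading.

Hubs are ranked by the sum of each node's descending rank positions
(average ranks on ties, stable order for exact ties) for strength,
betweenness, and regional efficiency.

## Community detection and null models

Modularity partitions come from greedy agglomerative (CNM-style) modularity
maximization, which is deterministic; a Louvain strategy can be selected via
`AnalysisConfig(community_method="louvain")` and is seeded. Q is the standard
Newman–Girvan quality of whichever partition is returned, weighted in
weighted mode. An edgeless graph gets a singleton-per-node partition with Q
undefined.

γ = C/⟨C_null⟩ and λ = L/⟨L_null⟩ are computed against `n_null_networks`
(default 10) degree-preserving rewired graphs, each produced by
`swap_factor × |E|` attempted double-edge swaps (default 10); σ = γ/λ.
Defaults follow common practice in the connectomics literature; more nulls
sharpen the normalization at linear cost. Nulls are rewired on the binarized
topology. For weighted graphs the original weight multiset, sorted
descending, is reassigned to the null's edges in lexicographic edge order —
a deterministic convention that preserves the weight distribution while
randomizing placement; when a null's edge set is unchanged (zero swaps, or
no legal swap exists) the original weights stay in place, so the identity
null gives γ = λ = 1 exactly. Disconnected nulls are resampled up to 10
times when the input is connected, after which the last candidate is
accepted. Graphs admitting no legal swap (complete graphs, stars) are
returned unchanged with a warning.

All randomness derives from the single config seed through a splittable
`numpy` seed sequence: community detection and null generation receive
independent child seeds, so reports are byte-identical across runs with the
same inputs.

## Lesioning

A virtual lesion zeroes the rows and columns of the selected nodes in the
*raw* matrix; the lesioned matrix is then re-thresholded at the same density
percent, independently of the unlesioned network — i.e., a lesion analysis is
exactly the standard analysis run on the modified matrix. (The alternative —
freezing the unlesioned edge set and deleting lesioned edges — retains more
edges and is intentionally not the default; it can be composed manually from
`threshold_by_density` output.) Lesioned nodes remain in the network as
isolates, so n and the region set are stable across the comparison.

## Cross-modal statistics

Edge-weight correlation is the Pearson r of the two upper triangles, either
over all pairs or restricted to pairs whose weight in the second (structural)
matrix exceeds 1 — "existent" connections with more than one fiber; the mask
is deliberately asymmetric. Nodal metric vectors are compared by Pearson and
Spearman correlation with two-sided p-values from the t-distribution with
n−2 degrees of freedom (Spearman uses average ranks). Partition similarity
uses the Hubert–Arabie adjusted Rand index (via scikit-learn, cross-checked
in the tests against brute-force pair counting). Correlations degenerate
cases — fewer than 3 pairs, constant vectors — are reported as undefined
(None/null), never coerced to a number.

## Synthetic data

The fixture generator emulates the two CM families the engine targets:

- **Modular bundles**: n nodes in m planted modules (round-robin
  assignment), edge probability p_within inside modules and p_between
  across. Functional weights are truncated normals on [−1, 1] with
  within-module mean 0.6 and between-module mean 0.1 (sd 0.15), so negative
  weights occur and exercise signed thresholding; structural weights are
  log-uniform over 10^0–10^4 within modules and 10^0–10^2.5 between.
  Defaults (n=40, m=4, p_within=0.9, p_between=0.05) plant structure that
  greedy modularity recovers essentially perfectly. Module centroids sit on
  a 60 mm grid with 8 mm isotropic node jitter, giving spatially plausible
  coordinates.
- **Coupled pairs**: a functional and a structural matrix over one region
  set with a controlled edge-weight Pearson correlation. The structural
  latent score (modular base + Gaussian noise) is censored at its 60th
  percentile and mapped linearly onto [1, 10^4]; because censoring
  attenuates linear association by a factor c = corr(score, weight), the
  functional score is drawn with latent coupling ρ = r_target/c, which makes
  the realized correlation land on the target (default 0.4) without
  post-hoc adjustment. The functional side's modular structure scales with
  ρ, so an uncoupled pair (r_target = 0) has an unstructured functional
  matrix.
- **Reference graphs**: complete, path, star, ring lattice, two disjoint
  cliques, and a two-clique barbell joined through a single bridge node,
  as unit-weight matrices — the shapes whose metrics have closed forms.

What the generator does *not* emulate: empirical spatial autocorrelation of
functional weights, distance-dependent connection probability, hemispheric
symmetry, realistic degree distributions, or measurement noise shared across
subjects. Passing tests therefore demonstrate the correctness of the graph
machinery and the statistical contracts, not that any neuroscientific
conclusion transfers to real data.

## Numerical choices and degenerate inputs

- Symmetry is validated with tolerance max|w_ij − w_ji| ≤ 1e−8 · max(1,
  max|w|); passing matrices are symmetrized by averaging so downstream math
  is exact. Nonzero diagonals are zeroed with a warning.
- Bundle output writes floats at `repr` precision, so write → read
  round-trips bit-for-bit.
- Undefined metrics are `None` in memory and `null` in JSON, never 0, NaN,
  or a sentinel; every undefined value has a structural reason (disconnected
  graph, no edges, constant vector).
- The analysis is designed for desk-scale networks (n up to ~1000 on one
  CPU); the test suite and the reproduction script run at n ≤ 188, the size
  of a typical functional parcellation.
- The `orientation` config field only selects the projection plane a
  plotting layer would use; no metric depends on it. Rendering itself
  (3D scenes, spring layouts) is out of scope — reports are pure data.

## Known limitations

- Weighted γ/λ depend on the weight-reassignment convention described above;
  other packages assign weights to rewired edges differently, so weighted
  small-world values are comparable only within this package. Binary-mode
  values are convention-free.
- Greedy modularity maximization is a heuristic; on degenerate modularity
  landscapes the returned partition (and hence participation coefficients
  and ARI values downstream) can differ from other optimizers at similar Q.
- Density thresholding with signed ranking is inappropriate for analyses
  where negative correlations are of interest; signed-network metrics are
  deliberately not provided.
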