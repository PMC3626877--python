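# Methods

## Model overview

`remic` scores each gene by the insertional mutation load in its genomic
vicinity, then re-distributes those scores over a protein-interaction
network with a Laplacian heat kernel, so that a gene's evidence reflects
its *interaction context* — its own mutations plus those of its network
neighborhood, weighted by topology and interaction confidence.
Significance is assessed per gene and per diffusion scale against a
permutation null that preserves each tumor's mutation load.

## Mutation scoring

An insertion contributes to a gene with the flat-top Gaussian weight

```
w(d) = 1                      d = 0 (inside the gene body)
       exp(-d² / 2σ²)         0 < d ≤ c
       0                      d > c
```

with σ = 25 kb and cutoff c = 50 kb by default (both configurable).
Coordinates are 0-based half-open `[start, end)`: a position `p` is
inside iff `start ≤ p < end`; outside, `d` is the distance to the nearer
of the start coordinate or the termination-site coordinate `end`, so
`p = end` has `d = 0`. The weight at the cutoff itself is kept
(`associated iff d ≤ c`); beyond it the weight drops discontinuously to
zero. Strand is ignored — the weighting is symmetric around the two gene
ends. An insertion within the cutoff of several genes contributes to all
of them; no nearest-gene assignment is made. `M[i, j]` sums the weights
of tumor *i*'s insertions against gene *j*, and `S_j = Σ_i M_ij`.

## Network construction

STRING-dialect edge lists carry combined confidence scores on a 0–1000
scale; these are used directly as edge weights, with no rescaling — the
diffusion parameter β absorbs the scale (see below). Edges below the
reliability threshold `T_I` (default 500, a compromise between
high-confidence ≥ 700 and low-confidence ≤ 400 conventions) are removed
*before* collapsing proteins to genes; when several protein pairs connect
two genes, the gene-level weight is their arithmetic mean. Threshold
comparison is ≥, so a weight equal to `T_I` survives. Proteins without a
gene mapping are dropped with a warning rather than an error. The gene
order is the sorted order of gene identifiers, fixed at construction and
shared by every matrix and vector downstream.

## Diffusion

With `W` the gene-level weight matrix, `D = diag(W·1)` and
`L = D − W`, the diffusion kernel is the matrix exponential

```
K_β = e^{−βL},   β ≥ 0.
```

The negative sign makes the kernel a proper heat kernel: `K_0 = I`,
`K_β` is symmetric, nonnegative and row-stochastic, the semigroup
property `K_{β₁}K_{β₂} = K_{β₁+β₂}` holds, the total score is conserved
per connected component, and as β → ∞ every component equilibrates to its
uniform distribution. `diffuse_scores` evaluates `S·K_β` as the action of
the exponential on a vector (`expm_multiply`), so memory stays linear in
nodes + edges; dense kernels are only formed below a node cap (default
2000). Disconnected graphs need no special handling — the exponential
acts blockwise.

The informative scale regime is set by the product β·w. With STRING-scale
weights (w ≈ 500–1000), β ≈ 5·10⁻⁴–10⁻³ mixes a gene with its direct
neighborhood, while β ≳ 5·10⁻³ is already close to component-wide
equilibrium, where all contrast vanishes. The default grid is 16 linearly
spaced scales on [0, 0.03]; logarithmic spacing (`"log"`, a geometric
grid spanning two decades below β_max with the zero scale prepended)
samples the small-scale regime more densely and is usually the better
choice for screening.

## Permutation significance

The null randomizes the gene–mutation association while preserving each
tumor's mutation load: every tumor's row of `M` is permuted independently
and the permuted rows are re-summed to a random score vector, which is
diffused at the scale under test. Two engines are available:

- `per-tumor` (default): a fresh permutation for every iteration — the
  exact null;
- `pooled`: a pool of random score vectors (default 10⁵) is precomputed
  once and whole vectors are resampled from it, trading exactness at high
  permutation counts for speed.

Both engines push null vectors through one exponential-action operator
per scale in batches. The empirical p-value is pseudocounted,
`p = (b+1)/(n+1)` with exceedance counted as ≥ (ties count against
significance), so `p ≥ 1/(n+1)` and is never zero. A gene's loop is
discontinued once more than 10 null scores (configurable) exceed its
observed score; such genes report p from the counts at stop and can never
have reached significance anyway, so early stopping does not change the
ReMIC calls when the permutation budget is adequate.

The permutation count must resolve the α level *after* FDR correction:
with m = genes × scales tests of which r reach the p-value floor
`1/(n+1)`, the smallest attainable q is roughly `π₀ · m/(r(n+1))`. A
full interactome-scale screen at α = 0.001 calls for on the order of 10⁷
permutations; the synthetic experiments in this package use 3·10⁴, which
puts the floor (3.3·10⁻⁵) comfortably below α/m·r at their problem sizes.

q-values follow Storey–Tibshirani: `π₀(λ) = #{p > λ}/(m(1−λ))` on a λ
grid 0–0.90, extrapolated to λ → 1 with a cubic smoothing spline; for
vectors shorter than 100 the single-point estimate at λ = 0.5 is used.
q-values are computed on the pooled gene × scale vector, so the
correction accounts for both multiplicities. The ReMIC call is q ≤ α
by default; calling on raw p ≤ α is available as an option since the
combination of α-level and FDR can be configured either way.

## Clustering

Each scale's ReMIC subnetwork (induced subgraph with original weights) is
cut by the Girvan–Newman procedure: repeatedly remove the edge with the
highest betweenness — the number of all-pairs shortest paths through the
edge, split fractionally among equal-length paths — *recomputing*
betweenness after every removal, and record the component partition at
every split. Shortest paths are hop-count (unweighted): betweenness is a
path-census statistic, and confidence weights are not distances; the
weights remain available as metadata. Ties in betweenness are broken by
the lexicographically smallest edge for determinism.

Modularity of a recorded partition with clusters 1…k uses the symmetric
edge-fraction matrix `E`: a within-cluster edge adds `1/m` to `E_ii`, an
inter-cluster edge adds `1/2m` to each of `E_ij`, `E_ji` (total mass 1).
Then `Q = Tr(E) − ‖E²‖` with `‖E²‖` the sum of entries of `E²`, which
equals `Σ_i a_i²` for row sums `a_i` — i.e. the Newman modularity. This
convention makes `Q = 0` exactly for the single-cluster partition and
`Q = 0.5` for two disconnected equal cliques. The dendrogram is cut at
maximum `Q`, ties resolved toward fewer clusters; isolated genes persist
as singleton clusters and are reported.

## Enrichment

Clusters are tested for over-representation in user-supplied GMT gene
sets with the one-sided Fisher exact test on the table
`(k, n−k, K−k, N−n−K+k)`, where the background `N` defaults to all genes
of the interaction network, followed by Benjamini–Hochberg adjustment
(delegated to `statsmodels`). Sets are intersected with the background
first; depletion is not tested.

## Mutual exclusivity

`M` binarized (`M_gt > 0`) is a bipartite gene–tumor graph. The switching
permutation picks two random edges `(g₁,t₁), (g₂,t₂)` and exchanges
endpoints unless a duplicate edge would arise; rejected attempts still
consume an iteration of the `k × q` budget (k = edges, q = 100). Degrees
are preserved exactly — audited on every randomization — which makes a
cluster's raw mutation count invariant under the null; the test statistic
is therefore the MEMo-style *tumor coverage*, the number of distinct
tumors hit in at least one cluster gene, which is maximal at fixed
degrees exactly when mutations are exclusive. The right-tail p-value over
randomizations (default 10⁴) is pseudocounted as elsewhere; clusters with
p ≤ 0.05 are called mutually exclusive. The inner swap loop operates on a
boolean adjacency matrix and is numba-compiled.

## Synthetic data

The generator emulates the structure of an insertional-mutagenesis screen
joined to a confidence-weighted interaction network, with a planted
ground truth: a planted-partition graph (module pairs connected with
probability `p_in` = 0.8, background pairs 0.03, weights uniform on
600–1000, above the 500 threshold) and per-tumor mutation events. Default
study conditions: 100 genes, 200 tumors, one 20-gene module hit in 80% of
tumors with exactly one member gene per affected tumor (round-robin), and
a 2% per-gene background rate. These sizes put each module gene at ~8
expected insertions against a background mean of ~4 — individually
unremarkable (z ≈ 1.4 at β = 0) yet jointly decisive once diffusion
averages over the module (z ≈ 6) — reproducing the regime the method is
designed for while remaining desk-scale. Synthetic gene models sit on one
chromosome at 200 kb spacing with 20 kb bodies, so 50 kb association
windows never overlap; placement noise (Gaussian, configurable sd) pushes
insertions into the scoring tails. Exclusivity modes `exclusive`,
`co-occurring` and `random` plant the corresponding co-mutation patterns.

What the generator does **not** emulate: realistic genome coordinates,
STRING's degree distribution and clustering coefficients, tumor-specific
insertion loads, or correlated backgrounds. Passing tests therefore
demonstrate correctness of the algorithms and calibration of the
statistics under the planted model, not performance on any real screen.

## Numerical choices and edge cases

- Matrix-free diffusion is validated against dense spectral kernels to
  1e−8 on graphs up to 200 nodes; conservation holds to 1e−10 relative.
- `expm` of the zero matrix returns the exact identity, so the β = 0
  kernel deviates from `I` by exactly 0.
- Empty graphs, empty partitions, zero-score genes, single-edge and
  complete bipartite mutation graphs are all handled explicitly (see
  tests).
- All randomness flows through seeded `numpy` generators; identical seeds
  give byte-identical output tables, including across the numba-compiled
  switching loop (seeded per randomization).
- Problem sizes in the test-suite experiments (100 genes, 200 tumors,
  3·10⁴ permutations, 10³ switching randomizations) were chosen as the
  smallest sizes at which the statistical regime of interest —
  sub-significant individual genes, decisive module evidence, resolvable
  α = 0.001 after FDR — is cleanly expressed.

## Known limitations

- The per-tumor permutation engine regenerates permutations per scale;
  for very large matrices the pooled engine is the practical choice, at
  the cost of resampling from a finite pool.
- Girvan–Newman recomputes betweenness after every removal (O(nm²) per
  connected run) and is intended for ReMIC subnetworks, not whole
  interactomes.
- The coverage statistic treats all mutations equally; weighted or
  per-tumor-load-adjusted exclusivity statistics are out of scope.
- Enrichment is set-overlap only; no pathway-topology-aware testing.
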