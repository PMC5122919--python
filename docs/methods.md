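# Methods

## Problem and model

`netfrag` addresses targeted immunization as network dismantling: choose an
order of node removals so that the size `G(q)` of the largest connected
component (LCC), as a fraction of the original `N`, drops as early as
possible in the removed fraction `q`. All analysis is on simple undirected
graphs; inputs are reduced to their LCC first (`preprocess`), mirroring the
usual cleanup of empirical networks (drop weights, self-loops, direction,
then keep the LCC).

Collective influence scores a node by how much it props up the giant
component under the locally tree-like (non-backtracking) approximation:
`CI_ℓ(i) = (k_i − 1) Σ_{j∈∂Ball(i,ℓ)} (k_j − 1)`. Community structure
violates that approximation at the mesoscopic scale. The community-based
variant coarse-grains the network — supernode = community, link weight =
inter-community edge count — and runs a weighted CI there, allocating each
community's score to its members in proportion to their inter-community
degree. The intuition: the nodes worth removing are the ones carrying the
few links that hold *communities* together, not the hubs inside a dense
community.

## Score construction on the coarse graph

The weighted generalizations are constrained by three requirements: a
community with a single neighbor must score zero, unit weights must
reproduce `k − 1` factors, and a singleton partition must reproduce node CI
exactly. The forms used are

* root factor `z_I = s_I (1 − 1/κ_I)` (0 for `κ_I ≤ 1`), computed as
  `s − s/κ` so that on unit weights it is exactly the integer `κ − 1` in
  floating point;
* frontier factor `s_J − Ã_{J,J⁻}`, the strength of frontier community `J`
  minus the weight of the link back toward its predecessor `J⁻` — the
  non-backtracking analog of `k_j − 1`;
* `CbCI(i) = (k_i^out / s_I) · CI_ℓ(I)`, with `k_i^out/s_I` evaluated
  before the product (exactly 1.0 on singleton partitions).

An admissible alternative root factor `s_I − max_J Ã_IJ` satisfies the same
constraints; the choice is isolated in `root_factor` and documented here as
a design decision. When several shortest paths reach a frontier community,
`J⁻` is the smallest-id predecessor (the coarse graph is assumed close to
tree-like, where the case does not arise); summation over all predecessors
is available via `CbCIConfig(sum_predecessors=True)`.

## Scheduling, tie-breaking, reinsertion

Removal is adaptive: scores are recomputed on the residual graph after every
removal (coarse weights updated with frozen community labels) until the LCC
holds at most `stop_frac·N` nodes (default 0.01). CbCI ties are broken by
the larger residual degree, then uniformly at random under the seed. CI uses
the *same* two-level rule. That is a deliberate choice: it makes CI and CbCI
bitwise-identical on singleton partitions (tie sets coincide and the RNG is
consumed identically), giving a strong exactness test of both
implementations; randomized-only CI tie-breaking is rank-equivalent in the
generic untied case.

Both CI and CbCI post-process the removal order by greedy reinsertion from
the fragmented state: CI adds back first the node joining the fewest alive
components; CbCI counts instead the number of distinct *communities* in the
component the node would join. The final removal order is the reverse of the
reinsertion sequence. Nodes never removed by the active phase are appended
in descending residual-degree order (ties by node id) so that curves are
defined on all of `[0, 1]`; this tail rule is a package convention.

On the synthetic suite, reinsertion consistently improves the integrated
LCC `F` (typically 0.30 → 0.25 for CI on the scaled community model) while
`q_c(0.05)` may move by ±0.02 in either direction; the test suite tracks
the `F` improvement. Comparisons are always like-for-like (both CI and CbCI
reinserted).

If the coarse graph runs out of edges before the stopping point (all
communities mutually disconnected), every CbCI score is zero and the
schedule falls back to degree-adaptive removal; the two-phase structure of
CbDI suggests this continuation, and it is flagged as a package choice
because the CbCI procedure itself leaves the situation unspecified.

## Comparator strategies

* **Degree / Betweenness**: adaptive argmax removal with recomputation each
  step; betweenness ties break by degree. Betweenness is exact (Brandes via
  networkx) and only practical at small `N`.
* **CbDI**: leading eigenpair `(λ, ṽ ≥ 0)` of the coarse matrix (largest
  coarse component if disconnected; eigh), node score
  `ṽ_I Σ_{J≠I} k_iJ ṽ_J` — the per-link dynamical importance `ṽ_I ṽ_J`
  summed over the inter-community links node i carries. Normalizations by
  `λ` or additional intra terms would not change the ranking and are
  omitted. Phase 2 (after the coarse graph empties) removes by
  intra-community degree.
* **LSP**: Fiedler vector of the current LCC's Laplacian (dense `eigh` up
  to 2000 nodes, Lanczos beyond; sign fixed by first nonzero component),
  scan of all threshold bipartitions (cuts between equal Fiedler values are
  skipped), objective = two-group modularity
  `m_in/M − (K_1² + K_2²)/(4M²)` (a registry accepts alternates such as
  `−m_out/(K_1K_2)`), then adaptive removal of max inter-group-link nodes
  until the groups disconnect; repeat until the LCC is below `θN`
  (`θ = 0.01`).
* None of the comparators uses reinsertion.

## Metrics

`removal_curve` replays a complete order with a reverse union-find
(equivalent to per-step recomputation — asserted against a BFS oracle).
`q_c(θ)` is the smallest `n/N` with `G_n ≤ θ`, θ = 0.05 by convention; `q`
is taken as `n/N` exactly at integer removals, no interpolation. `F` is the
left-excluded Riemann sum `(1/N) Σ_{n=1..N} G_n`, which lies in `[0, ½]`
because `G_n ≤ min(1, (N−n)/N)`. Entropy of a partition uses natural logs;
the normalized form `H/ln N_C` is base-free (defined as 1 for a single
community). The weighted clustering coefficient of a coarse graph uses the
strength normalization `C_I^w = [s_I(κ_I−1)]^{-1} Σ_{(J,K)} (Ã_IJ+Ã_IK)/2`
over ordered adjacent pairs closed by an edge, which reduces to the
unweighted coefficient on unit weights; supernodes with `κ < 2` contribute
zero (they are not excluded from the mean).

## Synthetic generators

`ba_network` is Barabási–Albert growth from an `m0`-clique, each new node
attaching `m` links to distinct degree-proportional targets
("repeat-sample until distinct"); the edge count
`m0(m0−1)/2 + (N−m0)m` is exact and the degree tail is scale-free.

`community_sf_network` emulates a scale-free network with planted
communities: a coarse BA network (`N_C = 100`, `m0 = m = 3`, mean degree
≈ 6) decides which communities touch; each community is an independent
BA(50, `m0 = m = 4`) block (190 intra edges exactly); and for every
adjacent community pair each of the 50×50 cross pairs links independently
with probability `k_g/(6N/N_C)`, so a node gains ≈ `k_g = 1`
inter-community neighbor on average (the realized mean is
`⟨κ⟩k_g/6 ≈ 0.98` at defaults because the finite coarse network's mean
degree is 5.88, not 6). The constant 6 generalizes to `2·m_coarse` if the
coarse parameters change. The generator returns the full (possibly
disconnected) graph plus the ground-truth partition; experiments reduce to
the LCC, which at defaults contains almost all nodes.

What the model does *not* emulate: degree–community correlations,
overlapping or nested communities, clustering inside communities beyond
what BA gives, and heterogeneous community sizes. Passing tests on this
model therefore demonstrate the mechanics and the direction of the
community effect, not performance on any particular empirical network.

## Problem sizes and reproducibility

The library-level exactness checks run on hundreds of random graphs with
`N ≤ 60`, where brute-force oracles (naive BFS scoring, pairwise
shortest-path betweenness, per-step component recomputation) are feasible.
The qualitative CI-vs-CbCI comparison uses the community model scaled to
`N = 1000` (20 communities of 50) over 5 seeds — large enough for a stable
ordering of the mean `q_c` and `F`, small enough to rerun routinely; at
these settings CbCI reduces `q_c` by ≈ 25% relative to CI, consistent in
direction and magnitude with runs at the full `N = 5000`.

All randomness (generators, tie-breaks, stochastic detection backends) is
seeded; an experiment manifest records the derived per-component seeds, and
rerunning from the same configuration reproduces schedules byte-for-byte.
Seeds for sub-components are derived with `numpy.random.SeedSequence`.

## Known limitations

* Community detection quality bounds CbCI: partitions with very
  heterogeneous community sizes (low partition entropy) blunt its
  advantage, and on genuinely unstructured graphs it degenerates towards
  (coarse) CI behavior at extra cost.
* The coarse-graph score assumes the *coarse* network is close to
  tree-like; strongly clustered supernetworks violate this, and no
  redundant-path suppression is implemented.
* The CbDI and LSP objective functions admit minor variants in the
  literature; the pinned forms are recorded above and isolated in single
  functions, but rankings under other variants may differ.
* Exact betweenness makes the Betweenness strategy impractical beyond a few
  thousand nodes; no approximation is provided.
* Online re-partitioning during removal and balanced-partition detection
  are out of scope.
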