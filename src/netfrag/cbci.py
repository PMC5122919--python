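"""Community-based collective influence (CbCI).

The idea: run a weighted variant of collective influence on the
coarse-grained community network and allocate each community's influence to
its member nodes in proportion to their inter-community degree. Nodes that
bridge many well-connected communities are removed first, which fragments
networks with community structure faster than node-level CI.

On the coarse graph with weights ``a[I, J]`` (inter-community link counts),
strength ``s_I`` and coarse degree ``kappa_I``:

* root factor       z_I = s_I * (1 - 1/kappa_I)   (0 when kappa_I <= 1),
  the weighted analog of k_i - 1;
* frontier factor   s_J - a[J, J-], the outgoing strength of frontier
  community J excluding the link towards its BFS predecessor J- (the
  non-backtracking analog of k_j - 1);
* community CI      CI_l(I) = z_I * sum_{J in dBall(I, l)} (s_J - a[J, J-]),
  with CI_0(I) = z_I;
* node score        CbCI(i) = (k_i^out / s_I) * CI_l(I), I the community
  of i and k_i^out its surviving inter-community degree.

When every community is a single node all of this collapses exactly to the
ordinary CI score, which the test suite asserts.

The partition is detected once on the intact graph and frozen; coarse
weights are recomputed from the residual graph at every removal step.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .ci import _UnionFind, pick_max, TIE_DECIMALS
from .netcore import Graph, RemovalSchedule, complete_order, lcc_size_csr
from .partition import CoarseGraph, Partition, coarse_grain

__all__ = [
    "CbCIConfig",
    "root_factor",
    "frontier_factor",
    "community_ci",
    "cbci_score",
    "cbci_schedule",
    "community_reinsert",
]


@dataclass
class CbCIConfig:
    """Parameters of the CbCI attack.

    ``ell`` is the ball radius on the *coarse* graph (2 ignores communities
    three or more hops away); ``fallback`` names the strategy used if the
    coarse graph runs out of edges before the LCC reaches ``stop_frac * N``
    (only degree-adaptive is provided); ``sum_predecessors`` switches the
    BFS-predecessor convention from "smallest-id predecessor" to summation
    over all shortest-path predecessors.
    """

    ell: int = 2
    stop_frac: float = 0.01
    seed: int | None = None
    fallback: str = "degree"
    sum_predecessors: bool = False

    def __post_init__(self):
        if self.ell < 0:
            raise ValueError("ell must be >= 0")
        if not 0 < self.stop_frac < 1:
            raise ValueError("stop_frac must lie in (0, 1)")
        if self.fallback != "degree":
            raise ValueError("only the degree-adaptive fallback is available")


def root_factor(cg: CoarseGraph, I: int) -> float:
    """z_I = s_I (1 - 1/kappa_I); zero when I has at most one neighbor.

    Computed as ``s - s/kappa`` so that on unit weights (s == kappa) the
    result is exactly the integer ``kappa - 1``.
    """
    kappa = int(cg.kappa[I])
    if kappa <= 1:
        return 0.0
    s = float(cg.strengths[I])
    return s - s / kappa


def frontier_factor(cg: CoarseGraph, J: int, J_minus: int) -> float:
    """s_J - a[J, J-]: strength of J excluding the link back towards J-.

    Zero when J- is J's only neighbor; reduces to kappa_J - 1 on unit
    weights.
    """
    if cg.a[J, J_minus] <= 0:
        raise ValueError(f"community {J_minus} is not adjacent to {J}")
    return float(cg.strengths[J] - cg.a[J, J_minus])


def _cci_one(
    a: np.ndarray,
    s: np.ndarray,
    adj: list[list[int]],
    I: int,
    ell: int,
    z: float,
    sum_predecessors: bool,
) -> float:
    """community CI for one root, given precomputed coarse adjacency lists.

    BFS in ascending id order, so the recorded predecessor of a frontier
    community is its smallest-id neighbor in the previous shell.
    """
    if z == 0.0:
        return 0.0
    if ell == 0:
        return z
    dist = {I: 0}
    pred: dict[int, int] = {}
    frontier = [I]
    for d in range(1, ell + 1):
        nxt: list[int] = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = d
                    pred[v] = u
                    nxt.append(v)
        nxt.sort()
        frontier = nxt
        if not frontier:
            return 0.0
    if not sum_predecessors:
        total = sum(s[J] - a[J, pred[J]] for J in frontier)
    else:
        total = 0.0
        for J in frontier:
            for P in adj[J]:
                if dist.get(P) == ell - 1:
                    total += s[J] - a[J, P]
    return float(z * total)


def community_ci(
    cg: CoarseGraph, I: int, ell: int, sum_predecessors: bool = False
) -> float:
    """Weighted collective influence of community I on the coarse graph.

    ``CI_0(I) = z_I`` by convention (large when I has a large coarse
    degree); for ``ell >= 1`` the frontier is taken at unweighted
    shortest-path distance exactly ``ell``, each frontier community J
    contributing its frontier factor towards its BFS predecessor.
    """
    a = cg.a
    s = cg.strengths.astype(np.float64)
    adj = cg.adjacency_lists()
    return _cci_one(a, s, adj, I, ell, root_factor(cg, I), sum_predecessors)


def _all_community_ci(
    a: np.ndarray, ell: int, sum_predecessors: bool = False
) -> np.ndarray:
    """community CI for every community of a coarse weight matrix."""
    n_c = a.shape[0]
    s = a.sum(axis=1).astype(np.float64)
    kappa = (a > 0).sum(axis=1)
    adj = [np.flatnonzero(row).tolist() for row in a]
    out = np.zeros(n_c)
    for I in range(n_c):
        z = 0.0 if kappa[I] <= 1 else float(s[I]) - float(s[I]) / int(kappa[I])
        out[I] = _cci_one(a, s, adj, I, ell, z, sum_predecessors)
    return out


def cbci_score(
    g: Graph,
    p: Partition,
    cg: CoarseGraph,
    i: int,
    ell: int,
    removed=(),
    sum_predecessors: bool = False,
) -> float:
    """CbCI(i) = (k_i^out / s_I) * CI_l(I); zero when s_I = 0."""
    removed = set(removed)
    if i in removed:
        raise ValueError(f"node {i} is removed")
    I = p.labels[i]
    s_I = float(cg.strengths[I])
    if s_I == 0.0:
        return 0.0
    k_out = sum(
        1 for v in g.adj[i] if v not in removed and p.labels[v] != I
    )
    if k_out == 0:
        return 0.0
    return (k_out / s_I) * community_ci(cg, I, ell, sum_predecessors)


def cbci_schedule(
    g: Graph, p: Partition, cfg: CbCIConfig | None = None
) -> RemovalSchedule:
    """Adaptive CbCI removal until LCC <= ``stop_frac * N`` (pre-reinsertion).

    Per step the coarse weights are those of the residual graph (labels
    frozen); the node with the largest CbCI is removed, ties broken by the
    largest residual degree, then uniformly at random under the seed. If the
    coarse graph becomes edgeless before the stopping point, removal falls
    back to degree-adaptive.
    """
    cfg = cfg or CbCIConfig()
    if p.n != g.n:
        raise ValueError("partition does not cover the graph")
    rng = np.random.default_rng(cfg.seed)
    A = g.csr()
    lab = np.asarray(p.labels)
    alive = np.ones(g.n, dtype=bool)
    deg = g.degrees().astype(np.float64)
    kout = np.array(
        [sum(1 for v in g.adj[u] if lab[v] != lab[u]) for u in range(g.n)],
        dtype=np.float64,
    )
    a = coarse_grain(g, p).a.copy()
    order: list[int] = []
    threshold = cfg.stop_frac * g.n
    while alive.any():
        idx = np.flatnonzero(alive)
        if lcc_size_csr(A, idx) <= threshold:
            break
        s = a.sum(axis=1)
        if s.sum() == 0:
            # coarse graph is edgeless: degree-adaptive fallback
            scores = deg[idx]
        else:
            cci = _all_community_ci(a, cfg.ell, cfg.sum_predecessors)
            s_safe = np.where(s > 0, s, 1).astype(np.float64)
            # ratio first: k_out/s_I is exactly 1.0 on singleton partitions,
            # keeping scores bit-identical to plain CI there
            scores = (kout[idx] / s_safe[lab[idx]]) * cci[lab[idx]]
        pick = pick_max(idx, scores, deg[idx], rng)
        alive[pick] = False
        for v in g.adj[pick]:
            if alive[v]:
                deg[v] -= 1
                if lab[v] != lab[pick]:
                    kout[v] -= 1
                    a[lab[pick], lab[v]] -= 1
                    a[lab[v], lab[pick]] -= 1
        order.append(pick)
    return RemovalSchedule(
        strategy="cbci",
        order=order,
        n_core=len(order),
        params={
            "ell": cfg.ell,
            "stop_frac": cfg.stop_frac,
            "fallback": cfg.fallback,
            "sum_predecessors": cfg.sum_predecessors,
        },
        seed=cfg.seed,
    )


def community_reinsert(
    g: Graph,
    p: Partition,
    removed_order: RemovalSchedule,
    seed: int | None = None,
) -> RemovalSchedule:
    """Community-informed greedy reinsertion.

    Each candidate is scored by the number of distinct communities present in
    the component it would join (its own label union the labels of all alive
    components adjacent to it); the candidate touching the fewest communities
    is reinserted first, ties broken uniformly at random. The final removal
    order is the reverse of the reinsertion sequence plus the usual
    descending-degree tail.
    """
    if p.n != g.n:
        raise ValueError("partition does not cover the graph")
    for u in removed_order.order:
        if not (0 <= u < g.n):
            raise ValueError(f"removed node {u} not in graph")
    if seed is None:
        seed = removed_order.seed
    rng = np.random.default_rng(seed)
    removed = set(removed_order.order)
    uf = _UnionFind(g.n)
    alive = [u not in removed for u in range(g.n)]
    for u, v in g.edges():
        if alive[u] and alive[v]:
            uf.union(u, v)
    # community labels present in each alive component, keyed by UF root
    comp_labels: dict[int, set[int]] = {}
    for u in range(g.n):
        if alive[u]:
            comp_labels.setdefault(uf.find(u), set()).add(p.labels[u])
    remaining = sorted(removed)
    sequence: list[int] = []
    while remaining:
        best_val = None
        ties: list[int] = []
        for i in remaining:
            roots = {uf.find(v) for v in g.adj[i] if alive[v]}
            labs = {p.labels[i]}
            for r in roots:
                labs |= comp_labels[r]
            val = len(labs)
            if best_val is None or val < best_val:
                best_val, ties = val, [i]
            elif val == best_val:
                ties.append(i)
        choice = ties[0] if len(ties) == 1 else ties[rng.integers(len(ties))]
        roots = {uf.find(v) for v in g.adj[choice] if alive[v]}
        merged = {p.labels[choice]}
        for r in roots:
            merged |= comp_labels.pop(r)
        alive[choice] = True
        for v in g.adj[choice]:
            if alive[v]:
                uf.union(choice, v)
        comp_labels[uf.find(choice)] = merged
        sequence.append(choice)
        remaining.remove(choice)
    core = list(reversed(sequence))
    return RemovalSchedule(
        strategy=removed_order.strategy,
        order=complete_order(g, core),
        n_core=len(core),
        params={**removed_order.params, "reinserted": "community"},
        seed=removed_order.seed,
    )
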