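"""Collective-influence (CI) immunization.

The CI score of a node,

    CI_l(i) = (k_i - 1) * sum_{j in dBall(i, l)} (k_j - 1),

derives from the stability analysis of the non-backtracking matrix: nodes
with large CI hold the giant component together. The attack removes the
current argmax adaptively until the largest connected component (LCC) drops
to ``stop_frac * N``, then greedily *reinserts* removed nodes (least
component-joining first); the reverse of the reinsertion sequence is the
final removal order.

Scoring is implemented twice on purpose: :func:`ci_score` is the
definitional per-node BFS form, and the schedule loop uses an equivalent
sparse-matrix formulation of the exact-distance frontier (asserted equal in
the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .netcore import (
    Graph,
    RemovalSchedule,
    ball_frontier,
    complete_order,
    lcc_size_csr,
)

__all__ = ["CIConfig", "ci_score", "ci_scores_all", "ci_schedule", "reinsert"]

#: decimals used when grouping floating-point scores into tie classes
TIE_DECIMALS = 9


@dataclass
class CIConfig:
    """Parameters of the CI attack.

    ``ell`` is the ball radius (frontier distance) of the score; ``stop_frac``
    the LCC fraction at which removal stops (0.01 as in the reference
    procedure); ``seed`` drives random tie-breaking only.
    """

    ell: int = 2
    stop_frac: float = 0.01
    seed: int | None = None

    def __post_init__(self):
        if self.ell < 0:
            raise ValueError("ell must be >= 0")
        if not 0 < self.stop_frac < 1:
            raise ValueError("stop_frac must lie in (0, 1)")


def ci_score(g: Graph, removed: Iterable[int], i: int, ell: int) -> float:
    """CI_l(i) on the residual graph (definitional BFS form).

    For ``ell = 0`` this is ``k_i - 1``, which ranks nodes exactly like the
    degree.
    """
    removed = set(removed)
    k_i = sum(1 for v in g.adj[i] if v not in removed)
    if ell == 0:
        return float(k_i - 1)
    frontier = ball_frontier(g, i, ell, removed)
    total = 0
    for j in frontier:
        k_j = sum(1 for v in g.adj[j] if v not in removed)
        total += k_j - 1
    return float((k_i - 1) * total)


def _frontier_csr(B: sp.csr_matrix, ell: int) -> sp.csr_matrix:
    """Row i of the result marks nodes at distance exactly ``ell`` from i."""
    n = B.shape[0]
    eye = sp.identity(n, dtype=np.int8, format="csr")
    seen = (eye + B).astype(bool).astype(np.int8)
    cur = B.copy()
    for _ in range(ell - 1):
        nxt = (cur @ B).astype(bool).astype(np.int8)
        nxt = nxt - nxt.multiply(seen)
        nxt.eliminate_zeros()
        seen = (seen + nxt).astype(bool).astype(np.int8)
        cur = nxt
        if cur.nnz == 0:
            break
    return cur


def _ci_scores_sub(sub: sp.csr_matrix, ell: int) -> tuple[np.ndarray, np.ndarray]:
    """(scores, degrees) for every node of an induced residual subgraph."""
    k = np.asarray(sub.sum(axis=1)).ravel().astype(np.float64)
    if ell == 0:
        return k - 1.0, k
    frontier = _frontier_csr(sub.astype(np.int8), ell)
    scores = (k - 1.0) * (frontier @ (k - 1.0))
    return scores, k

def ci_scores_all(g: Graph, removed: Iterable[int], ell: int) -> dict[int, float]:
    """CI_l for every alive node, via the sparse frontier formulation."""
    removed = set(removed)
    alive_idx = np.array([u for u in range(g.n) if u not in removed], dtype=np.int64)
    if alive_idx.size == 0:
        return {}
    sub = g.csr()[alive_idx][:, alive_idx]
    scores, _ = _ci_scores_sub(sub, ell)
    return {int(u): float(s) for u, s in zip(alive_idx, scores)}


def pick_max(
    candidates: np.ndarray,
    scores: np.ndarray,
    degrees: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """Argmax by (score, degree) with seeded uniform tie-breaking.

    Scores are rounded to :data:`TIE_DECIMALS` decimals when forming tie
    classes; the RNG is consumed only when the tie class has more than one
    member, which keeps structurally identical schedule loops in lockstep.
    """
    key_s = np.round(scores, TIE_DECIMALS)
    best_s = key_s.max()
    mask = key_s == best_s
    best_d = degrees[mask].max()
    ties = candidates[mask & (degrees == best_d)]
    if len(ties) == 1:
        return int(ties[0])
    return int(ties[rng.integers(len(ties))])


def ci_schedule(g: Graph, cfg: CIConfig | None = None) -> RemovalSchedule:
    """Adaptive CI removal until LCC <= ``stop_frac * N`` (pre-reinsertion).

    Ties in CI are broken by residual degree, then uniformly at random under
    the seed — the same two-level rule as the community-based variant, so the
    two algorithms coincide exactly on the singleton partition.
    """
    cfg = cfg or CIConfig()
    rng = np.random.default_rng(cfg.seed)
    A = g.csr()
    alive = np.ones(g.n, dtype=bool)
    order: list[int] = []
    threshold = cfg.stop_frac * g.n
    while alive.any():
        idx = np.flatnonzero(alive)
        sub = A[idx][:, idx]
        if lcc_size_csr(A, idx) <= threshold:
            break
        scores, k = _ci_scores_sub(sub, cfg.ell)
        pick = pick_max(idx, scores, k, rng)
        alive[pick] = False
        order.append(pick)
    return RemovalSchedule(
        strategy="ci",
        order=order,
        n_core=len(order),
        params={"ell": cfg.ell, "stop_frac": cfg.stop_frac},
        seed=cfg.seed,
    )


class _UnionFind:
    __slots__ = ("parent", "size")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, u: int) -> int:
        root = u
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[u] != root:
            self.parent[u], u = root, self.parent[u]
        return root

    def union(self, u: int, v: int) -> None:
        ru, rv = self.find(u), self.find(v)
        if ru == rv:
            return
        if self.size[ru] < self.size[rv]:
            ru, rv = rv, ru
        self.parent[rv] = ru
        self.size[ru] += self.size[rv]


def reinsert(
    g: Graph,
    removed_order: RemovalSchedule,
    counter: Callable[[int, set[int]], float] | None = None,
    seed: int | None = None,
) -> RemovalSchedule:
    """Greedy reinsertion: add back, first, the node joining the fewest alive
    components; the final removal order is the reverse of the reinsertion
    sequence, with never-removed nodes appended as a descending-degree tail.

    ``counter(i, adjacent_roots)`` scores a candidate given the union-find
    roots of the alive components adjacent to it; the default is
    ``len(adjacent_roots)`` (0 when the node has no alive neighbor).
    """
    for u in removed_order.order:
        if not (0 <= u < g.n):
            raise ValueError(f"removed node {u} not in graph")
    if counter is None:
        counter = lambda i, roots: float(len(roots))
    if seed is None:
        seed = removed_order.seed
    rng = np.random.default_rng(seed)
    removed = set(removed_order.order)
    uf = _UnionFind(g.n)
    alive = [u not in removed for u in range(g.n)]
    for u, v in g.edges():
        if alive[u] and alive[v]:
            uf.union(u, v)
    remaining = sorted(removed)
    sequence: list[int] = []
    while remaining:
        best_val = None
        ties: list[int] = []
        for i in remaining:
            roots = {uf.find(v) for v in g.adj[i] if alive[v]}
            val = counter(i, roots)
            if best_val is None or val < best_val:
                best_val, ties = val, [i]
            elif val == best_val:
                ties.append(i)
        choice = ties[0] if len(ties) == 1 else ties[rng.integers(len(ties))]
        alive[choice] = True
        for v in g.adj[choice]:
            if alive[v]:
                uf.union(choice, v)
        sequence.append(choice)
        remaining.remove(choice)
    core = list(reversed(sequence))
    return RemovalSchedule(
        strategy=removed_order.strategy,
        order=complete_order(g, core),
        n_core=len(core),
        params={**removed_order.params, "reinserted": True},
        seed=removed_order.seed,
    )
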