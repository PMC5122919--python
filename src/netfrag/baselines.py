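"""Comparator immunization strategies.

* Degree: adaptive highest-degree removal (the classic hub attack).
* Betweenness: adaptive highest-betweenness removal; effective on modular
  networks but O(NM) per step, so only practical at small N.
* CbDI: community-based dynamical importance — the leading eigenpair
  (lambda, v >= 0) of the coarse weight matrix scores node i by
  ``v_I * sum_{J != I} k_iJ v_J``; once all communities are disconnected a
  second phase removes nodes by intra-community degree.
* LSP: Laplacian spectral partitioning — repeatedly bipartition the current
  LCC along its Fiedler vector at the threshold maximizing a two-group
  quality score, then peel off the nodes with the most inter-group links
  until the groups disconnect.

None of these applies a reinsertion step; each stops at its stated LCC
threshold and appends the deterministic descending-degree tail so curves
are defined on all of [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg

from .ci import pick_max
from .netcore import (
    Graph,
    RemovalSchedule,
    complete_order,
    components,
    lcc_size_csr,
)
from .partition import CoarseGraph, Partition, coarse_grain

__all__ = [
    "degree_schedule",
    "betweenness_schedule",
    "cbdi_score",
    "cbdi_schedule",
    "LSPConfig",
    "LSP_VARIANTS",
    "lsp_schedule",
]


def degree_schedule(
    g: Graph, seed: int | None = None, stop_frac: float = 0.01
) -> RemovalSchedule:
    """Adaptive max-degree removal to the ``stop_frac * N`` stopping point."""
    rng = np.random.default_rng(seed)
    A = g.csr()
    alive = np.ones(g.n, dtype=bool)
    deg = g.degrees().astype(np.float64)
    order: list[int] = []
    threshold = stop_frac * g.n
    while alive.any():
        idx = np.flatnonzero(alive)
        if lcc_size_csr(A, idx) <= threshold:
            break
        d = deg[idx]
        pick = pick_max(idx, d, np.zeros_like(d), rng)
        alive[pick] = False
        for v in g.adj[pick]:
            if alive[v]:
                deg[v] -= 1
        order.append(pick)
    return RemovalSchedule(
        strategy="degree",
        order=complete_order(g, order),
        n_core=len(order),
        params={"stop_frac": stop_frac},
        seed=seed,
    )


def betweenness_schedule(
    g: Graph, seed: int | None = None, stop_frac: float = 0.01
) -> RemovalSchedule:
    """Adaptive max-betweenness removal (ties: degree, then random).

    Betweenness is recomputed exactly on the residual graph at every step,
    which is only practical for small networks.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    A = g.csr()
    alive = np.ones(g.n, dtype=bool)
    order: list[int] = []
    threshold = stop_frac * g.n
    nxg = g.to_networkx()
    while alive.any():
        idx = np.flatnonzero(alive)
        if lcc_size_csr(A, idx) <= threshold:
            break
        sub = nxg.subgraph(idx.tolist())
        btw = nx.betweenness_centrality(sub, normalized=False)
        scores = np.array([btw[u] for u in idx])
        degs = np.array([sub.degree(u) for u in idx], dtype=np.float64)
        pick = pick_max(idx, scores, degs, rng)
        alive[pick] = False
        order.append(pick)
    return RemovalSchedule(
        strategy="betweenness",
        order=complete_order(g, order),
        n_core=len(order),
        params={"stop_frac": stop_frac},
        seed=seed,
    )


# -- community-based dynamical importance ---------------------------------


def _leading_eigvec(a: np.ndarray) -> np.ndarray:
    """Nonnegative unit-norm leading eigenvector of the coarse matrix.

    For a disconnected coarse graph the eigenpair is taken on its largest
    connected component (size ties: smallest minimum id); communities outside
    it get weight zero. Returns the zero vector if the matrix has no edges.
    """
    n_c = a.shape[0]
    v_full = np.zeros(n_c)
    if a.sum() == 0:
        return v_full
    adj = [set(np.flatnonzero(row)) for row in a]
    comp_graph = Graph([set(x) for x in adj])
    comp = sorted(components(comp_graph)[0])
    sub = a[np.ix_(comp, comp)].astype(np.float64)
    w, vecs = scipy.linalg.eigh(sub)
    v = vecs[:, -1]
    v = np.abs(v)  # Perron-Frobenius: leading eigenvector has constant sign
    v /= np.linalg.norm(v)
    v_full[comp] = v
    return v_full


def cbdi_score(
    g: Graph,
    p: Partition,
    cg: CoarseGraph,
    i: int,
    removed: Iterable[int] = (),
    eigvec: np.ndarray | None = None,
) -> float:
    """CbDI(i) = v_I * sum_{J != I} k_iJ v_J on the residual graph.

    ``k_iJ`` counts the surviving links from i into community J; ``v`` is the
    nonnegative leading eigenvector of the coarse weight matrix (pass
    ``eigvec`` to reuse or rescale it — the ranking is scale-invariant).
    """
    removed = set(removed)
    if eigvec is None:
        eigvec = _leading_eigvec(cg.a)
    I = p.labels[i]
    acc = 0.0
    for v in g.adj[i]:
        if v not in removed and p.labels[v] != I:
            acc += eigvec[p.labels[v]]
    return float(eigvec[I] * acc)


def cbdi_schedule(
    g: Graph,
    p: Partition,
    seed: int | None = None,
    stop_frac: float = 0.01,
) -> RemovalSchedule:
    """Two-phase adaptive CbDI removal.

    Phase 1 removes the node with the largest CbDI (ties: most
    intra-community links, then random), recomputing the coarse eigenpair
    after every removal. Once the residual coarse graph has no edges (all
    communities disconnected), phase 2 removes nodes in descending order of
    intra-community degree. Stops at LCC <= ``stop_frac * N``.
    """
    if p.n != g.n:
        raise ValueError("partition does not cover the graph")
    rng = np.random.default_rng(seed)
    A = g.csr()
    lab = np.asarray(p.labels)
    alive = np.ones(g.n, dtype=bool)
    kintra = np.array(
        [sum(1 for v in g.adj[u] if lab[v] == lab[u]) for u in range(g.n)],
        dtype=np.float64,
    )
    a = coarse_grain(g, p).a.copy().astype(np.float64)
    order: list[int] = []
    threshold = stop_frac * g.n
    while alive.any():
        idx = np.flatnonzero(alive)
        if lcc_size_csr(A, idx) <= threshold:
            break
        if a.sum() == 0:
            ki = kintra[idx]
            pick = pick_max(idx, ki, np.zeros_like(ki), rng)
        else:
            v = _leading_eigvec(a)
            scores = np.empty(len(idx))
            for pos, u in enumerate(idx):
                acc = 0.0
                for w in g.adj[u]:
                    if alive[w] and lab[w] != lab[u]:
                        acc += v[lab[w]]
                scores[pos] = v[lab[u]] * acc
            pick = pick_max(idx, scores, kintra[idx], rng)
        alive[pick] = False
        for w in g.adj[pick]:
            if alive[w]:
                if lab[w] == lab[pick]:
                    kintra[w] -= 1
                else:
                    a[lab[pick], lab[w]] -= 1
                    a[lab[w], lab[pick]] -= 1
        order.append(pick)
    return RemovalSchedule(
        strategy="cbdi",
        order=complete_order(g, order),
        n_core=len(order),
        params={"stop_frac": stop_frac},
        seed=seed,
    )


# -- Laplacian spectral partitioning ---------------------------------------


def _two_group_modularity(m_in: float, m_cross: float, K1: float, K2: float, M: float) -> float:
    return m_in / M - (K1 * K1 + K2 * K2) / (4.0 * M * M)


def _neg_cut_over_degrees(m_in: float, m_cross: float, K1: float, K2: float, M: float) -> float:
    return -m_cross / (K1 * K2)


#: step-3 bipartition objectives (maximized); the default is the two-group
#: modularity m_in/M - (K1^2 + K2^2)/(4 M^2)
LSP_VARIANTS: dict[str, Callable[[float, float, float, float, float], float]] = {
    "two_group_modularity": _two_group_modularity,
    "neg_cut_over_degrees": _neg_cut_over_degrees,
}


@dataclass
class LSPConfig:
    theta: float = 0.01
    variant: str = "two_group_modularity"

    def __post_init__(self):
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")
        if self.variant not in LSP_VARIANTS:
            raise ValueError(f"unknown LSP variant {self.variant!r}")


def _fiedler_vector(sub_adj: sp.csr_matrix) -> np.ndarray:
    """Eigenvector of the smallest positive Laplacian eigenvalue (connected
    input), sign-fixed so the first nonzero component is positive."""
    n = sub_adj.shape[0]
    deg = np.asarray(sub_adj.sum(axis=1)).ravel().astype(np.float64)
    if n <= 2000:
        lap = np.diag(deg) - sub_adj.toarray().astype(np.float64)
        w, vecs = scipy.linalg.eigh(lap)
        vec = vecs[:, 1]
    else:
        lap = sp.diags(deg) - sub_adj.astype(np.float64)
        w, vecs = scipy.sparse.linalg.eigsh(lap, k=2, which="SM")
        vec = vecs[:, np.argsort(w)[1]]
    nz = np.flatnonzero(np.abs(vec) > 1e-12)
    if nz.size and vec[nz[0]] < 0:
        vec = -vec
    return vec


def lsp_schedule(
    g: Graph, cfg: LSPConfig | None = None, seed: int | None = None
) -> RemovalSchedule:
    """Laplacian spectral partitioning attack.

    Loop until the LCC drops below ``theta * N``: compute the Fiedler vector
    of the current LCC, scan the N_LCC - 1 threshold bipartitions (cuts
    between equal Fiedler values are skipped), keep the one maximizing the
    configured objective, then adaptively remove the node with the most
    inter-group links until the two groups disconnect. Tiny or uncuttable
    LCCs (<= 2 nodes, or a constant Fiedler vector) terminate the loop.
    """
    cfg = cfg or LSPConfig()
    score_fn = LSP_VARIANTS[cfg.variant]
    rng = np.random.default_rng(seed)
    A = g.csr()
    removed: set[int] = set()
    order: list[int] = []
    threshold = cfg.theta * g.n
    while True:
        comps = components(g, removed)
        if not comps:
            break
        lcc = sorted(comps[0])
        if len(lcc) < threshold or len(lcc) <= 2:
            break
        pos = {u: t for t, u in enumerate(lcc)}
        sub = A[lcc][:, lcc]
        fiedler = _fiedler_vector(sub)
        sweep = sorted(range(len(lcc)), key=lambda t: (-fiedler[t], t))
        vals = fiedler[sweep]
        deg = np.asarray(sub.sum(axis=1)).ravel().astype(np.float64)
        M = deg.sum() / 2.0
        in1 = np.zeros(len(lcc), dtype=bool)
        K1 = 0.0
        cross = 0.0
        best_score, best_cut = None, None
        for t, node in enumerate(sweep):
            for v in g.adj[lcc[node]]:
                if v in pos and v not in removed:
                    cross += -1.0 if in1[pos[v]] else 1.0
            in1[node] = True
            K1 += deg[node]
            if t == len(lcc) - 1:
                break
            if vals[t] == vals[t + 1]:
                continue  # equal Fiedler values cannot be separated
            K2 = 2.0 * M - K1
            score = score_fn(M - cross, cross, K1, K2, M)
            if best_score is None or score > best_score:
                best_score, best_cut = score, t
        if best_cut is None:
            break  # constant Fiedler vector: no admissible bipartition
        group1 = {lcc[sweep[t]] for t in range(best_cut + 1)}
        # peel nodes with the most inter-group links until groups disconnect
        inter = {}
        for u in lcc:
            cnt = 0
            for v in g.adj[u]:
                if v in pos and v not in removed and ((v in group1) != (u in group1)):
                    cnt += 1
            inter[u] = cnt
        while True:
            total_cross = sum(inter[u] for u in inter if u not in removed) // 2
            if total_cross == 0:
                break
            cand = np.array(sorted(u for u in inter if u not in removed))
            scores = np.array([float(inter[u]) for u in cand])
            pick = pick_max(cand, scores, np.zeros_like(scores), rng)
            removed.add(pick)
            order.append(pick)
            for v in g.adj[pick]:
                if v in pos and v not in removed and ((v in group1) != (pick in group1)):
                    inter[v] -= 1
    return RemovalSchedule(
        strategy="lsp",
        order=complete_order(g, order),
        n_core=len(order),
        params={"theta": cfg.theta, "variant": cfg.variant},
        seed=seed,
    )
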