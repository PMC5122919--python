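"""Synthetic network generators with ground-truth community structure.

Two generators back the whole test bench:

* :func:`ba_network` — Barabási–Albert preferential attachment seeded from
  an ``m0``-clique, each new node attaching ``m`` links to distinct existing
  nodes with probability proportional to current degree ("repeat-sample
  until distinct" convention). The edge count is deterministic:
  ``m0 (m0 - 1) / 2 + (N - m0) m``.

* :func:`community_sf_network` — a scale-free network with built-in
  communities: a coarse BA network (default: 100 supernodes, m0 = m = 3,
  mean degree ~6) fixes which communities are adjacent; each community is an
  independent BA network of 50 nodes with m0 = m = 4; and for every adjacent
  community pair each of the 50 x 50 cross pairs is linked independently
  with probability ``k_g / (6 N / N_C)``, so a node carries ~``k_g``
  inter-community links on average (default ``k_g = 1``).

The defaults therefore produce the standard 5000-node benchmark with a
known 100-community partition. The generated graph may be disconnected for
small ``k_g``; experiments reduce to the LCC via
:func:`netfrag.netcore.preprocess`, while the generator returns the full
graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netcore import Graph
from .partition import Partition

__all__ = ["CommunityModelConfig", "ba_network", "community_sf_network"]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def ba_network(n: int, m0: int = 3, m: int = 3, seed=None) -> Graph:
    """Barabási–Albert graph on ``n`` nodes, seeded from an ``m0``-clique."""
    if not (1 <= m <= m0 < n):
        raise ValueError("require 1 <= m <= m0 < n")
    rng = _as_rng(seed)
    adj: list[set[int]] = [set() for _ in range(n)]
    targets: list[int] = []  # one entry per link endpoint: degree-proportional
    for u in range(m0):
        for v in range(u + 1, m0):
            adj[u].add(v)
            adj[v].add(u)
            targets.append(u)
            targets.append(v)
    for new in range(m0, n):
        chosen: set[int] = set()
        while len(chosen) < m:
            cand = targets[rng.integers(len(targets))]
            chosen.add(cand)
        for v in chosen:
            adj[new].add(v)
            adj[v].add(new)
            targets.append(v)
        targets.extend([new] * m)
    return Graph(adj)


@dataclass
class CommunityModelConfig:
    """Parameters of the scale-free community model.

    ``k_inter`` is the target mean number of inter-community neighbors per
    node; the cross-pair linking probability is
    ``k_inter / (2 * coarse_m * nodes_per_community)``, which with the
    default ``coarse_m = 3`` is the literal ``k_inter / (6 N / N_C)``.
    """

    n_communities: int = 100
    nodes_per_community: int = 50
    coarse_m0: int = 3
    coarse_m: int = 3
    intra_m0: int = 4
    intra_m: int = 4
    k_inter: float = 1.0
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.n_communities * self.nodes_per_community

    @property
    def p_cross(self) -> float:
        return self.k_inter / (2 * self.coarse_m * self.nodes_per_community)

    def __post_init__(self):
        if self.n_communities < 2 or self.nodes_per_community < 1:
            raise ValueError("need >= 2 communities of >= 1 node")
        if self.k_inter < 0:
            raise ValueError("k_inter must be nonnegative")
        if self.p_cross > 1:
            raise ValueError("cross-pair probability exceeds 1; lower k_inter")


def community_sf_network(
    cfg: CommunityModelConfig | None = None,
) -> tuple[Graph, Partition]:
    """Generate the community model; returns (graph, ground-truth partition)."""
    cfg = cfg or CommunityModelConfig()
    rng = _as_rng(cfg.seed)
    npc = cfg.nodes_per_community
    coarse = ba_network(cfg.n_communities, cfg.coarse_m0, cfg.coarse_m, rng)
    adj: list[set[int]] = [set() for _ in range(cfg.n)]
    for I in range(cfg.n_communities):
        block = ba_network(npc, cfg.intra_m0, cfg.intra_m, rng) if npc > 1 else None
        if block is not None:
            off = I * npc
            for u, v in block.edges():
                adj[off + u].add(off + v)
                adj[off + v].add(off + u)
    p = cfg.p_cross
    if p > 0:
        for I, J in sorted(coarse.edges()):
            hits = np.flatnonzero(rng.random(npc * npc) < p)
            for h in hits:
                u = I * npc + h // npc
                v = J * npc + h % npc
                adj[u].add(v)
                adj[v].add(u)
    labels = tuple(i // npc for i in range(cfg.n))
    return Graph(adj), Partition(labels)
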