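"""Fragmentation curves and scalar attack-performance measures.

``G(q)`` is the size of the largest connected component (fraction of N)
after a fraction ``q`` of the nodes has been removed along a schedule. From
the curve we report:

* ``q_c(theta)`` — the smallest removed fraction with ``G <= theta``
  (theta = 0.05 by convention): the fragmentation point; lower is better.
* ``F`` — the integrated LCC size, ``(1/N) * sum_{n=1}^{N} G_n``, the area
  under G(q); it lies in [0, 1/2] for any valid removal process and again
  lower means a more efficient attack.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .netcore import Graph, RemovalSchedule

__all__ = [
    "RemovalCurve",
    "removal_curve",
    "q_critical",
    "integrated_lcc",
    "compare_strategies",
]


@dataclass
class RemovalCurve:
    """Normalized LCC sizes ``g[n]`` after n removals, n = 0..N."""

    n: int
    g: np.ndarray

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=np.float64)
        if self.g.shape != (self.n + 1,):
            raise ValueError("curve must have N + 1 entries")
        if (np.diff(self.g) > 1e-12).any():
            raise ValueError("G must be non-increasing")
        if self.g[-1] != 0.0:
            raise ValueError("G_N must be 0")

    @property
    def q(self) -> np.ndarray:
        return np.arange(self.n + 1) / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": np.arange(self.n + 1), "q": self.q, "G": self.g})


def removal_curve(g: Graph, order: RemovalSchedule | Sequence[int]) -> RemovalCurve:
    """Replay a complete removal order and record G_n for n = 0..N.

    Computed by building the graph backwards with a union-find (add nodes in
    reverse order together with their edges to already-present nodes), which
    is equivalent to recomputing components from scratch at every step.
    """
    if isinstance(order, RemovalSchedule):
        order = order.order
    order = list(order)
    if sorted(order) != list(range(g.n)):
        raise ValueError("order must cover every node of the graph exactly once")
    parent = list(range(g.n))
    size = [1] * g.n

    def find(u: int) -> int:
        root = u
        while parent[root] != root:
            root = parent[root]
        while parent[u] != root:
            parent[u], u = root, parent[u]
        return root

    present = [False] * g.n
    sizes = np.zeros(g.n + 1, dtype=np.int64)
    best = 0
    for step, u in enumerate(reversed(order)):
        present[u] = True
        for v in g.adj[u]:
            if present[v]:
                ru, rv = find(u), find(v)
                if ru != rv:
                    if size[ru] < size[rv]:
                        ru, rv = rv, ru
                    parent[rv] = ru
                    size[ru] += size[rv]
        best = max(best, size[find(u)])
        sizes[g.n - 1 - step] = best
    sizes[g.n] = 0
    return RemovalCurve(n=g.n, g=sizes / g.n)


def q_critical(curve: RemovalCurve, theta: float = 0.05) -> float:
    """Smallest removed fraction n/N at which G_n <= theta."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    hits = np.flatnonzero(curve.g <= theta)
    return float(hits[0] / curve.n)


def integrated_lcc(curve: RemovalCurve) -> float:
    """F = (1/N) sum_{n=1}^{N} G_n, the area under G(q); in [0, 1/2]."""
    return float(curve.g[1:].sum() / curve.n)


def compare_strategies(
    g: Graph,
    schedules: Mapping[str, RemovalSchedule],
    theta: float = 0.05,
    reference: str = "ci",
    ratios: bool | None = None,
) -> pd.DataFrame:
    """Per-strategy q_c and F, optionally normalized by a reference row.

    Ratio columns (``q_c_ratio``, ``F_ratio``) are added when the reference
    strategy is present (or always, raising KeyError if absent, when
    ``ratios=True``). Values below 1 mean the strategy fragments the network
    with fewer removals than the reference.
    """
    rows = []
    for name, sched in schedules.items():
        curve = removal_curve(g, sched)
        rows.append(
            {
                "strategy": name,
                "q_c": q_critical(curve, theta),
                "F": integrated_lcc(curve),
                "theta": theta,
                "n_core": sched.n_core,
                "seed": sched.seed,
            }
        )
    table = pd.DataFrame(rows).set_index("strategy")
    want_ratios = ratios if ratios is not None else reference in table.index
    if want_ratios:
        if reference not in table.index:
            raise KeyError(f"reference strategy {reference!r} missing from schedules")
        table["q_c_ratio"] = table["q_c"] / table.loc[reference, "q_c"]
        table["F_ratio"] = table["F"] / table.loc[reference, "F"]
    return table.reset_index()
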