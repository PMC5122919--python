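"""Graph container, preprocessing, connectivity, and edge-list I/O.

Everything downstream works on :class:`Graph`: a simple undirected graph on
0-based contiguous internal node ids. Original input labels are preserved in
``labels`` so schedules can be written back in the caller's id space. Node
removal is always modeled as a *mask* (a set of removed ids) over an immutable
graph, never as mutation, so removal schedules are replayable.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc

__all__ = [
    "Graph",
    "RemovalSchedule",
    "load_edge_list",
    "write_edge_list",
    "preprocess",
    "components",
    "largest_component_size",
    "ball_frontier",
    "complete_order",
    "write_schedule",
    "load_schedule",
]


class Graph:
    """Simple undirected graph with 0-based contiguous node ids.

    Parameters
    ----------
    adj
        Adjacency as a list of neighbor sets; must be symmetric, with no
        self-loops.
    labels
        Original node labels, ``labels[i]`` being the external id of internal
        node ``i``. Defaults to the identity.
    """

    __slots__ = ("adj", "labels", "_csr")

    def __init__(self, adj: list[set[int]], labels: Sequence[int] | None = None):
        self.adj = adj
        self.labels = list(labels) if labels is not None else list(range(len(adj)))
        if len(self.labels) != len(adj):
            raise ValueError("labels length must match number of nodes")
        self._csr = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls, pairs: Iterable[tuple[int, int]], labels: Sequence[int] | None = None
    ) -> "Graph":
        """Build from (u, v) pairs on external labels.

        Self-loops and duplicate edges are silently dropped; direction is
        ignored. Labels are normalized to 0-based contiguous internal ids in
        ascending label order.
        """
        pairs = list(pairs)
        if labels is None:
            seen: set[int] = set()
            for u, v in pairs:
                seen.add(u)
                seen.add(v)
            labels = sorted(seen)
        index = {lab: i for i, lab in enumerate(labels)}
        adj: list[set[int]] = [set() for _ in labels]
        for u, v in pairs:
            if u == v:
                continue
            iu, iv = index[u], index[v]
            adj[iu].add(iv)
            adj[iv].add(iu)
        return cls(adj, labels)

    @classmethod
    def from_networkx(cls, nxg) -> "Graph":
        labels = sorted(nxg.nodes())
        return cls.from_edges(nxg.edges(), labels=labels)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges())
        return g

    # -- basic queries -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.adj)

    @property
    def m(self) -> int:
        return sum(len(s) for s in self.adj) // 2

    def degree(self, i: int) -> int:
        return len(self.adj[i])

    def degrees(self) -> np.ndarray:
        return np.array([len(s) for s in self.adj], dtype=np.int64)

    def neighbors(self, i: int) -> set[int]:
        return self.adj[i]

    def edges(self) -> Iterator[tuple[int, int]]:
        for u, nbrs in enumerate(self.adj):
            for v in nbrs:
                if u < v:
                    yield (u, v)

    def has_edge(self, u: int, v: int) -> bool:
        return v in self.adj[u]

    def subgraph(self, nodes: Iterable[int]) -> "Graph":
        """Induced subgraph; preserves original labels, reindexes internally."""
        keep = sorted(set(nodes))
        index = {u: i for i, u in enumerate(keep)}
        adj = [set(index[v] for v in self.adj[u] if v in index) for u in keep]
        return Graph(adj, labels=[self.labels[u] for u in keep])

    def csr(self) -> sp.csr_matrix:
        """Adjacency as a cached boolean-ish CSR matrix (int8 data)."""
        if self._csr is None:
            rows, cols = [], []
            for u, nbrs in enumerate(self.adj):
                for v in nbrs:
                    rows.append(u)
                    cols.append(v)
            data = np.ones(len(rows), dtype=np.int8)
            self._csr = sp.csr_matrix(
                (data, (rows, cols)), shape=(self.n, self.n), dtype=np.int8
            )
        return self._csr

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Graph(n={self.n}, m={self.m})"


@dataclass
class RemovalSchedule:
    """An ordered node-removal sequence plus the provenance needed to replay it.

    ``order`` holds internal node ids. ``n_core`` is the length of the active
    attack phase (removals made before the stopping rule fired); entries past
    ``n_core`` are the deterministic tail appended so curves are defined on the
    whole of [0, 1].
    """

    strategy: str
    order: list[int]
    n_core: int
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if len(set(self.order)) != len(self.order):
            raise ValueError("schedule contains duplicate node ids")

    def is_complete(self, g: Graph) -> bool:
        return len(self.order) == g.n

    def validate(self, g: Graph) -> None:
        for u in self.order:
            if not (0 <= u < g.n):
                raise ValueError(f"schedule node {u} not in graph")


# -- I/O -------------------------------------------------------------------


def load_edge_list(path: str | Path, one_based: bool = False) -> Graph:
    """Read a whitespace/TSV edge list into a :class:`Graph`.

    Lines starting with ``#`` and blank lines are skipped; only the first two
    columns are used. Self-loops and duplicate edges are dropped. With
    ``one_based`` the input labels are shifted down by one so external output
    stays in the 0-based convention.
    """
    path = Path(path)
    if path.suffix == ".graphml":
        import networkx as nx

        return Graph.from_networkx(nx.read_graphml(path).to_undirected())
    pairs: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns, got {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer node id in {line!r}") from exc
            if one_based:
                u, v = u - 1, v - 1
            pairs.append((u, v))
    if not pairs:
        raise ValueError(f"{path}: empty edge list")
    return Graph.from_edges(pairs)


def write_edge_list(g: Graph, path: str | Path, one_based: bool = False) -> None:
    off = 1 if one_based else 0
    with open(path, "w") as fh:
        for u, v in sorted(g.edges()):
            fh.write(f"{g.labels[u] + off}\t{g.labels[v] + off}\n")


def write_schedule(sched: RemovalSchedule, g: Graph, prefix: str | Path) -> None:
    """Serialize a schedule: one external node id per line + a JSON sidecar."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".schedule.txt"), "w") as fh:
        for u in sched.order:
            fh.write(f"{g.labels[u]}\n")
    meta = {
        "strategy": sched.strategy,
        "n_core": sched.n_core,
        "params": sched.params,
        "seed": sched.seed,
        "n": g.n,
        "m": g.m,
    }
    with open(prefix.with_suffix(".schedule.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_schedule(g: Graph, prefix: str | Path) -> RemovalSchedule:
    prefix = Path(prefix)
    index = {lab: i for i, lab in enumerate(g.labels)}
    with open(prefix.with_suffix(".schedule.txt")) as fh:
        order = [index[int(line)] for line in fh if line.strip()]
    with open(prefix.with_suffix(".schedule.json")) as fh:
        meta = json.load(fh)
    return RemovalSchedule(
        strategy=meta["strategy"],
        order=order,
        n_core=meta["n_core"],
        params=meta.get("params", {}),
        seed=meta.get("seed"),
    )


# -- connectivity ----------------------------------------------------------


def components(g: Graph, removed: Iterable[int] = ()) -> list[set[int]]:
    """Connected components of the residual graph, largest first.

    Ties in size are broken by the smallest minimum node id, so the ordering
    is deterministic.
    """
    removed = set(removed)
    seen: set[int] = set(removed)
    comps: list[set[int]] = []
    for start in range(g.n):
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        seen.add(start)
        while queue:
            u = queue.popleft()
            for v in g.adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.add(v)
                    queue.append(v)
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def preprocess(g: Graph) -> Graph:
    """Reduce to the largest connected component (simple, undirected).

    Mirrors the usual empirical-network cleanup: weights/direction are already
    gone by construction; this keeps the LCC only. Size ties are broken by the
    smallest minimum node id.
    """
    if g.n == 0:
        raise ValueError("empty graph")
    comps = components(g)
    return g.subgraph(comps[0])


def largest_component_size(g: Graph, removed: Iterable[int] = ()) -> int:
    """Size of the largest connected component of the residual graph."""
    removed = set(removed)
    if len(removed) >= g.n:
        return 0
    best = 0
    seen: set[int] = set(removed)
    for start in range(g.n):
        if start in seen:
            continue
        size = 0
        queue = deque([start])
        seen.add(start)
        while queue:
            u = queue.popleft()
            size += 1
            for v in g.adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        best = max(best, size)
    return best


def lcc_size_csr(A: sp.csr_matrix, alive_idx: np.ndarray) -> int:
    """Largest-component size of the subgraph induced on ``alive_idx``.

    Fast path used by schedule loops; semantics identical to
    :func:`largest_component_size`.
    """
    if alive_idx.size == 0:
        return 0
    sub = A[alive_idx][:, alive_idx]
    ncomp, lab = _cc(sub, directed=False)
    return int(np.bincount(lab, minlength=ncomp).max())


def ball_frontier(g: Graph, i: int, ell: int, removed: Iterable[int] = ()) -> set[int]:
    """Nodes at shortest-path distance exactly ``ell`` from ``i`` (BFS).

    Distances are measured in the residual graph; ``ell=0`` returns ``{i}``.
    """
    removed = set(removed)
    if i in removed:
        raise ValueError(f"node {i} is removed")
    if ell == 0:
        return {i}
    seen = {i} | removed
    frontier = {i}
    for _ in range(ell):
        nxt: set[int] = set()
        for u in frontier:
            for v in g.adj[u]:
                if v not in seen:
                    nxt.add(v)
        seen |= nxt
        frontier = nxt
        if not frontier:
            break
    return frontier


def complete_order(g: Graph, order: Sequence[int]) -> list[int]:
    """Append every node absent from ``order`` in descending residual-degree
    order (ties by ascending id), so the order covers all of ``g``.

    Residual degree is the degree in the graph after the scheduled removals.
    """
    removed = set(order)
    rest = [u for u in range(g.n) if u not in removed]
    resdeg = {u: sum(1 for v in g.adj[u] if v not in removed) for u in rest}
    rest.sort(key=lambda u: (-resdeg[u], u))
    return list(order) + rest
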