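"""Community detection adapters, coarse-graining, and partition diagnostics.

A :class:`Partition` is a fixed node -> community labeling obtained once on
the intact graph and frozen thereafter. Coarse-graining collapses each
community into a supernode; the weight of a coarse link (I, J) counts the
surviving original-network edges between communities I and J. Diagnostics
(entropy, modularity, clustering coefficients) are those used to explain when
mesoscopic immunization pays off: egalitarian community sizes (high partition
entropy) are the empirically useful predictor.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .netcore import Graph

__all__ = [
    "Partition",
    "CoarseGraph",
    "DETECTION_METHODS",
    "detect_communities",
    "load_partition",
    "singleton_partition",
    "coarse_grain",
    "partition_entropy",
    "clustering_coefficients",
    "weighted_clustering",
    "modularity",
]


@dataclass(frozen=True)
class Partition:
    """Node -> community labeling with contiguous community ids 0..N_C-1."""

    labels: tuple[int, ...]

    def __post_init__(self):
        n_c = self.n_communities
        if n_c == 0:
            raise ValueError("empty partition")
        if set(self.labels) != set(range(n_c)):
            raise ValueError("community ids must be contiguous 0..N_C-1")

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "Partition":
        """Normalize arbitrary community ids to 0..N_C-1 (ascending id order)."""
        uniq = sorted(set(labels))
        remap = {c: i for i, c in enumerate(uniq)}
        return cls(tuple(remap[c] for c in labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_communities(self) -> int:
        return max(self.labels) + 1 if self.labels else 0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(np.asarray(self.labels), minlength=self.n_communities)

    def members(self, c: int) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab == c]


class CoarseGraph:
    """Weighted community supernetwork.

    ``a[I, J]`` is the number of original-network links between communities I
    and J (diagonal forced to zero). ``strengths`` is the row sum s_I and
    ``kappa`` the number of neighboring communities of I. Communities emptied
    by node removal keep their ids as all-zero rows.
    """

    __slots__ = ("a", "_s", "_kappa")

    def __init__(self, a: np.ndarray):
        a = np.asarray(a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("coarse matrix must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("coarse matrix must be symmetric")
        if (a < 0).any():
            raise ValueError("coarse weights must be nonnegative")
        a = a.copy()
        np.fill_diagonal(a, 0)
        self.a = a
        self._s = None
        self._kappa = None

    @property
    def n_communities(self) -> int:
        return self.a.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        if self._s is None:
            self._s = self.a.sum(axis=1)
        return self._s

    @property
    def kappa(self) -> np.ndarray:
        if self._kappa is None:
            self._kappa = (self.a > 0).sum(axis=1)
        return self._kappa

    def neighbors(self, I: int) -> np.ndarray:
        return np.flatnonzero(self.a[I])

    def adjacency_lists(self) -> list[list[int]]:
        return [list(np.flatnonzero(row)) for row in self.a]

    def unweighted_graph(self) -> Graph:
        """The coarse topology as an unweighted :class:`Graph`."""
        pairs = [
            (int(i), int(j))
            for i, j in zip(*np.nonzero(np.triu(self.a)))
        ]
        adj: list[set[int]] = [set() for _ in range(self.n_communities)]
        for i, j in pairs:
            adj[i].add(j)
            adj[j].add(i)
        return Graph(adj)

    def write_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, j in zip(*np.nonzero(np.triu(self.a))):
                fh.write(f"{i}\t{j}\t{int(self.a[i, j])}\n")


# -- community detection ---------------------------------------------------

DETECTION_METHODS = (
    "infomap",
    "walktrap",
    "label_propagation",
    "fast_greedy",
    "louvain",
    "simulated_annealing",
    "external",
)


def _to_igraph(g: Graph):
    import igraph

    return igraph.Graph(n=g.n, edges=list(g.edges()), directed=False)


def detect_communities(
    g: Graph,
    method: str,
    seed: int = 0,
    partition_path: str | Path | None = None,
) -> Partition:
    """Run a third-party community detection algorithm (adapter).

    ``method`` is one of :data:`DETECTION_METHODS`. Stochastic methods
    (Infomap, label propagation, Louvain) are made reproducible by seeding the
    backend RNG. ``external`` loads a node->community TSV instead of running
    any algorithm, which keeps every downstream consumer testable without a
    detection backend.
    """
    if method == "external":
        if partition_path is None:
            raise ValueError("external detection requires partition_path")
        return load_partition(partition_path, g)
    if method == "simulated_annealing":
        raise NotImplementedError(
            "simulated-annealing modularity maximization is not provided "
            "(impractically slow beyond ~1e4 nodes); use louvain or fast_greedy"
        )
    if method not in DETECTION_METHODS:
        raise ValueError(f"unknown detection method {method!r}")
    ig = _to_igraph(g)
    _pyrandom.seed(seed)  # python-igraph draws from the stdlib RNG
    if method == "infomap":
        clustering = ig.community_infomap()
    elif method == "walktrap":
        clustering = ig.community_walktrap().as_clustering()
    elif method == "label_propagation":
        clustering = ig.community_label_propagation()
    elif method == "fast_greedy":
        clustering = ig.community_fastgreedy().as_clustering()
    else:  # louvain
        clustering = ig.community_multilevel()
    return Partition.from_labels(clustering.membership)


def load_partition(path: str | Path, g: Graph) -> Partition:
    """Read a TSV ``node_id<TAB>community_id`` file (external labels)."""
    index = {lab: i for i, lab in enumerate(g.labels)}
    raw: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected node_id and community_id")
            node, comm = int(parts[0]), int(parts[1])
            if node not in index:
                raise ValueError(f"{path}:{lineno}: node {node} not in graph")
            raw[index[node]] = comm
    missing = set(range(g.n)) - set(raw)
    if missing:
        raise ValueError(f"{path}: no community label for {len(missing)} node(s)")
    return Partition.from_labels([raw[i] for i in range(g.n)])


def write_partition(p: Partition, g: Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, lab in enumerate(p.labels):
            fh.write(f"{g.labels[i]}\t{lab}\n")


def singleton_partition(g: Graph) -> Partition:
    """Every node its own community (coarse graph == original adjacency)."""
    return Partition(tuple(range(g.n)))


# -- coarse graining -------------------------------------------------------


def coarse_grain(g: Graph, p: Partition, removed: Iterable[int] = ()) -> CoarseGraph:
    """Count surviving inter-community links into the weighted supernetwork.

    Intra-community edges are ignored (the diagonal is zero); communities with
    all members removed remain as zero rows so community ids stay stable along
    a removal schedule.
    """
    if p.n != g.n:
        raise ValueError("partition does not cover the graph")
    removed = set(removed)
    n_c = p.n_communities
    a = np.zeros((n_c, n_c), dtype=np.int64)
    lab = p.labels
    for u, v in g.edges():
        if u in removed or v in removed:
            continue
        cu, cv = lab[u], lab[v]
        if cu != cv:
            a[cu, cv] += 1
            a[cv, cu] += 1
    return CoarseGraph(a)


# -- diagnostics -----------------------------------------------------------


def partition_entropy(p: Partition) -> tuple[float, float]:
    """Shannon entropy of community-size proportions (natural log).

    Returns ``(H, H / ln N_C)``; the normalized value is defined as 1.0 for a
    single community. H lies in [0, ln N_C], reaching the maximum exactly at
    the equipartition; high entropy means egalitarian community sizes.
    """
    frac = p.sizes / p.n
    h = float(-(frac * np.log(frac)).sum())
    n_c = p.n_communities
    h_norm = 1.0 if n_c == 1 else h / np.log(n_c)
    return h, float(h_norm)


def clustering_coefficients(g: Graph) -> float:
    """Mean local clustering coefficient (nodes with degree < 2 contribute 0)."""
    import networkx as nx

    if g.n == 0:
        return 0.0
    return float(nx.average_clustering(g.to_networkx()))


def weighted_clustering(cg: CoarseGraph) -> float:
    """Mean strength-normalized weighted clustering of the coarse graph.

    Per supernode I with kappa_I >= 2:

        C_I^w = 1/(s_I (kappa_I - 1)) * sum over ordered pairs (J, K) of
                (a_IJ + a_IK)/2  for J, K adjacent to I with a_JK > 0,

    which reduces to the unweighted coefficient when all weights are 1.
    Supernodes with kappa_I < 2 contribute 0 to the mean.
    """
    a = cg.a
    n_c = cg.n_communities
    if n_c == 0:
        return 0.0
    s = cg.strengths
    kappa = cg.kappa
    total = 0.0
    for i in range(n_c):
        if kappa[i] < 2:
            continue
        nbrs = np.flatnonzero(a[i])
        acc = 0.0
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                j, k = nbrs[x], nbrs[y]
                if a[j, k] > 0:
                    acc += a[i, j] + a[i, k]  # both (J,K) and (K,J) orderings
        total += acc / (s[i] * (kappa[i] - 1))
    return float(total / n_c)


def modularity(g: Graph, p: Partition) -> float:
    """Newman-Girvan modularity Q = sum_c [m_c/M - (K_c/2M)^2]."""
    import networkx as nx

    comms = [set(p.members(c)) for c in range(p.n_communities)]
    return float(nx.community.modularity(g.to_networkx(), comms))
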