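"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written from the definitions, with no imports from
netfrag's scoring/scheduling internals, and at O(N^2)-O(N^3) cost: distances
by repeated BFS, betweenness by pairwise shortest-path counting, curves by
recomputing components from scratch after every removal.
"""

from collections import deque


def bfs_distances(adj, source, removed):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in removed and v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def naive_ci(adj, removed, i, ell):
    """(k_i - 1) * sum over exact-distance-ell nodes of (k_j - 1)."""
    removed = set(removed)
    deg = lambda u: sum(1 for v in adj[u] if v not in removed)
    if ell == 0:
        return float(deg(i) - 1)
    dist = bfs_distances(adj, i, removed)
    return float((deg(i) - 1) * sum(deg(j) - 1 for j, d in dist.items() if d == ell))


def naive_lcc(adj, n, removed):
    removed = set(removed)
    seen = set(removed)
    best = 0
    for s in range(n):
        if s in seen:
            continue
        comp = 0
        queue = deque([s])
        seen.add(s)
        while queue:
            u = queue.popleft()
            comp += 1
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        best = max(best, comp)
    return best


def naive_curve(adj, n, order):
    """G_n for n = 0..N by full recomputation after every removal."""
    removed = set()
    out = [naive_lcc(adj, n, removed) / n]
    for u in order:
        removed.add(u)
        out.append(naive_lcc(adj, n, removed) / n)
    return out


def naive_betweenness(adj, alive):
    """Betweenness by explicit pairwise shortest-path counting.

    sigma[s][v] counts shortest s-v paths; node v lies on
    sigma_sv * sigma_vt of the sigma_st shortest s-t paths exactly when
    d(s,v) + d(v,t) = d(s,t). Unnormalized, endpoints excluded.
    """
    alive = set(alive)
    nodes = sorted(alive)
    dist, sigma = {}, {}
    for s in nodes:
        d = {s: 0}
        sig = {s: 1.0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in alive:
                    continue
                if v not in d:
                    d[v] = d[u] + 1
                    sig[v] = 0.0
                    queue.append(v)
                if d[v] == d[u] + 1:
                    sig[v] += sig[u]
        dist[s], sigma[s] = d, sig
    btw = {v: 0.0 for v in nodes}
    for si, s in enumerate(nodes):
        for t in nodes[si + 1:]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == d_st:
                    btw[v] += sigma[s][v] * sigma[t][v] / sigma[s][t]
    return btw
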