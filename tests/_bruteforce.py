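"""Independent brute-force graph-metric oracle for small graphs.

Pure-Python, first-principles implementations (BFS distance tables and
explicit enumeration of all simple paths) used to validate the package's
networkx-backed metrics.  Intentionally naive: only usable for graphs with
a handful of nodes.
"""

from collections import deque


def adjacency(edges, nodes):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bfs_distances(adj, src):
    dist = {src: 0}
    queue = deque([src])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def components(adj):
    seen, comps = set(), []
    for n in adj:
        if n in seen:
            continue
        comp = set(bfs_distances(adj, n))
        seen |= comp
        comps.append(comp)
    return comps


def all_simple_paths(adj, s, t, max_len=None):
    """Every simple path s → t as a list of nodes (DFS enumeration)."""
    paths, stack = [], [(s, [s])]
    while stack:
        u, path = stack.pop()
        if u == t:
            paths.append(path)
            continue
        if max_len is not None and len(path) > max_len:
            continue
        for w in adj[u]:
            if w not in path:
                stack.append((w, path + [w]))
    return paths


def shortest_paths(adj, s, t):
    """All geodesics between s and t (empty if unreachable)."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = all_simple_paths(adj, s, t, max_len=dist[t] + 1)
    return [p for p in paths if len(p) - 1 == dist[t]]


def degree(adj, v):
    return len(adj[v])


def clustering(adj, v):
    nbrs = list(adj[v])
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(
        1 for i in range(k) for j in range(i + 1, k) if nbrs[j] in adj[nbrs[i]]
    )
    return 2.0 * links / (k * (k - 1))


def closeness(adj, v):
    dist = bfs_distances(adj, v)
    reachable = [d for n, d in dist.items() if n != v]
    if not reachable:
        return 0.0
    return len(reachable) / sum(reachable)


def betweenness(adj):
    """Betweenness normalised within each connected component."""
    out = {n: 0.0 for n in adj}
    for comp in components(adj):
        nodes = sorted(comp, key=str)
        m = len(nodes)
        raw = {n: 0.0 for n in nodes}
        for i in range(m):
            for j in range(i + 1, m):
                geos = shortest_paths(adj, nodes[i], nodes[j])
                if not geos:
                    continue
                for v in nodes:
                    if v in (nodes[i], nodes[j]):
                        continue
                    passing = sum(1 for p in geos if v in p[1:-1])
                    raw[v] += passing / len(geos)
        norm = (m - 1) * (m - 2) / 2.0 if m > 2 else 1.0
        for v in nodes:
            out[v] = raw[v] / norm
    return out


def global_attributes(adj):
    """Density, centralization, heterogeneity, clustering, path metrics."""
    n = len(adj)
    degrees = [degree(adj, v) for v in adj]
    e = sum(degrees) // 2
    density = 2.0 * e / (n * (n - 1)) if n > 1 else float("nan")
    avg_neighbors = 2.0 * e / n
    k_mean = sum(degrees) / n
    var = sum((k - k_mean) ** 2 for k in degrees) / n
    heterogeneity = var**0.5 / k_mean if k_mean else float("nan")
    k_max = max(degrees)
    centralization = (
        (n / (n - 2.0)) * (k_max / (n - 1.0) - density) if n > 2 else float("nan")
    )
    clustering_mean = sum(clustering(adj, v) for v in adj) / n
    total, pairs = 0, 0
    for src in adj:
        for dst, d in bfs_distances(adj, src).items():
            if dst != src:
                total += d
                pairs += 1
    cpl = total / pairs if pairs else float("nan")
    return {
        "density": density,
        "avg_neighbors": avg_neighbors,
        "heterogeneity": heterogeneity,
        "network_centralization": centralization,
        "clustering_coefficient": clustering_mean,
        "characteristic_path_length": cpl,
        "shortest_paths_count": pairs,
        "shortest_paths_pct": 100.0 * pairs / (n * (n - 1)) if n > 1 else float("nan"),
    }
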