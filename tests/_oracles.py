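"""Independent brute-force oracles shared by the test modules.

These deliberately use naive loops/enumeration, not the package's own code
paths, so they can serve as ground truth for the optimised implementations.
"""

import itertools
import math

import numpy as np


def oracle_pseudo_f(d, labels):
    """One-way pseudo-F computed directly from pairwise-distance loops."""
    n = len(labels)
    groups = sorted(set(labels))
    a = len(groups)
    ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_w += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (n - a))


def oracle_exhaustive_p(d, n1):
    """Exact one-way two-group permutation p over every label split."""
    n = d.shape[0]
    obs = oracle_pseudo_f(d, [0] * n1 + [1] * (n - n1))
    ge = total = 0
    for combo in itertools.combinations(range(n), n1):
        labels = [0 if i in combo else 1 for i in range(n)]
        total += 1
        if oracle_pseudo_f(d, labels) >= obs - 1e-12:
            ge += 1
    return ge / total


def brute_clustering(g):
    """Mean local clustering; nodes with degree < 2 contribute 0."""
    vals = []
    for node in g.nodes:
        nbrs = list(g.neighbors(node))
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
        vals.append(2 * links / (k * (k - 1)))
    return float(np.mean(vals))


def brute_path_length(g):
    """Mean shortest-path length over connected ordered pairs, by plain BFS."""
    total, pairs = 0.0, 0
    for src in g.nodes:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for v, d in dist.items():
            if v != src:
                total += d
                pairs += 1
    return total / pairs if pairs else 0.0


def brute_modularity(g):
    """Exhaustive max Newman Q over all node partitions (tiny graphs only)."""
    nodes = list(g.nodes)
    n = len(nodes)
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    deg = dict(g.degree())
    best = -math.inf

    def assignments(i, k, labels):
        nonlocal best
        if i == n:
            comms = {}
            for node, lab in zip(nodes, labels):
                comms.setdefault(lab, []).append(node)
            q = 0.0
            for comm in comms.values():
                lc = sum(
                    1 for a, b in itertools.combinations(comm, 2) if g.has_edge(a, b)
                )
                dc = sum(deg[v] for v in comm)
                q += lc / m - (dc / (2 * m)) ** 2
            best = max(best, q)
            return
        for lab in range(k + 1):
            labels.append(lab)
            assignments(i + 1, max(k, lab + 1), labels)
            labels.pop()

    assignments(0, 0, [])
    return best
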