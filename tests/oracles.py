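"""Independent brute-force oracles used only by the test suite."""

import itertools

import networkx as nx
import numpy as np


def brute_modularity(w, assignment):
    """Double-loop evaluation of Q, independent of the package's vectorized path."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    k = w.sum(axis=1)
    two_m = k.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if assignment[i] == assignment[j]:
                q += w[i, j] - k[i] * k[j] / two_m
    return q / two_m


def set_partitions(items):
    """All set partitions of a sequence (Bell-number many; keep n small)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1 :]
        yield [[first]] + smaller


def exhaustive_best_q(w):
    """Maximum modularity over every partition (feasible for n <= 8)."""
    n = w.shape[0]
    best = -np.inf
    for parts in set_partitions(range(n)):
        a = np.empty(n, dtype=int)
        for m, block in enumerate(parts, start=1):
            a[block] = m
        best = max(best, brute_modularity(w, a))
    return best


def _nx_graph(w):
    g = nx.Graph()
    n = w.shape[0]
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if w[i, j] > 0:
            g.add_edge(i, j, length=1.0 / w[i, j])
    return g


def nx_global_efficiency(w):
    """Mean inverse shortest-path distance via networkx Dijkstra."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    g = _nx_graph(w)
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and j in dist.get(i, {}):
                acc += 1.0 / dist[i][j]
    return acc / (n * (n - 1))


def brute_local_efficiency(w):
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    acc = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) < 2:
            continue
        acc += nx_global_efficiency(w[np.ix_(nbrs, nbrs)])
    return acc / n


def nx_cpl(w):
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    g = _nx_graph(w)
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    vals = [
        dist[i][j]
        for i in range(n)
        for j in range(n)
        if i != j and j in dist.get(i, {})
    ]
    return float(np.mean(vals))
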