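"""Independent brute-force oracles used by the tests.

These deliberately re-derive results by the most transparent method
available (full quadratic DP, exhaustive enumeration) and share no code
with the package implementations they check.
"""

from __future__ import annotations

import numpy as np


def sw_affine_local(query: str, target: str, score: dict, gap_open: float,
                    gap_extend: float) -> float:
    """Smith-Waterman with affine gaps (gap of length L costs
    gap_open + (L-1) * gap_extend), three-matrix formulation."""
    n, m = len(query), len(target)
    NEG = -1e18
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)  # gap in target (up)
    Y = np.full((n + 1, m + 1), NEG)  # gap in query (left)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score[(query[i - 1], target[j - 1])]
            M[i, j] = max(0.0, max(M[i - 1, j - 1], X[i - 1, j - 1],
                                   Y[i - 1, j - 1]) + s)
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
            best = max(best, M[i, j])
    return best


def nw_global(a: str, b: str, match: float, mismatch: float,
              gap: float) -> float:
    """Needleman-Wunsch, linear gap penalty."""
    n, m = len(a), len(b)
    D = np.zeros((n + 1, m + 1))
    D[:, 0] = np.arange(n + 1) * gap
    D[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            D[i, j] = max(D[i - 1, j - 1] + s, D[i - 1, j] + gap,
                          D[i, j - 1] + gap)
    return D[n, m]


def longest_flank_duplication(seq: str, start: int, end: int,
                              k_min: int, k_max: int) -> int:
    """Exhaustive search for the longest duplicated flanking k-mer."""
    best = 0
    for k in range(k_min, k_max + 1):
        if start - k < 0 or end + k > len(seq):
            continue
        if seq[start - k:start] == seq[end:end + k]:
            best = k
    return best


def entropy_bits(freqs) -> float:
    h = 0.0
    for f in freqs:
        if f > 0:
            h -= f * np.log2(f)
    return h


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random unrooted binary tree with positive branch lengths and its
    exact path-length (additive) distance matrix.

    Built by sequential leaf attachment; distances computed on the graph.
    """
    # adjacency: node -> {node: length}
    adj: dict[int, dict[int, float]] = {}

    def add(u, v, ln):
        adj.setdefault(u, {})[v] = ln
        adj.setdefault(v, {})[u] = ln

    next_internal = n_taxa
    add(0, 1, float(rng.uniform(0.1, 1.0)))
    edges = [(0, 1)]
    for leaf in range(2, n_taxa):
        u, v = edges[int(rng.integers(0, len(edges)))]
        w = next_internal
        next_internal += 1
        ln_uv = adj[u].pop(v)
        adj[v].pop(u)
        edges.remove((u, v))
        lam = float(rng.uniform(0.2, 0.8))
        add(u, w, ln_uv * lam)
        add(w, v, ln_uv * (1 - lam))
        add(w, leaf, float(rng.uniform(0.1, 1.0)))
        edges += [(u, w), (w, v), (w, leaf)]
    d = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, ln in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + ln
                    stack.append(y)
        for dst in range(n_taxa):
            d[src, dst] = dist[dst]
    return d


def exhaustive_me_total(d: np.ndarray) -> float:
    """Minimum-evolution criterion (sum of raw OLS branch estimates)
    minimized over all unrooted topologies (feasible for <= 6 taxa).
    Topologies enumerated by leaf insertion."""
    n = d.shape[0]
    assert n <= 6

    def all_topologies(k):
        # each topology: list of edges; leaves 0..n-1, internal ids >= n
        if k == 3:
            yield [(0, n), (1, n), (2, n)], n + 1
            return
        for edges, nxt in all_topologies(k - 1):
            for i, (u, v) in enumerate(edges):
                w = nxt
                new = edges[:i] + edges[i + 1:] + [(u, w), (w, v), (w, k - 1)]
                yield new, nxt + 1

    import itertools as it
    best = np.inf
    pairs = list(it.combinations(range(n), 2))
    for edges, nnodes in all_topologies(n):
        sides = []
        adj = {}
        for u, v in edges:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        for u, v in edges:
            seen = {u, v}
            stack = [v]
            side = set()
            while stack:
                x = stack.pop()
                if x < n:
                    side.add(x)
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            sides.append(side)
        A = np.zeros((len(pairs), len(edges)))
        for e, side in enumerate(sides):
            for pi, (i, j) in enumerate(pairs):
                if (i in side) != (j in side):
                    A[pi, e] = 1.0
        y = np.array([d[i, j] for i, j in pairs])
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        best = min(best, float(x.sum()))
    return best
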