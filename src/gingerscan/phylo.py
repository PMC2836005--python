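"""Distance-based phylogenetics: a simple progressive protein aligner,
Poisson/gamma-corrected distances, neighbor-joining and minimum-evolution
trees, nonparametric bootstrap supports, and Newick output.

Distances: with p the proportion of differing sites over compared columns
(pairwise deletion drops columns gapped in either member of the pair,
complete deletion drops columns gapped anywhere), the Poisson correction
is d = -ln(1 - p) and the gamma correction with shape a is
d = a((1 - p)^(-1/a) - 1).  NJ follows the Saitou-Nei Q-criterion with
deterministic tie-breaking; ME refits ordinary-least-squares branch
lengths per topology and hill-climbs over nearest-neighbor interchanges,
accepting moves that reduce the total branch length.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

GAP = "-"

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"


class UndefinedDistanceError(ValueError):
    """p = 1 makes the Poisson/gamma corrections undefined."""


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray
    model: str = "p"
    gamma_a: float = 2.0
    deletion: str = "pairwise"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")

    def __len__(self) -> int:
        return len(self.taxa)


def correct_distance(p: float, model: str, gamma_a: float = 2.0) -> float:
    """Apply the chosen substitution-saturation correction to a p-distance."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-distance {p} outside [0, 1]")
    if model == "p":
        return p
    if p >= 1.0:
        raise UndefinedDistanceError(
            "p = 1: Poisson/gamma distance undefined for fully diverged pair")
    if model == "poisson":
        return -math.log(1.0 - p)
    if model == "gamma":
        return gamma_a * ((1.0 - p) ** (-1.0 / gamma_a) - 1.0)
    raise ValueError(f"unknown model {model!r}")


def distance(msa: Sequence[tuple[str, str]], model: str = "poisson",
             deletion: str = "pairwise", gamma_a: float = 2.0) -> DistanceMatrix:
    """Corrected pairwise distances from a (taxon, aligned sequence) MSA."""
    if len(msa) < 2:
        raise ValueError("need at least two aligned sequences")
    taxa = [t for t, _ in msa]
    rows = [s.upper() for _, s in msa]
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("aligned sequences must have equal length")
    if deletion == "complete":
        keep = [j for j in range(L) if all(r[j] != GAP for r in rows)]
        rows = ["".join(r[j] for j in keep) for r in rows]
        L = len(keep)
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            compared = mism = 0
            for a, b in zip(rows[i], rows[j]):
                if a == GAP or b == GAP:
                    continue
                compared += 1
                if a != b:
                    mism += 1
            if compared == 0:
                raise UndefinedDistanceError(
                    f"no comparable columns between {taxa[i]} and {taxa[j]}")
            d[i, j] = d[j, i] = correct_distance(mism / compared, model, gamma_a)
    return DistanceMatrix(taxa=taxa, d=d, model=model,
                          gamma_a=gamma_a, deletion=deletion)


# ---------------------------------------------------------------------------
# Unrooted trees
# ---------------------------------------------------------------------------

class Tree:
    """Unrooted tree: adjacency map with branch lengths; leaves labelled.

    Bootstrap supports are stored per leaf bipartition (the side of the
    split not containing the reference leaf, as a frozenset of names).
    """

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.labels: dict[int, str] = {}
        self.supports: dict[frozenset, float] = {}

    # -- construction -----------------------------------------------------
    def add_edge(self, u: int, v: int, length: float) -> None:
        self.adj.setdefault(u, {})[v] = length
        self.adj.setdefault(v, {})[u] = length

    def copy(self) -> "Tree":
        t = Tree()
        t.adj = {u: dict(nb) for u, nb in self.adj.items()}
        t.labels = dict(self.labels)
        t.supports = dict(self.supports)
        return t

    # -- queries ----------------------------------------------------------
    def leaves(self) -> list[int]:
        return sorted(n for n, nb in self.adj.items() if len(nb) == 1)

    def leaf_names(self) -> list[str]:
        return sorted(self.labels[n] for n in self.leaves())

    def edges(self) -> list[tuple[int, int]]:
        return sorted((u, v) for u in self.adj for v in self.adj[u] if u < v)

    def total_length(self) -> float:
        return sum(self.adj[u][v] for u, v in self.edges())

    def _side_leaves(self, u: int, v: int) -> set[str]:
        """Leaf names on v's side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        names: set[str] = set()
        while stack:
            x = stack.pop()
            if x in self.labels:
                names.add(self.labels[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return names

    def bipartition(self, u: int, v: int) -> frozenset:
        """Canonical bipartition of edge (u, v): the side not containing
        the lexicographically smallest leaf name."""
        all_names = set(self.leaf_names())
        ref = min(all_names)
        side = self._side_leaves(u, v)
        if ref in side:
            side = all_names - side
        return frozenset(side)

    def internal_bipartitions(self) -> dict[tuple[int, int], frozenset]:
        out = {}
        for u, v in self.edges():
            if len(self.adj[u]) > 1 and len(self.adj[v]) > 1:
                out[(u, v)] = self.bipartition(u, v)
        return out

    def path_length(self, name_a: str, name_b: str) -> float:
        id_of = {lbl: n for n, lbl in self.labels.items()}
        src, dst = id_of[name_a], id_of[name_b]
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            if x == dst:
                return dist[x]
            for y, ln in self.adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + ln
                    stack.append(y)
        raise KeyError(f"no path {name_a} -> {name_b}")

    # -- newick -----------------------------------------------------------
    def newick(self, supports: bool = True) -> str:
        leaves = self.leaves()
        if len(leaves) == 1:
            only = leaves[0]
            return f"{self.labels[only]};"
        ref = min(leaves, key=lambda n: self.labels[n])
        root = next(iter(self.adj[ref]))

        def rec(node: int, parent: int) -> str:
            if node in self.labels and len(self.adj[node]) == 1:
                return self.labels[node]
            kids = [c for c in sorted(self.adj[node]) if c != parent]
            inner = ",".join(
                f"{rec(c, node)}:{self.adj[node][c]:.10g}" for c in kids)
            label = ""
            if supports and parent is not None and parent != -1:
                bip = self.bipartition(parent, node)
                if bip in self.supports:
                    label = str(int(round(self.supports[bip])))
            return f"({inner}){label}"

        return rec(root, -1) + ";"


def write_newick(tree: Tree, path: str | Path | None = None,
                 supports: bool = True) -> str:
    s = tree.newick(supports=supports) + "\n"
    if path is not None:
        Path(path).write_text(s)
    return s.strip()


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _nj_joins(d: np.ndarray) -> tuple[list[tuple[int, int, int, float, float]],
                                      tuple[int, int, int, float, float, float]]:
    """Run NJ agglomeration; returns the join sequence
    [(i, j, new, len_i, len_j), ...] over node ids (leaves are 0..n-1) and
    the final three-node resolution (a, b, c, la, lb, lc)."""
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = {i: {j: float(d[i, j]) for j in range(n) if j != i} for i in range(n)}
    active = list(range(n))
    next_id = n
    joins = []
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i][j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i][j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i][j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i][j] - li
        if li < 0:
            logger.debug("NJ: clamping negative branch %.3g to 0", li)
            li = 0.0
        if lj < 0:
            logger.debug("NJ: clamping negative branch %.3g to 0", lj)
            lj = 0.0
        u = next_id
        next_id += 1
        D[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i][k] + D[j][k] - D[i][j])
            D[u][k] = D[k][u] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]
        joins.append((i, j, u, li, lj))
    a, b, c = sorted(active)
    la = 0.5 * (D[a][b] + D[a][c] - D[b][c])
    lb = 0.5 * (D[a][b] + D[b][c] - D[a][c])
    lc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return joins, (a, b, c, la, lb, lc)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; Q-criterion ties broken by the smallest
    node-index pair; negative branch length estimates clamped to 0."""
    joins, final = _nj_joins(dm.d)
    t = Tree()
    for i, name in enumerate(dm.taxa):
        t.labels[i] = name
    for i, j, u, li, lj in joins:
        t.add_edge(i, u, li)
        t.add_edge(j, u, lj)
    a, b, c, la, lb, lc = final
    center = max(max(t.adj) + 1 if t.adj else len(dm.taxa), len(dm.taxa))
    t.add_edge(a, center, la)
    t.add_edge(b, center, lb)
    t.add_edge(c, center, lc)
    return t


# ---------------------------------------------------------------------------
# Minimum evolution (OLS + NNI)
# ---------------------------------------------------------------------------

def ols_branch_lengths(tree: Tree, dm: DistanceMatrix) -> float:
    """Fit ordinary-least-squares branch lengths for the tree's topology in
    place (unweighted normal equations, solved by least squares).

    Returns the minimum-evolution criterion: the sum of the raw OLS
    estimates.  Negative estimates are clamped to 0 only in the lengths
    stored on the tree (reported trees have non-negative branches), not in
    the criterion — clamping inside the criterion would reward topologies
    that produce negative estimates."""
    taxa = dm.taxa
    idx = {name: i for i, name in enumerate(taxa)}
    edges = tree.edges()
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    A = np.zeros((len(pairs), len(edges)))
    for e, (u, v) in enumerate(edges):
        side = {idx[nm] for nm in tree._side_leaves(u, v)}
        for pi, (i, j) in enumerate(pairs):
            if (i in side) != (j in side):
                A[pi, e] = 1.0
    y = np.array([dm.d[i, j] for i, j in pairs])
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    criterion = float(x.sum())
    for (u, v), ln in zip(edges, np.clip(x, 0.0, None)):
        tree.adj[u][v] = tree.adj[v][u] = float(ln)
    return criterion


def _nni_neighbors(tree: Tree, u: int, v: int) -> list[Tree]:
    """The two nearest-neighbor interchanges across internal edge (u, v)."""
    others_u = sorted(x for x in tree.adj[u] if x != v)
    others_v = sorted(x for x in tree.adj[v] if x != u)
    if len(others_u) < 2 or len(others_v) < 2:
        return []
    b = others_u[1]
    out = []
    for c in others_v[:2]:
        t = tree.copy()
        lb = t.adj[u].pop(b); t.adj[b].pop(u)
        lc = t.adj[v].pop(c); t.adj[c].pop(v)
        t.add_edge(u, c, lc)
        t.add_edge(v, b, lb)
        out.append(t)
    return out


def me_tree(dm: DistanceMatrix, start: Optional[Tree] = None,
            max_rounds: int = 50) -> Tree:
    """Minimum-evolution tree: OLS branch lengths per topology with a
    nearest-neighbor-interchange hill climb accepting moves that strictly
    reduce the total branch length; deterministic given the start tree
    (default: the NJ tree)."""
    tree = (start or nj_tree(dm)).copy()
    total = ols_branch_lengths(tree, dm)
    for _ in range(max_rounds):
        best_tree, best_total = None, total
        for u, v in tree.edges():
            if len(tree.adj[u]) == 1 or len(tree.adj[v]) == 1:
                continue
            for cand in _nni_neighbors(tree, u, v):
                t = ols_branch_lengths(cand, dm)
                if t < best_total - 1e-12:
                    best_tree, best_total = cand, t
        if best_tree is None:
            break
        tree, total = best_tree, best_total
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap(msa: Sequence[tuple[str, str]], n_reps: int,
              builder: Callable[[Sequence[tuple[str, str]]], Tree],
              seed: int = 0) -> Tree:
    """Column bootstrap: resample alignment columns with replacement,
    rebuild with ``builder`` per replicate, and map bipartition supports
    (percent of replicates containing the same leaf split) onto the
    full-data tree.  Deterministic given ``seed``."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = builder(msa)
    L = len(msa[0][1])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    ok = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = [(t, "".join(s[c] for c in cols)) for t, s in msa]
        try:
            t = builder(rep)
        except UndefinedDistanceError:
            logger.debug("bootstrap replicate skipped (undefined distance)")
            continue
        ok += 1
        for bip in t.internal_bipartitions().values():
            counts[bip] = counts.get(bip, 0) + 1
    denom = max(ok, 1)
    full.supports = {
        bip: 100.0 * counts.get(bip, 0) / denom
        for bip in full.internal_bipartitions().values()
    }
    return full


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

def _score_matrix(alphabet: str, gap_score: float) -> np.ndarray:
    k = len(alphabet)
    S = np.zeros((k + 1, k + 1))
    if alphabet == PROTEIN_ALPHABET:
        blosum = substitution_matrices.load("BLOSUM62")
        for i, a in enumerate(alphabet):
            for j, b in enumerate(alphabet):
                S[i, j] = blosum[a, b]
    else:
        for i in range(k):
            for j in range(k):
                S[i, j] = 1.0 if i == j else -1.0
    S[k, :k] = S[:k, k] = gap_score
    S[k, k] = 0.0
    return S


class _Profile:
    def __init__(self, members: list[int], rows: list[str], alphabet: str):
        self.members = members
        self.rows = rows
        k = len(alphabet)
        idx = {c: i for i, c in enumerate(alphabet)}
        idx[GAP] = k
        L = len(rows[0])
        F = np.zeros((L, k + 1))
        for r in rows:
            for j, c in enumerate(r):
                if c not in idx:
                    raise ValueError(f"character {c!r} not in alphabet")
                F[j, idx[c]] += 1
        self.F = F / len(rows)


def _merge_profiles(p1: _Profile, p2: _Profile, S: np.ndarray,
                    alphabet: str) -> _Profile:
    pair = p1.F @ S @ p2.F.T
    g1 = p1.F @ S[:, -1]
    g2 = p2.F @ S[:, -1]
    n1, n2 = pair.shape
    M = np.zeros((n1 + 1, n2 + 1))
    M[0, 1:] = np.cumsum(g2)
    M[1:, 0] = np.cumsum(g1)
    TB = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    TB[0, 1:] = 2
    TB[1:, 0] = 1
    for i in range(1, n1 + 1):
        prow = pair[i - 1]
        gi = g1[i - 1]
        mi = M[i]
        mim = M[i - 1]
        for j in range(1, n2 + 1):
            diag = mim[j - 1] + prow[j - 1]
            up = mim[j] + gi
            left = mi[j - 1] + g2[j - 1]
            if diag >= up and diag >= left:
                mi[j] = diag
            elif up >= left:
                mi[j] = up
                TB[i, j] = 1
            else:
                mi[j] = left
                TB[i, j] = 2
    # traceback
    i, j = n1, n2
    ops = []
    while i > 0 or j > 0:
        t = TB[i, j]
        ops.append(t)
        if t == 0:
            i, j = i - 1, j - 1
        elif t == 1:
            i -= 1
        else:
            j -= 1
    ops.reverse()
    rows1 = [[] for _ in p1.rows]
    rows2 = [[] for _ in p2.rows]
    i = j = 0
    for t in ops:
        if t in (0, 1):
            for r, src in zip(rows1, p1.rows):
                r.append(src[i])
            i += 1
        else:
            for r in rows1:
                r.append(GAP)
        if t in (0, 2):
            for r, src in zip(rows2, p2.rows):
                r.append(src[j])
            j += 1
        else:
            for r in rows2:
                r.append(GAP)
    return _Profile(p1.members + p2.members,
                    ["".join(r) for r in rows1] + ["".join(r) for r in rows2],
                    alphabet)


def _guide_pdistance(seqs: Sequence[str], alphabet: str,
                     S: np.ndarray) -> np.ndarray:
    """Pairwise p-distances from global pairwise profile alignments."""
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = _Profile([0], [seqs[i]], alphabet)
            pj = _Profile([1], [seqs[j]], alphabet)
            merged = _merge_profiles(pi, pj, S, alphabet)
            a, b = merged.rows
            comp = mism = 0
            for x, y in zip(a, b):
                if x == GAP or y == GAP:
                    continue
                comp += 1
                if x != y:
                    mism += 1
            d[i, j] = d[j, i] = mism / comp if comp else 1.0
    return d


def progressive_align(seqs: Sequence[str], alphabet: str = "protein",
                      gap_score: Optional[float] = None) -> list[str]:
    """Progressive multiple alignment: guide order from p-distance NJ over
    pairwise global alignments, profiles merged by global DP with
    sum-of-pairs scoring.  Deterministic; output rows follow input order."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    ab = PROTEIN_ALPHABET if alphabet == "protein" else DNA_ALPHABET
    gs = gap_score if gap_score is not None else (-4.0 if alphabet == "protein" else -2.0)
    S = _score_matrix(ab, gs)
    profiles = {i: _Profile([i], [seqs[i]], ab) for i in range(len(seqs))}
    if len(seqs) == 2:
        final = _merge_profiles(profiles[0], profiles[1], S, ab)
    else:
        d = _guide_pdistance(seqs, ab, S)
        joins, (a, b, c, *_rest) = _nj_joins(d)
        for i, j, u, _li, _lj in joins:
            profiles[u] = _merge_profiles(profiles[i], profiles[j], S, ab)
            del profiles[i], profiles[j]
        pab = _merge_profiles(profiles[a], profiles[b], S, ab)
        final = _merge_profiles(pab, profiles[c], S, ab)
    order = np.argsort(final.members)
    return [final.rows[k] for k in order]


# ---------------------------------------------------------------------------
# Distance matrix I/O
# ---------------------------------------------------------------------------

def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(dm.taxa) + "\n")
        for name, row in zip(dm.taxa, dm.d):
            fh.write(name + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    """Read a square distance matrix: either our TSV (header row + name
    column) or PHYLIP square format (leading taxon-count line)."""
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    first = lines[0].split()
    if len(first) == 1 and first[0].isdigit():
        n = int(first[0])
        taxa, rows = [], []
        for ln in lines[1:1 + n]:
            parts = ln.split()
            taxa.append(parts[0])
            rows.append([float(x) for x in parts[1:1 + n]])
    else:
        taxa_header = lines[0].split("\t")[1:]
        taxa, rows = [], []
        for ln in lines[1:]:
            parts = ln.split("\t")
            taxa.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        if taxa_header and taxa_header != taxa:
            raise ValueError("row and column taxa disagree")
    return DistanceMatrix(taxa=taxa, d=np.array(rows))
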