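"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (graph
enumeration, factorial matching, hand-rolled formulas) and shares no code
with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


# ---------------------------------------------------------------------------
# unrooted binary tree enumeration (as graphs) + newick conversion
# ---------------------------------------------------------------------------

def enumerate_unrooted_binary(labels: list[str]) -> list[nx.Graph]:
    """All unrooted binary tree topologies on the labels, by edge insertion.

    1 tree on 3 leaves, 3 on 4, 15 on 5, 105 on 6.
    """
    counter = itertools.count()
    g0 = nx.Graph()
    root = f"__i{next(counter)}"
    g0.add_edges_from((root, lab) for lab in labels[:3])
    trees = [g0]
    for leaf in labels[3:]:
        grown = []
        for g in trees:
            for u, v in list(g.edges):
                h = g.copy()
                mid = f"__i{next(counter)}"
                h.remove_edge(u, v)
                h.add_edges_from([(u, mid), (mid, v), (mid, leaf)])
                grown.append(h)
        trees = grown
    return trees


def graph_to_newick(g: nx.Graph, labels: list[str]) -> str:
    """Serialize the tree graph as Newick with unit branch lengths, rooted
    at the internal neighbor of the first label."""
    leaf_set = set(labels)
    start = next(iter(g.neighbors(labels[0])))

    def build(node, parent):
        if node in leaf_set:
            return f"{node}:1"
        parts = [build(nb, node) for nb in g.neighbors(node) if nb != parent]
        return "(" + ",".join(parts) + "):1"

    inner = ",".join(build(nb, start) for nb in g.neighbors(start))
    return f"({inner});"


def graph_splits(g: nx.Graph, labels: list[str]) -> set[frozenset]:
    """Non-trivial splits: drop each edge, collect the leaf side not holding
    the alphabetically first label."""
    leaf_set = set(labels)
    ref = min(labels)
    splits = set()
    for u, v in g.edges:
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(comp & leaf_set)
        if ref in side:
            side = frozenset(leaf_set - side)
        if 2 <= len(side) <= len(labels) - 2:
            splits.add(side)
    return splits


# ---------------------------------------------------------------------------
# information-theoretic split matching from first principles
# ---------------------------------------------------------------------------

def h2(a: int, n: int) -> float:
    out = 0.0
    for k in (a, n - a):
        if 0 < k < n:
            out -= (k / n) * math.log2(k / n)
    return out


def mi_splits(a: frozenset, b: frozenset, tips: frozenset) -> float:
    n = len(tips)
    cells = [
        (len(a & b), len(a), len(b)),
        (len(a - b), len(a), n - len(b)),
        (len(b - a), n - len(a), len(b)),
        (n - len(a | b), n - len(a), n - len(b)),
    ]
    mi = 0.0
    for nij, ni, nj in cells:
        if nij > 0:
            mi += (nij / n) * math.log2(n * nij / (ni * nj))
    return mi


def brute_generalized_rf(
    splits1: set[frozenset], splits2: set[frozenset], tips: frozenset
) -> float:
    """Distance via exhaustive enumeration of all injective split matchings."""
    n = len(tips)
    h_tot = sum(h2(len(s), n) for s in splits1) + sum(h2(len(s), n) for s in splits2)
    if h_tot == 0:
        return 0.0
    small, large = sorted([list(splits1), list(splits2)], key=len)
    best = 0.0
    for perm in itertools.permutations(range(len(large)), len(small)):
        total = sum(mi_splits(small[i], large[j], tips) for i, j in enumerate(perm))
        best = max(best, total)
    return min(max(1.0 - 2.0 * best / h_tot, 0.0), 1.0)


# ---------------------------------------------------------------------------
# other oracles
# ---------------------------------------------------------------------------

def shortest_path_patristic(tree) -> dict[tuple[str, str], float]:
    """Tip-tip distances by Dijkstra on the tree's edge graph."""
    g = nx.Graph()
    for i, node in enumerate(tree.preorder_node_iter()):
        node._oracle_id = i
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            g.add_edge(node._oracle_id, child._oracle_id, weight=child.edge.length or 0.0)
    tips = {leaf.taxon.label: leaf._oracle_id for leaf in tree.leaf_node_iter()}
    out = {}
    for a, b in itertools.combinations(sorted(tips), 2):
        out[(a, b)] = nx.dijkstra_path_length(g, tips[a], tips[b])
    return out


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit hypergeometric point-probability
    enumeration (sum of tables no more probable than the observed one)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def log_pmf(k):
        return (
            math.lgamma(r1 + 1) - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - k + 1) - math.lgamma(r2 - c1 + k + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {k: math.exp(log_pmf(k)) for k in range(lo, hi + 1)}
    obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= obs * (1 + 1e-7)))


def procrustes_residual(X: np.ndarray, Y: np.ndarray) -> float:
    """Residual sum of squares after explicit optimal rotation and scaling of
    centered unit-trace configurations (direct construction, not the
    singular-value shortcut)."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    X = X / np.sqrt((X ** 2).sum())
    Y = Y / np.sqrt((Y ** 2).sum())
    p = max(X.shape[1], Y.shape[1])
    X = np.pad(X, ((0, 0), (0, p - X.shape[1])))
    Y = np.pad(Y, ((0, 0), (0, p - Y.shape[1])))
    U, s, Vt = np.linalg.svd(Y.T @ X)
    Q = U @ Vt                      # rotation applied to Y
    b = s.sum()                     # optimal scale given unit traces
    return float(((X - b * (Y @ Q)) ** 2).sum())
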