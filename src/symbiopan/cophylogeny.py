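"""Cophylogeny statistics: patristic distances, principal coordinates,
the PACo Procrustes permutation test, information-based generalized
Robinson-Foulds distances, and the signal/congruence classification.

The PACo statistic superimposes principal-coordinate embeddings of the host
and symbiont patristic distance matrices over the association links.  Both
link-expanded configurations are column-centered and scaled to unit trace
(symmetric Procrustes), so the residual sum of squares after the optimal
rotation and scaling, m², lies in [0,1] and R² = 1 − m² is well defined.
Significance comes from permuting the association matrix (default scheme
"r0": each host row's links are re-placed uniformly among symbionts,
preserving the row's link count) with the add-one p-value estimator
p = (1 + #{m²_perm ≤ m²_obs}) / (n_permutations + 1).

The generalized RF distance scores every pair of non-trivial splits by their
mutual clustering information (in bits, from the 2×2 co-membership table of
the two bipartitions), finds the maximum-weight bipartite matching between
the two split sets, and normalizes:
distance = 1 − 2·matched_info / (H(tree1) + H(tree2)).
Identical split sets give 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_formats import (
    AssociationMatrix,
    SquareMatrix,
    SymbiopanError,
    ValidationError,
    get_logger,
    tree_tip_labels,
)

log = get_logger(__name__)

__all__ = [
    "PacoResult",
    "GeneralizedRFResult",
    "PhylosymbiosisCall",
    "patristic_distances",
    "PcoaResult",
    "pcoa",
    "paco",
    "generalized_rf",
    "map_symbiont_tips",
    "congruence_rf",
    "classify_phylosymbiosis",
]


# ---------------------------------------------------------------------------
# patristic distances
# ---------------------------------------------------------------------------

def patristic_distances(tree: dendropy.Tree) -> SquareMatrix:
    """Sum of branch lengths along the path between every pair of tips."""
    labels = tree_tip_labels(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            values[i, j] = values[j, i] = d
    if n > 1 and np.allclose(values, 0):
        log.info("patristic_distances: all-zero distances (zero-length tree)")
    return SquareMatrix(labels, values, "distance")


# ---------------------------------------------------------------------------
# principal coordinates (classical MDS) with negative-eigenvalue corrections
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    coords: np.ndarray        # items x retained axes, eigenvalue-descending
    eigenvalues: np.ndarray   # all eigenvalues, descending
    correction: str
    constant: float           # Cailliez/Lingoes constant applied (0 if none)


def _gram(dsq: np.ndarray) -> np.ndarray:
    n = dsq.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * J @ dsq @ J


def _cailliez_constant(D: np.ndarray) -> float:
    """Smallest constant c so that D + c (off-diagonal) is Euclidean."""
    n = D.shape[0]
    d1 = _gram(D ** 2)
    d2 = _gram(D)  # note: -0.5 J D J enters the companion matrix scaled below
    M = np.block([
        [np.zeros((n, n)), 2.0 * d1],
        [-np.eye(n), -4.0 * d2],
    ])
    eig = np.linalg.eigvals(M)
    return float(max(eig.real.max(), 0.0))


def pcoa(d: SquareMatrix, correction: str = "cailliez") -> PcoaResult:
    """Classical MDS of a distance matrix via the double-centered Gram matrix.

    ``cailliez`` adds a constant to the off-diagonal distances, ``lingoes``
    adds one to the squared distances, either making all eigenvalues
    >= -1e-9; ``none`` drops negative axes with a warning.  Axes with
    eigenvalue > 1e-9 are retained, ordered descending; Euclidean distances
    among the rows of ``coords`` reproduce the corrected input distances.
    """
    if d.mode != "distance":
        raise ValidationError("pcoa needs a distance-mode matrix")
    D = d.values.copy()
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    constant = 0.0

    G = _gram(D ** 2)
    eigvals = np.linalg.eigvalsh(G)
    if eigvals.min() < -1e-9:
        if correction == "cailliez":
            constant = _cailliez_constant(D)
            D = D + constant * off
        elif correction == "lingoes":
            constant = float(max(-eigvals.min(), 0.0))
            Dsq = D ** 2 + 2.0 * constant * off
            D = np.sqrt(Dsq)
        elif correction == "none":
            log.warning("pcoa: non-Euclidean distances, negative axes dropped")
        else:
            raise ValueError(f"unknown correction {correction!r}")

    G = _gram(D ** 2)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > 1e-9
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    return PcoaResult(coords, vals, correction, constant)


# ---------------------------------------------------------------------------
# PACo
# ---------------------------------------------------------------------------

@dataclass
class PacoResult:
    m2: float
    r2: float
    p_value: float
    n_permutations: int
    permutation_scheme: str
    seed: int


def _procrustes_m2(
    X: np.ndarray, Y: np.ndarray, on_degenerate: str = "raise"
) -> float:
    """Normalized residual of symmetric Procrustes: both configurations are
    centered and scaled to unit trace, then m² = 1 − (Σ singular values)²."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    nx = np.sqrt((X ** 2).sum())
    ny = np.sqrt((Y ** 2).sum())
    if nx < 1e-12 or ny < 1e-12:
        if on_degenerate == "max":
            return 1.0
        raise ValidationError("degenerate (all-identical) coordinates in PACo")
    X = X / nx
    Y = Y / ny
    s = np.linalg.svd(X.T @ Y, compute_uv=False)
    return float(min(max(1.0 - s.sum() ** 2, 0.0), 1.0))


def _permute_links_r0(
    row_counts: np.ndarray, n_symbionts: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    links = []
    for i, k in enumerate(row_counts):
        for j in rng.choice(n_symbionts, size=int(k), replace=False):
            links.append((i, int(j)))
    return links


def _permute_links_full(
    n_links: int, n_hosts: int, n_symbionts: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    # with as many links as hosts and symbionts, the occupancy constraints
    # force a permutation matrix: draw one uniformly
    if n_links == n_hosts == n_symbionts:
        return list(enumerate(rng.permutation(n_symbionts).tolist()))
    # otherwise place all links uniformly among cells; reject layouts leaving
    # an empty host row or symbiont column
    cells = n_hosts * n_symbionts
    for _ in range(10_000):
        flat = rng.choice(cells, size=n_links, replace=False)
        hosts = flat // n_symbionts
        symb = flat % n_symbionts
        if len(set(hosts.tolist())) == n_hosts and len(set(symb.tolist())) == n_symbionts:
            return list(zip(hosts.tolist(), symb.tolist()))
    raise SymbiopanError("full_shuffle permutation rejected too many layouts")


def paco(
    host_d: SquareMatrix,
    symb_d: SquareMatrix,
    assoc: AssociationMatrix,
    n_permutations: int = 1000,
    scheme: str = "r0",
    seed: int = 0,
    correction: str = "cailliez",
) -> PacoResult:
    """Procrustean test of cophylogenetic congruence.

    ``host_d`` and ``symb_d`` are tip distance matrices whose labels cover
    the association's hosts and symbionts.  Returns m², R² = 1 − m², and the
    permutation p-value.
    """
    if scheme not in ("r0", "full_shuffle"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    links = assoc.link_pairs()
    if len(links) < 3:
        raise ValidationError("PACo needs at least 3 association links")
    host_d = host_d.as_distance().reorder(assoc.hosts)
    symb_d = symb_d.as_distance().reorder(assoc.symbionts)
    Xh = pcoa(host_d, correction).coords
    Ys = pcoa(symb_d, correction).coords

    def stat(link_list, on_degenerate="raise"):
        hi = np.array([h for h, _ in link_list])
        si = np.array([s for _, s in link_list])
        return _procrustes_m2(Xh[hi], Ys[si], on_degenerate)

    m2_obs = stat(links)
    rng = np.random.default_rng(seed)
    row_counts = assoc.links.sum(axis=1)
    n_le = 0
    for _ in range(n_permutations):
        if scheme == "r0":
            perm = _permute_links_r0(row_counts, len(assoc.symbionts), rng)
        else:
            perm = _permute_links_full(
                len(links), len(assoc.hosts), len(assoc.symbionts), rng
            )
        if stat(perm, on_degenerate="max") <= m2_obs:
            n_le += 1
    p = (1 + n_le) / (n_permutations + 1)
    result = PacoResult(
        m2=m2_obs,
        r2=1.0 - m2_obs,
        p_value=p,
        n_permutations=n_permutations,
        permutation_scheme=scheme,
        seed=seed,
    )
    log.info(
        "paco: m2=%.4f R2=%.4f p=%.4g (%d links, %d permutations, %s)",
        result.m2, result.r2, p, len(links), n_permutations, scheme,
    )
    return result


# ---------------------------------------------------------------------------
# generalized Robinson-Foulds (mutual clustering information matching)
# ---------------------------------------------------------------------------

@dataclass
class GeneralizedRFResult:
    distance: float
    matched_info: float   # bits
    entropy_t1: float     # bits
    entropy_t2: float     # bits
    n_subsamples: int = 1
    seed: int | None = None


def nontrivial_splits(tree: dendropy.Tree) -> list[frozenset]:
    """Non-trivial bipartitions (both sides >= 2 tips), canonicalized as the
    side not containing the alphabetically first tip."""
    tips = set(tree_tip_labels(tree))
    ref = min(tips)
    n = len(tips)
    splits: set[frozenset] = set()
    for node in tree.preorder_internal_node_iter():
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 2 <= len(below) <= n - 2:
            side = below if ref not in below else frozenset(tips - below)
            splits.add(side)
    return sorted(splits, key=lambda s: sorted(s))


def _entropy2(a: int, n: int) -> float:
    """Entropy (bits) of a 2-block partition with block sizes a, n-a."""
    h = 0.0
    for k in (a, n - a):
        if 0 < k < n:
            p = k / n
            h -= p * np.log2(p)
    return h


def split_mutual_information(a: frozenset, b: frozenset, tips: frozenset) -> float:
    """Mutual information (bits) between two bipartitions of the same tip set,
    from the 2x2 co-membership confusion counts."""
    n = len(tips)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = n - n11 - n10 - n01
    mi = 0.0
    for nij, ni, nj in (
        (n11, len(a), len(b)),
        (n10, len(a), n - len(b)),
        (n01, n - len(a), len(b)),
        (n00, n - len(a), n - len(b)),
    ):
        if nij > 0:
            mi += (nij / n) * np.log2(n * nij / (ni * nj))
    return float(mi)


def generalized_rf(t1: dendropy.Tree, t2: dendropy.Tree) -> GeneralizedRFResult:
    """Information-based generalized RF distance between two trees on the
    same tips: maximum-weight matching of split pairs scored by mutual
    clustering information, normalized by the total split entropies."""
    tips1 = set(tree_tip_labels(t1))
    tips2 = set(tree_tip_labels(t2))
    if tips1 != tips2:
        raise ValidationError(
            f"tip sets differ: only-in-first={sorted(tips1 - tips2)}, "
            f"only-in-second={sorted(tips2 - tips1)}"
        )
    if len(tips1) < 4:
        raise ValidationError("generalized RF needs at least 4 tips")
    tips = frozenset(tips1)
    n = len(tips)
    s1 = nontrivial_splits(t1)
    s2 = nontrivial_splits(t2)
    h1 = sum(_entropy2(len(s), n) for s in s1)
    h2 = sum(_entropy2(len(s), n) for s in s2)
    if not s1 or not s2:
        matched = 0.0
    else:
        score = np.array(
            [[split_mutual_information(a, b, tips) for b in s2] for a in s1]
        )
        rows, cols = linear_sum_assignment(-score)
        matched = float(score[rows, cols].sum())
    if h1 + h2 <= 0:
        distance = 0.0
    else:
        distance = float(min(max(1.0 - 2.0 * matched / (h1 + h2), 0.0), 1.0))
        if distance < 1e-12:  # identical split sets up to rounding
            distance = 0.0
    return GeneralizedRFResult(distance, matched, h1, h2)


# ---------------------------------------------------------------------------
# multi-association handling: one-to-one subsampling
# ---------------------------------------------------------------------------

def map_symbiont_tips(
    symb: dendropy.Tree,
    assoc: AssociationMatrix,
    n_subsamples: int = 100,
    seed: int = 0,
) -> list[dendropy.Tree]:
    """For each subsample, pick one linked symbiont tip per host uniformly at
    random, prune the symbiont tree to the chosen tips, and relabel them by
    host.  A one-to-one association yields exactly one tree."""
    symb_tips = set(tree_tip_labels(symb))
    missing = set(assoc.symbionts) - symb_tips
    if missing:
        raise ValidationError(f"symbionts missing from tree: {sorted(missing)}")
    candidates = {
        h: [assoc.symbionts[j] for j in np.flatnonzero(assoc.links[i])]
        for i, h in enumerate(assoc.hosts)
    }
    if any(not c for c in candidates.values()):
        raise ValidationError("a host has no linked symbiont tip")
    rng = np.random.default_rng(seed)
    if assoc.is_one_to_one():
        n_subsamples = 1
    trees = []
    for _ in range(n_subsamples):
        for _attempt in range(1000):
            choice = {h: c[int(rng.integers(len(c)))] for h, c in candidates.items()}
            if len(set(choice.values())) == len(choice):
                break
        else:
            raise SymbiopanError(
                "could not draw a collision-free one-to-one tip assignment"
            )
        sub = symb.extract_tree_with_taxa_labels(list(choice.values()))
        # re-parse for an independent taxon namespace: the extracted tree
        # shares taxa with the source, which relabeling must not touch
        from .io_formats import tree_from_string, tree_to_string

        sub = tree_from_string(tree_to_string(sub))
        relabel = {s: h for h, s in choice.items()}
        for leaf in sub.leaf_node_iter():
            leaf.taxon.label = relabel[leaf.taxon.label]
        trees.append(sub)
    return trees


def congruence_rf(
    host: dendropy.Tree,
    symb: dendropy.Tree,
    assoc: AssociationMatrix,
    n_subsamples: int = 100,
    seed: int = 0,
) -> GeneralizedRFResult:
    """Mean generalized RF between the host tree and host-relabeled one-to-one
    subsamples of the symbiont tree."""
    if len(tree_tip_labels(host)) < 4:
        raise ValidationError("host tree needs at least 4 tips for RF")
    subs = map_symbiont_tips(symb, assoc, n_subsamples, seed)
    results = [generalized_rf(host, s) for s in subs]
    return GeneralizedRFResult(
        distance=float(np.mean([r.distance for r in results])),
        matched_info=float(np.mean([r.matched_info for r in results])),
        entropy_t1=results[0].entropy_t1,
        entropy_t2=float(np.mean([r.entropy_t2 for r in results])),
        n_subsamples=len(subs),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# signal / congruence classification
# ---------------------------------------------------------------------------

@dataclass
class PhylosymbiosisCall:
    signal: str       # none | low | high
    congruence: str   # none | weak | strong
    alpha: float = 0.05
    r2_high_threshold: float = 0.20
    r2_congruence_threshold: float = 0.25
    r2_strong_threshold: float = 0.60
    rf_gate: float | None = None


def classify_phylosymbiosis(
    p: float,
    r2: float,
    rf: float | None = None,
    alpha: float = 0.05,
    r2_high_threshold: float = 0.20,
    r2_congruence_threshold: float = 0.25,
    r2_strong_threshold: float = 0.60,
    rf_gate: float | None = None,
) -> PhylosymbiosisCall:
    """Label cophylogenetic signal and phylogenetic congruence.

    Signal is "none" when the PACo permutation test is non-significant
    (p >= alpha), otherwise "high" when R² >= 0.20 and "low" below.
    Congruence requires a significant test with R² > 0.25 (and RF <= rf_gate
    when a gate is set); it is "strong" above R² = 0.60, "weak" otherwise.
    """
    if not 0.0 <= p <= 1.0 or not 0.0 <= r2 <= 1.0:
        raise ValidationError("p and r2 must lie in [0,1]")
    eps = 1e-9  # guard the threshold comparisons against float round-off
    if p >= alpha:
        signal = "none"
    elif r2 >= r2_high_threshold - eps:
        signal = "high"
    else:
        signal = "low"
    congruence = "none"
    if (
        p < alpha
        and r2 > r2_congruence_threshold + eps
        and (rf_gate is None or (rf is not None and rf <= rf_gate))
    ):
        congruence = "strong" if r2 > r2_strong_threshold + eps else "weak"
    return PhylosymbiosisCall(
        signal, congruence, alpha, r2_high_threshold,
        r2_congruence_threshold, r2_strong_threshold, rf_gate,
    )
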