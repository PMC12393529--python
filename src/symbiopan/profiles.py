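"""Read-recruitment profiles: RPKM normalization with detection
thresholding, Bray-Curtis dissimilarity, UPGMA dendrograms, and PACo
concordance between a host phylogeny and the profile clustering.

RPKM = reads / ((genome_length / 10^3) * (library_size / 10^6)); values
below the detection threshold (default 0.1) are zeroed to suppress spurious
low-coverage hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .cophylogeny import PacoResult, paco, patristic_distances
from .io_formats import (
    AssociationMatrix,
    ReadCountTable,
    SquareMatrix,
    ValidationError,
    get_logger,
    tree_from_string,
    tree_tip_labels,
)

log = get_logger(__name__)

__all__ = [
    "RpkmProfile",
    "compute_rpkm",
    "bray_curtis",
    "upgma",
    "cophenetic_distances",
    "profile_concordance",
    "mean_rpkm_by_group",
]


@dataclass
class RpkmProfile:
    samples: list[str]
    genomes: list[str]
    values: np.ndarray  # samples x genomes, thresholded RPKM
    detection_threshold: float
    sample_to_host: dict[str, str] = field(default_factory=dict)


def compute_rpkm(
    counts: ReadCountTable,
    threshold: float = 0.1,
    sample_to_host: dict[str, str] | None = None,
) -> RpkmProfile:
    """Normalize counts to RPKM and zero cells below the detection threshold."""
    if (counts.library_size <= 0).any():
        raise ValidationError("zero library size")
    kb = counts.genome_length_bp / 1e3
    millions = counts.library_size / 1e6
    rpkm = counts.counts / (kb[None, :] * millions[:, None])
    rpkm[rpkm < threshold] = 0.0
    return RpkmProfile(
        samples=list(counts.samples),
        genomes=list(counts.genomes),
        values=rpkm,
        detection_threshold=threshold,
        sample_to_host=dict(sample_to_host or {}),
    )


def bray_curtis(p: RpkmProfile) -> SquareMatrix:
    """BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i); two all-zero samples are at
    distance 0 by convention."""
    if len(p.samples) < 2:
        raise ValidationError("need at least 2 samples")
    X = p.values
    n = X.shape[0]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (X[i] + X[j]).sum()
            if denom == 0:
                log.info(
                    "bray_curtis: samples %s and %s are both empty; distance 0",
                    p.samples[i], p.samples[j],
                )
                d = 0.0
            else:
                d = np.abs(X[i] - X[j]).sum() / denom
            values[i, j] = values[j, i] = d
    return SquareMatrix(list(p.samples), values, "distance")


def upgma(d: SquareMatrix) -> dendropy.Tree:
    """Average-linkage agglomeration into an ultrametric dendrogram.

    Ties are broken deterministically: among equally close cluster pairs the
    pair whose (lexicographically smallest member, then smallest member of
    the other cluster) sorts first is merged.  Merge heights are half the
    inter-cluster distance, so cophenetic tip-tip distances reproduce the
    merge-time distances.
    """
    if d.mode != "distance":
        raise ValidationError("upgma needs a distance-mode matrix")
    n = d.n
    if n < 2:
        raise ValidationError("need at least 2 items")
    # cluster state: id -> (member labels, size, height, newick fragment)
    clusters: dict[int, dict] = {
        i: {"members": (d.labels[i],), "size": 1, "height": 0.0, "nwk": d.labels[i]}
        for i in range(n)
    }
    dist = {
        (i, j): d.values[i, j] for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        def sort_key(pair):
            i, j = pair
            a = min(min(clusters[i]["members"]), min(clusters[j]["members"]))
            b = max(min(clusters[i]["members"]), min(clusters[j]["members"]))
            return (dist[pair], a, b)

        (i, j) = min(dist, key=sort_key)
        dij = dist[(i, j)]
        height = dij / 2.0
        ci, cj = clusters.pop(i), clusters.pop(j)
        nwk = (
            f"({ci['nwk']}:{height - ci['height']:.10g},"
            f"{cj['nwk']}:{height - cj['height']:.10g})"
        )
        new = {
            "members": tuple(sorted(ci["members"] + cj["members"])),
            "size": ci["size"] + cj["size"],
            "height": height,
            "nwk": nwk,
        }
        # arithmetic-average update over member counts
        for k in list(clusters):
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(k, next_id), max(k, next_id))] = (
                ci["size"] * dik + cj["size"] * djk
            ) / (ci["size"] + cj["size"])
        for key in [k for k in dist if i in k or j in k]:
            del dist[key]
        clusters[next_id] = new
        next_id += 1
    root = next(iter(clusters.values()))
    return tree_from_string(root["nwk"] + ";")


def cophenetic_distances(tree: dendropy.Tree) -> SquareMatrix:
    """Patristic distances of a dendrogram = cophenetic merge distances."""
    return patristic_distances(tree)


def profile_concordance(
    host: dendropy.Tree,
    p: RpkmProfile,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PacoResult:
    """PACo between host patristic distances and the cophenetic distances of
    the Bray-Curtis UPGMA dendrogram of the RPKM profiles.

    Each sample is linked to its host taxon; host tips without a sample are
    dropped with a warning.
    """
    if not p.sample_to_host:
        raise ValidationError("profile carries no sample -> host mapping")
    host_tips = set(tree_tip_labels(host))
    missing = set(p.sample_to_host.values()) - host_tips
    if missing:
        raise ValidationError(f"sample hosts missing from tree: {sorted(missing)}")
    used_hosts = sorted(set(p.sample_to_host.values()))
    unused = host_tips - set(used_hosts)
    if unused:
        log.warning(
            "profile_concordance: dropping %d host tips without samples", len(unused)
        )
    if len(used_hosts) < 3:
        raise ValidationError("need samples on at least 3 host tips")
    host_d = patristic_distances(host).reorder(used_hosts)

    dend = upgma(bray_curtis(p))
    samp_d = cophenetic_distances(dend)

    links = np.zeros((len(used_hosts), len(p.samples)), dtype=np.int8)
    for si, s in enumerate(p.samples):
        links[used_hosts.index(p.sample_to_host[s]), si] = 1
    assoc = AssociationMatrix(used_hosts, list(p.samples), links)
    return paco(host_d, samp_d, assoc, n_permutations=n_permutations, seed=seed)


def mean_rpkm_by_group(p: RpkmProfile, sample_groups: dict[str, str]) -> dict[str, float]:
    """Mean RPKM over all sample x genome cells, per sample group (e.g. host
    family); a reporting helper for recruitment-strength summaries."""
    out: dict[str, list[float]] = {}
    for i, s in enumerate(p.samples):
        g = sample_groups.get(s)
        if g is None:
            continue
        out.setdefault(g, []).append(float(p.values[i].mean()))
    return {g: float(np.mean(v)) for g, v in out.items()}
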