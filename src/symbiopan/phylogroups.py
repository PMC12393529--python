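"""ANI-based phylogroup delineation and lifestyle composition summaries.

Genomes are clustered by hierarchical agglomeration on 1 - ANI and the tree
is cut at 1 - threshold (default 0.95 similarity, the conventional bacterial
species boundary).  Average linkage is the default, matching dereplication
tools' secondary clustering; single linkage (equivalent to connected
components of the >=threshold graph) is the documented alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_formats import (
    GenomeMetadata,
    SquareMatrix,
    ValidationError,
    get_logger,
    metadata_by_id,
)

log = get_logger(__name__)

__all__ = [
    "PhylogroupAssignment",
    "PhylogroupComposition",
    "ani_cluster",
    "phylogroup_composition",
    "composition_from_counts",
]


@dataclass
class PhylogroupAssignment:
    assignment: dict[str, str]  # genome_id -> "PGk"
    ani_threshold: float
    linkage: str
    n_phylogroups: int

    def members(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for g, pg in self.assignment.items():
            groups.setdefault(pg, []).append(g)
        return {pg: sorted(ms) for pg, ms in groups.items()}


def ani_cluster(
    ani: SquareMatrix, threshold: float = 0.95, linkage: str = "average"
) -> PhylogroupAssignment:
    """Cut an agglomerative tree on 1 - ANI at distance 1 - threshold.

    Labels PG1..PGk are assigned by descending cluster size, ties broken by
    the lexicographically smallest member, so numbering is a deterministic
    function of the clustering alone.
    """
    if ani.mode != "similarity":
        raise ValidationError("ANI matrix must be in similarity mode")
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in (0,1)")
    if linkage not in ("average", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    dist = 1.0 - ani.values
    np.fill_diagonal(dist, 0.0)
    if ani.n == 1:
        flat = np.array([1])
    else:
        Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
        flat = hierarchy.fcluster(Z, t=1.0 - threshold, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for lab, c in zip(ani.labels, flat):
        clusters.setdefault(int(c), []).append(lab)
    ordered = sorted(
        clusters.values(), key=lambda ms: (-len(ms), min(ms))
    )
    assignment = {
        g: f"PG{rank + 1}" for rank, ms in enumerate(ordered) for g in ms
    }
    log.info(
        "ani_cluster: %d genomes -> %d phylogroups at ANI %.2f (%s linkage)",
        ani.n, len(ordered), threshold, linkage,
    )
    return PhylogroupAssignment(assignment, threshold, linkage, len(ordered))


@dataclass
class PhylogroupComposition:
    n_mixed: int
    n_host_only: int
    n_free_only: int
    pct_mixed: float
    pct_specific: float
    n_small: int  # phylogroups with < 3 genomes


def composition_from_counts(
    n_mixed: int, n_host_only: int, n_free_only: int, n_small: int = 0
) -> PhylogroupComposition:
    total = n_mixed + n_host_only + n_free_only
    if total == 0:
        raise ValidationError("no phylogroups")
    pct_mixed = round(100.0 * n_mixed / total, 2)
    pct_specific = round(100.0 * (n_host_only + n_free_only) / total, 2)
    return PhylogroupComposition(
        n_mixed, n_host_only, n_free_only, pct_mixed, pct_specific, n_small
    )


def phylogroup_composition(
    assign: PhylogroupAssignment, meta: list[GenomeMetadata]
) -> PhylogroupComposition:
    """Count phylogroups containing both lifestyles (mixed) vs. only one."""
    by_id = metadata_by_id(meta)
    missing = [g for g in assign.assignment if g not in by_id]
    if missing:
        raise ValidationError(f"missing metadata for genomes: {sorted(missing)[:5]}")
    n_mixed = n_host = n_free = n_small = 0
    for pg, members in assign.members().items():
        lifestyles = {by_id[g].lifestyle for g in members}
        if len(members) < 3:
            n_small += 1
        if lifestyles == {"host_associated", "free_living"}:
            n_mixed += 1
        elif lifestyles == {"host_associated"}:
            n_host += 1
        else:
            n_free += 1
    comp = composition_from_counts(n_mixed, n_host, n_free, n_small)
    log.info(
        "phylogroup_composition: %d mixed (%.2f%%), %d host-only, %d free-only",
        n_mixed, comp.pct_mixed, n_host, n_free,
    )
    return comp
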