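"""Accessory-genome genome-genome similarity networks.

The accessory gene-family matrix (prevalence-filtered, default >5%) yields
pairwise Jaccard similarities between genomes; edges above a threshold form
a network whose structuring by phylogroup vs. lifestyle is quantified with a
weighted categorical (Newman) assortativity coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .io_formats import (
    GeneFamilyMatrix,
    GenomeMetadata,
    SquareMatrix,
    ValidationError,
    get_logger,
    metadata_by_id,
)
from .pangenome import PangenomeSummary
from .phylogroups import PhylogroupAssignment

log = get_logger(__name__)

__all__ = [
    "filter_accessory",
    "genome_similarity",
    "build_network",
    "label_assortativity",
    "export_graphml",
    "export_edge_list",
]


def filter_accessory(
    m: GeneFamilyMatrix, summary: PangenomeSummary, prevalence: float = 0.05
) -> GeneFamilyMatrix:
    """Keep families classified accessory whose prevalence strictly exceeds
    ``prevalence``; core and unique families are excluded."""
    if set(summary.genomes) != set(m.genomes):
        raise ValidationError("summary was computed on different genomes")
    n = len(m.genomes)
    counts = m.presence.sum(axis=1)
    keep = [
        i
        for i, fam in enumerate(m.families)
        if summary.classification.get(fam) == "accessory" and counts[i] / n > prevalence
    ]
    if not keep:
        raise ValidationError(
            "no accessory families pass the prevalence filter; lower the threshold"
        )
    log.info(
        "filter_accessory: kept %d/%d families at prevalence > %.2f",
        len(keep), len(m.families), prevalence,
    )
    return GeneFamilyMatrix(
        families=[m.families[i] for i in keep],
        genomes=list(m.genomes),
        presence=m.presence[keep],
    )


def genome_similarity(m: GeneFamilyMatrix, metric: str = "jaccard") -> SquareMatrix:
    """Pairwise genome similarity over binary family-presence vectors.

    ``jaccard`` = |intersection| / |union| (0/0 defined as 0);
    ``simple_matching`` = matching positions / total families.
    """
    X = m.presence.astype(np.float64)
    n = len(m.genomes)
    inter = X.T @ X
    sums = X.sum(axis=0)
    if metric == "jaccard":
        union = sums[:, None] + sums[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 0.0)
    elif metric == "simple_matching":
        both_absent = (1 - X).T @ (1 - X)
        sim = (inter + both_absent) / X.shape[0]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(sim, 1.0)
    sim = (sim + sim.T) / 2.0
    return SquareMatrix(list(m.genomes), sim, "similarity")


def build_network(
    sim: SquareMatrix,
    edge_threshold: float = 0.5,
    metadata: list[GenomeMetadata] | None = None,
    phylogroups: PhylogroupAssignment | None = None,
) -> nx.Graph:
    """Graph with an edge for every pair at similarity >= threshold; isolated
    nodes are retained.  Node attributes carry lifestyle and phylogroup."""
    if sim.mode != "similarity":
        raise ValidationError("need a similarity matrix")
    g = nx.Graph(edge_threshold=edge_threshold)
    by_id = metadata_by_id(metadata) if metadata else {}
    for lab in sim.labels:
        attrs = {}
        if lab in by_id:
            attrs["lifestyle"] = by_id[lab].lifestyle
        if phylogroups is not None:
            attrs["phylogroup"] = phylogroups.assignment.get(lab, "NA")
        g.add_node(lab, **attrs)
    n = sim.n
    for i in range(n):
        for j in range(i + 1, n):
            w = sim.values[i, j]
            if w >= edge_threshold:
                g.add_edge(sim.labels[i], sim.labels[j], weight=float(w))
    log.info(
        "build_network: %d nodes, %d edges at threshold %.2f",
        g.number_of_nodes(), g.number_of_edges(), edge_threshold,
    )
    return g


def label_assortativity(net: nx.Graph, label: str) -> float:
    """Newman categorical assortativity over edge weights.

    r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i) where e is the
    weight-normalized category mixing matrix.  Positive r means edges prefer
    same-category endpoints.
    """
    if net.number_of_edges() == 0:
        raise ValidationError("assortativity undefined on an edgeless network")
    cats = sorted({net.nodes[v].get(label) for v in net.nodes})
    if None in cats:
        raise ValidationError(f"node attribute {label!r} missing on some nodes")
    index = {c: i for i, c in enumerate(cats)}
    e = np.zeros((len(cats), len(cats)))
    for u, v, data in net.edges(data=True):
        w = data.get("weight", 1.0)
        i, j = index[net.nodes[u][label]], index[net.nodes[v][label]]
        e[i, j] += w / 2.0
        e[j, i] += w / 2.0
    e /= e.sum()
    a = e.sum(axis=1)
    trace = np.trace(e)
    ab = float(a @ a)
    if np.isclose(1.0, ab):
        return 1.0  # single category: perfectly assortative by convention
    return float((trace - ab) / (1.0 - ab))


def export_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, str(path))


def export_edge_list(net: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tsimilarity\n")
        for u, v, data in sorted(net.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):.6g}\n")
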