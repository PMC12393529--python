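"""Seeded generators for synthetic inputs with known planted structure.

Every downstream stage of the pipeline can be exercised without external
data: cophylogenies with tunable codivergence vs. host switching, pangenome
presence/absence matrices with core/accessory/unique strata and planted
lifestyle-associated genes, block-structured ANI matrices, and Poisson read
recruitment counts concentrated on host-matched genomes.

All generators are pure functions of (config, seed): the same arguments give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io_formats import (
    AssociationMatrix,
    GeneFamilyMatrix,
    GenomeMetadata,
    ReadCountTable,
    SquareMatrix,
    SymbiopanError,
    get_logger,
    tree_from_string,
)

log = get_logger(__name__)

__all__ = [
    "CophyloSimConfig",
    "PangenomeSimConfig",
    "simulate_cophylogeny",
    "simulate_pangenome",
    "simulate_ani",
    "simulate_read_counts",
    "block_association",
    "yule_tree",
]


class ConfigError(SymbiopanError):
    pass


# ---------------------------------------------------------------------------
# host tree: Yule (pure birth)
# ---------------------------------------------------------------------------

class _Lineage:
    """A live branch: knows its birth time and, once closed, its children."""

    __slots__ = ("birth", "children", "length", "label")

    def __init__(self, birth: float):
        self.birth = birth
        self.children: list["_Lineage"] = []
        self.length = 0.0
        self.label: str | None = None


def _lineage_to_newick(node: _Lineage) -> str:
    if not node.children:
        return f"{node.label}:{node.length:.10g}"
    inner = ",".join(_lineage_to_newick(c) for c in node.children)
    return f"({inner}):{node.length:.10g}"


def yule_tree(
    n_tips: int, birth_rate: float, rng: np.random.Generator, label_prefix: str = "H"
) -> tuple[dendropy.Tree, "_YuleTrace"]:
    """Simulate a pure-birth tree, returning the tree plus the event trace
    (split times and lineage identities) that the symbiont process replays."""
    if n_tips < 3:
        raise ConfigError("need at least 3 tips")
    if birth_rate <= 0:
        raise ConfigError("birth rate must be positive")
    t = 0.0
    root = _Lineage(0.0)
    active = [root]
    events: list[tuple[float, _Lineage, _Lineage, _Lineage]] = []
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        splitter = active[int(rng.integers(len(active)))]
        c1, c2 = _Lineage(t), _Lineage(t)
        splitter.children = [c1, c2]
        splitter.length = t - splitter.birth
        active.remove(splitter)
        active.extend([c1, c2])
        events.append((t, splitter, c1, c2))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    width = len(str(n_tips))
    for i, leaf in enumerate(active):
        leaf.length = t_end - leaf.birth
        leaf.label = f"{label_prefix}{i + 1:0{width}d}"
    tree = tree_from_string(_lineage_to_newick(root) + ";")
    return tree, _YuleTrace(root=root, events=events, tips=list(active), t_end=t_end)


@dataclass
class _YuleTrace:
    root: _Lineage
    events: list
    tips: list
    t_end: float


# ---------------------------------------------------------------------------
# cophylogeny simulator
# ---------------------------------------------------------------------------

@dataclass
class CophyloSimConfig:
    """Host-symbiont codivergence simulation settings.

    At every host bifurcation, each symbiont lineage resident on the
    splitting branch goes extinct with probability ``loss_prob`` and
    otherwise codiverges into the two daughter branches; each daughter
    lineage then independently host-switches with probability
    ``switch_prob`` by swapping branches with a uniformly chosen other
    lineage (two simultaneous prune-and-graft moves, so per-branch symbiont
    occupancy is conserved and every host tip stays occupied even under
    heavy switching).  ``multi_assoc_rate`` adds Poisson-distributed extra
    symbiont lineages at the root, so hosts can carry several symbionts.
    """

    n_hosts: int = 16
    birth_rate: float = 1.0
    switch_prob: float = 0.0
    loss_prob: float = 0.0
    multi_assoc_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hosts < 3:
            raise ConfigError("n_hosts must be >= 3")
        for p in (self.switch_prob, self.loss_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0,1]")
        if self.switch_prob + self.loss_prob > 1.0:
            raise ConfigError("switch_prob + loss_prob must not exceed 1")
        if self.multi_assoc_rate < 0:
            raise ConfigError("multi_assoc_rate must be >= 0")


class _SymLineage:
    __slots__ = ("host", "birth", "parent")

    def __init__(self, host: _Lineage, birth: float, parent: _Lineage):
        self.host = host          # host branch currently occupied
        self.birth = birth        # time this symbiont edge started
        self.parent = parent      # closed symbiont node the edge hangs from


def _prune_dead(node: _Lineage) -> _Lineage | None:
    """Drop childless internals, splice out unifurcations (summing lengths)."""
    if node.label is not None:
        return node
    kept = [c for c in (_prune_dead(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        kept[0].length += node.length
        return kept[0]
    node.children = kept
    return node


def simulate_cophylogeny(
    config: CophyloSimConfig,
) -> tuple[dendropy.Tree, dendropy.Tree, AssociationMatrix]:
    """Simulate (host tree, symbiont tree, association matrix).

    The host tree is Yule; the symbiont tree tracks it through codivergence,
    host switching, and loss, with branch lengths accumulating host time.
    Symbiont histories in which a host tip ends up with no symbiont (or
    fewer than 3 symbiont tips survive) are resampled on the fixed host tree,
    so the association always satisfies its invariants.
    """
    rng = np.random.default_rng(config.seed)
    host_tree, trace = yule_tree(config.n_hosts, config.birth_rate, rng)

    for attempt in range(500):
        # map host branch -> resident symbiont lineages, replayed over events
        sym_root = _Lineage(0.0)
        n_start = 1 + int(rng.poisson(config.multi_assoc_rate))
        lineages = [
            _SymLineage(trace.root, 0.0, sym_root) for _ in range(n_start)
        ]
        for t, splitter, c1, c2 in trace.events:
            residents = [s for s in lineages if s.host is splitter]
            for s in residents:
                lineages.remove(s)
                if rng.random() < config.loss_prob:
                    continue
                node = _Lineage(s.birth)
                node.length = t - s.birth
                s.parent.children.append(node)
                daughters = [
                    _SymLineage(c1, t, node), _SymLineage(c2, t, node),
                ]
                lineages.extend(daughters)
                for d in daughters:
                    if rng.random() < config.switch_prob:
                        # partners still waiting to codiverge on the dying
                        # branch are excluded: swapping with them would
                        # strand a lineage on a pruned host branch
                        candidates = [
                            l for l in lineages
                            if l is not d and l.host is not splitter
                        ]
                        if candidates:
                            partner = candidates[int(rng.integers(len(candidates)))]
                            d.host, partner.host = partner.host, d.host
        tip_set = set(map(id, trace.tips))
        if (
            len(lineages) >= 3
            and all(id(s.host) in tip_set for s in lineages)
            and all(any(s.host is h for s in lineages) for h in trace.tips)
        ):
            break
    else:
        raise SymbiopanError(
            "could not produce an association leaving every host occupied; "
            "lower loss_prob/switch_prob or raise multi_assoc_rate"
        )

    width = len(str(len(lineages)))
    links: list[tuple[str, str]] = []
    for k, s in enumerate(lineages):
        leaf = _Lineage(s.birth)
        leaf.length = trace.t_end - s.birth
        leaf.label = f"S{k + 1:0{width}d}"
        s.parent.children.append(leaf)
        links.append((s.host.label, leaf.label))

    pruned = _prune_dead(sym_root)
    symb_tree = tree_from_string(_lineage_to_newick(pruned) + ";")

    hosts = sorted({h for h, _ in links})
    symbionts = sorted({s for _, s in links})
    link_m = np.zeros((len(hosts), len(symbionts)), dtype=np.int8)
    for h, s in links:
        link_m[hosts.index(h), symbionts.index(s)] = 1
    assoc = AssociationMatrix(hosts, symbionts, link_m)
    log.info(
        "simulate_cophylogeny: %d hosts, %d symbionts, %d links (seed=%d)",
        len(hosts), len(symbionts), int(link_m.sum()), config.seed,
    )
    return host_tree, symb_tree, assoc


# ---------------------------------------------------------------------------
# pangenome simulator
# ---------------------------------------------------------------------------

@dataclass
class PangenomeSimConfig:
    """Settings for simulated gene-family presence/absence matrices.

    Accessory prevalences are Beta(a, b) truncated to (1/n_genomes, 0.95) so
    accessory families are, in expectation, neither unique nor core.  Trait
    genes have lifestyle-dependent presence probabilities whose odds differ
    by ``trait_odds_ratio`` (baseline presence probability 0.3 in the
    free-living group).
    """

    n_genomes: int = 50
    n_core: int = 20
    n_accessory: int = 100
    accessory_prevalence_ab: tuple[float, float] = (1.0, 2.0)
    unique_per_genome_mean: float = 2.0
    n_trait_genes: int = 0
    trait_odds_ratio: float = 1.0
    lifestyle_fraction: float = 0.5
    trait_base_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core + self.n_accessory == 0:
            raise ConfigError("need at least one core or accessory family")
        if not 0.0 < self.lifestyle_fraction < 1.0:
            raise ConfigError("lifestyle_fraction must lie in (0,1)")
        if self.trait_odds_ratio <= 0:
            raise ConfigError("trait_odds_ratio must be positive")


def simulate_pangenome(
    config: PangenomeSimConfig,
) -> tuple[GeneFamilyMatrix, list[GenomeMetadata]]:
    rng = np.random.default_rng(config.seed)
    n = config.n_genomes
    width = len(str(n))
    genomes = [f"G{i + 1:0{width}d}" for i in range(n)]

    n_ha = int(round(config.lifestyle_fraction * n))
    is_ha = np.zeros(n, dtype=bool)
    is_ha[rng.permutation(n)[:n_ha]] = True
    meta = [
        GenomeMetadata(
            genome_id=g,
            lifestyle="host_associated" if ha else "free_living",
        )
        for g, ha in zip(genomes, is_ha)
    ]

    families: list[str] = []
    rows: list[np.ndarray] = []

    for i in range(config.n_core):
        families.append(f"CORE{i + 1:05d}")
        rows.append(np.ones(n, dtype=np.int8))

    a, b = config.accessory_prevalence_ab
    lo, hi = 1.0 / n, 0.95
    for i in range(config.n_accessory):
        prev = rng.beta(a, b)
        while not lo < prev < hi:
            prev = rng.beta(a, b)
        col = (rng.random(n) < prev).astype(np.int8)
        while col.sum() == 0:  # a family must exist somewhere
            col = (rng.random(n) < prev).astype(np.int8)
        families.append(f"ACC{i + 1:05d}")
        rows.append(col)

    p0 = config.trait_base_prob
    odds0 = p0 / (1.0 - p0)
    odds1 = config.trait_odds_ratio * odds0
    p1 = odds1 / (1.0 + odds1)
    probs = np.where(is_ha, p1, p0)
    for i in range(config.n_trait_genes):
        col = (rng.random(n) < probs).astype(np.int8)
        while col.sum() == 0:
            col = (rng.random(n) < probs).astype(np.int8)
        families.append(f"TRAIT{i + 1:05d}")
        rows.append(col)

    for j in range(n):
        for k in range(int(rng.poisson(config.unique_per_genome_mean))):
            col = np.zeros(n, dtype=np.int8)
            col[j] = 1
            families.append(f"UNIQ_{genomes[j]}_{k + 1:03d}")
            rows.append(col)

    matrix = GeneFamilyMatrix(families, genomes, np.vstack(rows))
    log.info(
        "simulate_pangenome: %d families x %d genomes (%d host-associated, seed=%d)",
        len(families), n, n_ha, config.seed,
    )
    return matrix, meta


# ---------------------------------------------------------------------------
# ANI simulator
# ---------------------------------------------------------------------------

def simulate_ani(
    blocks: list[tuple[int, float]],
    between_sim: float,
    noise_sd: float,
    seed: int,
) -> tuple[SquareMatrix, dict[str, int]]:
    """Block-diagonal similarity matrix with Gaussian noise.

    Returns the matrix and the planted genome -> block-index partition.
    """
    if any(size <= 0 for size, _ in blocks):
        raise ConfigError("block sizes must be positive")
    if any(not 0.0 <= w <= 1.0 for _, w in blocks) or not 0.0 <= between_sim <= 1.0:
        raise ConfigError("similarities must lie in [0,1]")
    if any(w <= between_sim for _, w in blocks):
        raise ConfigError("within-block similarity must exceed between_sim")
    rng = np.random.default_rng(seed)
    n = sum(size for size, _ in blocks)
    values = np.full((n, n), between_sim)
    labels: list[str] = []
    truth: dict[str, int] = {}
    width = len(str(n))
    pos = 0
    for b, (size, within) in enumerate(blocks):
        values[pos:pos + size, pos:pos + size] = within
        for i in range(size):
            lab = f"G{pos + i + 1:0{width}d}"
            labels.append(lab)
            truth[lab] = b
        pos += size
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        noise = np.triu(noise, k=1)
        values = values + noise + noise.T
    values = np.clip(values, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SquareMatrix(labels, values, "similarity"), truth


# ---------------------------------------------------------------------------
# read-recruitment simulator
# ---------------------------------------------------------------------------

def simulate_read_counts(
    host_tree: dendropy.Tree,
    assoc: AssociationMatrix,
    depth_mean: float,
    enrichment: float,
    seed: int,
) -> tuple[ReadCountTable, dict[str, str]]:
    """One sample per host tip; Poisson counts with mean ``depth_mean *
    enrichment`` on linked genomes and ``depth_mean`` elsewhere.

    Genome lengths are uniform on [3, 6] Mbp; library sizes are ten times the
    per-sample mapped total (floored at 1 so empty samples stay valid).
    Returns the count table and the sample -> host-tip mapping.
    """
    if enrichment < 1:
        raise ConfigError("enrichment must be >= 1")
    if depth_mean < 0:
        raise ConfigError("depth_mean must be >= 0")
    rng = np.random.default_rng(seed)
    host_tips = [leaf.taxon.label for leaf in host_tree.leaf_node_iter()]
    missing = set(assoc.hosts) - set(host_tips)
    if missing:
        raise ConfigError(f"association hosts missing from tree: {sorted(missing)}")
    genomes = list(assoc.symbionts)
    samples = [f"sample_{h}" for h in host_tips]
    sample_to_host = dict(zip(samples, host_tips))
    mean = np.full((len(host_tips), len(genomes)), depth_mean)
    for i, h in enumerate(host_tips):
        if h in assoc.hosts:
            row = assoc.links[assoc.hosts.index(h)]
            mean[i, row == 1] = depth_mean * enrichment
    counts = rng.poisson(mean)
    lengths = rng.integers(3_000_000, 6_000_001, size=len(genomes))
    library = np.maximum(counts.sum(axis=1) * 10, 1)
    table = ReadCountTable(samples, genomes, counts, lengths, library)
    return table, sample_to_host


def block_association(
    host_tree: dendropy.Tree, n_blocks: int, genomes_per_block: int
) -> AssociationMatrix:
    """Clade-block association: host tips (in tree order, so consecutive tips
    are close relatives) are split into ``n_blocks`` contiguous groups, and
    every host in a group links to the same set of genomes.

    Profiles simulated from such an association mirror host-tree blocks,
    which is the regime where read-recruitment concordance is expected to
    detect phylosymbiosis.
    """
    tips = [leaf.taxon.label for leaf in host_tree.leaf_node_iter()]
    if n_blocks < 2 or n_blocks > len(tips):
        raise ConfigError("n_blocks must lie in [2, n_hosts]")
    bounds = np.linspace(0, len(tips), n_blocks + 1).astype(int)
    genomes = [
        f"B{b + 1:02d}_G{i + 1:02d}"
        for b in range(n_blocks)
        for i in range(genomes_per_block)
    ]
    links = np.zeros((len(tips), len(genomes)), dtype=np.int8)
    for b in range(n_blocks):
        cols = slice(b * genomes_per_block, (b + 1) * genomes_per_block)
        links[bounds[b]:bounds[b + 1], cols] = 1
    return AssociationMatrix(tips, genomes, links)
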