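"""Readers, writers, and validated containers for every format the pipeline touches.

Trees are handled as :class:`dendropy.Tree` objects read from and written to
Newick; tabular inputs (gene-family presence/absence, ANI matrices, metadata,
read counts) travel as TSV/CSV and are validated into small dataclasses on
load.  A single YAML config document with one block per pipeline stage holds
every threshold used downstream; :data:`DEFAULT_CONFIG` carries the default
values (95% core prevalence, 5% accessory prevalence filter, 95% ANI, 1000
permutations, 0.1 RPKM detection, alpha 0.05, 0.25 congruence R²).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SymbiopanError",
    "ParseError",
    "ValidationError",
    "GeneFamilyMatrix",
    "GenomeMetadata",
    "SquareMatrix",
    "AssociationMatrix",
    "ReadCountTable",
    "read_tree",
    "tree_from_string",
    "write_tree",
    "tree_to_string",
    "read_gene_matrix",
    "write_gene_matrix",
    "read_metadata",
    "write_metadata",
    "read_square_matrix",
    "write_square_matrix",
    "read_association",
    "write_association",
    "read_read_counts",
    "write_read_counts",
    "DEFAULT_CONFIG",
    "load_config",
    "get_logger",
]


class SymbiopanError(Exception):
    """Base class for pipeline errors."""


class ParseError(SymbiopanError):
    """A file could not be parsed in its declared format."""


class ValidationError(SymbiopanError):
    """Parsed content violates a container invariant."""


# ---------------------------------------------------------------------------
# logging
# ---------------------------------------------------------------------------

def get_logger(name: str = "symbiopan") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


log = get_logger(__name__)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

#: branch lengths are emitted with this format so read->write->read round-trips
#: to 10 significant digits
_BRLEN_FORMAT = ".10g"


def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if any(lab is None for lab in labels):
        raise ValidationError("tree has unlabeled tips")
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
        elif edge.length < 0:
            raise ValidationError(
                f"negative branch length {edge.length} on edge to "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
            )
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    """Parse a Newick string into a validated tree (polytomies allowed)."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        if "Duplicate taxon" in str(exc):
            raise ValidationError(f"duplicate tip labels: {exc}") from exc
        raise ParseError(f"malformed Newick: {exc}") from exc
    return _validate_tree(tree)


def read_tree(path: str | Path, format: str = "newick") -> dendropy.Tree:
    """Read a Newick tree file.

    Branch lengths and internal labels are optional; absent lengths default
    to 0.  Duplicate tip labels raise :class:`ValidationError`.
    """
    if format != "newick":
        raise ValueError(f"unsupported tree format: {format}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return tree_from_string(path.read_text())


_NEWICK_SPECIAL = set(" ,():;'[]\t\n")


def _quote_label(label: str) -> str:
    if any(ch in _NEWICK_SPECIAL for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _node_to_newick(node: dendropy.Node, is_root: bool) -> str:
    if node.is_leaf():
        core = _quote_label(node.taxon.label)
    else:
        core = "(" + ",".join(
            _node_to_newick(c, False) for c in node.child_nodes()
        ) + ")"
        if node.label:
            core += _quote_label(node.label)
    if is_root:
        return core
    length = node.edge.length if node.edge.length is not None else 0.0
    return f"{core}:{length:{_BRLEN_FORMAT}}"


def tree_to_string(tree: dendropy.Tree) -> str:
    """Serialize a tree to single-line Newick with %.10g branch lengths.

    The root edge length is omitted, so read -> write -> read is the
    identity on topology, labels, and lengths to 10 significant digits.
    """
    return _node_to_newick(tree.seed_node, True) + ";\n"


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_string(tree))


def tree_tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# gene-family presence/absence
# ---------------------------------------------------------------------------

@dataclass
class GeneFamilyMatrix:
    """Binary gene-family x genome presence/absence matrix.

    Invariants: entries in {0,1}; unique family and genome IDs; every family
    present in at least one genome.
    """

    families: list[str]
    genomes: list[str]
    presence: np.ndarray  # shape (n_families, n_genomes), dtype int8

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=np.int8)
        if self.presence.shape != (len(self.families), len(self.genomes)):
            raise ValidationError(
                f"presence shape {self.presence.shape} does not match "
                f"{len(self.families)} families x {len(self.genomes)} genomes"
            )
        if len(set(self.families)) != len(self.families):
            raise ValidationError("duplicate family IDs")
        if len(set(self.genomes)) != len(self.genomes):
            raise ValidationError("duplicate genome IDs")
        bad = (self.presence != 0) & (self.presence != 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary cell at family {self.families[i]!r}, "
                f"genome {self.genomes[j]!r}"
            )
        empty = np.flatnonzero(self.presence.sum(axis=1) == 0)
        if empty.size:
            raise ValidationError(
                f"family present in no genome: {self.families[empty[0]]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.presence.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.families, columns=self.genomes)

    def subset_genomes(self, genomes: Sequence[str], drop_empty: bool = True) -> "GeneFamilyMatrix":
        """Restrict to a genome subset, dropping families absent from it."""
        missing = [g for g in genomes if g not in self.genomes]
        if missing:
            raise ValidationError(f"unknown genomes: {missing}")
        cols = [self.genomes.index(g) for g in genomes]
        sub = self.presence[:, cols]
        if drop_empty:
            keep = sub.sum(axis=1) > 0
        else:
            keep = np.ones(len(self.families), dtype=bool)
        return GeneFamilyMatrix(
            families=[f for f, k in zip(self.families, keep) if k],
            genomes=list(genomes),
            presence=sub[keep],
        )


def read_gene_matrix(path: str | Path, dialect: str = "rtab") -> GeneFamilyMatrix:
    """Read a presence/absence matrix (first column = family IDs, header = genomes).

    ``rtab`` is tab-separated (PIRATE/Roary style), ``csv`` comma-separated.
    Non-binary cells and all-zero families are rejected.
    """
    sep = {"rtab": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect: {dialect}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"ragged or malformed table in {path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"empty gene matrix in {path}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.map(lambda v: not str(v).strip() in ("0", "1"))
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-binary cell {df.iat[i, j]!r} at family {df.index[i]!r}, "
            f"genome {df.columns[j]!r}"
        )
    bad = (values != 0) & (values != 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-binary cell {df.iat[i, j]!r} at family {df.index[i]!r}, "
            f"genome {df.columns[j]!r}"
        )
    return GeneFamilyMatrix(
        families=[str(f) for f in df.index],
        genomes=[str(g) for g in df.columns],
        presence=values.astype(np.int8),
    )


def write_gene_matrix(m: GeneFamilyMatrix, path: str | Path, dialect: str = "rtab") -> None:
    sep = {"rtab": "\t", "csv": ","}[dialect]
    m.to_frame().to_csv(path, sep=sep, index_label="Gene")


# ---------------------------------------------------------------------------
# genome metadata
# ---------------------------------------------------------------------------

LIFESTYLES = ("host_associated", "free_living")


@dataclass
class GenomeMetadata:
    """Per-genome annotation; lifestyle is mandatory, the rest optional."""

    genome_id: str
    lifestyle: str
    host_phylum: str | None = None
    host_taxon: str | None = None
    pigmentation: str | None = None
    geography: str | None = None

    def __post_init__(self) -> None:
        if self.lifestyle not in LIFESTYLES:
            raise ValidationError(
                f"genome {self.genome_id!r}: lifestyle must be one of {LIFESTYLES}, "
                f"got {self.lifestyle!r}"
            )
        if self.pigmentation not in (None, "pigmented", "nonpigmented"):
            raise ValidationError(
                f"genome {self.genome_id!r}: bad pigmentation {self.pigmentation!r}"
            )


_META_COLUMNS = [
    "genome_id", "lifestyle", "host_phylum", "host_taxon", "pigmentation", "geography",
]


def read_metadata(path: str | Path) -> list[GenomeMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str).where(lambda d: d.notna(), None)
    if "genome_id" not in df.columns or "lifestyle" not in df.columns:
        raise ParseError(f"{path}: metadata needs genome_id and lifestyle columns")
    records = []
    seen: set[str] = set()
    for row in df.to_dict("records"):
        gid = row["genome_id"]
        if gid in seen:
            raise ValidationError(f"duplicate genome_id {gid!r}")
        seen.add(gid)
        records.append(GenomeMetadata(**{k: row.get(k) for k in _META_COLUMNS}))
    return records


def write_metadata(meta: Iterable[GenomeMetadata], path: str | Path) -> None:
    df = pd.DataFrame([vars(m) for m in meta], columns=_META_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def metadata_by_id(meta: Iterable[GenomeMetadata]) -> dict[str, GenomeMetadata]:
    return {m.genome_id: m for m in meta}


# ---------------------------------------------------------------------------
# square matrices (ANI, patristic, Bray-Curtis)
# ---------------------------------------------------------------------------

@dataclass
class SquareMatrix:
    """Symmetric labeled matrix, either similarity (unit diagonal, values in
    [0,1]) or distance (zero diagonal) mode."""

    labels: list[str]
    values: np.ndarray
    mode: str  # "similarity" | "distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in square matrix")
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if self.mode not in ("similarity", "distance"):
            raise ValidationError(f"bad mode {self.mode!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValidationError("matrix not symmetric within 1e-9")
        diag = np.diag(self.values)
        target = 1.0 if self.mode == "similarity" else 0.0
        if not np.allclose(diag, target, atol=1e-9):
            raise ValidationError(f"{self.mode} matrix diagonal must be {target}")
        if self.mode == "similarity" and (
            (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any()
        ):
            raise ValidationError("similarity values outside [0,1]")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels: Sequence[str]) -> "SquareMatrix":
        idx = [self.labels.index(lab) for lab in labels]
        return SquareMatrix(list(labels), self.values[np.ix_(idx, idx)], self.mode)

    def as_distance(self) -> "SquareMatrix":
        """1 - similarity; identity if already in distance mode."""
        if self.mode == "distance":
            return self
        return SquareMatrix(list(self.labels), 1.0 - self.values, "distance")


def read_square_matrix(path: str | Path, mode: str = "similarity") -> SquareMatrix:
    """Read a labeled square table (TSV).

    Similarity values above 1 are interpreted as percentages and divided by
    100.  Reciprocal pairs are averaged when they differ by <= 1e-6 (suitable
    for fastANI-style asymmetric outputs already close to symmetric); larger
    asymmetry is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if set(labels) != set(cols):
        raise ValidationError(
            f"row/column label mismatch: {sorted(set(labels) ^ set(cols))}"
        )
    df.columns = cols
    df = df.loc[labels, labels]
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError(f"{path}: missing values in square matrix")
    if mode == "similarity" and values.max() > 1.0 + 1e-12:
        values = values / 100.0
    asym = np.abs(values - values.T)
    if asym.max() > 1e-6:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValidationError(
            f"asymmetric entries for ({labels[i]}, {labels[j]}): "
            f"{values[i, j]} vs {values[j, i]} (|diff| > 1e-6)"
        )
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0 if mode == "similarity" else 0.0)
    return SquareMatrix(labels, values, mode)


def write_square_matrix(m: SquareMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="label", float_format="%.10g")


# ---------------------------------------------------------------------------
# host-symbiont association
# ---------------------------------------------------------------------------

@dataclass
class AssociationMatrix:
    """Binary host x symbiont link matrix; every row and column has >= 1 link."""

    hosts: list[str]
    symbionts: list[str]
    links: np.ndarray  # (n_hosts, n_symbionts) int8

    def __post_init__(self) -> None:
        self.links = np.asarray(self.links, dtype=np.int8)
        if self.links.shape != (len(self.hosts), len(self.symbionts)):
            raise ValidationError("links shape does not match host/symbiont labels")
        if len(set(self.hosts)) != len(self.hosts):
            raise ValidationError("duplicate host labels")
        if len(set(self.symbionts)) != len(self.symbionts):
            raise ValidationError("duplicate symbiont labels")
        if ((self.links != 0) & (self.links != 1)).any():
            raise ValidationError("association entries must be 0/1")
        if (self.links.sum(axis=1) == 0).any():
            bad = self.hosts[int(np.argmin(self.links.sum(axis=1)))]
            raise ValidationError(f"host {bad!r} has no linked symbiont")
        if (self.links.sum(axis=0) == 0).any():
            bad = self.symbionts[int(np.argmin(self.links.sum(axis=0)))]
            raise ValidationError(f"symbiont {bad!r} has no linked host")

    def link_pairs(self) -> list[tuple[int, int]]:
        """(host_index, symbiont_index) for every 1 entry, row-major order."""
        return [tuple(ij) for ij in np.argwhere(self.links == 1)]

    def is_one_to_one(self) -> bool:
        return bool(
            (self.links.sum(axis=0) == 1).all() and (self.links.sum(axis=1) == 1).all()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.links, index=self.hosts, columns=self.symbionts)


def read_association(path: str | Path) -> AssociationMatrix:
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    return AssociationMatrix(
        hosts=[str(h) for h in df.index],
        symbionts=[str(s) for s in df.columns],
        links=values,
    )


def write_association(a: AssociationMatrix, path: str | Path) -> None:
    a.to_frame().to_csv(path, index_label="host")


# ---------------------------------------------------------------------------
# read-recruitment counts
# ---------------------------------------------------------------------------

@dataclass
class ReadCountTable:
    """Reads mapped per genome per sample, with genome lengths and library sizes."""

    samples: list[str]
    genomes: list[str]
    counts: np.ndarray  # (n_samples, n_genomes) int64
    genome_length_bp: np.ndarray  # per genome
    library_size: np.ndarray  # per sample

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.genome_length_bp = np.asarray(self.genome_length_bp, dtype=np.int64)
        self.library_size = np.asarray(self.library_size, dtype=np.int64)
        if self.counts.shape != (len(self.samples), len(self.genomes)):
            raise ValidationError("counts shape does not match sample/genome labels")
        if (self.counts < 0).any():
            raise ValidationError("negative read counts")
        if (self.genome_length_bp <= 0).any():
            raise ValidationError("genome lengths must be positive")
        if (self.library_size <= 0).any():
            raise ValidationError("library sizes must be positive")
        mapped = self.counts.sum(axis=1)
        if (self.library_size < mapped).any():
            bad = self.samples[int(np.argmax(mapped - self.library_size))]
            raise ValidationError(
                f"sample {bad!r}: library size smaller than mapped read total"
            )


def read_read_counts(prefix: str | Path) -> ReadCountTable:
    """Read a count table from ``<prefix>.counts.tsv``, ``<prefix>.genomes.tsv``
    (genome_id, length_bp) and ``<prefix>.samples.tsv`` (sample_id, library_size)."""
    prefix = str(prefix)
    counts = pd.read_csv(prefix + ".counts.tsv", sep="\t", index_col=0)
    genomes = pd.read_csv(prefix + ".genomes.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(prefix + ".samples.tsv", sep="\t", index_col=0)
    genome_ids = [str(g) for g in counts.columns]
    sample_ids = [str(s) for s in counts.index]
    return ReadCountTable(
        samples=sample_ids,
        genomes=genome_ids,
        counts=counts.to_numpy(),
        genome_length_bp=genomes.loc[genome_ids, "length_bp"].to_numpy(),
        library_size=samples.loc[sample_ids, "library_size"].to_numpy(),
    )


def write_read_counts(t: ReadCountTable, prefix: str | Path) -> None:
    prefix = str(prefix)
    pd.DataFrame(t.counts, index=t.samples, columns=t.genomes).to_csv(
        prefix + ".counts.tsv", sep="\t", index_label="sample"
    )
    pd.DataFrame(
        {"length_bp": t.genome_length_bp}, index=pd.Index(t.genomes, name="genome_id")
    ).to_csv(prefix + ".genomes.tsv", sep="\t")
    pd.DataFrame(
        {"library_size": t.library_size}, index=pd.Index(t.samples, name="sample_id")
    ).to_csv(prefix + ".samples.tsv", sep="\t")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "pangenome": {
        "core_threshold": 0.95,
        "accumulation_permutations": 100,
        "openness_gamma_threshold": 0.02,
    },
    "phylogroups": {"ani_threshold": 0.95, "linkage": "average"},
    "network": {
        "prevalence_filter": 0.05,
        "edge_threshold": 0.5,
        "similarity_metric": "jaccard",
    },
    "cophylogeny": {
        "n_permutations": 1000,
        "permutation_scheme": "r0",
        "pcoa_correction": "cailliez",
        "alpha": 0.05,
        "r2_high_threshold": 0.20,
        "r2_congruence_threshold": 0.25,
        "r2_strong_threshold": 0.60,
        "rf_gate": None,
        "n_subsamples": 100,
    },
    "pangwas": {"alpha": 0.05, "fwer_cutoff": 0.99},
    "profiles": {
        "rpkm_threshold": 0.1,
        "n_permutations": 1000,
        "linkage": "average",
    },
}


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, shallow-merged per stage with an optional YAML overlay."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            overlay = yaml.safe_load(fh) or {}
        for stage, block in overlay.items():
            if stage in config and isinstance(block, dict):
                config[stage].update(block)
            else:
                config[stage] = block
    return config
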