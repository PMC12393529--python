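"""Pangenome structure: core/accessory/unique partition, accumulation curves
with a Heaps-law openness verdict, and the gene-class x lifestyle chi-square
test.

A gene family is *unique* if present in exactly one genome of the subset
under study, *core* if its prevalence strictly exceeds the core threshold
(default 0.95, i.e. "present in >95% of genomes"), and *accessory*
otherwise.  Families absent from the subset are dropped before
classification, so lifestyle-restricted pangenomes have independent totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import (
    GeneFamilyMatrix,
    SymbiopanError,
    ValidationError,
    get_logger,
)

log = get_logger(__name__)

__all__ = [
    "PangenomeSummary",
    "AccumulationCurve",
    "ChiSquareResult",
    "partition_gene_families",
    "accumulation_curve",
    "gene_class_lifestyle_chisq",
]

CLASSES = ("core", "accessory", "unique")


@dataclass
class PangenomeSummary:
    n_core: int
    n_accessory: int
    n_unique: int
    pct_core: float
    pct_accessory: float
    pct_unique: float
    core_threshold: float
    subset_label: str
    #: family -> class, for downstream filtering
    classification: dict[str, str] = field(repr=False, default_factory=dict)
    #: genomes the summary was computed on
    genomes: list[str] = field(repr=False, default_factory=list)

    @property
    def total(self) -> int:
        return self.n_core + self.n_accessory + self.n_unique


def _percentages(counts: tuple[int, int, int]) -> tuple[float, float, float]:
    total = sum(counts)
    return tuple(round(100.0 * c / total, 2) for c in counts)


def summary_from_counts(
    n_core: int,
    n_accessory: int,
    n_unique: int,
    core_threshold: float = 0.95,
    subset_label: str = "all",
) -> PangenomeSummary:
    """Build a summary directly from class counts (percentages to 2 decimals)."""
    if n_core + n_accessory + n_unique == 0:
        raise ValidationError("empty pangenome summary")
    pc, pa, pu = _percentages((n_core, n_accessory, n_unique))
    return PangenomeSummary(
        n_core, n_accessory, n_unique, pc, pa, pu, core_threshold, subset_label
    )


def partition_gene_families(
    m: GeneFamilyMatrix,
    core_threshold: float = 0.95,
    subset: list[str] | None = None,
    subset_label: str = "all",
) -> PangenomeSummary:
    """Classify every family present in the (sub)pangenome as core, accessory,
    or unique by prevalence: unique = present in exactly 1 genome, core =
    prevalence strictly > ``core_threshold``, accessory = the rest."""
    if subset is not None:
        if len(subset) < 2:
            raise ValidationError("subset must contain at least 2 genomes")
        m = m.subset_genomes(subset)
    n_genomes = len(m.genomes)
    if n_genomes < 2:
        raise ValidationError("need at least 2 genomes")
    counts = m.presence.sum(axis=1)
    classification: dict[str, str] = {}
    for fam, c in zip(m.families, counts):
        if c == 1:
            classification[fam] = "unique"
        elif c / n_genomes > core_threshold:
            classification[fam] = "core"
        else:
            classification[fam] = "accessory"
    tallies = {cls: sum(1 for v in classification.values() if v == cls) for cls in CLASSES}
    summary = summary_from_counts(
        tallies["core"], tallies["accessory"], tallies["unique"],
        core_threshold, subset_label,
    )
    summary.classification = classification
    summary.genomes = list(m.genomes)
    log.info(
        "partition_gene_families[%s]: %d core (%.2f%%), %d accessory (%.2f%%), "
        "%d unique (%.2f%%) over %d genomes",
        subset_label, summary.n_core, summary.pct_core, summary.n_accessory,
        summary.pct_accessory, summary.n_unique, summary.pct_unique, n_genomes,
    )
    return summary


@dataclass
class AccumulationCurve:
    n_genomes_axis: np.ndarray
    mean_families: np.ndarray
    sd_families: np.ndarray
    n_permutations: int
    seed: int
    heaps_kappa: float
    heaps_gamma: float
    open_pangenome: bool


def accumulation_curve(
    m: GeneFamilyMatrix,
    n_permutations: int = 100,
    seed: int = 0,
    family_filter: str = "all",
    gamma_threshold: float = 0.02,
    exhaustive: bool = False,
) -> AccumulationCurve:
    """Rarefaction of distinct gene families over random genome orderings.

    ``family_filter="accessory_only"`` restricts to families classified
    accessory on the full matrix before permuting.  ``exhaustive=True``
    enumerates all n! genome orderings instead of sampling (only sensible
    for small matrices).  Openness is decided from a Heaps-law fit
    log(mean) = log(kappa) + gamma*log(N) over N >= 3: the pangenome is
    called open when gamma exceeds ``gamma_threshold`` and new families are
    still gained, on average, by the last genome added.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if family_filter == "accessory_only":
        summary = partition_gene_families(m)
        keep = [f for f in m.families if summary.classification[f] == "accessory"]
        if not keep:
            raise ValidationError("no accessory families to accumulate")
        idx = [m.families.index(f) for f in keep]
        presence = m.presence[idx]
    elif family_filter == "all":
        presence = m.presence
    else:
        raise ValueError(f"unknown family_filter {family_filter!r}")

    n_genomes = presence.shape[1]
    if exhaustive:
        import itertools

        if n_genomes > 8:
            raise ValidationError("exhaustive enumeration only for <= 8 genomes")
        orders = list(itertools.permutations(range(n_genomes)))
        n_permutations = len(orders)
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(n_genomes) for _ in range(n_permutations)]
    curves = np.empty((n_permutations, n_genomes), dtype=np.int64)
    for p, order in enumerate(orders):
        seen = np.zeros(presence.shape[0], dtype=bool)
        for k, g in enumerate(order):
            seen |= presence[:, g].astype(bool)
            curves[p, k] = seen.sum()
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=0)
    axis = np.arange(1, n_genomes + 1)

    fit_mask = axis >= 3
    if fit_mask.sum() >= 2 and (mean[fit_mask] > 0).all():
        slope, intercept = np.polyfit(
            np.log(axis[fit_mask]), np.log(mean[fit_mask]), 1
        )
        gamma, kappa = float(slope), float(np.exp(intercept))
    else:
        gamma, kappa = 0.0, float(mean[0]) if len(mean) else 0.0
    gained_last = float(mean[-1] - mean[-2]) if n_genomes >= 2 else 0.0
    is_open = bool(gamma > gamma_threshold and gained_last > 0)
    log.info(
        "accumulation_curve[%s]: final=%d families, gamma=%.4f, open=%s",
        family_filter, int(mean[-1]), gamma, is_open,
    )
    return AccumulationCurve(
        axis, mean, sd, n_permutations, seed, kappa, gamma, is_open
    )


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    table: np.ndarray  # 2 x 3, lifestyle x (core, accessory, unique)


def gene_class_lifestyle_chisq(
    host_summary: PangenomeSummary, free_summary: PangenomeSummary
) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction) on the 2x3 table of
    gene-class counts for the two lifestyle-restricted pangenomes."""
    table = np.array(
        [
            [host_summary.n_core, host_summary.n_accessory, host_summary.n_unique],
            [free_summary.n_core, free_summary.n_accessory, free_summary.n_unique],
        ],
        dtype=np.int64,
    )
    if (table.sum(axis=1) == 0).any():
        raise ValidationError("both summaries need positive totals")
    expected = stats.contingency.expected_freq(table)
    if (expected < 1).any():
        log.warning("chi-square: expected cell count below 1; result may be unstable")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    log.info("gene_class_lifestyle_chisq: X2=%.4f df=%d p=%.3g", stat, df, p)
    return ChiSquareResult(float(stat), int(df), float(p), table)
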