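"""Pangenome-wide association of gene presence/absence with a binary trait.

Each gene family is tested against the trait (e.g. host-associated vs.
free-living lifestyle) with a two-sided Fisher's exact test — summing all
2x2 tables with point hypergeometric probability at most that of the
observed table — plus an odds ratio (Haldane +0.5 correction when any cell
is zero) and a Bonferroni-adjusted p-value.  A hit passes when its raw p is
below alpha (default 0.05) and its Bonferroni p is at most the family-wise
error cutoff (default 0.99).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import GeneFamilyMatrix, ValidationError, get_logger

log = get_logger(__name__)

__all__ = ["PangwasHit", "fisher_association", "odds_ratio", "fisher_exact_p"]


@dataclass
class PangwasHit:
    family_id: str
    table: tuple[int, int, int, int]  # (present+trait, present-trait, absent+trait, absent-trait)
    odds_ratio: float
    p_value: float
    p_bonferroni: float
    passes: bool


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c), with +0.5 added to every cell when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a,b],[c,d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_association(
    m: GeneFamilyMatrix,
    trait: dict[str, bool],
    clade_filter: list[str] | None = None,
    alpha: float = 0.05,
    fwer_cutoff: float = 0.99,
) -> list[PangwasHit]:
    """Per-family Fisher's exact association between presence and trait.

    ``trait`` maps every genome to a boolean phenotype; ``clade_filter``
    restricts the test to a genome subset (e.g. one pigmentation clade).
    Families constant across the tested genomes are skipped and excluded
    from the Bonferroni denominator.  Hits are ordered by ascending p,
    ties broken by family ID.
    """
    genomes = list(m.genomes)
    if clade_filter is not None:
        unknown = set(clade_filter) - set(genomes)
        if unknown:
            raise ValidationError(f"clade_filter genomes not in matrix: {sorted(unknown)}")
        genomes = [g for g in genomes if g in set(clade_filter)]
    missing = [g for g in genomes if g not in trait]
    if missing:
        raise ValidationError(f"trait missing for genomes: {sorted(missing)[:5]}")
    y = np.array([bool(trait[g]) for g in genomes])
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValidationError("need at least 2 genomes per trait class")
    cols = [m.genomes.index(g) for g in genomes]
    X = m.presence[:, cols].astype(bool)

    candidates = []
    for i, fam in enumerate(m.families):
        x = X[i]
        if x.all() or not x.any():
            continue  # constant family carries no information
        a = int((x & y).sum())
        b = int((x & ~y).sum())
        c = int((~x & y).sum())
        d = int((~x & ~y).sum())
        candidates.append((fam, a, b, c, d))

    n_tested = len(candidates)
    hits = []
    for fam, a, b, c, d in candidates:
        p = fisher_exact_p(a, b, c, d)
        p_bonf = min(1.0, p * n_tested)
        hits.append(
            PangwasHit(
                family_id=fam,
                table=(a, b, c, d),
                odds_ratio=odds_ratio(a, b, c, d),
                p_value=p,
                p_bonferroni=p_bonf,
                passes=bool(p < alpha and p_bonf <= fwer_cutoff),
            )
        )
    hits.sort(key=lambda h: (h.p_value, h.family_id))
    log.info(
        "fisher_association: %d families tested, %d pass (alpha=%.3g, FWER<=%.3g)",
        n_tested, sum(h.passes for h in hits), alpha, fwer_cutoff,
    )
    return hits
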