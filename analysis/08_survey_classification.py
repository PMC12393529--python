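#!/usr/bin/env python
"""Re-derive the published survey's classification table from its printed
statistics.

The marine-invertebrate phylosymbiosis survey this pipeline re-implements
prints, per host clade, the PACo permutation p, the Procrustes residual
m2, and a generalized RF distance.  Feeding those printed numbers through
R2 = 1 - m2 and the default classification thresholds (alpha 0.05, high
signal at R2 >= 0.20, congruence at R2 > 0.25) reproduces its R2 column
and every signal/congruence label; the one printed R2 that disagrees
(0.34 vs 1 - 0.65 = 0.35) is a rounding inconsistency in the source.
"""

from pathlib import Path

import pandas as pd

from symbiopan.cophylogeny import classify_phylosymbiosis

BASE = Path(__file__).resolve().parent.parent / "results"

SURVEY_ROWS = [
    ("Animalia", 0.00, 0.93, 0.85, 0.07, "low", "none"),
    ("Mollusca", 0.01, 0.60, 0.60, 0.40, "high", "weak"),
    ("Cnidaria", 0.01, 0.89, 0.85, 0.11, "low", "none"),
    ("Porifera", 0.47, 0.86, 0.93, 0.14, "none", "none"),
    ("Nematoda", 0.00, 0.80, None, 0.20, "high", "none"),
    ("Bivalvia", 0.01, 0.65, 0.75, 0.34, "high", "weak"),
    ("Faviidae", 0.03, 0.59, 0.73, 0.41, "high", "weak"),
]


def main() -> None:
    rows = []
    for clade, p, m2, rf, r2_printed, signal, congruence in SURVEY_ROWS:
        call = classify_phylosymbiosis(p, 1 - m2, rf)
        rows.append({
            "clade": clade, "p": p, "m2": m2, "r2_computed": round(1 - m2, 2),
            "r2_printed": r2_printed, "rf": rf,
            "signal_computed": call.signal, "signal_printed": signal,
            "congruence_computed": call.congruence, "congruence_printed": congruence,
        })
    df = pd.DataFrame(rows)
    df.to_csv(BASE / "survey_classification.tsv", sep="\t", index=False)
    labels_ok = (
        (df.signal_computed == df.signal_printed)
        & (df.congruence_computed == df.congruence_printed)
    ).sum()
    r2_ok = (df.r2_computed == df.r2_printed).sum()
    print(df.to_string(index=False))
    print(f"\nlabel pairs reproduced: {labels_ok}/7; R2 values matched: {r2_ok}/7 "
          "(the Bivalvia row is the documented rounding inconsistency)")


if __name__ == "__main__":
    main()
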