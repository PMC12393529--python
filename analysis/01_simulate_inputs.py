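#!/usr/bin/env python
"""Generate the synthetic study inputs every later step consumes.

Writes, under results/simulated/: a host tree, a symbiont tree and its
host association (moderate host switching, some multi-association), a
presence/absence gene-family matrix with planted lifestyle-associated
genes, a block-structured ANI matrix, and single-host read-recruitment
counts over clade-block genome sets.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from symbiopan.io_formats import (
    write_association,
    write_gene_matrix,
    write_metadata,
    write_read_counts,
    write_square_matrix,
    write_tree,
)
from symbiopan.synthetic import (
    CophyloSimConfig,
    PangenomeSimConfig,
    block_association,
    simulate_ani,
    simulate_cophylogeny,
    simulate_pangenome,
    simulate_read_counts,
    yule_tree,
)

SEED = 20240901
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    host, symb, assoc = simulate_cophylogeny(
        CophyloSimConfig(
            n_hosts=16, switch_prob=0.3, loss_prob=0.05,
            multi_assoc_rate=0.5, seed=SEED,
        )
    )
    write_tree(host, OUT / "host.nwk")
    write_tree(symb, OUT / "symbiont.nwk")
    write_association(assoc, OUT / "assoc.csv")
    print(f"cophylogeny: {len(assoc.hosts)} hosts, {len(assoc.symbionts)} symbionts")

    matrix, meta = simulate_pangenome(
        PangenomeSimConfig(
            n_genomes=60, n_core=40, n_accessory=250, n_trait_genes=15,
            trait_odds_ratio=8.0, unique_per_genome_mean=3.0,
            lifestyle_fraction=0.6, seed=SEED + 1,
        )
    )
    write_gene_matrix(matrix, OUT / "gene_matrix.rtab")
    write_metadata(meta, OUT / "metadata.tsv")
    print(f"pangenome: {len(matrix.families)} families x {len(matrix.genomes)} genomes")

    rng = np.random.default_rng(SEED + 2)
    blocks = [(int(rng.integers(2, 9)), float(rng.uniform(0.965, 0.985)))
              for _ in range(12)]
    ani, _ = simulate_ani(blocks, between_sim=0.85, noise_sd=0.003, seed=SEED + 2)
    write_square_matrix(ani, OUT / "ani.tsv")
    print(f"ani: {ani.n} genomes in {len(blocks)} planted blocks")

    reads_host, _ = yule_tree(16, 1.0, np.random.default_rng(SEED + 3))
    write_tree(reads_host, OUT / "reads_host.nwk")
    reads_assoc = block_association(reads_host, 4, 3)
    table, s2h = simulate_read_counts(
        reads_host, reads_assoc, depth_mean=0.5, enrichment=200.0, seed=SEED + 3
    )
    write_read_counts(table, OUT / "reads")
    pd.Series(s2h, name="host").rename_axis("sample").to_csv(
        OUT / "reads.sample_hosts.tsv", sep="\t"
    )
    print(f"reads: {len(table.samples)} samples x {len(table.genomes)} genomes")


if __name__ == "__main__":
    main()
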