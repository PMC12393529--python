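"""End-to-end pipeline orchestration with a single YAML config.

Stages run in dependency order (simulate -> pangenome -> phylogroups ->
network -> cophylogeny -> pangwas -> profiles); a run manifest records the
config snapshot, per-stage seeds, output paths, and SHA-256 digests so a
re-run with the same manifest reproduces byte-identical outputs.  A
top-level ``seed`` is mandatory whenever any randomized stage is requested:
there is no silent nondeterminism.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cophylogeny import classify_phylosymbiosis, congruence_rf, paco, patristic_distances
from .io_formats import (
    DEFAULT_CONFIG,
    SymbiopanError,
    get_logger,
    load_config,
    read_association,
    read_gene_matrix,
    read_metadata,
    read_read_counts,
    read_square_matrix,
    read_tree,
    write_association,
    write_gene_matrix,
    write_metadata,
    write_read_counts,
    write_square_matrix,
    write_tree,
)
from .network import (
    build_network,
    export_edge_list,
    export_graphml,
    filter_accessory,
    genome_similarity,
    label_assortativity,
)
from .pangenome import (
    accumulation_curve,
    gene_class_lifestyle_chisq,
    partition_gene_families,
)
from .pangwas import fisher_association
from .phylogroups import ani_cluster, phylogroup_composition
from .profiles import bray_curtis, compute_rpkm, profile_concordance, upgma
from .synthetic import (
    CophyloSimConfig,
    PangenomeSimConfig,
    simulate_ani,
    simulate_cophylogeny,
    simulate_pangenome,
    simulate_read_counts,
)

log = get_logger(__name__)

__all__ = ["RunManifest", "run_pipeline"]

#: fixed per-stage offsets applied to the master seed, recorded in the manifest
STAGE_SEED_OFFSETS = {
    "simulate": 11,
    "pangenome": 23,
    "cophylogeny": 37,
    "profiles": 53,
}

ALL_STAGES = [
    "simulate", "pangenome", "phylogroups", "network",
    "cophylogeny", "pangwas", "profiles",
]


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int]
    outputs: dict[str, str]  # relative path -> sha256
    version: str = ""
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> RunManifest:
    """Execute the stages requested in the config and write a run manifest."""
    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = load_config()  # stage-threshold defaults
    for k, v in raw.items():
        if k in cfg and isinstance(v, dict):
            cfg[k] = {**cfg[k], **v}
        else:
            cfg[k] = v
    stages = cfg.get("stages", ALL_STAGES)
    master_seed = cfg.get("seed")
    needs_seed = any(s in STAGE_SEED_OFFSETS for s in stages)
    if needs_seed and master_seed is None:
        raise SymbiopanError("config must set a top-level 'seed' for randomized stages")
    seeds = {
        s: int(master_seed) + off
        for s, off in STAGE_SEED_OFFSETS.items()
        if s in stages
    }

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seeds=seeds, outputs={}, version=__version__)
    state: dict = {}

    def record(path: Path) -> None:
        manifest.outputs[str(path.relative_to(out))] = _sha256(path)

    try:
        for stage in stages:
            runner = _STAGE_RUNNERS[stage]
            for path in runner(cfg, seeds.get(stage), out, state):
                record(path)
    except Exception:
        manifest.failed_stage = stage
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    log.info("run_pipeline: %d stages complete, outputs in %s", len(stages), out)
    return manifest


# ---------------------------------------------------------------------------
# stage runners: each yields the paths it wrote
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, seed, out, state):
    block = cfg.get("simulate", {})
    written = []
    co = block.get("cophylogeny")
    if co is not None:
        host, symb, assoc = simulate_cophylogeny(
            CophyloSimConfig(**{**co, "seed": seed})
        )
        state.update(host_tree=host, symb_tree=symb, assoc=assoc)
        for name, writer, obj in [
            ("host.nwk", write_tree, host),
            ("symbiont.nwk", write_tree, symb),
        ]:
            writer(obj, out / name)
            written.append(out / name)
        write_association(assoc, out / "assoc.csv")
        written.append(out / "assoc.csv")
    pg = block.get("pangenome")
    if pg is not None:
        matrix, meta = simulate_pangenome(
            PangenomeSimConfig(**{**pg, "seed": seed + 1})
        )
        state.update(gene_matrix=matrix, metadata=meta)
        write_gene_matrix(matrix, out / "gene_matrix.rtab")
        write_metadata(meta, out / "metadata.tsv")
        written += [out / "gene_matrix.rtab", out / "metadata.tsv"]
    ani = block.get("ani")
    if ani is not None:
        blocks = [tuple(b) for b in ani["blocks"]]
        mat, truth = simulate_ani(
            blocks, ani["between_sim"], ani.get("noise_sd", 0.0), seed + 2
        )
        state.update(ani=mat, ani_truth=truth)
        write_square_matrix(mat, out / "ani.tsv")
        written.append(out / "ani.tsv")
    reads = block.get("reads")
    if reads is not None:
        table, s2h = simulate_read_counts(
            state["host_tree"], state["assoc"],
            reads["depth_mean"], reads["enrichment"], seed + 3,
        )
        state.update(read_counts=table, sample_to_host=s2h)
        write_read_counts(table, out / "reads")
        pd.Series(s2h, name="host").rename_axis("sample").to_csv(
            out / "reads.sample_hosts.tsv", sep="\t"
        )
        written += [
            out / "reads.counts.tsv", out / "reads.genomes.tsv",
            out / "reads.samples.tsv", out / "reads.sample_hosts.tsv",
        ]
    return written


def _load_matrix(cfg, state):
    if "gene_matrix" not in state:
        state["gene_matrix"] = read_gene_matrix(
            cfg["inputs"]["gene_matrix"],
            cfg["inputs"].get("gene_matrix_dialect", "rtab"),
        )
        state["metadata"] = read_metadata(cfg["inputs"]["metadata"])
    return state["gene_matrix"], state["metadata"]


def _stage_pangenome(cfg, seed, out, state):
    block = cfg["pangenome"]
    m, meta = _load_matrix(cfg, state)
    ha = [x.genome_id for x in meta if x.lifestyle == "host_associated"]
    fl = [x.genome_id for x in meta if x.lifestyle == "free_living"]
    thr = block["core_threshold"]
    summaries = {"all": partition_gene_families(m, thr, subset_label="all")}
    if len(ha) >= 2:
        summaries["host_associated"] = partition_gene_families(
            m, thr, subset=ha, subset_label="host_associated"
        )
    if len(fl) >= 2:
        summaries["free_living"] = partition_gene_families(
            m, thr, subset=fl, subset_label="free_living"
        )
    state["pangenome_summaries"] = summaries
    rows = [
        {
            "subset": s.subset_label, "n_core": s.n_core,
            "n_accessory": s.n_accessory, "n_unique": s.n_unique,
            "pct_core": s.pct_core, "pct_accessory": s.pct_accessory,
            "pct_unique": s.pct_unique,
        }
        for s in summaries.values()
    ]
    pd.DataFrame(rows).to_csv(out / "pangenome_summary.tsv", sep="\t", index=False)
    written = [out / "pangenome_summary.tsv"]
    if "host_associated" in summaries and "free_living" in summaries:
        chi = gene_class_lifestyle_chisq(
            summaries["host_associated"], summaries["free_living"]
        )
        pd.DataFrame(
            [{"statistic": chi.statistic, "df": chi.df, "p_value": chi.p_value}]
        ).to_csv(out / "pangenome_chisq.tsv", sep="\t", index=False)
        written.append(out / "pangenome_chisq.tsv")
    curve = accumulation_curve(
        m,
        n_permutations=block["accumulation_permutations"],
        seed=seed,
        gamma_threshold=block["openness_gamma_threshold"],
    )
    pd.DataFrame(
        {
            "n_genomes": curve.n_genomes_axis,
            "mean_families": curve.mean_families,
            "sd_families": curve.sd_families,
        }
    ).to_csv(out / "accumulation_curve.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{
            "heaps_kappa": curve.heaps_kappa, "heaps_gamma": curve.heaps_gamma,
            "open_pangenome": curve.open_pangenome,
        }]
    ).to_csv(out / "openness.tsv", sep="\t", index=False)
    written += [out / "accumulation_curve.tsv", out / "openness.tsv"]
    return written


def _stage_phylogroups(cfg, seed, out, state):
    block = cfg["phylogroups"]
    if "ani" not in state:
        state["ani"] = read_square_matrix(cfg["inputs"]["ani"], "similarity")
    assign = ani_cluster(state["ani"], block["ani_threshold"], block["linkage"])
    state["phylogroups"] = assign
    pd.Series(assign.assignment, name="phylogroup").rename_axis("genome_id").to_csv(
        out / "phylogroups.tsv", sep="\t"
    )
    written = [out / "phylogroups.tsv"]
    meta = state.get("metadata")
    if meta is not None and all(
        g in {m.genome_id for m in meta} for g in assign.assignment
    ):
        comp = phylogroup_composition(assign, meta)
        pd.DataFrame([vars(comp)]).to_csv(
            out / "phylogroup_composition.tsv", sep="\t", index=False
        )
        written.append(out / "phylogroup_composition.tsv")
    return written


def _stage_network(cfg, seed, out, state):
    block = cfg["network"]
    m, meta = _load_matrix(cfg, state)
    summary = state.get("pangenome_summaries", {}).get("all") or partition_gene_families(
        m, cfg["pangenome"]["core_threshold"]
    )
    acc = filter_accessory(m, summary, block["prevalence_filter"])
    sim = genome_similarity(acc, block["similarity_metric"])
    net = build_network(
        sim, block["edge_threshold"], meta, state.get("phylogroups")
    )
    export_graphml(net, out / "network.graphml")
    export_edge_list(net, out / "network_edges.tsv")
    rows = []
    for label in ("lifestyle", "phylogroup"):
        if net.number_of_edges() and all(
            net.nodes[v].get(label) is not None for v in net.nodes
        ):
            rows.append(
                {"label": label, "assortativity": label_assortativity(net, label)}
            )
    pd.DataFrame(rows).to_csv(out / "assortativity.tsv", sep="\t", index=False)
    return [out / "network.graphml", out / "network_edges.tsv", out / "assortativity.tsv"]


def _stage_cophylogeny(cfg, seed, out, state):
    block = cfg["cophylogeny"]
    if "host_tree" not in state:
        state["host_tree"] = read_tree(cfg["inputs"]["host_tree"])
        state["symb_tree"] = read_tree(cfg["inputs"]["symbiont_tree"])
        state["assoc"] = read_association(cfg["inputs"]["association"])
    host, symb, assoc = state["host_tree"], state["symb_tree"], state["assoc"]
    res = paco(
        patristic_distances(host), patristic_distances(symb), assoc,
        n_permutations=block["n_permutations"],
        scheme=block["permutation_scheme"],
        seed=seed,
        correction=block["pcoa_correction"],
    )
    rf = congruence_rf(host, symb, assoc, block["n_subsamples"], seed + 1)
    call = classify_phylosymbiosis(
        res.p_value, res.r2, rf.distance,
        alpha=block["alpha"],
        r2_high_threshold=block["r2_high_threshold"],
        r2_congruence_threshold=block["r2_congruence_threshold"],
        r2_strong_threshold=block["r2_strong_threshold"],
        rf_gate=block["rf_gate"],
    )
    pd.DataFrame(
        [{
            "p_value": res.p_value, "m2": res.m2, "r2": res.r2,
            "generalized_rf": rf.distance, "signal": call.signal,
            "congruence": call.congruence, "n_permutations": res.n_permutations,
            "permutation_scheme": res.permutation_scheme,
            "alpha": call.alpha, "r2_high_threshold": call.r2_high_threshold,
            "r2_congruence_threshold": call.r2_congruence_threshold,
        }]
    ).to_csv(out / "phylosymbiosis.tsv", sep="\t", index=False)
    return [out / "phylosymbiosis.tsv"]


def _stage_pangwas(cfg, seed, out, state):
    block = cfg["pangwas"]
    m, meta = _load_matrix(cfg, state)
    trait = {x.genome_id: x.lifestyle == "host_associated" for x in meta}
    hits = fisher_association(
        m, trait, alpha=block["alpha"], fwer_cutoff=block["fwer_cutoff"]
    )
    pd.DataFrame(
        [{
            "family_id": h.family_id, "odds_ratio": h.odds_ratio,
            "p_value": h.p_value, "p_bonferroni": h.p_bonferroni,
            "passes": h.passes,
        } for h in hits]
    ).to_csv(out / "pangwas_hits.tsv", sep="\t", index=False)
    return [out / "pangwas_hits.tsv"]


def _stage_profiles(cfg, seed, out, state):
    block = cfg["profiles"]
    if "read_counts" not in state:
        state["read_counts"] = read_read_counts(cfg["inputs"]["reads_prefix"])
        s2h = pd.read_csv(
            cfg["inputs"]["sample_hosts"], sep="\t", index_col=0
        )["host"].to_dict()
        state["sample_to_host"] = s2h
    profile = compute_rpkm(
        state["read_counts"], block["rpkm_threshold"], state["sample_to_host"]
    )
    pd.DataFrame(
        profile.values, index=profile.samples, columns=profile.genomes
    ).to_csv(out / "rpkm.tsv", sep="\t", index_label="sample")
    bc = bray_curtis(profile)
    write_square_matrix(bc, out / "bray_curtis.tsv")
    write_tree(upgma(bc), out / "profile_dendrogram.nwk")
    res = profile_concordance(
        state["host_tree"], profile, block["n_permutations"], seed
    )
    pd.DataFrame(
        [{
            "p_value": res.p_value, "m2": res.m2, "r2": res.r2,
            "n_permutations": res.n_permutations,
        }]
    ).to_csv(out / "profile_paco.tsv", sep="\t", index=False)
    return [
        out / "rpkm.tsv", out / "bray_curtis.tsv",
        out / "profile_dendrogram.nwk", out / "profile_paco.tsv",
    ]


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "pangenome": _stage_pangenome,
    "phylogroups": _stage_phylogroups,
    "network": _stage_network,
    "cophylogeny": _stage_cophylogeny,
    "pangwas": _stage_pangwas,
    "profiles": _stage_profiles,
}
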