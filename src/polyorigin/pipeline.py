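"""End-to-end orchestration: simulate (or ingest) -> genotype ->
concordance -> merge/filter -> IBS/PCA -> tree -> origin report.

The single entry point :func:`run_pipeline` consumes one configuration
dict (typically loaded from YAML), runs every stage deterministically
under the configured seed, persists each stage's outputs under the run
directory, and returns a machine-readable *origin report*: for every
dissected subgenome tip, its nearest wild relatives by IBS, the clade it
falls in on the bootstrap tree with that edge's support, and its
principal-component coordinates, alongside the filter and concordance
tables and run metadata.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict

import pandas as pd
import yaml

from . import __version__
from .concordance import concordance
from .panel import (
    FilterConfig,
    merge_panels,
    pseudosequences,
    run_filter_pipeline,
    write_calls,
    write_pseudo_fasta,
)
from .phylogeny import TreeConfig, bootstrap_support, find_sister, write_newick, _tip_sets
from .probes import AlignConfig, genotype_genome, partition_by_prefix, single_partition, write_probes
from .relatedness import encode_dosage, euclidean_distances, ibs_matrix, nearest_neighbors, pcoa, select_pcs
from .simulate import SimulationConfig, genome_to_bytes, simulate_panel, write_fasta, write_truth
from .windows import WindowConfig, classify_lineage_specific, max_variant_span, restrict_to_regions, window_counts

_REQUIRED_FIELDS = ("seed",)


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> None:
    for key in _REQUIRED_FIELDS:
        if key not in config:
            raise ValueError(f"missing required config field: {key}")
    if "simulation" not in config and "inputs" not in config:
        raise ValueError("missing required config field: simulation (or inputs)")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def origin_clade(tree, focal_tips, query_tips) -> tuple[frozenset, float | None]:
    """Smallest bipartition side containing the focal tips plus at least
    one non-query tip, with that edge's support.

    This is the 'origin clade' readout: the wild accessions sharing the
    shallowest well-defined edge with the dissected subgenome tips.
    """
    focal = frozenset(focal_tips)
    queries = frozenset(query_tips)
    _tip_sets(tree)
    all_tips = tree._tipset
    best = None
    best_node = None
    for node in tree.traverse(include_self=False):
        for side in (node._tipset, all_tips - node._tipset):
            if focal <= side and side != all_tips and (side - queries):
                if best is None or len(side) < len(best):
                    best, best_node = side, node
    if best is None:
        raise ValueError("no containing clade found")
    return best, getattr(best_node, "support", None)


def run_pipeline(config: dict, outdir: str) -> dict:
    """Run the full analysis; returns the origin report (also written to
    ``<outdir>/origin_report.json``)."""
    validate_config(config)
    os.makedirs(outdir, exist_ok=True)
    seed = int(config["seed"])
    align_cfg = AlignConfig(**config.get("align", {}))
    filter_cfg = FilterConfig(**config.get("filters", {}))
    tree_cfg = TreeConfig(
        n_resamples=int(config.get("tree", {}).get("n_resamples", 1000)),
        seed=seed,
    )
    pca_threshold = float(config.get("pca", {}).get("variance_threshold", 80))

    report: dict = {
        "metadata": {
            "seed": seed,
            "config_hash": config_hash(config),
            "version": __version__,
        }
    }

    if "simulation" in config:
        sim_cfg = SimulationConfig(seed=seed, **(config.get("simulation") or {}))
        genomes, probes, array_calls, truth = simulate_panel(sim_cfg)
        genome_dir = os.path.join(outdir, "genomes")
        os.makedirs(genome_dir, exist_ok=True)
        for sample, genome in genomes.items():
            write_fasta(genome, os.path.join(genome_dir, f"{sample}.fasta"))
        write_probes(probes, os.path.join(outdir, "probes.tsv"))
        write_calls(array_calls, os.path.join(outdir, "array_calls.tsv"))
        write_truth(truth, os.path.join(outdir, "truth"))
        tet_ids = [s for s in genomes if s.startswith("tet")]
        tet_genomes = {t: genome_to_bytes(genomes[t]) for t in tet_ids}
        diploid_ids = [c for c in array_calls.columns]
        n_conc = int(config.get("concordance", {}).get("n_insilico_diploids", 5))
        conc_samples = diploid_ids[:n_conc]
        conc_genomes = {s: genome_to_bytes(genomes[s]) for s in conc_samples}
    else:
        raise NotImplementedError(
            "ingest mode: supply pre-computed call matrices via the CLI "
            "subcommands; the orchestrated pipeline runs on simulated panels"
        )

    # in-silico genotyping of the tetraploids, dissected by subgenome
    addition_cols = []
    for tid in tet_ids:
        partition = partition_by_prefix(list(tet_genomes[tid]))
        addition_cols.append(
            genotype_genome(probes, tet_genomes[tid], partition, align_cfg, sample_id=tid)
        )
    additions = pd.concat(addition_cols, axis=1)
    write_calls(additions, os.path.join(outdir, "insilico_tetraploid_calls.tsv"))

    # concordance: in-silico assembly calls vs array calls, same accessions
    conc_rows = []
    for sample in conc_samples:
        insilico = genotype_genome(
            probes,
            conc_genomes[sample],
            single_partition(list(conc_genomes[sample]), "D"),
            align_cfg,
            sample_id=sample,
        )
        rep = concordance(insilico[f"{sample}_D"], array_calls[sample])
        conc_rows.append(
            {
                "sample": sample,
                "n_shared": rep.n_shared_markers,
                "n_compared": rep.n_compared,
                "n_matching": rep.n_matching,
                "percent": rep.percent,
            }
        )
    conc_table = pd.DataFrame(conc_rows)
    conc_table.to_csv(os.path.join(outdir, "concordance.tsv"), sep="\t", index=False)
    report["concordance"] = conc_rows

    # merge and three-step filter
    merged = merge_panels(array_calls, additions)
    filtered, filter_report = run_filter_pipeline(merged, filter_cfg)
    write_calls(filtered, os.path.join(outdir, "filtered_calls.tsv"))
    report["filter_report"] = filter_report.as_dict()

    # IBS nearest neighbors for the dissected tips
    tet_tips = list(additions.columns)
    sim = ibs_matrix(filtered)
    sim.to_frame().to_csv(os.path.join(outdir, "ibs_similarity.tsv"), sep="\t")
    ranks = nearest_neighbors(sim, tet_tips)
    ranks.to_csv(os.path.join(outdir, "nearest_neighbors.tsv"), sep="\t", index=False)

    # PCA
    dosage, _ = encode_dosage(filtered)
    ids, dist = euclidean_distances(dosage)
    pca = pcoa(ids, dist)
    n_pcs = select_pcs(pca, pca_threshold)
    pca.coordinates.to_csv(os.path.join(outdir, "pca_scores.tsv"), sep="\t")
    report["pca"] = {
        "variance_percent": [round(float(v), 4) for v in pca.variance_percent[:10]],
        "n_selected_pcs": n_pcs,
        "tip_coordinates": {
            t: [round(float(x), 6) for x in pca.coordinates.loc[t][:n_pcs]]
            for t in tet_tips
        },
    }

    # bootstrap NJ tree over pseudosequences
    pseudo = pseudosequences(filtered)
    write_pseudo_fasta(filtered, os.path.join(outdir, "pseudosequences.fasta"))
    tree = bootstrap_support(pseudo, tree_cfg)
    write_newick(tree, os.path.join(outdir, "tree.nwk"))

    # per-subgenome origin readout
    subgenomes: dict[str, dict] = {}
    labels = sorted({t.rsplit("_", 1)[1] for t in tet_tips})
    for label in labels:
        tips = [t for t in tet_tips if t.endswith(f"_{label}")]
        top = ranks[ranks["query"].isin(tips) & (ranks["rank"] <= 5)]
        clade, support = origin_clade(tree, tips, tet_tips)
        entry = {
            "tips": tips,
            "nearest_neighbors": {
                t: [
                    {"neighbor": r.neighbor, "similarity": round(float(r.similarity), 6)}
                    for r in top[top["query"] == t].itertuples()
                ]
                for t in tips
            },
            "origin_clade": {
                "wild_members": sorted(clade - set(tet_tips)),
                "support": None if support is None else round(float(support), 4),
            },
        }
        try:
            sister, s_support = find_sister(tree, tips)
            entry["sister"] = {
                "tips": sorted(sister),
                "support": None if s_support is None else round(float(s_support), 4),
            }
        except ValueError:
            entry["sister"] = None
        if truth is not None:
            parent = truth.parent_a_id if label == "A" else truth.parent_b_id
            entry["true_parent"] = parent
            entry["parent_recovered_by_ibs"] = all(
                ranks[(ranks["query"] == t) & (ranks["rank"] == 1)]["neighbor"].iloc[0]
                == parent
                for t in tips
            )
        subgenomes[label] = entry
    report["subgenomes"] = subgenomes

    # lineage-specific variants of the truth VCF in windows
    if truth is not None and truth.true_variants:
        win_cfg = config.get("windows", {})
        fine_size = int(win_cfg.get("fine_size", 100_000))
        coarse_size = int(win_cfg.get("coarse_size", 2_000_000))
        lineages = truth.variant_lineages
        var_report: dict = {"lineages": lineages, "counts": {}}
        for focal, other in (lineages, lineages[::-1]):
            specific = classify_lineage_specific(truth.true_variants, focal, other)
            fine = window_counts(
                specific, WindowConfig(fine_size, truth.chrom_lengths)
            )
            fine.to_csv(
                os.path.join(outdir, f"windows_{focal}_{fine_size}.tsv"),
                sep="\t",
                index=False,
            )
            coarse = window_counts(
                specific, WindowConfig(coarse_size, truth.chrom_lengths)
            )
            genic = restrict_to_regions(specific, truth.genic_bed)
            var_report["counts"][focal] = {
                "lineage_specific": len(specific),
                "genic_lineage_specific": len(genic),
                "coarse_window_total": int(coarse["count"].sum()),
            }
        var_report["max_variant_span"] = max_variant_span(truth.true_variants)
        report["variants"] = var_report

    with open(os.path.join(outdir, "origin_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def summarize_report(report: dict) -> str:
    """Human-readable digest of an origin report."""
    lines = [f"origin-kit report (seed {report['metadata']['seed']})"]
    fr = report.get("filter_report", {})
    lines.append(
        "markers: "
        f"{fr.get('n_input')} -> {fr.get('n_after_polymorphic')} polymorphic -> "
        f"{fr.get('n_after_maf')} MAF -> {fr.get('n_after_missing')} final"
    )
    for label, entry in report.get("subgenomes", {}).items():
        for tip, nn in entry["nearest_neighbors"].items():
            top = nn[0] if nn else None
            if top:
                lines.append(
                    f"subgenome {label} tip {tip}: closest wild relative "
                    f"{top['neighbor']} (IBS {top['similarity']:.4f})"
                )
        oc = entry["origin_clade"]
        lines.append(
            f"subgenome {label} clade: {', '.join(oc['wild_members'])} "
            f"(support {oc['support']})"
        )
        if "true_parent" in entry:
            lines.append(
                f"  true parent {entry['true_parent']}; recovered by IBS: "
                f"{entry['parent_recovered_by_ibs']}"
            )
    return "\n".join(lines)
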