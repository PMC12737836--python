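import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from polyorigin.panel import merge_panels, pseudosequences, run_filter_pipeline
from polyorigin.phylogeny import TreeConfig, bootstrap_support
from polyorigin.probes import AlignConfig, genotype_genome, partition_by_prefix
from polyorigin.relatedness import ibs_matrix, nearest_neighbors
from polyorigin.simulate import SimulationConfig, genome_to_bytes, simulate_panel


def run_study(seed: int, n_resamples: int = 200, **overrides):
    """One full simulated study: simulate, dissect-genotype the
    tetraploids, merge, filter, rank IBS neighbors, infer the bootstrap
    tree. Returns a dict of every intermediate."""
    cfg = SimulationConfig(seed=seed, **overrides)
    genomes, probes, array_calls, truth = simulate_panel(cfg)
    align = AlignConfig()
    tet_ids = sorted(s for s in genomes if s.startswith("tet"))
    cols = []
    for tid in tet_ids:
        g = genome_to_bytes(genomes[tid])
        cols.append(
            genotype_genome(probes, g, partition_by_prefix(list(g)), align, sample_id=tid)
        )
    additions = pd.concat(cols, axis=1)
    merged = merge_panels(array_calls, additions)
    filtered, filter_report = run_filter_pipeline(merged)
    sim = ibs_matrix(filtered)
    ranks = nearest_neighbors(sim, list(additions.columns))
    tree = bootstrap_support(
        pseudosequences(filtered), TreeConfig(n_resamples=n_resamples, seed=seed)
    )
    return {
        "config": cfg,
        "genomes": genomes,
        "probes": probes,
        "array_calls": array_calls,
        "truth": truth,
        "additions": additions,
        "merged": merged,
        "filtered": filtered,
        "filter_report": filter_report,
        "similarity": sim,
        "ranks": ranks,
        "tree": tree,
        "tet_tips": list(additions.columns),
    }


@pytest.fixture(scope="session")
def default_study():
    """Default study conditions, seed 1 (shared across tests)."""
    return run_study(seed=1)


@pytest.fixture(scope="session")
def replicate_studies():
    """Default study conditions across seeds 1..10 (shared by the
    simulation-based recovery tests)."""
    return {seed: run_study(seed=seed) for seed in range(1, 11)}
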