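"""Independent reference implementations used to check the package.

These deliberately take the slow, obvious route (full scans, direct
eigendecompositions, literal recounts) so they share no code path with
the implementations they validate.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from polyorigin.iupac import MISSING, alleles
from polyorigin.probes import AlignConfig, ProbeHit, ProbeRecord, revcomp


def brute_force_placements(
    probe: ProbeRecord,
    genome: dict[str, bytes],
    cfg: AlignConfig | None = None,
    target_id: str = "genome",
) -> list[ProbeHit]:
    """Exhaustive scan of every offset, strand and allele."""
    cfg = cfg or AlignConfig()
    flank = len(probe.left_flank)
    hits = []
    for chrom, seq in genome.items():
        g = np.frombuffer(seq, dtype=np.uint8)
        for allele in (probe.allele1, probe.allele2):
            full = (probe.left_flank + allele + probe.right_flank).encode()
            for strand in "+-":
                q = full if strand == "+" else revcomp(full)
                qa = np.frombuffer(q, dtype=np.uint8)
                if len(g) < len(qa):
                    continue
                win = sliding_window_view(g, len(qa))
                mism = win != qa
                center_ok = ~mism[:, flank]
                first = mism[:, :flank].sum(axis=1)
                last = mism[:, flank + 1 :].sum(axis=1)
                if strand == "+":
                    left_mm, right_mm = first, last
                else:
                    right_mm, left_mm = first, last
                if cfg.mismatch_scope == "per_arm":
                    ok = (
                        center_ok
                        & (left_mm <= cfg.max_flank_mismatch_per_arm)
                        & (right_mm <= cfg.max_flank_mismatch_per_arm)
                    )
                else:
                    ok = center_ok & (
                        left_mm + right_mm <= cfg.max_flank_mismatch_per_arm
                    )
                for s in np.flatnonzero(ok):
                    hits.append(
                        ProbeHit(
                            probe_id=probe.probe_id,
                            target_id=target_id,
                            chrom=chrom,
                            pos=int(s) + flank + 1,
                            strand=strand,
                            called_allele=allele,
                            left_mm=int(left_mm[s]),
                            right_mm=int(right_mm[s]),
                        )
                    )
    hits.sort(key=lambda h: (h.chrom, h.pos, h.strand))
    return hits


def recount_polymorphic(matrix) -> list[str]:
    """Marker ids with >= 2 distinct non-missing calls, by literal count."""
    out = []
    for marker in matrix.index:
        seen = {c for c in matrix.loc[marker] if c != MISSING}
        if len(seen) >= 2:
            out.append(marker)
    return out


def recount_maf_survivors(matrix, threshold: float) -> list[str]:
    """Biallelic markers whose literal minor-allele frequency is >= threshold."""
    out = []
    for marker in matrix.index:
        copies = []
        for call in matrix.loc[marker]:
            if call != MISSING:
                copies.extend(alleles(call))
        distinct = sorted(set(copies))
        if len(distinct) != 2:
            continue
        minor = min(copies.count(a) for a in distinct)
        if minor / len(copies) >= threshold:
            out.append(marker)
    return out


def recount_missing_survivors(matrix, cap: float) -> list[str]:
    out = []
    for marker in matrix.index:
        row = list(matrix.loc[marker])
        if row.count(MISSING) / len(row) <= cap:
            out.append(marker)
    return out


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """A random binary tree with positive branch lengths and its exact
    tip-to-tip distance matrix."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.uniform(0.05, 1.0))
    pool = list(nodes)
    while len(pool) > 2:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        new = TreeNode(children=[pool[i], pool[j]])
        new.length = float(rng.uniform(0.05, 1.0))
        pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [new]
    root = TreeNode(children=pool)
    names = [f"t{i}" for i in range(n_taxa)]
    dm = root.tip_tip_distances(endpoints=names)
    order = [list(dm.ids).index(n) for n in names]
    return root, names, dm.data[np.ix_(order, order)]
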