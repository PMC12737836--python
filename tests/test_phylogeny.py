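"""Tests of distances, neighbor joining, bootstrap support and sister
queries."""

import numpy as np
import pytest

from _oracles import random_additive_tree
from polyorigin.phylogeny import (
    TreeConfig,
    bipartitions,
    bootstrap_support,
    find_sister,
    neighbor_joining,
    pdistance_matrix,
    read_newick,
    write_newick,
)


def nj_from(seq_dict=None, ids=None, dist=None):
    if seq_dict is not None:
        ids, dist = pdistance_matrix(seq_dict)
    return neighbor_joining(ids, np.asarray(dist, dtype=float))


# ------------------------------------------------------------- distances


def test_pdistance_examples():
    ids, d = pdistance_matrix({"a": "AAAA", "b": "AAAA"})
    assert d[0, 1] == 0.0
    ids, d = pdistance_matrix({"a": "AAAA", "b": "AACC"})
    assert d[0, 1] == pytest.approx(0.5)
    ids, d = pdistance_matrix({"a": "A", "b": "M"})
    assert d[0, 1] == pytest.approx(0.5)


def test_pdistance_skips_missing_and_errors_on_empty():
    ids, d = pdistance_matrix({"a": "ANA", "b": "ACN"})
    assert d[0, 1] == 0.0  # only site 1 comparable
    with pytest.raises(ValueError, match="no comparable sites"):
        pdistance_matrix({"a": "NN", "b": "AN"})
    with pytest.raises(ValueError, match="equal length"):
        pdistance_matrix({"a": "AA", "b": "A"})


# ------------------------------------------------------------- NJ


def test_three_taxon_closed_form():
    dist = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    tree = nj_from(ids=list("ABC"), dist=dist)
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}


def test_four_taxon_topology_and_internal_edge():
    # four-point condition: internal edge = ((dAC + dBD) - (dAB + dCD)) / 2 = 1
    ids = list("ABCD")
    dist = np.array(
        [
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ],
        dtype=float,
    )
    tree = nj_from(ids=ids, dist=dist)
    bips = bipartitions(tree)
    assert bips == {frozenset({"C", "D"})}
    internal = [
        n for n in tree.non_tips(include_self=False)
    ]
    assert len(internal) == 1
    assert internal[0].length == pytest.approx(1.0)
    # full additivity: path lengths reproduce the input distances
    tt = tree.tip_tip_distances(endpoints=ids)
    order = [list(tt.ids).index(i) for i in ids]
    np.testing.assert_allclose(tt.data[np.ix_(order, order)], dist, atol=1e-10)


def test_nj_exact_on_random_additive_trees():
    rng = np.random.default_rng(0)
    for _ in range(10):
        n = int(rng.integers(4, 13))
        true_tree, names, dist = random_additive_tree(rng, n)
        rec = nj_from(ids=names, dist=dist)
        tt = rec.tip_tip_distances(endpoints=names)
        order = [list(tt.ids).index(i) for i in names]
        np.testing.assert_allclose(tt.data[np.ix_(order, order)], dist, atol=1e-10)
        assert bipartitions(rec) == bipartitions(true_tree)


def test_nj_invariant_under_taxon_permutation():
    rng = np.random.default_rng(1)
    _, names, dist = random_additive_tree(rng, 8)
    t1 = nj_from(ids=names, dist=dist)
    perm = list(rng.permutation(len(names)))
    names_p = [names[i] for i in perm]
    t2 = nj_from(ids=names_p, dist=dist[np.ix_(perm, perm)])
    assert bipartitions(t1) == bipartitions(t2)


def test_nj_clamps_negative_branch_lengths():
    # a violently non-additive matrix that induces a negative estimate
    dist = np.array(
        [
            [0.0, 0.1, 9.0, 9.0],
            [0.1, 0.0, 0.2, 9.0],
            [9.0, 0.2, 0.0, 0.1],
            [9.0, 9.0, 0.1, 0.0],
        ]
    )
    tree = nj_from(ids=list("ABCD"), dist=dist)
    for node in tree.traverse(include_self=False):
        assert node.length >= 0
    with pytest.raises(ValueError, match="at least 3"):
        nj_from(ids=["A", "B"], dist=np.zeros((2, 2)))


# ------------------------------------------------------------- bootstrap


def two_clade_seqs(rng, n_per_clade=4, n_sites=120, n_diag=40):
    """Two groups separated by many fixed differences plus noise."""
    base = rng.choice(list("ACGT"), n_sites)
    seqs = {}
    for g, offset in (("x", 0), ("y", 1)):
        group_base = base.copy()
        if offset:
            group_base[:n_diag] = [{"A": "C", "C": "A", "G": "T", "T": "G"}[b] for b in base[:n_diag]]
        for i in range(n_per_clade):
            s = group_base.copy()
            j = rng.integers(n_diag, n_sites, 2)
            s[j] = rng.choice(list("ACGT"), 2)
            seqs[f"{g}{i}"] = "".join(s)
    return seqs


def test_bootstrap_separating_bipartition_has_full_support():
    rng = np.random.default_rng(2)
    seqs = two_clade_seqs(rng)
    tree = bootstrap_support(seqs, TreeConfig(n_resamples=100, seed=3))
    split = frozenset(n for n in seqs if n.startswith("y"))
    found = False
    for node in tree.non_tips(include_self=False):
        side = node._tipset
        if side == split or side == frozenset(seqs) - split:
            found = True
            assert node.support == pytest.approx(1.0)
    assert found


def test_single_resample_supports_are_zero_or_one():
    rng = np.random.default_rng(4)
    seqs = two_clade_seqs(rng)
    tree = bootstrap_support(seqs, TreeConfig(n_resamples=1, seed=5))
    supports = [
        n.support for n in tree.non_tips(include_self=False) if hasattr(n, "support")
    ]
    assert supports and all(s in (0.0, 1.0) for s in supports)


def test_bootstrap_supports_invariant_to_tip_order():
    rng = np.random.default_rng(6)
    seqs = two_clade_seqs(rng)
    reordered = {k: seqs[k] for k in sorted(seqs, reverse=True)}
    t1 = bootstrap_support(seqs, TreeConfig(n_resamples=50, seed=7))
    t2 = bootstrap_support(reordered, TreeConfig(n_resamples=50, seed=7))

    def support_map(tree):
        out = {}
        all_tips = frozenset(t.name for t in tree.tips())
        anchor = min(all_tips)
        for n in tree.non_tips(include_self=False):
            if hasattr(n, "support"):
                side = n._tipset
                key = all_tips - side if anchor in side else side
                out[key] = n.support
        return out

    m1, m2 = support_map(t1), support_map(t2)
    assert m1.keys() == m2.keys()
    for key in m1:
        assert m1[key] == pytest.approx(m2[key], abs=0.1)


def test_support_increases_with_species_divergence():
    """Deeper species branches give the separating edge more exclusive
    characters, so its support is non-decreasing."""
    rng = np.random.default_rng(8)
    supports = []
    for n_diag in (1, 8, 40):
        seqs = two_clade_seqs(rng, n_diag=n_diag)
        tree = bootstrap_support(seqs, TreeConfig(n_resamples=60, seed=9))
        split = frozenset(n for n in seqs if n.startswith("y"))
        value = 0.0
        for node in tree.non_tips(include_self=False):
            if node._tipset in (split, frozenset(seqs) - split):
                value = node.support
        supports.append(value)
    assert supports[0] <= supports[1] <= supports[2]
    assert supports[2] == pytest.approx(1.0)


# ------------------------------------------------------------- sister queries


def quartet():
    dist = np.array(
        [
            [0, 2, 6, 6],
            [2, 0, 6, 6],
            [6, 6, 0, 2],
            [6, 6, 2, 0],
        ],
        dtype=float,
    )
    return nj_from(ids=list("ABCD"), dist=dist)


def test_sister_of_single_tip_is_its_cherry_mate():
    tree = quartet()
    sister, _ = find_sister(tree, {"A"})
    assert sister == frozenset({"B"})


def test_sister_of_all_but_one_is_that_tip():
    tree = quartet()
    sister, _ = find_sister(tree, {"A", "B", "C"})
    assert sister == frozenset({"D"})


def test_sister_of_cherry_pair():
    tree = quartet()
    sister, _ = find_sister(tree, {"C", "D"})
    assert sister <= frozenset({"A", "B"})


def test_sister_errors_on_non_clade():
    tree = quartet()
    with pytest.raises(ValueError, match="do not form a clade"):
        find_sister(tree, {"A", "C"})
    with pytest.raises(ValueError):
        find_sister(tree, {"A", "B", "C", "D"})
    with pytest.raises(ValueError):
        find_sister(tree, {"ghost"})


# ------------------------------------------------------------- Newick IO


def test_newick_round_trip_with_supports(tmp_path):
    rng = np.random.default_rng(10)
    seqs = two_clade_seqs(rng)
    tree = bootstrap_support(seqs, TreeConfig(n_resamples=20, seed=11))
    path = str(tmp_path / "tree.nwk")
    write_newick(tree, path)
    back = read_newick(path)
    assert {t.name for t in back.tips()} == set(seqs)
    assert bipartitions(back) == bipartitions(tree)

    def supports(t):
        all_tips = frozenset(x.name for x in t.tips())
        anchor = min(all_tips)
        return {
            (all_tips - n._tipset if anchor in n._tipset else n._tipset): n.support
            for n in t.non_tips(include_self=False)
            if getattr(n, "support", None) is not None
        }

    assert supports(back) == supports(tree)


def test_truth_tree_parses(tmp_path):
    from polyorigin.simulate import SimulationConfig, simulate_panel

    _, _, _, truth = simulate_panel(
        SimulationConfig(seed=1, n_chrom_per_subgenome=1, chrom_length=30_000,
                         n_probes_per_subgenome=50)
    )
    tree = read_newick(truth.true_tree)
    tips = {t.name for t in tree.tips()}
    assert truth.parent_a_id in tips
    assert {"tet1_A", "tet1_B", "tet2_A", "tet2_B"} <= tips
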