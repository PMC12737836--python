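"""Distance trees over SNP pseudosequences with resampling support.

Pairwise distances are the complement of the mean IBS site score
(IUPAC-aware, the same scoring as the similarity matrix, so trees and
similarity rankings are mutually consistent). Trees are built by
canonical neighbor joining (Q-criterion agglomeration with
Studier-Keppler distance updates), which reconstructs additive distances
exactly; negative branch-length estimates are clamped to zero and the
clamp count logged. Internal-edge support is the fraction of
site-resampled (bootstrap) replicate trees containing the same
bipartition. Sister-group queries mechanize clade readouts on the
resulting unrooted tree.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .iupac import SCORE_TABLE

logger = logging.getLogger(__name__)


@dataclass
class TreeConfig:
    n_resamples: int = 1000
    seed: int = 0
    distance_model: str = "site-IBS-complement"

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")


def _encode_seqs(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    names = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("pseudosequences must be equal length")
    mat = np.array(
        [np.frombuffer(seqs[n].encode(), dtype=np.uint8) for n in names]
    )
    return names, mat


def _pdist_codes(mat: np.ndarray, on_empty: str = "raise") -> np.ndarray:
    """1 - mean IBS score per pair, over sites comparable in both.

    ``on_empty`` controls pairs with zero comparable sites: ``raise`` or
    ``max`` (substitute the largest finite distance observed).
    """
    n = mat.shape[0]
    dist = np.zeros((n, n))
    empty = []
    for i in range(n - 1):
        scores = SCORE_TABLE[mat[i][None, :], mat[i + 1 :]]
        valid = ~np.isnan(scores)
        counts = valid.sum(axis=1)
        sums = np.nansum(scores, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - sums / counts
        for k, j in enumerate(range(i + 1, n)):
            if counts[k] == 0:
                if on_empty == "raise":
                    raise ValueError(
                        f"no comparable sites between sequences {i} and {j}"
                    )
                empty.append((i, j))
            else:
                dist[i, j] = dist[j, i] = d[k]
    if empty:
        fallback = dist.max()
        for i, j in empty:
            dist[i, j] = dist[j, i] = fallback
    return dist


def pdistance_matrix(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """IBS-complement distance matrix over equal-length pseudosequences."""
    names, mat = _encode_seqs(seqs)
    return names, _pdist_codes(mat)


def neighbor_joining(ids: list[str], dist: np.ndarray) -> TreeNode:
    """Canonical neighbor joining of a distance matrix.

    Returns an unrooted tree (trifurcating root). On additive distances
    the generating topology and branch lengths are recovered exactly.
    Negative branch-length estimates are clamped to zero (the deficit is
    moved to the sibling branch so the joined path length is preserved);
    the number of clamps is logged and stored as ``tree.n_clamped``.
    """
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    nodes = [TreeNode(name=i) for i in ids]
    d = dist.astype(float).copy()
    active = list(range(n))
    n_clamped = 0

    def clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0:
            n_clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(q.argmin())  # first minimum in scan order: deterministic
        ai, aj = flat // m, flat % m
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        if li < 0:
            li = clamp(li)
        elif li > dij:
            n_clamped += 1
            li = dij
        lj = dij - li
        nodes[i].length = li
        nodes[j].length = lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        # Studier-Keppler update
        for ak in active:
            if ak in (i, j):
                continue
            d[i, ak] = d[ak, i] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        nodes[i] = new
        active.remove(j)

    a, b, c = active
    la = clamp(0.5 * (d[a, b] + d[a, c] - d[b, c]))
    lb = clamp(0.5 * (d[a, b] + d[b, c] - d[a, c]))
    lc = clamp(0.5 * (d[a, c] + d[b, c] - d[a, b]))
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = length
    tree = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    tree.n_clamped = n_clamped
    if n_clamped:
        logger.info("neighbor_joining: clamped %d negative branch length(s)", n_clamped)
    return tree


def _tip_sets(tree: TreeNode) -> None:
    """Annotate every node with the frozenset of tip names below it."""
    for node in tree.postorder():
        if node.is_tip():
            node._tipset = frozenset([node.name])
        else:
            node._tipset = frozenset().union(*(c._tipset for c in node.children))


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Canonicalized non-trivial bipartitions (internal edges) of an
    unrooted tree. Each is represented by the side not containing the
    lexicographically smallest tip."""
    _tip_sets(tree)
    all_tips = tree._tipset
    anchor = min(all_tips)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = node._tipset
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        out.add(all_tips - side if anchor in side else side)
    return out


def bootstrap_support(seqs: dict[str, str], cfg: TreeConfig | None = None) -> TreeNode:
    """Reference NJ tree with bootstrap supports on internal nodes.

    Sites (marker columns) are resampled with replacement ``n_resamples``
    times; each internal edge's support is the fraction of replicate
    trees containing the same bipartition, stored as ``node.support``.
    """
    cfg = cfg or TreeConfig()
    names, mat = _encode_seqs(seqs)
    if len(names) < 4:
        raise ValueError("bootstrap support needs at least 4 taxa")
    ref_tree = neighbor_joining(names, _pdist_codes(mat))
    _tip_sets(ref_tree)
    all_tips = ref_tree._tipset
    anchor = min(all_tips)
    counts: dict[frozenset, int] = {b: 0 for b in bipartitions(ref_tree)}
    rng = np.random.default_rng(cfg.seed)
    n_sites = mat.shape[1]
    for _ in range(cfg.n_resamples):
        idx = rng.integers(0, n_sites, n_sites)
        rep = neighbor_joining(names, _pdist_codes(mat[:, idx], on_empty="max"))
        for b in bipartitions(rep):
            if b in counts:
                counts[b] += 1
    for node in ref_tree.non_tips(include_self=False):
        side = node._tipset
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        key = all_tips - side if anchor in side else side
        node.support = counts[key] / cfg.n_resamples
    return ref_tree


def find_sister(tree: TreeNode, focal_tips) -> tuple[frozenset, float | None]:
    """Tip set of the clade adjacent to the focal clade's stem edge.

    The focal tips must form a clade under some rooting of the unrooted
    tree (i.e. be one side of an edge). Among the subtrees meeting the
    stem edge on the far side, the smallest (ties by sorted tip names) is
    reported as the sister, together with the stem edge's support when
    available.
    """
    focal = frozenset(focal_tips)
    _tip_sets(tree)
    all_tips = tree._tipset
    if not focal or not focal <= all_tips:
        raise ValueError("focal tips must be a non-empty subset of the tree's tips")
    if focal == all_tips:
        raise ValueError("focal tips cannot be the whole tree")
    target = None
    complement = False
    for node in tree.traverse(include_self=False):
        if node._tipset == focal:
            target = node
            break
        if all_tips - node._tipset == focal:
            target = node
            complement = True
            break
    if target is None:
        raise ValueError("focal tips do not form a clade")
    support = getattr(target, "support", None)
    if complement:
        if target.is_tip():
            return frozenset([target.name]), support
        candidates = [c._tipset for c in target.children]
    else:
        parent = target.parent
        candidates = [c._tipset for c in parent.children if c is not target]
        if parent.parent is not None:
            candidates.append(all_tips - parent._tipset)
    sister = min(candidates, key=lambda s: (len(s), tuple(sorted(s))))
    return sister, support


def write_newick(tree: TreeNode, path: str) -> None:
    """Serialize with supports as internal-node labels (the ``support``
    attribute is written as the label by the newick writer)."""
    tree.write(path, format="newick")


def read_newick(path_or_handle) -> TreeNode:
    """Parse Newick; numeric internal-node labels become supports."""
    if isinstance(path_or_handle, str) and "(" in path_or_handle:
        path_or_handle = io.StringIO(path_or_handle)
    tree = TreeNode.read(path_or_handle, format="newick", convert_underscores=False)
    for node in tree.non_tips(include_self=True):
        if node.name is not None:
            try:
                node.support = float(node.name)
                node.name = None
            except ValueError:
                pass
    return tree
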