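"""Neighbour-joining trees and nonparametric bootstrap support.

Neighbour joining follows the Saitou–Nei agglomeration on the Q-matrix
criterion, terminating at a central trifurcation (the tree is unrooted).
Ties in the Q minimisation are broken on the lowest (row, column) index
pair of the current matrix, so the construction is fully deterministic.
Negative branch-length estimates, which arise on non-additive input, are
clamped to zero with the deficit transferred to the sister branch; every
clamp is logged.

Bootstrap support resamples alignment *columns* with replacement, rebuilds
the K2P distance matrix and NJ tree per replicate, and scores each
internal edge of the full-data tree by the percentage of replicate trees
containing the same bipartition of the taxon set.
"""

from __future__ import annotations

import logging

import numpy as np
from skbio import TreeNode

from . import _kernels
from .distances import DistanceMatrix, k2p_matrix
from .errors import DegenerateAlignmentError, ParameterError, SaturationError
from .seq_io import Alignment

logger = logging.getLogger(__name__)


def _nj_from_array(d: np.ndarray, ids) -> TreeNode:
    nodes = [TreeNode(name=str(i)) for i in ids]
    D = np.asarray(d, dtype=float).copy()

    def clamp_pair(li: float, lj: float, total: float) -> tuple[float, float]:
        # Transfer any negative estimate to the sister branch, keep the sum.
        if li < 0:
            logger.info("clamped negative NJ branch length %.6g to 0", li)
            li, lj = 0.0, total
        if lj < 0:
            logger.info("clamped negative NJ branch length %.6g to 0", lj)
            lj, li = 0.0, max(total, 0.0)
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        Q[np.tril_indices(m)] = np.inf  # scan i<j only; argmin is row-major,
        k = int(np.argmin(Q))           # i.e. lowest (row, col) on ties
        i, j = divmod(k, m)
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj, dij)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([
            np.hstack([D[np.ix_(keep, keep)], dnew[keep, None]]),
            np.hstack([dnew[keep], [0.0]]),
        ])
        np.maximum(D, 0.0, out=D)
        nodes = [nodes[x] for x in keep] + [parent]

    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for node, length in ((a, la), (b, lb), (c, lc)):
        if length < 0:
            logger.info("clamped negative NJ branch length %.6g to 0", length)
        node.length = max(length, 0.0)
    return TreeNode(children=[a, b, c])


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Build an unrooted NJ tree from a finite distance matrix.

    On an additive matrix, leaf-to-leaf path lengths reproduce the input
    distances exactly (up to floating-point error).
    """
    if len(dm.ids) < 3:
        raise ParameterError("neighbour joining needs at least 3 taxa")
    if not np.isfinite(dm.data).all():
        raise SaturationError(
            "distance matrix contains saturated (non-finite) entries; "
            "neighbour joining refuses such input"
        )
    return _nj_from_array(dm.data, dm.ids)


def tip_names(tree: TreeNode) -> frozenset[str]:
    return frozenset(t.name for t in tree.tips())


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the taxon set, one per internal edge.

    Each bipartition is canonicalised as the side *not* containing the
    lexicographically smallest taxon, so rooted representations of the
    same unrooted tree compare equal.
    """
    tips = tip_names(tree)
    ref = min(tips)
    parts: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = tips - side
        if 2 <= len(side) <= len(tips) - 2:
            parts.add(side)
    return parts


def path_length_matrix(tree: TreeNode, ids) -> np.ndarray:
    """Leaf-to-leaf path-length distances, in the order of ``ids``."""
    dm = tree.tip_tip_distances(endpoints=list(ids))
    return np.asarray(dm.data)


def bootstrap_support(
    aln: Alignment,
    replicates: int = 1000,
    seed: int = 0,
    max_redraw_factor: int = 10,
) -> TreeNode:
    """NJ tree on the full data with bootstrap support on internal edges.

    Replicates in which some pair loses all comparable columns (or
    saturates) are redrawn; the total number of draws is capped at
    ``max_redraw_factor * replicates``, beyond which the alignment is
    considered degenerate.  Support values are integer percentages stored
    as ``node.support``, which the Newick writer emits as standard
    internal node labels.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    full = neighbor_joining(k2p_matrix(aln))
    target = {}
    tips = tip_names(full)
    ref = min(tips)
    for node in full.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = tips - side
        if 2 <= len(side) <= len(tips) - 2:
            target[side] = node

    arr = aln.to_array()
    ncol = arr.shape[1]
    rng = np.random.default_rng(seed)
    counts = {b: 0 for b in target}
    done = draws = 0
    cap = max_redraw_factor * replicates
    while done < replicates:
        if draws >= cap:
            raise DegenerateAlignmentError(
                f"exceeded {cap} bootstrap draws for {replicates} usable "
                "replicates; alignment too gappy/ambiguous to resample"
            )
        draws += 1
        cols = rng.integers(0, ncol, size=ncol)
        d = _kernels.k2p_matrix(arr[:, cols])
        if not np.isfinite(d).all():
            logger.info("redrew bootstrap replicate with unusable distances")
            continue
        rep_tree = _nj_from_array(d, aln.ids)
        for b in bipartitions(rep_tree):
            if b in counts:
                counts[b] += 1
        done += 1

    for side, node in target.items():
        # skbio's Newick writer emits node.support as the internal label
        node.support = int(round(100.0 * counts[side] / replicates))
    return full


def support_table(tree: TreeNode):
    """(bipartition side, support) pairs for every supported internal edge."""
    rows = []
    for node in tree.traverse(include_self=False):
        if node.is_tip() or getattr(node, "support", None) is None:
            continue
        side = sorted(t.name for t in node.tips())
        rows.append((";".join(side), node.support))
    return rows
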