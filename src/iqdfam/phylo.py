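"""Distance-based neighbor-joining trees with bootstrap support.

p-distances are computed on a user-supplied multiple protein alignment
(columns where either sequence is gapped are ignored per pair).  The NJ
implementation is the Saitou–Nei agglomeration with the standard Q
criterion; ties are broken deterministically by the lexicographically
smallest leaf label of the candidate clusters, so the topology does not
depend on input order.  Bootstrap resamples alignment columns with
replacement and reports, for every internal bipartition of the original
tree, the fraction of replicate trees that contain it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .io import SeqRecord


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal not zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")


def pdistance_matrix(aln: list[SeqRecord]) -> DistanceMatrix:
    """Pairwise proportion of differing sites over mutually ungapped columns."""
    labels = [r.id for r in aln]
    rows = [r.sequence for r in aln]
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("alignment rows differ in length")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = diffs = 0
            for a, b in zip(rows[i], rows[j]):
                if a == "-" or b == "-":
                    continue
                comparable += 1
                diffs += a != b
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]} and {labels[j]}"
                )
            d[i, j] = d[j, i] = diffs / comparable
    return DistanceMatrix(labels, d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; returns an unrooted (trifurcating) tree.

    Recovers the generating topology and exact branch lengths on additive
    matrices.  Requires at least three taxa.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes = [TreeNode(name=lbl) for lbl in dm.labels]
    reps = list(dm.labels)  # smallest leaf label per cluster, for tie-breaks
    d = dm.d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        # reuse slot i for the merged cluster; retire slot j
        new_d = np.zeros(d.shape[0] + 1)
        for k in active:
            if k not in (i, j):
                new_d[k] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :] = new_d
        d[:, -1] = new_d
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # terminal star join of the last three clusters
    i, j, k = active
    root = TreeNode()
    nodes[i].length = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    nodes[j].length = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    nodes[k].length = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    root.extend([nodes[i], nodes[j], nodes[k]])
    return root


def _bipartitions(tree: TreeNode, all_labels: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions, canonicalized to the side not containing
    the alphabetically first label."""
    ref = min(all_labels)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if ref in side:
            side = all_labels - side
        if 1 < len(side) < len(all_labels) - 1:
            parts.add(side)
    return parts


def bootstrap_support(
    aln: list[SeqRecord], n_reps: int = 1000, seed: int = 0
) -> TreeNode:
    """NJ tree of ``aln`` with bootstrap proportions on internal nodes.

    Columns are resampled with replacement ``n_reps`` times; each internal
    node of the original tree gets ``node.support`` in [0, 1], which the
    newick writer emits as the internal node label.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(pdistance_matrix(aln))
    all_labels = frozenset(r.id for r in aln)
    length = len(aln[0].sequence)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = [
            SeqRecord(r.id, "".join(r.sequence[c] for c in cols), "protein")
            for r in aln
        ]
        for part in _bipartitions(nj_tree(pdistance_matrix(resampled)), all_labels):
            counts[part] = counts.get(part, 0) + 1
    ref = min(all_labels)
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if ref in side:
            side = all_labels - side
        if 1 < len(side) < len(all_labels) - 1:
            node.support = counts.get(side, 0) / n_reps
        else:
            node.support = 1.0  # trivial split, present in every tree
    return tree


def sister_pairs(tree: TreeNode, min_support: float = 0.5) -> list[tuple[str, str]]:
    """Leaf pairs forming a cherry whose parent support >= min_support.

    Nodes without a ``support`` attribute (e.g. a tree built without
    bootstrap) are treated as fully supported.
    """
    pairs = []
    for node in tree.non_tips(include_self=False):
        children = node.children
        if len(children) == 2 and all(c.is_tip() for c in children):
            support = getattr(node, "support", 1.0)
            if support >= min_support:
                pairs.append(tuple(sorted(c.name for c in children)))
    return sorted(pairs)


def topologies_equal(a: TreeNode, b: TreeNode) -> bool:
    """Unrooted topology comparison via bipartition sets."""
    labels = frozenset(leaf.name for leaf in a.tips())
    if labels != frozenset(leaf.name for leaf in b.tips()):
        return False
    return _bipartitions(a, labels) == _bipartitions(b, labels)
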