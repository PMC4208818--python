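import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

from iqdfam.io import SeqRecord
from iqdfam.phylo import (
    DistanceMatrix,
    bootstrap_support,
    nj_tree,
    pdistance_matrix,
    sister_pairs,
    topologies_equal,
)


def aligned(rows):
    return [SeqRecord(name, seq, "protein") for name, seq in rows]


class TestPDistance:
    def test_identical_rows_have_distance_zero(self):
        dm = pdistance_matrix(aligned([("a", "MKV"), ("b", "MKV")]))
        assert dm.d[0, 1] == 0.0

    def test_one_mismatch_in_ten(self):
        dm = pdistance_matrix(
            aligned([("a", "MKVLIDEQRS"), ("b", "MKVLIDEQRT")])
        )
        assert dm.d[0, 1] == pytest.approx(0.1)

    def test_fully_different_rows(self):
        dm = pdistance_matrix(aligned([("a", "AAAA"), ("b", "CCCC")]))
        assert dm.d[0, 1] == 1.0

    def test_gapped_columns_excluded_per_pair(self):
        dm = pdistance_matrix(aligned([("a", "MK-V"), ("b", "MKAV")]))
        assert dm.d[0, 1] == 0.0

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(ValueError, match="comparable"):
            pdistance_matrix(aligned([("a", "MK--"), ("b", "--AV")]))


def _least_squares_fit(d, split):
    """Residual of fitting 5 branch lengths of a 4-taxon topology.

    Independent oracle: for the unrooted topology pairing `split` (e.g.
    (0,1)|(2,3)) express each pairwise distance as a sum of the two
    pendant branches plus the internal edge when the pair spans the split,
    and solve the 6x5 system by least squares.
    """
    rows, y = [], []
    (p, q), (r, s) = split
    cols = {p: 0, q: 1, r: 2, s: 3}
    for i, j in itertools.combinations(range(4), 2):
        row = [0.0] * 5
        row[cols[i]] = row[cols[j]] = 1.0
        same_side = {i, j} in ({p, q}, {r, s})
        if not same_side:
            row[4] = 1.0
        rows.append(row)
        y.append(d[i, j])
    coef, residual, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
    fitted = np.array(rows) @ coef
    return float(np.sum((fitted - np.array(y)) ** 2)), coef


class TestNeighborJoining:
    # additive matrix of ((A:1,B:1):1,(C:2,D:2))
    LABELS = ["A", "B", "C", "D"]
    D = np.array(
        [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 4], [4, 4, 4, 0]], dtype=float
    )

    def test_recovers_topology_and_exact_lengths_on_additive_matrix(self):
        # oracle: least-squares over the three unrooted 4-taxon topologies
        splits = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
        residuals = [_least_squares_fit(self.D, s)[0] for s in splits]
        assert int(np.argmin(residuals)) == 0  # AB|CD is the additive fit
        tree = nj_tree(DistanceMatrix(self.LABELS, self.D))
        tip_d = {t.name: t.length for t in tree.tips()}
        assert tip_d == pytest.approx({"A": 1.0, "B": 1.0, "C": 2.0, "D": 2.0})
        cherry = {
            frozenset(leaf.name for leaf in n.tips())
            for n in tree.non_tips(include_self=False)
        }
        assert frozenset({"A", "B"}) in cherry or frozenset({"C", "D"}) in cherry

    def test_three_taxa_give_unique_topology(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        assert sorted(t.name for t in tree.tips()) == ["a", "b", "c"]
        # star distances: la = (dab + dac - dbc)/2 = 1, lb = 2, lc = 3
        assert {t.name: t.length for t in tree.tips()} == pytest.approx(
            {"a": 1.0, "b": 2.0, "c": 3.0}
        )

    def test_fewer_than_three_taxa_is_an_error(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]])))

    def test_label_permutation_gives_same_topology(self):
        perm = [2, 0, 3, 1]
        labels = [self.LABELS[i] for i in perm]
        d = self.D[np.ix_(perm, perm)]
        t1 = nj_tree(DistanceMatrix(self.LABELS, self.D))
        t2 = nj_tree(DistanceMatrix(labels, d))
        assert topologies_equal(t1, t2)

    def _random_additive_case(self, rng, n_taxa=6):
        """A random binary tree and the additive distances it induces."""
        nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
        for node in nodes:
            node.length = float(rng.uniform(0.1, 1.0))
        while len(nodes) > 3:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            parent = TreeNode()
            parent.length = float(rng.uniform(0.1, 1.0))
            parent.extend([nodes[i], nodes[j]])
            nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
            nodes.append(parent)
        root = TreeNode()
        root.extend(nodes)
        dm = root.tip_tip_distances()
        labels = list(dm.ids)
        return root, DistanceMatrix(labels, dm.data)

    def test_recovers_twenty_random_additive_six_taxon_trees(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            truth, dm = self._random_additive_case(rng)
            assert topologies_equal(nj_tree(dm), truth)

    def test_agrees_with_skbio_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 7
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = [f"x{i}" for i in range(n)]
            mine = nj_tree(DistanceMatrix(labels, m))
            theirs = skbio_nj(SkbioDM(m, labels))
            assert topologies_equal(mine, theirs)


class TestBootstrap:
    ROWS = [
        ("A", "MKVLIDEQRST" * 4),
        ("B", "MKVLIDEQRST" * 4),
        ("C", "MPPPPPWWWWW" * 4),
        ("D", "MYYYYYGGGGG" * 4),
    ]

    def test_identical_sequences_form_fully_supported_cherry(self):
        tree = bootstrap_support(aligned(self.ROWS), n_reps=25, seed=1)
        assert ("A", "B") in sister_pairs(tree, min_support=0.99)

    def test_same_seed_reproduces_supports(self):
        t1 = bootstrap_support(aligned(self.ROWS), n_reps=25, seed=7)
        t2 = bootstrap_support(aligned(self.ROWS), n_reps=25, seed=7)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False))
        assert s1 == s2

    def test_small_and_large_replicate_counts_agree_within_noise(self):
        small = bootstrap_support(aligned(self.ROWS), n_reps=10, seed=5)
        large = bootstrap_support(aligned(self.ROWS), n_reps=200, seed=5)
        for ns, nl in zip(
            small.non_tips(include_self=False), large.non_tips(include_self=False)
        ):
            assert abs(ns.support - nl.support) < 0.35  # binomial sampling error


class TestSisterPairs:
    def test_low_support_cherry_not_reported(self):
        tree = TreeNode.read(["((A:1,B:1)0.3:1,(C:1,D:1)0.9:1);"])
        for node in tree.non_tips(include_self=False):
            node.support = float(node.name)
        assert sister_pairs(tree, min_support=0.5) == [("C", "D")]

    def test_caterpillar_without_cherries_above_threshold(self):
        tree = TreeNode.read(["(((A:1,B:1)0.1:1,C:1)0.1:1,D:1);"])
        for node in tree.non_tips(include_self=False):
            node.support = 0.1
        assert sister_pairs(tree, min_support=0.5) == []
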