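import itertools

import numpy as np
import pytest

from spiscan.io_formats import make_aligned_block
from spiscan.phylogenetics import (
    DistanceMatrix,
    PhyloError,
    bipartitions,
    bootstrap_support,
    is_monophyletic,
    nj_tree,
    p_distance,
    tree_path_lengths,
)
from spiscan.synthetic_data import generate_two_cluster_alignment, random_additive_matrix


def ls_fit_four_taxa(labels, d):
    """Exhaustive least-squares oracle over the 3 unrooted 4-taxon topologies.

    Returns (best split as frozenset pair, fitted path-length matrix).
    """
    best = None
    idx = {lab: i for i, lab in enumerate(labels)}
    for pair in [(0, 1), (0, 2), (0, 3)]:
        a, b = pair
        c, d2 = [i for i in range(4) if i not in pair]
        # edges: ea, eb, ec, ed, internal
        rows, rhs = [], []
        paths = {
            (a, b): [1, 1, 0, 0, 0],
            (c, d2): [0, 0, 1, 1, 0],
            (a, c): [1, 0, 1, 0, 1],
            (a, d2): [1, 0, 0, 1, 1],
            (b, c): [0, 1, 1, 0, 1],
            (b, d2): [0, 1, 0, 1, 1],
        }
        for (i, j), coeffs in paths.items():
            rows.append(coeffs)
            rhs.append(d[i, j])
        sol, residual, *_ = np.linalg.lstsq(np.array(rows, float), np.array(rhs), rcond=None)
        fitted = np.zeros((4, 4))
        for (i, j), coeffs in paths.items():
            fitted[i, j] = fitted[j, i] = float(np.dot(coeffs, sol))
        rss = float(((fitted - d) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, frozenset([labels[a], labels[b]]), fitted)
    return best[1], best[2]


class TestPDistance:
    def test_single_mismatch(self):
        block = make_aligned_block([("a", "AAAA"), ("b", "AAAT")])
        assert p_distance(block).matrix[0, 1] == pytest.approx(0.25)

    def test_identical_sequences_zero(self):
        block = make_aligned_block([("a", "MKKR"), ("b", "MKKR")])
        assert p_distance(block).matrix[0, 1] == 0.0

    def test_pairwise_deletion_skips_gap_columns(self):
        block = make_aligned_block([("a", "A-AA"), ("b", "AAAA")])
        assert p_distance(block, "pairwise_deletion").matrix[0, 1] == 0.0

    def test_complete_deletion_drops_any_gap_column(self):
        block = make_aligned_block([("a", "A-TT"), ("b", "AAAT"), ("c", "AAAT")])
        d = p_distance(block, "complete_deletion")
        # only columns 1, 3, 4 survive; a vs b mismatch at column 3
        assert d.matrix[0, 1] == pytest.approx(1 / 3)

    def test_all_gap_pair_is_error(self):
        block = make_aligned_block([("a", "--AA"), ("b", "AA--"), ("c", "AAAA")])
        with pytest.raises(PhyloError, match="'a'.*'b'|no comparable"):
            p_distance(block)


class TestNJ:
    def test_three_taxa_closed_form(self):
        # three-point formulas: la = (dab + dac - dbc)/2 etc.
        d = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        dm = DistanceMatrix(labels=("a", "b", "c"), matrix=d)
        tree = nj_tree(dm)
        lengths = {n.taxon.label: n.edge.length for n in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((0.4 + 0.6 - 0.8) / 2)
        assert lengths["b"] == pytest.approx((0.4 + 0.8 - 0.6) / 2)
        assert lengths["c"] == pytest.approx((0.6 + 0.8 - 0.4) / 2)

    def test_four_taxon_additive_matches_ls_oracle(self):
        for seed in range(20):
            tree, dm = random_additive_matrix(seed, n_taxa=4)
            built = nj_tree(dm)
            split, fitted = ls_fit_four_taxa(dm.labels, dm.matrix)
            got = set(bipartitions(built).values())
            anchor = min(dm.labels)
            norm = split if anchor not in split else frozenset(dm.labels) - split
            assert got == {norm}
            rebuilt = tree_path_lengths(built)
            assert np.abs(rebuilt.matrix - fitted).max() < 1e-9

    def test_recovers_random_additive_topologies(self):
        for seed in range(30):
            n = 5 + seed % 4
            tree, dm = random_additive_matrix(seed, n_taxa=n)
            built = nj_tree(dm)
            assert set(bipartitions(tree).values()) == set(bipartitions(built).values())
            rebuilt = tree_path_lengths(built)
            assert np.abs(rebuilt.matrix - dm.matrix).max() < 1e-6

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(PhyloError, match="symmetric"):
            DistanceMatrix(labels=("a", "b"), matrix=np.array([[0, 1], [2, 0]]))

    def test_negative_branch_lengths_clamped(self):
        # non-additive matrix known to produce a negative NJ estimate
        d = np.array(
            [
                [0.0, 0.1, 0.6, 0.6],
                [0.1, 0.0, 0.6, 0.6],
                [0.6, 0.6, 0.0, 0.05],
                [0.6, 0.6, 0.05, 0.0],
            ]
        )
        dm = DistanceMatrix(labels=("a", "b", "c", "d"), matrix=d)
        tree = nj_tree(dm)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


class TestBootstrap:
    def test_two_cluster_central_split_fully_supported(self):
        block = generate_two_cluster_alignment(seed=3)
        tree = bootstrap_support(block, n_reps=100, seed=5)
        supports = [int(n.label) for n in bipartitions(tree)]
        assert supports == [100]

    def test_single_replicate_supports_binary(self):
        block = generate_two_cluster_alignment(seed=3, n_per_cluster=3)
        tree = bootstrap_support(block, n_reps=1, seed=11)
        for node in bipartitions(tree):
            assert int(node.label) in (0, 100)

    def test_same_seed_reproducible(self):
        block = generate_two_cluster_alignment(seed=4)
        t1 = bootstrap_support(block, n_reps=25, seed=9)
        t2 = bootstrap_support(block, n_reps=25, seed=9)
        s1 = sorted(n.label for n in bipartitions(t1))
        s2 = sorted(n.label for n in bipartitions(t2))
        assert s1 == s2

    def test_supports_invariant_to_taxon_order(self):
        # per-taxon private mutations keep all distances distinct, so the
        # topology is determined by the data rather than tie-breaking
        base = generate_two_cluster_alignment(seed=6, n_per_cluster=3)
        rng = np.random.default_rng(21)
        items = []
        for k, r in enumerate(base.records):
            seq = list(r.sequence)
            for c in rng.choice(len(seq), size=3 + 2 * k, replace=False):
                seq[c] = "W" if seq[c] != "W" else "M"
            items.append((r.id, "".join(seq)))
        block = make_aligned_block(items)
        reversed_block = make_aligned_block(list(reversed(items)))
        t1 = bootstrap_support(block, n_reps=50, seed=13)
        t2 = bootstrap_support(reversed_block, n_reps=50, seed=13)
        m1 = {b: int(n.label) for n, b in bipartitions(t1).items()}
        m2 = {b: int(n.label) for n, b in bipartitions(t2).items()}
        assert set(m1) == set(m2)


class TestMonophyly:
    def test_full_set_and_singleton_trivially_monophyletic(self):
        _, dm = random_additive_matrix(2, n_taxa=5)
        tree = nj_tree(dm)
        assert is_monophyletic(tree, set(dm.labels))
        assert is_monophyletic(tree, {dm.labels[0]})

    def test_planted_clade_detected_straddling_set_rejected(self):
        block = generate_two_cluster_alignment(seed=8, n_per_cluster=3)
        tree = nj_tree(p_distance(block))
        assert is_monophyletic(tree, {"A1", "A2", "A3"})
        assert not is_monophyletic(tree, {"A1", "B1"})

    def test_unknown_taxon_is_error(self):
        _, dm = random_additive_matrix(2, n_taxa=4)
        tree = nj_tree(dm)
        with pytest.raises(PhyloError, match="unknown"):
            is_monophyletic(tree, {"nope"})
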