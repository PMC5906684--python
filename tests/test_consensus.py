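"""Evidence channels, single linkage and the strict consensus tree."""

import numpy as np
import pytest

from znrfold.consensus import (
    Dendrogram, build_channel, build_clade_tree, single_linkage, strict_consensus,
)
from znrfold.io import SimilarityTable, newick_string
from znrfold.simulate import CladeSimSpec, simulate_similarity_pair


def ztable(labels, values):
    return SimilarityTable(labels=labels, values=np.asarray(values, float),
                           measure="zscore")


def tree_clades(tree):
    out = set()

    def walk(node):
        leaves = frozenset(node.leaf_labels())
        if len(leaves) > 1:
            out.add(leaves)
        for c in node.children:
            walk(c)

    walk(tree.root)
    return out


class TestBuildChannel:
    def test_neglog10_transform(self):
        e = SimilarityTable(labels=["a", "b"],
                            values=np.array([[np.nan, 1e-5], [1e-5, np.nan]]),
                            measure="evalue")
        ch = build_channel(e)
        assert ch.transform == "neglog10"
        # both similarities are 5 -> the single off-diagonal distance is 0
        assert ch.distances[0, 1] == pytest.approx(0.0)

    def test_one_sided_missing_keeps_present_value(self):
        z = ztable(["a", "b", "c"], [[np.nan, 8.0, 2.0],
                                     [np.nan, np.nan, 2.0],
                                     [2.0, 2.0, np.nan]])
        ch = build_channel(z)
        # s'(a,b) = 8 (one-sided), s_max = 8, so d(a,b) = 0
        assert ch.distances[0, 1] == pytest.approx(0.0)
        assert ch.distances[0, 2] == pytest.approx(6.0)

    def test_double_missing_is_zero_similarity(self):
        z = ztable(["a", "b", "c"], [[np.nan, np.nan, 5.0],
                                     [np.nan, np.nan, 5.0],
                                     [5.0, 5.0, np.nan]])
        ch = build_channel(z)
        assert ch.distances[0, 1] == pytest.approx(5.0)  # s_max - 0

    def test_zero_evalue_capped(self):
        e = SimilarityTable(labels=["a", "b"],
                            values=np.array([[np.nan, 0.0], [0.0, np.nan]]),
                            measure="evalue")
        assert np.isfinite(build_channel(e).distances).all()

    def test_all_missing_rejected(self):
        z = ztable(["a", "b"], [[np.nan, np.nan], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="missing"):
            build_channel(z)

    def test_noise_free_blocks_give_two_distances(self):
        e, z = simulate_similarity_pair(CladeSimSpec(noise_sd=0.0, missing_frac=0.0,
                                                     seed=0))
        for table in (e, z):
            ch = build_channel(table)
            off = ch.distances[~np.eye(len(table.labels), dtype=bool)]
            assert len(set(np.round(off, 9))) == 2


class TestSingleLinkage:
    def test_two_leaves(self):
        ch = build_channel(ztable(["a", "b"], [[np.nan, 3.0], [3.0, np.nan]]))
        dendro = single_linkage(ch)
        assert len(dendro.merges) == 1
        assert dendro.merges[0][:2] == (("a",), ("b",))

    def test_hand_computable_two_pairs(self):
        # distances: 1 within {a,b} and {c,d}, 5 between
        z = ztable(["a", "b", "c", "d"], [[np.nan, 5, 1, 1], [5, np.nan, 1, 1],
                                          [1, 1, np.nan, 5], [1, 1, 5, np.nan]])
        dendro = single_linkage(build_channel(z))
        first_two = {frozenset(a) | frozenset(b) for a, b, _ in dendro.merges[:2]}
        assert first_two == {frozenset({"a", "b"}), frozenset({"c", "d"})}

    def test_heights_non_decreasing(self):
        for seed in range(10):
            _, z = simulate_similarity_pair(CladeSimSpec(seed=seed, noise_sd=2.0))
            heights = [h for _, _, h in single_linkage(build_channel(z)).merges]
            assert heights == sorted(heights)

    def test_matches_scipy_on_distinct_distances(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        n = 8
        labels = [f"l{i}" for i in range(n)]
        condensed = rng.permutation(np.arange(1, n * (n - 1) // 2 + 1)).astype(float)
        square = squareform(condensed)
        sim = square.max() - square  # convert to a similarity matrix
        np.fill_diagonal(sim, np.nan)
        ch = build_channel(ztable(labels, sim))
        # channel distances are shifted by the off-diagonal minimum (here 1)
        off = ~np.eye(n, dtype=bool)
        assert np.allclose(ch.distances[off], square[off] - 1.0)
        ours = single_linkage(ch)
        theirs = linkage(condensed, method="single")
        assert np.allclose(sorted(h + 1.0 for _, _, h in ours.merges),
                           sorted(theirs[:, 2]))
        # same clade heights imply the same topology when distances are distinct
        sets = set()
        members = {i: frozenset([labels[i]]) for i in range(n)}
        for k, (i, j, h, _) in enumerate(theirs):
            members[n + k] = members[int(i)] | members[int(j)]
            sets.add(members[n + k])
        assert ours.clades() == sets

    def test_rank_invariance(self):
        """A monotone transform of similarities leaves the topology unchanged."""
        _, z = simulate_similarity_pair(CladeSimSpec(seed=3, missing_frac=0.0))
        ch = build_channel(z)
        base = single_linkage(ch).clades()
        squashed = SimilarityTable(labels=z.labels, values=np.sqrt(z.values),
                                   measure="zscore")
        assert single_linkage(build_channel(squashed)).clades() == base


class TestStrictConsensus:
    def test_idempotence(self):
        _, z = simulate_similarity_pair(CladeSimSpec(seed=1))
        dendro = single_linkage(build_channel(z))
        tree = strict_consensus(dendro, dendro)
        assert tree_clades(tree) == dendro.clades() | {frozenset(dendro.leaf_labels)}

    def test_hand_computed_intersection(self):
        d1 = Dendrogram(leaf_labels=list("abcd"), merges=[
            (("a",), ("b",), 1.0), (("a", "b"), ("c",), 2.0),
            (("a", "b", "c"), ("d",), 3.0)])
        d2 = Dendrogram(leaf_labels=list("abcd"), merges=[
            (("a",), ("b",), 1.0), (("c",), ("d",), 1.5),
            (("a", "b"), ("c", "d"), 3.0)])
        tree = strict_consensus(d1, d2)
        assert tree_clades(tree) == {frozenset("ab"), frozenset("abcd")}

    def test_differing_leaf_sets_rejected(self):
        d1 = Dendrogram(leaf_labels=["a", "b"], merges=[(("a",), ("b",), 1.0)])
        d2 = Dendrogram(leaf_labels=["a", "c"], merges=[(("a",), ("c",), 1.0)])
        with pytest.raises(ValueError, match="b"):
            strict_consensus(d1, d2)

    def test_consensus_equals_brute_force_intersection(self):
        for seed in range(25):
            e, z = simulate_similarity_pair(CladeSimSpec(seed=seed))
            d1 = single_linkage(build_channel(e))
            d2 = single_linkage(build_channel(z))
            tree = strict_consensus(d1, d2)
            expected = (d1.clades() & d2.clades()) | {frozenset(d1.leaf_labels)}
            assert tree_clades(tree) == expected

    def test_support_counts_on_internal_nodes(self):
        _, z = simulate_similarity_pair(CladeSimSpec(seed=2))
        dendro = single_linkage(build_channel(z))
        newick = newick_string(strict_consensus(dendro, dendro))
        assert ")2" in newick


class TestBuildCladeTree:
    def test_planted_groups_recovered(self):
        spec = CladeSimSpec(seed=0)
        e, z = simulate_similarity_pair(spec)
        clades = tree_clades(build_clade_tree(e, z))
        for group in spec.planted_partition:
            assert frozenset(group) in clades

    def test_label_permutation_invariance(self, rng):
        spec = CladeSimSpec(seed=4, missing_frac=0.0)
        e, z = simulate_similarity_pair(spec)
        base = tree_clades(build_clade_tree(e, z))
        perm = list(rng.permutation(len(e.labels)))
        ep = SimilarityTable(labels=[e.labels[i] for i in perm],
                             values=e.values[np.ix_(perm, perm)], measure="evalue")
        zp = SimilarityTable(labels=[z.labels[i] for i in perm],
                             values=z.values[np.ix_(perm, perm)], measure="zscore")
        assert tree_clades(build_clade_tree(ep, zp)) == base

    def test_one_channel_all_missing_errors(self):
        spec = CladeSimSpec(seed=0)
        e, z = simulate_similarity_pair(spec)
        blank = SimilarityTable(labels=z.labels,
                                values=np.full_like(z.values, np.nan),
                                measure="zscore")
        with pytest.raises(ValueError):
            build_clade_tree(e, blank)

    def test_contradictory_plants_give_star(self):
        # channel 1 groups {a,b}/{c,d}; channel 2 groups {a,c}/{b,d}
        z1 = ztable(list("abcd"), [[np.nan, 9, 1, 1], [9, np.nan, 1, 1],
                                   [1, 1, np.nan, 9], [1, 1, 9, np.nan]])
        z2 = ztable(list("abcd"), [[np.nan, 1, 9, 1], [1, np.nan, 1, 9],
                                   [9, 1, np.nan, 1], [1, 9, 1, np.nan]])
        d1 = single_linkage(build_channel(z1))
        d2 = single_linkage(build_channel(z2))
        tree = strict_consensus(d1, d2)
        assert tree_clades(tree) == {frozenset("abcd")}
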