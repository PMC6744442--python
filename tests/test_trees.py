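"""Dendrograms, cophenetic comparison, branch collapsing, Newick round-trip."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from conftest import toy_matrix
from famcontent.trees import (
    LinkageTree,
    agglomerative,
    collapse_and_count,
    cophenetic_correlation,
    jaccard_distance_matrix,
    read_newick,
    to_newick,
    within_group_similarity_test,
)


def _dist(labels, entries):
    n = len(labels)
    d = np.zeros((n, n))
    for (i, j), v in entries.items():
        d[i, j] = d[j, i] = v
    return pd.DataFrame(d, index=labels, columns=labels)


THREE_POINT = _dist(["A", "B", "C"], {(0, 1): 0.1, (0, 2): 0.9, (1, 2): 0.8})


class TestJaccardDistance:
    def test_identical_rows_zero(self):
        m = toy_matrix([(1, 0, 1), (1, 0, 1)])
        assert jaccard_distance_matrix(m).iloc[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        m = toy_matrix([(1, 0), (0, 1)])
        assert jaccard_distance_matrix(m).iloc[0, 1] == 1.0

    def test_forced_arithmetic(self):
        m = toy_matrix([(1, 1, 0, 1), (1, 0, 0, 1)])
        assert jaccard_distance_matrix(m).iloc[0, 1] == pytest.approx(1 / 3)

    def test_empty_profiles_warned_distance_zero(self):
        m = toy_matrix([(0, 0), (0, 0)])
        with pytest.warns(UserWarning, match="empty profiles"):
            d = jaccard_distance_matrix(m)
        assert d.iloc[0, 1] == 0.0

    def test_columns_axis(self):
        m = toy_matrix([(1, 1), (1, 0), (0, 0), (1, 1)])
        d = jaccard_distance_matrix(m, axis="columns")
        assert d.loc["f1", "f2"] == pytest.approx(1 - 2 / 3)


class TestAgglomerative:
    @pytest.mark.parametrize(
        "method,final_height",
        [("complete", 0.9), ("single", 0.8), ("average", 0.85)],
    )
    def test_three_point_merge_heights(self, method, final_height):
        tree = agglomerative(THREE_POINT, method=method)
        assert tree.Z[0, 2] == pytest.approx(0.1)   # A,B merge first
        assert tree.Z[1, 2] == pytest.approx(final_height)

    def test_rejects_single_item(self):
        with pytest.raises(ValueError):
            agglomerative(_dist(["A"], {}))

    def test_rejects_unknown_linkage(self):
        with pytest.raises(ValueError):
            agglomerative(THREE_POINT, method="ward")

    def test_linkage_ordering_on_random_matrices(self):
        """Single-linkage cophenetic distances never exceed average- or
        complete-linkage ones (single linkage realizes the subdominant
        ultrametric), and root heights order single <= average <= complete.

        The pairwise average-vs-complete ordering is deliberately not
        asserted: the two methods can produce different topologies, under
        which individual average-linkage cophenetic entries exceed
        complete-linkage ones.
        """
        rng = np.random.default_rng(12)
        for _ in range(20):
            m = toy_matrix(rng.random((12, 25)) < rng.uniform(0.2, 0.8))
            d = jaccard_distance_matrix(m)
            trees = {
                meth: agglomerative(d, method=meth)
                for meth in ("single", "average", "complete")
            }
            coph = {meth: cophenet(t.Z) for meth, t in trees.items()}
            assert (coph["single"] <= coph["average"] + 1e-12).all()
            assert (coph["single"] <= coph["complete"] + 1e-12).all()
            roots = [trees[m].Z[-1, 2] for m in ("single", "average", "complete")]
            assert roots[0] <= roots[1] + 1e-12 <= roots[2] + 2e-12


class TestCopheneticCorrelation:
    def test_self_correlation_is_one(self):
        tree = agglomerative(THREE_POINT, method="complete")
        assert cophenetic_correlation(tree, tree) == pytest.approx(1.0)

    def test_scale_invariance(self):
        tree = agglomerative(THREE_POINT)
        scaled = LinkageTree(Z=tree.Z * np.array([1, 1, 2, 1]), leaves=tree.leaves)
        assert cophenetic_correlation(tree, scaled) == pytest.approx(1.0)

    def test_symmetry(self):
        t1 = agglomerative(THREE_POINT, method="complete")
        t2 = agglomerative(THREE_POINT, method="single")
        assert cophenetic_correlation(t1, t2) == pytest.approx(
            cophenetic_correlation(t2, t1)
        )

    def test_caterpillar_vs_leaf_swap_hand_enumeration(self):
        """4-leaf caterpillars ((A,B),C),D and ((D,B),C),A compared by
        enumerating all 6 cophenetic pairs of each tree by hand."""
        d1 = _dist(["A", "B", "C", "D"],
                   {(0, 1): 1, (0, 2): 2, (1, 2): 2, (0, 3): 3, (1, 3): 3, (2, 3): 3})
        d2 = _dist(["A", "B", "C", "D"],
                   {(3, 1): 1, (3, 2): 2, (1, 2): 2, (3, 0): 3, (1, 0): 3, (2, 0): 3})
        t1 = agglomerative(d1, method="complete")
        t2 = agglomerative(d2, method="complete")
        # tree 1 LCA heights, pair order (A,B),(A,C),(A,D),(B,C),(B,D),(C,D)
        v1 = np.array([1, 2, 3, 2, 3, 3], dtype=float)
        # tree 2 merges (B,D)@1, +C@2, +A@3
        v2 = np.array([3, 3, 3, 2, 1, 2], dtype=float)
        expected = np.corrcoef(v1, v2)[0, 1]  # = -0.5
        assert cophenetic_correlation(t1, t2) == pytest.approx(expected)
        assert expected == pytest.approx(-0.5)

    def test_star_tree_undefined(self):
        d = _dist(["A", "B", "C"], {(0, 1): 1, (0, 2): 1, (1, 2): 1})
        star = agglomerative(d, method="complete")
        other = agglomerative(THREE_POINT)
        assert cophenetic_correlation(star, other) is None

    def test_leaf_set_mismatch_rejected(self):
        t1 = agglomerative(THREE_POINT)
        t2 = agglomerative(_dist(["A", "B", "X"], {(0, 1): 0.1, (0, 2): 0.9, (1, 2): 0.8}))
        with pytest.raises(ValueError):
            cophenetic_correlation(t1, t2)

    def test_dendrogram_vs_newick_phylogeny(self):
        """A dendrogram correlates perfectly with the patristic distances of
        its own Newick export (patristic = 2 x cophenetic on an ultrametric
        tree; Pearson is scale-invariant)."""
        rng = np.random.default_rng(5)
        m = toy_matrix(rng.random((10, 30)) < 0.5)
        tree = agglomerative(jaccard_distance_matrix(m))
        assert cophenetic_correlation(tree, to_newick(tree)) == pytest.approx(1.0)


class TestCollapseAndCount:
    def _tree(self):
        # A,B merge at 0.1, C joins at 1.0
        return agglomerative(
            _dist(["A", "B", "C"], {(0, 1): 0.1, (0, 2): 1.0, (1, 2): 1.0}),
            method="complete",
        )

    def test_hand_evaluated_contraction(self):
        """Edges A->0.1, B->0.1, (AB)->0.9, C->1.0; cutoff 0.25 contracts
        only the two 0.1 branches, giving wedges {A,B} and {C}."""
        groups = {"A": "CPR", "B": "CPR", "C": "BAC"}
        summary = collapse_and_count(self._tree(), groups, fraction=0.25)
        assert sorted((set(w) for w, _ in summary.wedges), key=sorted) == [
            {"A", "B"}, {"C"},
        ]
        assert summary.group_wedge_counts == {"CPR": 1, "BAC": 1}
        assert summary.purity == 1.0

    def test_fraction_zero_every_leaf_a_wedge(self):
        groups = {"A": "x", "B": "x", "C": "x"}
        summary = collapse_and_count(self._tree(), groups, fraction=0.0)
        assert summary.n_wedges == 3

    def test_strict_rule_on_equal_edges(self):
        """Branches equal to the cutoff are not contracted (strictly-shorter
        rule), so equal-length branches survive fraction 1; only a fraction
        above 1 collapses everything into one wedge."""
        d = _dist(["A", "B", "C", "D"],
                  {(0, 1): 1, (2, 3): 1, (0, 2): 2, (0, 3): 2, (1, 2): 2, (1, 3): 2})
        tree = agglomerative(d, method="complete")
        groups = dict.fromkeys("ABCD", "g")
        assert collapse_and_count(tree, groups, fraction=1.0).n_wedges == 4
        assert collapse_and_count(tree, groups, fraction=1.01).n_wedges == 1

    def test_mixed_wedge_counts_toward_both_groups(self):
        groups = {"A": "CPR", "B": "BAC", "C": "BAC"}
        summary = collapse_and_count(self._tree(), groups, fraction=0.25)
        assert summary.group_wedge_counts == {"CPR": 1, "BAC": 2}
        assert summary.purity == pytest.approx(0.5)


class TestWithinGroupSimilarity:
    def test_separated_groups_match_rank_enumeration(self):
        """3 tight CPR-like genomes vs 3 tight but mutually distant non-CPR
        genomes; the two within-group similarity samples (3 pairs each) are
        fully separated, so the two-sided exact p equals the enumeration
        value 2 x C(6,3)^-1 x 2 = 0.1."""
        m = toy_matrix(
            [
                (1, 1, 1, 1, 0, 0, 0, 0, 0, 0),
                (1, 1, 1, 1, 0, 0, 0, 0, 0, 0),
                (1, 1, 1, 1, 0, 0, 0, 0, 0, 0),  # identical: similarity 1
                (0, 0, 0, 0, 1, 1, 0, 0, 0, 0),
                (0, 0, 0, 0, 0, 0, 1, 1, 0, 0),
                (0, 0, 0, 0, 0, 0, 0, 0, 1, 1),  # disjoint: similarity 0
            ],
            genome_ids=[f"g{i}" for i in range(6)],
        )
        groups = {f"g{i}": ("CPR" if i < 3 else "BAC") for i in range(6)}
        res = within_group_similarity_test(m, groups, "CPR", "BAC")
        # independent oracle: exact two-sided p by enumerating all C(6,3)
        # assignments of the 6 pooled similarities {1,1,1,0,0,0}
        from math import comb
        u_obs = 0  # all BAC pairs below all CPR pairs
        n_extreme = 2  # the two fully separated labelings
        assert res.p_value == pytest.approx(2 * 1 / comb(6, 3) * 2 / 2)
        assert res.p_value == pytest.approx(0.1)
        assert res.median_a == 1.0 and res.median_b == 0.0

    def test_identical_groups_p_one(self):
        m = toy_matrix(
            [(1, 1, 0), (1, 0, 1), (1, 1, 0), (1, 0, 1)],
            genome_ids=["a1", "a2", "b1", "b2"],
        )
        groups = {"a1": "CPR", "a2": "CPR", "b1": "BAC", "b2": "BAC"}
        res = within_group_similarity_test(m, groups, "CPR", "BAC")
        assert res.p_value == pytest.approx(1.0)

    def test_small_group_rejected(self):
        m = toy_matrix([(1, 0), (0, 1), (1, 1)], genome_ids=["a1", "a2", "b1"])
        groups = {"a1": "CPR", "a2": "CPR", "b1": "BAC"}
        with pytest.raises(ValueError):
            within_group_similarity_test(m, groups, "CPR", "BAC")

    def test_higher_cpr_dropout_detected(self):
        """With more fragmentary CPR-like drafts (dropout 0.3 vs 0.1) the
        within-CPR similarity distribution sits significantly below the
        within-BAC one at 100 genomes per group."""
        from famcontent import synthetic

        truth = synthetic.default_truth(dropout={"CPR": 0.3, "BAC": 0.1}, seed=4)
        matrix, taxonomy = synthetic.generate_presence_matrix(truth)
        groups = dict(zip(taxonomy["genome_id"], taxonomy["group"]))
        res = within_group_similarity_test(matrix, groups, "CPR", "BAC")
        assert res.median_a < res.median_b
        assert res.p_value < 0.01


class TestNewick:
    def test_two_leaf_round_trip(self):
        t = read_newick("(A:1,B:1):0;")
        assert sorted(l.taxon.label for l in t.leaf_node_iter()) == ["A", "B"]
        lengths = {l.taxon.label: l.edge.length for l in t.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0}

    def test_random_tree_round_trip_preserves_distances(self):
        rng = np.random.default_rng(8)
        m = toy_matrix(rng.random((50, 60)) < 0.5)
        tree = agglomerative(jaccard_distance_matrix(m))
        text = to_newick(tree)
        parsed = read_newick(text)
        # patristic distance on the exported ultrametric tree equals twice
        # the cophenetic distance, to full precision
        from famcontent.trees import _pair_distances

        coph = _pair_distances(tree)
        patristic = _pair_distances(parsed).reindex(coph.index)
        np.testing.assert_allclose(patristic.to_numpy(), 2 * coph.to_numpy(),
                                   atol=1e-9)

    def test_labels_with_special_characters_quoted(self):
        d = _dist(["genome one", "g(2)", "g;3"],
                  {(0, 1): 0.1, (0, 2): 0.9, (1, 2): 0.8})
        tree = agglomerative(d)
        parsed = read_newick(to_newick(tree))
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(d.index)

    def test_malformed_newick_rejected(self):
        with pytest.raises(Exception):
            read_newick("((A:1,B:1:0;")
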