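import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

import phenolscreen.profiles as prof
from phenolscreen.errors import EmptyMatrixError


class TestOverlapAnalysis:
    def test_three_disjoint_sets(self):
        s = prof.overlap_analysis({"A": {1, 2, 3}, "B": {4, 5, 6, 7}})
        assert s.union == 7
        assert s.unique == {"A": 3, "B": 4}
        assert s.pairwise[frozenset(("A", "B"))] == 0

    def test_triple_overlap_from_sets(self):
        sets = {
            "A": {1, 2, 3, 4, 5},
            "B": {4, 5, 6, 7},
            "C": {5, 7, 8},
        }
        s = prof.overlap_analysis(sets)
        assert s.triple == 1  # only gene 5
        assert s.pairwise[frozenset(("A", "B"))] == 2  # inclusive of triple
        assert s.union == 8
        assert s.unique == {"A": 3, "B": 1, "C": 1}
        s.check_inclusion_exclusion()

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 40), max_size=30),
        b=st.sets(st.integers(0, 40), max_size=30),
        c=st.sets(st.integers(0, 40), max_size=30),
    )
    def test_inclusion_exclusion_property(self, a, b, c):
        s = prof.overlap_analysis({"A": a, "B": b, "C": c})
        total = (
            sum(s.sizes.values()) - sum(s.pairwise.values()) + s.triple
        )
        assert total == s.union == len(a | b | c)


class TestOverlapFromCounts:
    def test_genomic_screen_marginals(self):
        """The printed fission-yeast marginals determine the unique counts."""
        s = prof.overlap_from_counts(
            {"BHA": 300, "BPA": 117, "BHT": 15},
            pairwise={("BHA", "BPA"): 74, ("BHA", "BHT"): 5, ("BPA", "BHT"): 2},
            triple=2,
        )
        assert s.unique == {"BHA": 223, "BPA": 43, "BHT": 10}
        assert s.union == 353
        assert s.unique_fraction["BHA"] == pytest.approx(223 / 353)

    def test_bha_unique_from_partial_marginals(self):
        """BHA-only needs just |BHA|, its two pairwise counts and the triple."""
        s = prof.overlap_from_counts(
            {"BHA": 300, "BPA": 117, "BHT": 15},
            pairwise={("BHA", "BPA"): 74, ("BHA", "BHT"): 5},
            triple=2,
        )
        assert s.unique["BHA"] == 223
        assert s.union is None  # undetermined without the third pairwise
        assert s.unique["BPA"] is None

    def test_two_set_union_from_one_unique(self):
        s = prof.overlap_from_counts(
            {"BHA": 154, "BPA": 159}, unique={"BHA": 145}
        )
        assert s.union == 304
        assert s.unique["BPA"] == 150

    def test_undetermined_quantities_reported_as_none(self):
        s = prof.overlap_from_counts({"A": 10, "B": 20})
        assert s.union is None
        assert s.unique == {"A": None, "B": None}


class TestProfileMatrix:
    def _scores(self, rows):
        return pd.DataFrame(rows, columns=["strain", "compound", "gsv"])

    @pytest.mark.parametrize(
        "gsv,expected", [(1.0, 0.0), (2.0, 1.0), (0.5, -1.0)]
    )
    def test_log2_conversion(self, gsv, expected):
        scores = self._scores([["s1", "BHA", gsv], ["s2", "BHA", 1.0]])
        pm = prof.build_profile_matrix(scores)
        assert pm.values.at["s1", "BHA"] == pytest.approx(expected)

    def test_zero_gsv_clipped_at_floor(self):
        scores = self._scores([["s1", "BHA", 0.0]])
        pm = prof.build_profile_matrix(scores, floor=0.05)
        assert pm.values.at["s1", "BHA"] == pytest.approx(np.log2(0.05))

    def test_no_call_rows_dropped_and_reported(self):
        scores = self._scores(
            [["s1", "BHA", 1.0], ["s1", "BPA", 2.0],
             ["s2", "BHA", float("nan")], ["s2", "BPA", 1.0]]
        )
        pm = prof.build_profile_matrix(scores)
        assert pm.strains == ["s1"]
        assert pm.dropped == ["s2"]

    def test_empty_input_raises(self):
        with pytest.raises(EmptyMatrixError):
            prof.build_profile_matrix(self._scores([]))


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_zero(self):
        mat = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]],
                           index=["a", "b", "c"])
        cl = prof.hierarchical_cluster(mat)
        assert cl.heights[0] == 0.0

    def test_three_row_average_linkage_hand_calculation(self):
        """Rows at (0,0), (1,0), (0,4): d12=1, d13=4, d23=sqrt(17).
        Average linkage merges {1,2} at 1, then 3 at (4+sqrt(17))/2."""
        mat = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [0.0, 4.0]],
                           index=["a", "b", "c"])
        cl = prof.hierarchical_cluster(mat)
        np.testing.assert_allclose(
            cl.heights, [1.0, (4.0 + np.sqrt(17.0)) / 2.0]
        )

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(12, 4)))
        cl = prof.hierarchical_cluster(mat)
        assert (np.diff(cl.heights) >= -1e-12).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(rng.normal(size=(10, 3)),
                           index=[f"s{i}" for i in range(10)])
        cl1 = prof.hierarchical_cluster(mat)
        perm = rng.permutation(10)
        cl2 = prof.hierarchical_cluster(mat.iloc[perm])
        # same tree up to leaf relabeling: cophenetic distances between the
        # same labeled pairs agree
        d1 = pd.DataFrame(squareform(cophenet(cl1.linkage_matrix)),
                          index=cl1.labels, columns=cl1.labels)
        d2 = pd.DataFrame(squareform(cophenet(cl2.linkage_matrix)),
                          index=cl2.labels, columns=cl2.labels)
        np.testing.assert_allclose(
            d1.loc[cl1.labels, cl1.labels], d2.loc[cl1.labels, cl1.labels]
        )

    def test_two_effect_regimes_split_into_top_clusters(self):
        """Strains planted at rho~0.2 vs rho~1 separate at the top split."""
        from scipy.cluster.hierarchy import fcluster

        import phenolscreen as ps

        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rho = np.concatenate([np.full(10, 0.2), np.full(10, 1.0)])
            noise = lambda: rng.lognormal(-0.011, 0.149, size=(20, 3))  # cv 0.15
            gsv = rho[:, None] * noise() / noise()
            mat = pd.DataFrame(np.log2(np.clip(gsv, 0.05, None)),
                               index=[f"s{i}" for i in range(20)])
            cl = prof.hierarchical_cluster(mat)
            groups = fcluster(cl.linkage_matrix, t=2, criterion="maxclust")
            if len(set(groups[:10])) == 1 and len(set(groups[10:])) == 1:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_non_finite_entries_rejected(self):
        mat = pd.DataFrame([[0.0, np.inf], [1.0, 2.0]])
        with pytest.raises(ValueError):
            prof.hierarchical_cluster(mat)

    def test_newick_is_parseable_with_matching_leaves(self):
        import io

        from skbio import TreeNode

        mat = pd.DataFrame(np.random.default_rng(1).normal(size=(5, 3)),
                           index=list("abcde"))
        cl = prof.hierarchical_cluster(mat)
        tree = TreeNode.read(io.StringIO(prof.to_newick(cl)))
        assert {t.name for t in tree.tips()} == set("abcde")
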