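"""Ward agglomeration against independent oracles, cophenetic validation,
tree cuts and split-half stability."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, fcluster, linkage

import hmrisk as h
from hmrisk.cluster import (
    DistanceMatrix,
    co_membership_agreement,
    cophenetic_correlation,
    cophenetic_distances,
    cut_tree,
    cut_tree_k,
    merge_table,
    split_half_stability,
    squared_euclidean,
    to_newick,
    ward_agglomerate,
)


def ward_oracle(X):
    """Exhaustive greedy Ward from raw points: at each step merge the pair
    of clusters whose merge cost 2·n_a·n_b/(n_a+n_b)·||c̄_a − c̄_b||² is
    minimal (tie-break: smallest leaf-index pair).  Returns the sequence of
    (merged partition, height)."""
    X = np.asarray(X, float)
    clusters = [frozenset([i]) for i in range(len(X))]
    steps = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            A, B = clusters[a], clusters[b]
            ca = X[list(A)].mean(axis=0)
            cb = X[list(B)].mean(axis=0)
            cost = 2 * len(A) * len(B) / (len(A) + len(B)) * ((ca - cb) ** 2).sum()
            key = (cost, min(min(A), min(B)), max(min(A), min(B)))
            if best is None or key < best[0]:
                best = (key, a, b)
        (cost, _, _), a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
        steps.append((frozenset(clusters), cost))
    return steps


def tree_partitions(tree):
    """Partition after each merge, as a set of frozensets of leaf indices."""
    n = tree.n_leaves
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for t, (a, b, height, _) in enumerate(tree.merges):
        members[n + t] = members.pop(a) | members.pop(b)
        out.append((frozenset(members.values()), height))
    return out


class TestSquaredEuclidean:
    def test_three_four_five(self):
        D = squared_euclidean(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D.values[0, 1] == pytest.approx(25.0)

    def test_identical_rows_zero(self):
        D = squared_euclidean(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert D.values[0, 1] == 0.0

    def test_matches_double_loop(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(6, 3))
        D = squared_euclidean(X)
        for i in range(6):
            for j in range(6):
                assert D.values[i, j] == pytest.approx(
                    sum((X[i, f] - X[j, f]) ** 2 for f in range(3)))

    def test_missing_value_names_item_and_feature(self):
        m = pd.DataFrame({"x": [1.0, np.nan]}, index=["a", "b"])
        m["y"] = [2.0, 3.0]
        with pytest.raises(ValueError, match="'b'.*'x'"):
            squared_euclidean(m)

    def test_fewer_than_two_items_rejected(self):
        with pytest.raises(ValueError):
            squared_euclidean(np.array([[1.0, 2.0]]))


class TestWardAgglomerate:
    def test_two_items_single_merge(self):
        D = DistanceMatrix(ids=("a", "b"), values=np.array([[0.0, 5.0],
                                                            [5.0, 0.0]]))
        tree = ward_agglomerate(D)
        assert len(tree.merges) == 1
        assert tree.merges[0][2] == pytest.approx(5.0)

    def test_well_separated_pairs_merge_first(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 0.0], [10.1, 0.0]])
        tree = ward_agglomerate(squared_euclidean(X))
        first_two = {frozenset(m[:2]) for m in tree.merges[:2]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_bruteforce_greedy_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(3, 8))
        X = rng.normal(size=(n, int(rng.integers(1, 4))))
        tree = ward_agglomerate(squared_euclidean(X))
        got = tree_partitions(tree)
        expected = ward_oracle(X)
        for (pg, hg), (pe, he) in zip(got, expected):
            assert pg == pe
            assert hg == pytest.approx(he, rel=1e-9)

    @pytest.mark.parametrize("trial", range(10))
    def test_heights_nondecreasing(self, trial):
        rng = np.random.default_rng(trial)
        X = rng.normal(size=(12, 4))
        heights = ward_agglomerate(squared_euclidean(X)).heights()
        assert (np.diff(heights) >= -1e-9).all()

    def test_agrees_with_scipy_ward(self):
        """Independent cross-check: scipy's Ward heights on Euclidean input
        are the square roots of the Lance–Williams heights on squared
        Euclidean input, with identical merge structure."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 3))
        tree = ward_agglomerate(squared_euclidean(X))
        Z = linkage(X, "ward")
        np.testing.assert_allclose(tree.heights(), Z[:, 2] ** 2, rtol=1e-9)
        for k in (2, 3, 5):
            mine = cut_tree_k(tree, k).to_numpy()
            theirs = fcluster(Z, k, criterion="maxclust")
            assert co_membership_agreement(
                pd.Series(mine, index=range(10)),
                pd.Series(theirs, index=range(10))) == 1.0

    def test_permutation_invariance_up_to_relabel(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame(rng.normal(size=(9, 3)),
                         index=[f"b{i}" for i in range(9)])
        perm = X.sample(frac=1.0, random_state=5)
        c1 = cut_tree_k(ward_agglomerate(squared_euclidean(X)), 3)
        c2 = cut_tree_k(ward_agglomerate(squared_euclidean(perm)), 3)
        assert co_membership_agreement(c1, c2) == 1.0

    def test_single_item_rejected(self):
        D = DistanceMatrix(ids=("a",), values=np.zeros((1, 1)))
        with pytest.raises(ValueError):
            ward_agglomerate(D)


class TestCophenetic:
    def test_self_ultrametric_correlation_is_one(self):
        """Scored against its own cophenetic matrix, a tree correlates
        perfectly; re-agglomerating that ultrametric also reproduces the
        merge partitions (Ward inflates the heights, so only the topology
        is a fixed point)."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(7, 3))
        tree = ward_agglomerate(squared_euclidean(X))
        coph = cophenetic_distances(tree)
        D2 = DistanceMatrix(ids=tree.leaf_ids, values=coph)
        assert cophenetic_correlation(D2, tree) == pytest.approx(1.0)
        tree2 = ward_agglomerate(D2)
        assert ([frozenset(p) for p, _ in tree_partitions(tree2)]
                == [frozenset(p) for p, _ in tree_partitions(tree)])

    def test_matches_pairwise_pearson_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(8, 3))
        D = squared_euclidean(X)
        tree = ward_agglomerate(D)
        coph = cophenetic_distances(tree)
        pairs = list(itertools.combinations(range(8), 2))
        xs = np.array([D.values[i, j] for i, j in pairs])
        ys = np.array([coph[i, j] for i, j in pairs])
        r_oracle = (((xs - xs.mean()) * (ys - ys.mean())).sum()
                    / np.sqrt(((xs - xs.mean()) ** 2).sum()
                              * ((ys - ys.mean()) ** 2).sum()))
        assert cophenetic_correlation(D, tree) == pytest.approx(r_oracle)

    def test_agrees_with_scipy_cophenet(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(8, 3))
        tree = ward_agglomerate(squared_euclidean(X))
        Z = linkage(X, "ward")
        scipy_coph = cophenet(Z)
        iu = np.triu_indices(8, k=1)
        np.testing.assert_allclose(cophenetic_distances(tree)[iu],
                                   scipy_coph ** 2, rtol=1e-9)

    @pytest.mark.parametrize("trial", range(5))
    def test_bounded(self, trial):
        rng = np.random.default_rng(30 + trial)
        X = rng.normal(size=(6, 2))
        D = squared_euclidean(X)
        r = cophenetic_correlation(D, ward_agglomerate(D))
        assert -1.0 <= r <= 1.0

    def test_constant_distances_undefined(self):
        # equilateral: all pairwise distances equal
        v = np.full((3, 3), 4.0)
        np.fill_diagonal(v, 0.0)
        D = DistanceMatrix(ids=("a", "b", "c"), values=v)
        tree = ward_agglomerate(D)
        assert cophenetic_correlation(D, tree) is None


class TestCutTree:
    def _tree(self):
        X = np.array([[0.0], [0.2], [5.0], [5.2], [10.0], [10.2]])
        return ward_agglomerate(squared_euclidean(X))

    def test_height_zero_all_singletons(self):
        labels = cut_tree(self._tree(), 0.0)
        assert labels.nunique() == 6

    def test_above_root_one_cluster(self):
        tree = self._tree()
        labels = cut_tree(tree, tree.heights()[-1] * 10)
        assert labels.nunique() == 1

    def test_three_planted_groups_recovered(self):
        tree = self._tree()
        heights = tree.heights()
        cut = (heights[2] + heights[3]) / 2  # between pair and group merges
        labels = cut_tree(tree, cut)
        assert labels.nunique() == 3
        assert labels.iloc[0] == labels.iloc[1]
        assert labels.iloc[2] == labels.iloc[3]
        assert labels.iloc[4] == labels.iloc[5]

    def test_cut_k_spans_all_counts(self):
        tree = self._tree()
        for k in range(1, 7):
            assert cut_tree_k(tree, k).nunique() == k


class TestFeatureExclusion:
    def test_excluding_feature_equals_deleting_column(self):
        rng = np.random.default_rng(14)
        m = pd.DataFrame(rng.uniform(0, 10, size=(8, 5)),
                         columns=["Cu", "As", "Zn", "Pb", "Se"],
                         index=[f"b{i}" for i in range(8)])
        t1 = ward_agglomerate(squared_euclidean(m.drop(columns=["Cu"])))
        t2 = ward_agglomerate(squared_euclidean(m[["As", "Zn", "Pb", "Se"]]))
        assert t1.merges == t2.merges


class TestSplitHalfStability:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(10, 3)))
        m.index = [f"b{i}" for i in range(10)]
        r1 = split_half_stability(m, n_splits=5, seed=99)
        r2 = split_half_stability(m, n_splits=5, seed=99)
        assert r1 == r2

    def test_duplicated_items_perfectly_stable(self):
        base = pd.DataFrame([[0.0, 0.0], [0.1, 0.1], [8.0, 8.0], [8.1, 8.1]],
                            index=["a1", "a2", "b1", "b2"])
        dup = pd.concat([base, base.set_index(base.index + "x")])
        rep = split_half_stability(dup, n_splits=10, seed=1)
        assert rep["mean_agreement"] == pytest.approx(1.0)

    def test_planted_two_clusters_highly_stable(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0.0, 0.5, size=(8, 3))
        b = rng.normal(8.0, 0.5, size=(8, 3))
        m = pd.DataFrame(np.vstack([a, b]),
                         index=[f"i{k}" for k in range(16)])
        rep = split_half_stability(m, n_splits=20, seed=7)
        assert rep["mean_agreement"] > 0.9

    def test_too_few_splits_rejected(self):
        m = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError):
            split_half_stability(m, n_splits=0, seed=0)


class TestSerialization:
    def test_merge_table_shape(self):
        tree = ward_agglomerate(squared_euclidean(np.random.default_rng(0)
                                                  .normal(size=(5, 2))))
        mt = merge_table(tree)
        assert list(mt.columns) == ["cluster_a", "cluster_b", "height", "size"]
        assert len(mt) == 4

    def test_newick_is_parseable_and_ultrametric(self):
        from io import StringIO
        from Bio import Phylo
        rng = np.random.default_rng(13)
        X = rng.normal(size=(6, 2))
        tree = ward_agglomerate(squared_euclidean(X))
        nwk = to_newick(tree)
        phylo = Phylo.read(StringIO(nwk), "newick")
        depths = phylo.depths()
        leaf_depths = [d for cl, d in depths.items() if cl.is_terminal()]
        assert len(leaf_depths) == 6
        # every leaf sits at the root height
        assert np.allclose(leaf_depths, tree.heights()[-1], rtol=1e-6)
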