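import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

import typoclust as tc
from typoclust.core import DataMatrix, DistanceSpec


def euclid(X):
    return DistanceSpec("euclidean")


class TestAgglomerative:
    def test_chain_single_linkage(self):
        dm = DataMatrix(np.array([[0.0], [1.0], [10.0]]))
        dend = tc.ahca(dm, method="single", spec=DistanceSpec("euclidean"))
        np.testing.assert_allclose(dend.heights, [1.0, 9.0])
        assert dend.merges[0, :2].tolist() == [0, 1]

    def test_single_linkage_heights_are_mst_edges(self, rng):
        for _ in range(5):
            X = rng.normal(size=(20, 3))
            dend = tc.ahca(DataMatrix(X), "single", DistanceSpec("euclidean"))
            mst = minimum_spanning_tree(squareform(pdist(X))).toarray()
            edges = np.sort(mst[mst > 0])
            np.testing.assert_allclose(np.sort(dend.heights), edges, rtol=1e-10)

    @pytest.mark.parametrize(
        "method, scipy_method",
        [("single", "single"), ("complete", "complete"),
         ("average", "average"), ("mcquitty", "weighted")],
    )
    def test_matches_reference_linkage(self, method, scipy_method, rng):
        X = rng.normal(size=(25, 4))
        dend = tc.ahca(DataMatrix(X), method, DistanceSpec("euclidean"))
        Z = linkage(pdist(X), scipy_method)
        np.testing.assert_allclose(np.sort(dend.heights), np.sort(Z[:, 2]), rtol=1e-9)
        # cut at several k and compare partitions
        from scipy.cluster.hierarchy import fcluster

        for k in (2, 4, 7):
            mine = tc.cut_tree(dend, k).labels
            ref = fcluster(Z, k, criterion="maxclust")
            assert adjusted_rand_score(mine, ref) == pytest.approx(1.0)

    def test_ward_two_blobs_last_merge_dominates(self, two_blobs):
        data, _ = two_blobs
        dend = tc.ahca(data, "ward", DistanceSpec("squared_euclidean"))
        assert dend.heights[-1] > 10 * dend.heights[:-1].max()

    def test_ward_heights_sum_is_twice_total_ss(self, rng):
        """ward.D on squared Euclidean: each merge height is twice the ESS
        increment, so the heights sum to 2T."""
        X = rng.normal(size=(30, 3))
        dm = DataMatrix(X)
        dend = tc.ahca(dm, "ward", DistanceSpec("squared_euclidean"))
        assert dend.heights.sum() == pytest.approx(2 * tc.total_ss(dm), rel=1e-8)

    def test_flexible_beta_default_matches_median_free_form(self, rng):
        # beta=-0.25 flexible scheme still yields a valid monotone-ish tree
        X = rng.normal(size=(15, 2))
        dend = tc.ahca(DataMatrix(X), "flexible_beta", DistanceSpec("squared_euclidean"))
        assert dend.n_leaves == 15
        assert (dend.heights >= 0).all()

    def test_centroid_inversion_flagged_not_raised(self):
        # near-equilateral triangle: classic centroid-linkage inversion
        X = np.array([[0, 0], [1.0, 0], [0.5, 0.9]])
        dend = tc.ahca(DataMatrix(X), "centroid", DistanceSpec("squared_euclidean"))
        assert dend.inversions == [1]

    def test_nonfinite_distance_rejected(self):
        D = np.array([[0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            tc.ahca(D, "average")

    def test_permuting_cases_permutes_labels_only(self, rng):
        X = rng.normal(size=(18, 3))
        perm = rng.permutation(18)
        a = tc.cut_tree(tc.ahca(DataMatrix(X), "average", DistanceSpec("euclidean")), 4)
        b = tc.cut_tree(
            tc.ahca(DataMatrix(X[perm]), "average", DistanceSpec("euclidean")), 4
        )
        assert adjusted_rand_score(a.labels[perm], b.labels) == pytest.approx(1.0)


def brute_force_diana_split(D, members):
    """Independent re-implementation of the splinter procedure with plain
    loops, used as the oracle for every split."""
    members = list(members)
    m = len(members)
    avg = []
    for i in members:
        avg.append(sum(D[i, j] for j in members if j != i) / (m - 1))
    splinter = [members[int(np.argmax(avg))]]
    rest = [i for i in members if i not in splinter]
    while len(rest) > 1:
        best_gain, best_i = 0.0, None
        for i in rest:
            d_rest = sum(D[i, j] for j in rest if j != i) / (len(rest) - 1)
            d_spl = sum(D[i, j] for j in splinter) / len(splinter)
            gain = d_rest - d_spl
            if gain > best_gain + 1e-12:
                best_gain, best_i = gain, i
        if best_i is None:
            break
        splinter.append(best_i)
        rest.remove(best_i)
    return set(splinter), set(rest)


class TestDiana:
    def test_two_separated_pairs_split_first(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        dend = tc.diana(DataMatrix(X), DistanceSpec("euclidean"))
        part = tc.cut_tree(dend, 2)
        assert part.labels.tolist() == [1, 1, 2, 2]

    def test_n2_single_split_at_their_distance(self):
        X = np.array([[0.0], [3.0]])
        dend = tc.diana(DataMatrix(X), DistanceSpec("euclidean"))
        assert dend.heights.tolist() == [3.0]

    def test_every_split_matches_brute_force_splinter_oracle(self, rng):
        for trial in range(4):
            n = int(rng.integers(8, 15))
            X = rng.normal(size=(n, 2))
            D = squareform(pdist(X))
            dend = tc.diana(DataMatrix(X), DistanceSpec("euclidean"))
            # replay the divisive process from the oracle
            clusters = [list(range(n))]
            oracle_partitions = [frozenset(map(frozenset, clusters))]
            while len(clusters) < n:
                diams = [
                    max((D[i, j] for i in c for j in c), default=0.0)
                    for c in clusters
                ]
                idx = int(np.argmax(diams))
                target = clusters.pop(idx)
                if len(target) == 2:
                    a, b = {target[0]}, {target[1]}
                else:
                    a, b = brute_force_diana_split(D, target)
                clusters.extend([sorted(a), sorted(b)])
                oracle_partitions.append(frozenset(frozenset(c) for c in clusters))
            for k in range(1, n + 1):
                part = tc.cut_tree(dend, k)
                got = frozenset(
                    frozenset(np.where(part.labels == c)[0].tolist())
                    for c in range(1, k + 1)
                )
                assert got == oracle_partitions[k - 1], f"trial {trial}, k={k}"

    def test_divisive_merge_heights_nondecreasing(self, rng):
        X = rng.normal(size=(20, 3))
        dend = tc.diana(DataMatrix(X), DistanceSpec("squared_euclidean"))
        assert (np.diff(dend.heights) >= -1e-12).all()


class TestCutTree:
    def test_extreme_cuts(self, rng):
        X = rng.normal(size=(10, 2))
        dend = tc.ahca(DataMatrix(X), "complete", DistanceSpec("euclidean"))
        assert tc.cut_tree(dend, 10).k == 10
        assert tc.cut_tree(dend, 1).k == 1
        with pytest.raises(ValueError):
            tc.cut_tree(dend, 0)
        with pytest.raises(ValueError):
            tc.cut_tree(dend, 11)

    def test_chain_dendrogram_height_rule(self):
        """Cutting between merge j and j+1 leaves n-j clusters."""
        X = np.array([[0.0], [1.0], [3.0], [7.0], [15.0]])
        dm = DataMatrix(X)
        dend = tc.ahca(dm, "single", DistanceSpec("euclidean"))
        n = 5
        for j in range(1, n):
            # after j merges there are n - j clusters
            part = tc.cut_tree(dend, n - j)
            assert part.k == n - j

    def test_nested_cuts_split_exactly_one_cluster(self, rng):
        X = rng.normal(size=(22, 3))
        dend = tc.ahca(DataMatrix(X), "ward", DistanceSpec("squared_euclidean"))
        for k in range(2, 8):
            a = tc.cut_tree(dend, k)
            b = tc.cut_tree(dend, k + 1)
            # count clusters of a that are unions of >1 cluster of b
            split = 0
            for c in range(1, k + 1):
                sub = set(b.labels[a.labels == c])
                if len(sub) > 1:
                    split += 1
                    assert len(sub) == 2
            assert split == 1


class TestWss:
    def test_extremes(self, std_sample):
        dend = tc.ahca(std_sample, "ward", DistanceSpec("squared_euclidean"))
        parts = [tc.cut_tree(dend, k) for k in (1, std_sample.n)]
        tab = tc.wss_series(std_sample, parts)
        assert tab.total_wss.iloc[0] == pytest.approx(tc.total_ss(std_sample))
        assert tab.total_wss.iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_nonincreasing_over_nested_cuts(self, std_sample):
        dend = tc.ahca(std_sample, "ward", DistanceSpec("squared_euclidean"))
        parts = [tc.cut_tree(dend, k) for k in range(1, 10)]
        w = tc.wss_series(std_sample, parts).total_wss.to_numpy()
        assert (np.diff(w) <= 1e-9).all()

    def test_pairwise_identity(self, rng):
        """WSS_c equals the within-cluster pairwise sum of squares over n_c."""
        X = rng.normal(size=(30, 4))
        dm = DataMatrix(X)
        labels = rng.integers(1, 4, 30)
        labels[:3] = [1, 2, 3]
        part = tc.Partition(labels, k=3)
        w = tc.wss_series(dm, [part]).total_wss.iloc[0]
        acc = 0.0
        for c in range(1, 4):
            sub = X[part.labels == c]
            pw = sum(
                ((sub[i] - sub[j]) ** 2).sum()
                for i, j in itertools.combinations(range(len(sub)), 2)
            )
            acc += pw / len(sub)
        assert w == pytest.approx(acc, rel=1e-10)


class TestBannerExport:
    def test_leaf_order_covers_all_cases_contiguously(self, rng):
        X = rng.normal(size=(12, 2))
        dend = tc.ahca(DataMatrix(X), "average", DistanceSpec("euclidean"))
        order = dend.leaf_order()
        assert sorted(order) == list(range(12))
        # every cluster of every cut is contiguous in the leaf order
        pos = {case: i for i, case in enumerate(order)}
        for k in (2, 3, 5):
            part = tc.cut_tree(dend, k)
            for c in range(1, k + 1):
                idx = sorted(pos[i] for i in np.where(part.labels == c)[0])
                assert idx == list(range(idx[0], idx[0] + len(idx)))

    def test_banner_heights_are_first_join_heights(self):
        dm = DataMatrix(np.array([[0.0], [1.0], [10.0]]))
        dend = tc.ahca(dm, "single", DistanceSpec("euclidean"))
        banner = dend.banner_data()
        assert sorted(banner.height.tolist()) == [1.0, 9.0]
        assert len(banner) == 2
        # the adjacent pair {0, 1} joins at height 1
        for _, row in banner.iterrows():
            if {row.case, row.next_case} == {0, 1}:
                assert row.height == 1.0
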