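import itertools

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

import typoclust as tc
from typoclust.core import DataMatrix, DistanceSpec, Partition
from typoclust.quality import (
    QCSet,
    homogeneity_percentages,
    pattern_code,
)


def random_partition(rng, n, k):
    labels = rng.integers(1, k + 1, n)
    labels[:k] = np.arange(1, k + 1)
    return Partition(labels, k=k)


class TestClusterHC:
    def test_identical_members_have_zero_hc(self):
        X = np.vstack([np.zeros((5, 3)), np.ones((5, 3))])
        dm = DataMatrix(X)
        part = Partition(np.repeat([1, 2], 5))
        hc, hcmean, hcmin, hcmax = tc.cluster_hc(dm, part)
        assert hc.tolist() == [0.0, 0.0]

    def test_full_standardized_sample_is_exactly_two(self, std_sample):
        hc, hcmean, *_ = tc.cluster_hc(
            std_sample, Partition(np.ones(std_sample.n, int), k=1)
        )
        assert hc[0] == pytest.approx(2.0, abs=1e-10)

    def test_matches_pairwise_ased_double_loop(self, rng):
        X = rng.normal(size=(40, 3))
        dm = DataMatrix(X)
        part = random_partition(rng, 40, 4)
        hc, hcmean, hcmin, hcmax = tc.cluster_hc(dm, part)
        p = 3
        for c in range(1, 5):
            sub = X[part.labels == c]
            pairs = list(itertools.combinations(range(len(sub)), 2))
            oracle = np.mean([((sub[i] - sub[j]) ** 2).sum() / p for i, j in pairs])
            assert hc[c - 1] == pytest.approx(oracle, rel=1e-10)
        sizes = part.sizes
        assert hcmean == pytest.approx((sizes * hc).sum() / 40)

    def test_wss_identity_links_hc_and_eess(self, rng):
        """sum_c (n_c - 1) * HC_c * p / 2 equals TotalWSS exactly."""
        X = rng.normal(size=(50, 4))
        dm = DataMatrix(X)
        part = random_partition(rng, 50, 5)
        hc, *_ = tc.cluster_hc(dm, part)
        wss = tc.wss_series(dm, [part]).total_wss.iloc[0]
        lhs = ((part.sizes - 1) * hc * 4 / 2).sum()
        assert lhs == pytest.approx(wss, abs=1e-9)


class TestEess:
    def test_singleton_partition_explains_everything(self, std_sample):
        part = Partition(np.arange(1, std_sample.n + 1))
        assert tc.eess_pct(std_sample, part) == pytest.approx(100.0)

    def test_one_cluster_explains_nothing(self, std_sample):
        part = Partition(np.ones(std_sample.n, int), k=1)
        assert tc.eess_pct(std_sample, part) == pytest.approx(0.0)

    def test_matches_per_variable_eta_squared_aggregation(self, rng):
        X = rng.normal(size=(60, 3))
        dm = DataMatrix(X)
        part = random_partition(rng, 60, 4)
        # oracle: aggregate between/total SS variable by variable (ANOVA)
        between = total = 0.0
        for j in range(3):
            x = X[:, j]
            gm = x.mean()
            total += ((x - gm) ** 2).sum()
            for c in range(1, 5):
                sub = x[part.labels == c]
                between += len(sub) * (sub.mean() - gm) ** 2
        assert tc.eess_pct(dm, part) == pytest.approx(100 * between / total, rel=1e-10)

    def test_degenerate_constant_data_rejected(self):
        dm = DataMatrix(np.ones((4, 2)))
        with pytest.raises(ValueError):
            tc.eess_pct(dm, Partition(np.array([1, 1, 2, 2])))


class TestXBmod:
    def test_coincident_centroids_give_minus_hcmean(self, rng):
        base = rng.normal(size=(20, 3))
        X = np.vstack([base, base])  # two clusters, identical centroids
        dm = DataMatrix(X)
        part = Partition(np.repeat([1, 2], 20))
        _, hcmean, *_ = tc.cluster_hc(dm, part)
        assert tc.xbmod(dm, part) == pytest.approx(-hcmean)

    def test_point_clusters_give_their_ased(self):
        X = np.vstack([np.zeros((5, 2)), np.full((5, 2), 3.0)])
        dm = DataMatrix(X)
        part = Partition(np.repeat([1, 2], 5))
        # HCmean = 0, centroid ASED = (9+9)/2 = 9
        assert tc.xbmod(dm, part) == pytest.approx(9.0)

    def test_strictly_increasing_in_separation(self, rng):
        noise = rng.normal(0, 0.4, (30, 2))
        vals = []
        for sep in (1.0, 2.0, 4.0, 8.0):
            X = noise.copy()
            X[15:] += sep
            part = Partition(np.repeat([1, 2], 15))
            vals.append(tc.xbmod(DataMatrix(X), part))
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestSilhouette:
    def test_well_separated_blobs_high(self, two_blobs):
        data, truth = two_blobs
        D = tc.pairwise_distances(data, DistanceSpec("euclidean"))
        assert tc.silhouette_mean(D, truth) > 0.8

    def test_zero_internal_distance_gives_one(self):
        X = np.vstack([np.zeros((4, 2)), np.full((3, 2), 2.0)])
        D = tc.pairwise_distances(DataMatrix(X), DistanceSpec("euclidean"))
        part = Partition(np.array([1, 1, 1, 1, 2, 2, 2]))
        s = tc.silhouette_mean(D, part)
        assert s == pytest.approx(1.0)

    def test_matches_reference_implementation(self, rng):
        X = rng.normal(size=(45, 3))
        part = random_partition(rng, 45, 4)
        D = tc.pairwise_distances(DataMatrix(X), DistanceSpec("euclidean"))
        ref = silhouette_score(X, part.labels, metric="euclidean")
        assert tc.silhouette_mean(D, part) == pytest.approx(ref, abs=1e-10)


class TestHomogeneityPercentages:
    def test_strictness_and_monotonicity(self):
        homs = homogeneity_percentages(
            np.array([0.10, 0.19, 0.50]), np.array([10, 20, 70])
        )
        # 0.10 is NOT below 0.10; 0.50 is NOT below 0.50
        assert homs == (0.0, 30.0, 30.0, 30.0)
        assert homs[0] <= homs[1] <= homs[2] <= homs[3]

    def test_everything_heterogeneous_gives_zeros(self):
        homs = homogeneity_percentages(np.array([0.5, 0.9]), np.array([5, 5]))
        assert homs == (0.0, 0.0, 0.0, 0.0)

    def test_invariant_to_cluster_order(self, rng):
        hc = rng.uniform(0, 1, 6)
        sizes = rng.integers(5, 50, 6)
        perm = rng.permutation(6)
        assert homogeneity_percentages(hc, sizes) == homogeneity_percentages(
            hc[perm], sizes[perm]
        )


class TestAcceptability:
    def _qc(self, eess, xb, hcmean):
        return QCSet(
            k=7, EESS_pct=eess, XBmod=xb, HCmean=hcmean, HCmin=0.1, HCmax=1.0
        )

    def test_good_solution_accepted(self):
        flags = tc.acceptability(self._qc(78.5, 0.554, 0.435))
        assert flags["acceptable"]

    def test_overlapping_solution_rejected(self):
        flags = tc.acceptability(self._qc(44.4, -0.948, 1.122))
        assert not flags["acceptable"]
        assert not flags["eess_ok"] and not flags["xbmod_ok"] and not flags["hcmean_ok"]

    def test_boundaries_are_strict(self):
        flags = tc.acceptability(self._qc(70.0, 0.50, 0.50))
        assert not any([flags["eess_ok"], flags["xbmod_ok"], flags["hcmean_ok"]])


class TestPatterns:
    @pytest.mark.parametrize(
        "z, code",
        [
            (0.05, "."), (-0.05, "."), (0.3, "(H)"), (-0.3, "(L)"),
            (0.6, "H"), (-0.6, "L"), (-1.2, "L+"), (1.7, "H++"),
            (2.2, "H+++"), (2.7, "H++++"), (-3.5, "L++++"),
        ],
    )
    def test_band_lookup(self, z, code):
        assert pattern_code(z) == code

    def test_table_attaches_sizes_and_hc(self, typology7):
        data, truth = typology7
        tab = tc.pattern_table(data, truth)
        df = tab.to_frame()
        assert df.shape == (truth.k, data.p + 2)
        assert df["CLsize"].sum() == data.n
        # codes are driven by the standardized means alone
        for cl in range(truth.k):
            for j, v in enumerate(data.var_names):
                assert tab.codes.iloc[cl, j] == pattern_code(tab.means.iloc[cl, j])


class TestQcInvariances:
    def test_all_qcs_invariant_to_relabeling_and_case_order(self, rng):
        X = rng.normal(size=(50, 3))
        part = random_partition(rng, 50, 4)
        dm = DataMatrix(X)
        D = tc.pairwise_distances(dm, DistanceSpec("ased"))
        q1 = tc.qc_set(dm, part, D=D)
        # permute cases
        perm = rng.permutation(50)
        dmp = DataMatrix(X[perm])
        partp = Partition(part.labels[perm], k=4)
        Dp = tc.pairwise_distances(dmp, DistanceSpec("ased"))
        q2 = tc.qc_set(dmp, partp, D=Dp)
        # relabel clusters
        relab = np.array([0, 3, 1, 4, 2])[part.labels]
        q3 = tc.qc_set(dm, Partition(relab, k=4), D=D)
        for a, b in [(q1, q2), (q1, q3)]:
            for key in ("EESS%", "XBmod", "HCmean", "HCmin", "HCmax",
                        "silhouette", "Hom10", "Hom50"):
                assert a.as_dict()[key] == pytest.approx(b.as_dict()[key], rel=1e-9)

    def test_eess_hcmean_relation_on_balanced_clusters(self, typology7):
        """For clusters that are all reasonably large, EESS% is close to
        100*(1 - HCmean/2)."""
        data, truth = typology7
        assert truth.sizes.min() >= 20
        q = tc.qc_set(data, truth)
        assert abs(q.EESS_pct - 100 * (1 - q.HCmean / 2)) < 1.5
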