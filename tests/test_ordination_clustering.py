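import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from cmfscan.annotation_io import SourceGroup
from cmfscan.ordination_clustering import (
    DistanceMatrix,
    cluster_source_table,
    distance_matrix,
    logistic_pca,
    pca_binary,
    permanova,
    ward_cluster,
)
from cmfscan.screening import PresenceMatrix


def oracle_permanova_f(d, labels):
    """Pseudo-F from the definition, with explicit loops."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i][j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        s = 0.0
        for a, b in itertools.combinations(idx, 2):
            s += d[a][b] ** 2
        ss_within += s / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (len(groups) - 1)) / (ss_within / (n - len(groups)))


def oracle_permanova_exact_p(d, labels):
    f_obs = oracle_permanova_f(d, labels)
    n = len(labels)
    extreme = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if oracle_permanova_f(d, [labels[i] for i in perm]) >= f_obs - 1e-12:
            extreme += 1
    return extreme / total


class TestDistances:
    def test_count_oracle_example(self):
        m = PresenceMatrix(
            ["a", "b"],
            [SourceGroup.NCBI] * 2,
            ["k1", "k2", "k3"],
            np.array([[1, 1, 0], [1, 0, 1]]),
        )
        dj = distance_matrix(m, "jaccard_binary")
        de = distance_matrix(m, "euclidean_binary")
        assert dj.values[0, 1] == pytest.approx(2.0 / 3.0)  # a=1, b=1, c=1
        assert de.values[0, 1] == pytest.approx(math.sqrt(2.0))

    def test_identical_rows_zero_both_metrics(self):
        m = PresenceMatrix(
            ["a", "b"],
            [SourceGroup.NCBI] * 2,
            ["k1", "k2"],
            np.array([[1, 0], [1, 0]]),
        )
        for metric in ("jaccard_binary", "euclidean_binary"):
            assert distance_matrix(m, metric).values[0, 1] == 0.0

    def test_complementary_rows_jaccard_one(self):
        m = PresenceMatrix(
            ["a", "b"],
            [SourceGroup.NCBI] * 2,
            ["k1", "k2"],
            np.array([[1, 0], [0, 1]]),
        )
        assert distance_matrix(m, "jaccard_binary").values[0, 1] == 1.0

    def test_all_zero_pair_convention(self):
        m = PresenceMatrix(
            ["a", "b", "c"],
            [SourceGroup.NCBI] * 3,
            ["k1", "k2"],
            np.array([[0, 0], [0, 0], [1, 1]]),
        )
        with pytest.warns(UserWarning, match="all-zero"):
            d = distance_matrix(m, "jaccard_binary")
        assert d.values[0, 1] == 0.0

    def test_matches_scipy_pdist(self, random_binary_matrix):
        x = random_binary_matrix.cells.astype(bool)
        dj = distance_matrix(random_binary_matrix, "jaccard_binary")
        de = distance_matrix(random_binary_matrix, "euclidean_binary")
        np.testing.assert_allclose(
            dj.condensed(), pdist(x, metric="jaccard"), atol=1e-12
        )
        np.testing.assert_allclose(
            de.condensed(), pdist(x.astype(float), metric="euclidean"), atol=1e-12
        )

    def test_euclidean_triangle_inequality(self, random_binary_matrix):
        d = distance_matrix(random_binary_matrix, "euclidean_binary").values
        n = d.shape[0]
        for i, j, k in itertools.combinations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestWardClustering:
    def test_planted_groups_recovered(self, two_group_matrix):
        d = distance_matrix(two_group_matrix, "jaccard_binary")
        labels = ward_cluster(d, 2).labels(2)
        first, second = labels[:10], labels[10:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_two_points_two_clusters(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert sorted(ward_cluster(d, 2).labels(2)) == [1, 2]

    def test_heights_monotone(self, random_binary_matrix):
        d = distance_matrix(random_binary_matrix, "euclidean_binary")
        z = ward_cluster(d, 2).linkage
        assert np.all(np.diff(z[:, 2]) >= -1e-9)

    def test_row_permutation_equivariance(self, two_group_matrix):
        d = distance_matrix(two_group_matrix, "euclidean_binary")
        rng = np.random.default_rng(0)
        perm = rng.permutation(two_group_matrix.n_genomes)
        m2 = PresenceMatrix(
            [two_group_matrix.genome_ids[i] for i in perm],
            [two_group_matrix.source_groups[i] for i in perm],
            two_group_matrix.cmf_keys,
            two_group_matrix.cells[perm],
        )
        d2 = distance_matrix(m2, "euclidean_binary")
        l1 = ward_cluster(d, 2).labels(2)
        l2 = ward_cluster(d2, 2).labels(2)
        # partition identical up to relabeling
        mapping = {}
        for a, b in zip(l1[perm], l2):
            mapping.setdefault(a, b)
            assert mapping[a] == b

    def test_k_exceeding_n_errors(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            ward_cluster(d, 3)


class TestClusterSourceTable:
    def test_perfect_alignment(self):
        labels = np.array([1] * 10 + [2] * 10)
        groups = ["NCBI"] * 10 + ["UMGS"] * 10
        t = cluster_source_table(labels, groups)
        assert sorted(np.diag(t).tolist() + np.diag(t[::-1]).tolist()) == [0, 0, 10, 10]

    def test_swapped_numbering_same_fisher_p(self):
        from cmfscan.group_stats import fisher_exact_2x2

        labels = np.array([1, 1, 1, 2, 2, 1, 2, 2])
        groups = ["A", "A", "B", "B", "A", "B", "A", "B"]
        t1 = cluster_source_table(labels, groups)
        t2 = cluster_source_table(3 - labels, groups)
        np.testing.assert_array_equal(t1, t2[::-1])
        assert fisher_exact_2x2(t1).p_value == pytest.approx(
            fisher_exact_2x2(t2).p_value
        )

    def test_one_group_errors(self):
        with pytest.raises(ValueError):
            cluster_source_table(np.array([1, 1, 2, 2]), ["A", "A", "A", "A"])


class TestPCA:
    def test_rank_one_pattern_single_axis(self):
        cells = np.array([[0, 0, 0], [1, 1, 0], [1, 1, 0], [0, 0, 0]])
        m = PresenceMatrix(
            ["a", "b", "c", "d"], [SourceGroup.NCBI] * 4, ["k1", "k2", "k3"], cells
        )
        res = pca_binary(m, n_axes=3)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_score_distances_reproduce_binary_euclidean(self, random_binary_matrix):
        res = pca_binary(
            random_binary_matrix,
            n_axes=min(random_binary_matrix.n_genomes, random_binary_matrix.n_keys),
        )
        d_scores = squareform(pdist(res.coordinates))
        d_binary = distance_matrix(random_binary_matrix, "euclidean_binary").values
        np.testing.assert_allclose(d_scores, d_binary, atol=1e-9)

    def test_planted_groups_separate_on_axis_one(self, two_group_matrix):
        res = pca_binary(two_group_matrix, n_axes=1)
        signs = np.sign(res.coordinates[:, 0])
        assert len(set(signs[:10])) == 1 and signs[0] != signs[-1]

    def test_constant_matrix_errors(self):
        m = PresenceMatrix(
            ["a", "b"], [SourceGroup.NCBI] * 2, ["k1", "k2"], np.ones((2, 2))
        )
        with pytest.raises(ValueError, match="zero variance"):
            pca_binary(m)


class TestLogisticPCA:
    @pytest.fixture
    def planted(self):
        rng = np.random.default_rng(2024)
        n, p = 40, 60
        probs = np.full((n, p), 0.1)
        probs[: n // 2, : p // 2] = 0.9
        probs[n // 2 :, p // 2 :] = 0.9
        cells = (rng.random((n, p)) < probs).astype("int8")
        return PresenceMatrix(
            [f"g{i}" for i in range(n)],
            [SourceGroup.NCBI] * (n // 2) + [SourceGroup.UMGS] * (n // 2),
            [f"k{j}" for j in range(p)],
            cells,
        )

    def test_objective_monotone_non_increasing(self, planted):
        res = logistic_pca(planted, rank=1, max_iter=200, tol=0.0)
        assert np.all(np.diff(res.objective_trace) <= 1e-8)

    def test_planted_blocks_fully_separated_on_axis_one(self, planted):
        res = logistic_pca(planted, rank=1, max_iter=200)
        s = res.coordinates[:, 0]
        # zero overlap between the two planted blocks
        assert s[:20].max() < s[20:].min() or s[20:].max() < s[:20].min()

    def test_final_objective_beats_linear_init(self, planted):
        res = logistic_pca(planted, rank=2, max_iter=100)
        assert res.objective_trace[-1] <= res.objective_trace[0] + 1e-9

    def test_deterministic_given_seed(self, planted):
        a = logistic_pca(planted, rank=2, seed=3, init="random")
        b = logistic_pca(planted, rank=2, seed=3, init="random")
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_non_binary_or_bad_rank_errors(self, planted):
        with pytest.raises(ValueError):
            logistic_pca(planted, rank=0)
        with pytest.raises(ValueError):
            logistic_pca(planted, rank=min(planted.cells.shape))


class TestPermanova:
    def test_exact_enumeration_matches_oracle(self):
        rng = np.random.default_rng(13)
        x = rng.random((6, 4))
        d = squareform(pdist(x))
        dm = DistanceMatrix([f"g{i}" for i in range(6)], d)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(dm, labels, all_permutations=True)
        assert res.pseudo_F == pytest.approx(oracle_permanova_f(d, labels))
        assert res.p_value == pytest.approx(oracle_permanova_exact_p(d, labels))

    def test_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(21)
        x = rng.random((20, 5))
        x[:10] += 0.8
        d = squareform(pdist(x))
        ids = [f"g{i}" for i in range(20)]
        labels = ["a"] * 10 + ["b"] * 10
        mine = permanova(DistanceMatrix(ids, d), labels, n_permutations=199, seed=0)
        ref = skbio_permanova(SkbioDM(d, ids), grouping=labels, permutations=199)
        assert mine.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_maximal_separation_minimum_p(self):
        # two zero-diameter groups at distance 1
        d = np.ones((6, 6)) - np.eye(6)
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix([f"g{i}" for i in range(6)], d)
        with pytest.warns(UserWarning, match="infinite"):
            res = permanova(dm, ["a"] * 3 + ["b"] * 3, n_permutations=999, seed=1)
        assert res.p_value == pytest.approx(1.0 / 1000.0)

    def test_joint_permutation_invariance_of_f(self):
        rng = np.random.default_rng(8)
        x = rng.random((10, 3))
        d = squareform(pdist(x))
        labels = ["a"] * 5 + ["b"] * 5
        perm = rng.permutation(10)
        f1 = oracle_permanova_f(d, labels)
        f2 = oracle_permanova_f(d[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert f1 == pytest.approx(f2)
        dm = DistanceMatrix([f"g{i}" for i in range(10)], d)
        assert permanova(dm, labels, n_permutations=99, seed=0).pseudo_F == pytest.approx(f1)

    def test_p_bounded_below(self):
        rng = np.random.default_rng(30)
        x = rng.random((12, 4))
        x[:6] += 5.0
        d = squareform(pdist(x))
        dm = DistanceMatrix([f"g{i}" for i in range(12)], d)
        res = permanova(dm, ["a"] * 6 + ["b"] * 6, n_permutations=99, seed=0)
        assert res.p_value >= 1.0 / 100.0
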