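"""Distances, average-linkage trees, cophenetic fit, cuts and k-means.

Tree construction is cross-checked against a brute-force agglomerative
oracle that recomputes inter-cluster distances from the original matrix
at every merge (UPGMA: mean over all cross pairs; WPGMA: recursive
midpoint of the two merged clusters' distances).
"""

import itertools

import numpy as np
import pandas as pd
import pytest

import phyloeco as pe
from phyloeco.cluster import ClusteringError, DistanceMatrix

from conftest import random_distance_matrix


def brute_force_linkage(D: DistanceMatrix, method: str):
    """Return (sorted merge heights, cophenetic matrix) by direct simulation."""
    n = D.n
    clusters = {i: [i] for i in range(n)}
    dist = {frozenset((i, j)): D.data[i, j] for i, j in itertools.combinations(range(n), 2)}
    coph = np.zeros((n, n))
    heights = []
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(
            (((x, y), dist[frozenset((x, y))])
             for x, y in itertools.combinations(sorted(clusters), 2)),
            key=lambda kv: kv[1],
        )
        heights.append(h)
        merged = clusters[a] + clusters[b]
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        for c in list(clusters):
            if c in (a, b):
                continue
            if method == "upgma":
                d = np.mean([D.data[i, j] for i in merged for j in clusters[c]])
            else:  # wpgma
                d = (dist[frozenset((a, c))] + dist[frozenset((b, c))]) / 2.0
            dist[frozenset((next_id, c))] = d
        del clusters[a], clusters[b]
        clusters[next_id] = merged
        next_id += 1
    return heights, coph


class TestDistances:
    def test_euclidean_3_4_5(self):
        m = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        D = pe.pairwise_distances(m, "euclidean")
        assert D.data[0, 1] == pytest.approx(5.0)

    def test_correlation_of_negated_row_is_two(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]], index=["a", "b"])
        D = pe.pairwise_distances(m, "correlation")
        assert D.data[0, 1] == pytest.approx(2.0)

    @pytest.mark.parametrize("metric", ["euclidean", "correlation", "cosine", "cityblock"])
    def test_identical_rows_distance_zero(self, metric):
        m = pd.DataFrame([[1.0, 2.0, 4.0]] * 2, index=["a", "b"])
        assert pe.pairwise_distances(m, metric).data[0, 1] == pytest.approx(0.0)

    def test_constant_row_rejected_under_correlation(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ClusteringError, match="flat"):
            pe.pairwise_distances(m, "correlation")


class TestZscore:
    def test_one_two_three(self):
        m = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        z = pe.zscore_columns(m)
        np.testing.assert_allclose(z["f"], [-1.0, 0.0, 1.0])

    def test_idempotent_and_centered(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(20, 4)))
        z = pe.zscore_columns(m)
        assert np.abs(z.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0)
        np.testing.assert_allclose(pe.zscore_columns(z).to_numpy(), z.to_numpy(), atol=1e-12)


class TestLinkage:
    def test_three_taxon_hand_example(self):
        D = DistanceMatrix(("A", "B", "C"), np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float))
        for method in ("upgma", "wpgma"):
            t = pe.linkage_tree(D, method)
            np.testing.assert_allclose(t.heights, [2.0, 8.0])

    def test_two_taxa_base_case(self):
        D = DistanceMatrix(("A", "B"), np.array([[0, 3.5], [3.5, 0]]))
        t = pe.linkage_tree(D)
        assert t.heights[0] == pytest.approx(3.5)

    def test_upgma_and_wpgma_differ_for_unequal_cluster_sizes(self):
        # A,B merge, then C joins; D last. Unequal sizes make the final
        # UPGMA height a size-weighted mean but the WPGMA height a midpoint.
        d = np.array(
            [[0, 1, 4, 9],
             [1, 0, 4, 11],
             [4, 4, 0, 13],
             [9, 11, 13, 0]], float)
        D = DistanceMatrix(tuple("ABCD"), d)
        hu = pe.linkage_tree(D, "upgma").heights[-1]
        hw = pe.linkage_tree(D, "wpgma").heights[-1]
        assert hu == pytest.approx((9 + 11 + 13) / 3)
        assert hw == pytest.approx(((9 + 11) / 2 + 13) / 2)
        assert hu != pytest.approx(hw)

    @pytest.mark.parametrize("method", ["upgma", "wpgma"])
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, method, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        D = random_distance_matrix(n, seed + 100)
        t = pe.linkage_tree(D, method)
        heights, coph_oracle = brute_force_linkage(D, method)
        np.testing.assert_allclose(sorted(t.heights), sorted(heights), rtol=1e-9)
        coph, _ = pe.cophenetic(D, t)
        np.testing.assert_allclose(coph.data, coph_oracle, rtol=1e-9)


class TestCophenetic:
    def test_ultrametric_input_fits_perfectly(self):
        D = DistanceMatrix(("A", "B", "C"), np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float))
        t = pe.linkage_tree(D, "upgma")
        coph, c = pe.cophenetic(D, t)
        np.testing.assert_allclose(coph.data, D.data)
        assert c == pytest.approx(1.0, abs=1e-12)

    def test_coefficient_equals_independent_condensed_correlation(self):
        D = random_distance_matrix(6, 77)
        t = pe.linkage_tree(D, "upgma")
        coph, c = pe.cophenetic(D, t)
        x, y = D.condensed(), coph.condensed()
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert c == pytest.approx(r, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_cophenetic_distances_are_ultrametric(self, seed):
        D = random_distance_matrix(7, seed)
        coph, _ = pe.cophenetic(D, pe.linkage_tree(D, "wpgma"))
        c = coph.data
        for i, j, k in itertools.combinations(range(7), 3):
            assert c[i, k] <= max(c[i, j], c[j, k]) + 1e-12


class TestCutTree:
    def make_tree(self):
        D = DistanceMatrix(("A", "B", "C"), np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float))
        return pe.linkage_tree(D, "upgma")

    def test_intermediate_cut(self):
        a = pe.cut_tree(self.make_tree(), 5.0)
        assert a.labels["A"] == a.labels["B"] != a.labels["C"]

    def test_cut_above_root_single_cluster(self):
        assert pe.cut_tree(self.make_tree(), 100.0).n_clusters == 1

    def test_cut_below_first_merge_all_singletons(self):
        assert pe.cut_tree(self.make_tree(), 0.5).n_clusters == 3

    def test_boundary_height_is_severed(self):
        # a merge exactly at the cutoff does not survive (strict <)
        a = pe.cut_tree(self.make_tree(), 2.0)
        assert a.n_clusters == 3

    @pytest.mark.parametrize("height", [0.5, 2.5, 6.0, 9.0])
    def test_cut_is_a_partition(self, height):
        D = random_distance_matrix(9, 5)
        t = pe.linkage_tree(D, "upgma")
        a = pe.cut_tree(t, height)
        assert sorted(a.labels) == sorted(D.ids)
        assert set(a.labels.values()) == set(range(1, a.n_clusters + 1))


class TestSelectBestTree:
    def test_enumerates_at_most_eight(self, pipeline_result):
        result, _, _ = pipeline_result
        assert len(result.tree_scores) <= 8

    def test_ranked_descending(self, pipeline_result):
        result, _, _ = pipeline_result
        cs = [s.coefficient for s in result.tree_scores if s.coefficient is not None]
        assert cs == sorted(cs, reverse=True)

    def test_well_separated_archetypes_fit_well(self, pipeline_result):
        result, _, _ = pipeline_result
        assert result.best.coefficient > 0.8

    def test_ultrametric_euclidean_input_wins_with_perfect_fit(self):
        # two 1-d clusters at exact distances -> euclidean tree is exact
        m = pd.DataFrame({"f": [0.0, 0.0, 10.0, 10.0], "g": [0.0, 1.0, 0.0, 1.0]},
                         index=list("abcd"))
        z = pe.zscore_columns(m)
        scores = pe.select_best_tree(z)
        assert scores[0].coefficient <= 1.0 + 1e-12


class TestTreeVsDataCorrelation:
    def test_ultrametric_gives_unity(self):
        d = np.array([[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float)
        D = DistanceMatrix(tuple("ABCD"), d)
        t = pe.linkage_tree(D, "upgma")
        rho, p_rho, r, p_r = pe.tree_vs_data_correlation(D, t)
        assert rho == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_pearson_equals_cophenetic_coefficient(self):
        D = random_distance_matrix(8, 3)
        t = pe.linkage_tree(D, "upgma")
        _, _, r, _ = pe.tree_vs_data_correlation(D, t)
        _, c = pe.cophenetic(D, t)
        assert r == pytest.approx(c, rel=1e-12)

    def test_too_few_taxa_rejected(self):
        D = random_distance_matrix(3, 0)
        with pytest.raises(ClusteringError):
            pe.tree_vs_data_correlation(D, pe.linkage_tree(D))


class TestKmeansCorrelation:
    def two_group_matrix(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        a = np.array([2.0, -1.0, 0.5, -2.0, 1.0])
        b = np.array([-1.5, 2.0, -1.0, 1.0, -0.5])
        rows = [a + rng.normal(scale=0.1, size=5) for _ in range(n // 2)]
        rows += [b + rng.normal(scale=0.1, size=5) for _ in range(n // 2)]
        return pd.DataFrame(rows, index=[f"s{i}" for i in range(n)])

    def test_two_tight_groups_recovered(self):
        m = self.two_group_matrix()
        a, mean_sil, sil = pe.kmeans_correlation(m, k=2, replicates=8, seed=0)
        labels = a.vector(list(m.index))
        assert len(set(labels[:6])) == 1
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[-1]
        assert mean_sil > 0.7
        assert sil.between(-1, 1).all()

    def test_duplicated_points_co_cluster(self):
        m = self.two_group_matrix()
        doubled = pd.concat([m, m.set_index(m.index + "_dup")])
        a, _, _ = pe.kmeans_correlation(doubled, k=2, replicates=8, seed=1)
        for s in m.index:
            assert a.labels[s] == a.labels[s + "_dup"]

    def test_k_equal_n_minus_one_no_crash(self):
        m = self.two_group_matrix(n=6)
        a, mean_sil, sil = pe.kmeans_correlation(m, k=5, replicates=2, seed=2)
        assert a.n_clusters == 5
        assert np.isfinite(mean_sil)

    def test_same_seed_reproducible(self):
        m = self.two_group_matrix(seed=9)
        a1, s1, _ = pe.kmeans_correlation(m, 2, 4, seed=7)
        a2, s2, _ = pe.kmeans_correlation(m, 2, 4, seed=7)
        assert a1.labels == a2.labels
        assert s1 == s2

    def test_random_labels_have_near_zero_silhouette(self):
        rng = np.random.default_rng(4)
        from scipy.spatial.distance import pdist, squareform
        from sklearn.metrics import silhouette_samples

        x = rng.normal(size=(40, 6))
        d = squareform(pdist(x, metric="correlation"))
        labels = rng.integers(0, 3, size=40)
        sil = silhouette_samples(d, labels, metric="precomputed")
        assert abs(sil.mean()) < 0.15
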