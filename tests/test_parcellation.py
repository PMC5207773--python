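"""Feature binning, Spearman distances, deterministic linkage, and cuts."""

import numpy as np
import pytest
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

import striomap as sm
from striomap.parcellation import average_linkage, distance_matrix

from conftest import SMALL_GRID, coarse_truth_labels, mask, naive_average_linkage


class TestFeatureMatrix:
    def _classmap(self, classes):
        from striomap.projection_density import DensityClassMap

        return DensityClassMap(classes, (0.2, 0.05, 0.005), (100.0,) * 3)

    def test_uniform_dense_and_empty(self):
        stri = mask(np.ones((3, 3, 3)))
        dense = self._classmap(np.full((3, 3, 3), 3, dtype=np.uint8))
        none = self._classmap(np.zeros((3, 3, 3), dtype=np.uint8))
        fm = sm.build_feature_matrix({"d": dense, "n": none}, stri, 150.0)
        assert np.all(fm.data[:, 0] == 3)
        assert np.all(fm.data[:, 1] == 0)

    def test_tie_goes_to_higher_category(self):
        # a 150 um bin over 100 um voxels pairs 2 fine voxels on even bins
        stri = mask(np.ones((2, 1, 1)))
        classes = np.zeros((2, 1, 1), dtype=np.uint8)
        classes[0, 0, 0] = 3
        classes[1, 0, 0] = 0  # 1-1 tie inside the first coarse bin
        fm = sm.build_feature_matrix({"a": self._classmap(classes)}, stri, 150.0)
        assert fm.n_voxels == 1
        assert fm.data[0, 0] == 3

    def test_row_count_matches_coarse_striatal_voxels(self, small_scene, small_classmaps):
        fm = sm.build_feature_matrix(small_classmaps, small_scene.striatum_ipsi, 150.0)
        fine_idx = np.argwhere(small_scene.striatum_ipsi.values)
        coarse = np.unique(np.floor(fine_idx * 100.0 / 150.0 + 1e-9).astype(int), axis=0)
        assert fm.n_voxels == coarse.shape[0]

    def test_empty_striatum_rejected(self):
        with pytest.raises(sm.VolumeError):
            sm.build_feature_matrix(
                {"a": self._classmap(np.zeros((2, 2, 2), dtype=np.uint8))},
                mask(np.zeros((2, 2, 2))),
                150.0,
            )


class TestSpearmanDistance:
    def test_identical_and_anticorrelated_rows(self):
        X = np.array([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]], dtype=float)
        D = sm.spearman_distance_matrix(X)
        assert D[0, 1] == pytest.approx(0.0)
        assert D[0, 2] == pytest.approx(2.0)

    def test_constant_rows_follow_declared_rule(self):
        X = np.array([[0, 0, 0], [0, 0, 0], [1, 2, 3]], dtype=float)
        D = sm.spearman_distance_matrix(X)
        assert D[0, 1] == 0.0  # identical constant rows
        assert D[0, 2] == 1.0  # constant vs anything else


class TestAverageLinkage:
    def test_two_identical_rows_merge_at_zero(self):
        X = np.array([[1, 2, 3], [1, 2, 3], [9, 1, 5]], dtype=float)
        Z = sm.cluster_voxels(X, metric="euclidean").linkage
        assert Z[0, 2] == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [10, 30, 50])
    def test_matches_naive_oracle_exactly(self, n):
        rng = np.random.default_rng(n)
        X = rng.integers(0, 4, size=(n, 8)).astype(float)
        D = distance_matrix(X, "spearman")
        Z = average_linkage(D)
        Zo = naive_average_linkage(D)
        assert np.array_equal(Z[:, :2], Zo[:, :2])
        assert np.allclose(Z[:, 2], Zo[:, 2])
        assert np.array_equal(Z[:, 3], Zo[:, 3])

    def test_ultrametric_data_has_unit_cophenetic_everywhere(self):
        # two tight, far-apart groups of duplicated rows
        X = np.vstack([np.tile([0, 0, 1, 1], (4, 1)), np.tile([5, 5, 0, 0], (4, 1))]).astype(float)
        X = X + np.arange(8)[:, None] * 1e-9  # break exact duplicates benignly
        best, coeffs = sm.select_distance_metric(X, candidates=("euclidean", "cityblock"))
        for c in coeffs.values():
            assert c == pytest.approx(1.0, abs=1e-6)

    def test_cophenetic_matches_independent_recomputation(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 5))
        D = distance_matrix(X, "euclidean")
        Z = average_linkage(D)
        # independent cophenetic distances by walking the merge tree
        n = 20
        members = {i: [i] for i in range(n)}
        coph = np.zeros((n, n))
        for step, (a, b, h, _) in enumerate(Z):
            for i in members[int(a)]:
                for j in members[int(b)]:
                    coph[i, j] = coph[j, i] = h
            members[n + step] = members.pop(int(a)) + members.pop(int(b))
        iu = np.triu_indices(n, 1)
        c_oracle = np.corrcoef(D[iu], coph[iu])[0, 1]
        from scipy.spatial.distance import squareform

        c_scipy, _ = hierarchy.cophenet(Z, squareform(D, checks=False))
        assert c_scipy == pytest.approx(c_oracle, abs=1e-9)


class TestCuts:
    def test_k_equals_one(self):
        X = np.random.default_rng(1).normal(size=(10, 4))
        parc = sm.cut_dendrogram(sm.cluster_voxels(X, metric="euclidean"), k=1)
        assert parc.n_clusters == 1
        assert np.all(parc.labels == 1)

    def test_k_above_row_count_rejected(self):
        X = np.random.default_rng(2).normal(size=(5, 3))
        with pytest.raises(sm.VolumeError):
            sm.cut_dendrogram(sm.cluster_voxels(X, metric="euclidean"), k=9)

    def test_outlier_singleton_dropped(self):
        X = np.vstack([np.tile([0.0, 0.0], (5, 1)),
                       np.tile([10.0, 10.0], (5, 1)),
                       [[100.0, -100.0]]])
        parc = sm.cut_dendrogram(sm.cluster_voxels(X, metric="euclidean"), k=3)
        assert parc.n_clusters == 2
        assert parc.singleton_dropped.sum() == 1
        assert parc.labels[-1] == 0

    def test_zero_noise_scene_recovers_planted_subdivisions(self):
        cfg = sm.SceneConfig(seed=5, grid_shape=SMALL_GRID, noise_sd=0.0)
        scene = sm.make_scene(cfg)
        cms = {n: sm.classify_density(v, scene.striatum_ipsi)
               for n, v in scene.cortical_fields.items()}
        fm = sm.build_feature_matrix(cms, scene.striatum_ipsi, 150.0)
        parc = sm.cut_dendrogram(sm.cluster_voxels(fm), k=4)
        truth = coarse_truth_labels(scene, fm)
        keep = ~parc.singleton_dropped
        assert adjusted_rand_score(truth[keep], parc.labels[keep]) >= 0.95


class TestSourcesAndContiguity:
    def test_identical_sources_merge_at_zero(self, small_scene, small_classmaps):
        fm = sm.build_feature_matrix(small_classmaps, small_scene.striatum_ipsi, 150.0)
        dup = sm.FeatureMatrix(
            np.hstack([fm.data, fm.data[:, :1]]),
            fm.coords,
            fm.source_names + ["dup"],
            fm.voxel_um,
            fm.grid_shape,
        )
        Z = sm.cluster_sources(dup).linkage
        assert Z[0, 2] == pytest.approx(0.0)

    def test_two_family_sources_split_at_top(self):
        rng = np.random.default_rng(3)
        n = 40
        fam_a = rng.integers(2, 4, size=(n, 1)) * np.ones((1, 4))
        fam_b = rng.integers(0, 2, size=(n, 1)) * np.ones((1, 4))
        X = np.hstack([fam_a, fam_b])
        res = sm.cluster_sources(
            sm.FeatureMatrix(X.astype(np.uint8), np.zeros((n, 3), int),
                             [f"s{i}" for i in range(8)], 150.0, (1, 1, 1)),
            metric="euclidean",
        )
        labels = hierarchy.fcluster(res.linkage, 2, criterion="maxclust")
        assert set(labels[:4]) != set(labels[4:])
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1

    def test_column_permutation_does_not_change_parcellation(self, small_scene, small_classmaps):
        fm = sm.build_feature_matrix(small_classmaps, small_scene.striatum_ipsi, 150.0)
        parc = sm.cut_dendrogram(sm.cluster_voxels(fm), k=4)
        rng = np.random.default_rng(4)
        perm = rng.permutation(fm.data.shape[1])
        fm_perm = sm.FeatureMatrix(fm.data[:, perm], fm.coords,
                                   [fm.source_names[i] for i in perm],
                                   fm.voxel_um, fm.grid_shape)
        parc_p = sm.cut_dendrogram(sm.cluster_voxels(fm_perm), k=4)
        assert adjusted_rand_score(parc.labels, parc_p.labels) == pytest.approx(1.0)

    def test_split_region_reports_two_components(self):
        coords = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 5], [0, 0, 6]])
        fm = sm.FeatureMatrix(
            np.ones((4, 2), dtype=np.uint8), coords, ["a", "b"], 150.0, (1, 1, 8)
        )
        parc = sm.Parcellation(
            labels=np.ones(4, dtype=np.int64),
            n_clusters=1,
            linkage=np.zeros((3, 4)),
            cut={"k": 1},
            singleton_dropped=np.zeros(4, dtype=bool),
        )
        report = sm.report_contiguity(parc, fm)
        assert report.loc[0, "components"] == 2

    def test_contiguity_report_on_zero_noise_scene(self):
        cfg = sm.SceneConfig(seed=6, grid_shape=SMALL_GRID, noise_sd=0.0)
        scene = sm.make_scene(cfg)
        cms = {n: sm.classify_density(v, scene.striatum_ipsi)
               for n, v in scene.cortical_fields.items()}
        fm = sm.build_feature_matrix(cms, scene.striatum_ipsi, 150.0)
        parc = sm.cut_dendrogram(sm.cluster_voxels(fm), k=4)
        report = sm.report_contiguity(parc, fm)
        assert len(report) == parc.n_clusters
        # planted subdivisions are contiguous: each recovered cluster is
        # largely one component, up to small boundary satellites whose mixed
        # signatures matched another cluster
        assert (report["largest_fraction"] >= 0.9).all()
        assert (report["components"] == 1).sum() >= 1
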