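"""Clustering tests: feature pooling, normalization, the split/merge loop and
out-of-sample assignment."""
import numpy as np
import pandas as pd
import pytest

from hifuseg.isodata import (ISODATAParams, ClusterModel, NormalizationStats,
                             assemble_feature_matrix, assign_to_clusters,
                             isodata_cluster, labels_by_scan, labels_to_volume,
                             normalize_features, FeatureMatrix)
from hifuseg.mapping import ParameterMapSet


def _toy_maps(seed=0, n_excluded=0, shape=(4, 4, 2)):
    rng = np.random.default_rng(seed)
    vols = {name: rng.uniform(1.0, 2.0, shape)
            for name in ("t1_ms", "t2_ms", "adc", "mtr")}
    tumor = np.ones(shape, dtype=bool)
    excl = np.zeros(shape, dtype=bool)
    excl.ravel()[:n_excluded] = True
    return ParameterMapSet(tumor_mask=tumor, exclusion_mask=excl, **vols)


class TestAssemble:
    def test_row_count_and_order(self):
        maps = {("A1", "pre"): _toy_maps(0), ("A1", "post1h"): _toy_maps(1),
                ("A2", "pre"): _toy_maps(2), ("A2", "post1h"): _toy_maps(3)}
        fm = assemble_feature_matrix(maps, ("T1", "T2", "ADC"))
        assert fm.X.shape == (4 * 32, 3)
        # deterministic ordering: animal id, then time point
        first = fm.index.iloc[0]
        assert (first["animal_id"], first["timepoint"]) == ("A1", "pre")
        order = fm.index[["animal_id", "timepoint"]].drop_duplicates()
        assert list(map(tuple, order.values)) == [
            ("A1", "pre"), ("A1", "post1h"), ("A2", "pre"), ("A2", "post1h")]

    def test_excluded_voxels_never_appear(self):
        maps = {("A1", "pre"): _toy_maps(0, n_excluded=5)}
        fm = assemble_feature_matrix(maps, ("T1",))
        assert fm.X.shape[0] == 32 - 5

    def test_column_order_follows_spec(self):
        m = _toy_maps(0)
        fm = assemble_feature_matrix({("A", "pre"): m}, ("T2", "ADC", "T1"))
        np.testing.assert_array_equal(fm.X[:, 2], m.t1_ms[m.included_mask])
        np.testing.assert_array_equal(fm.X[:, 0], m.t2_ms[m.included_mask])

    def test_bad_feature_name_rejected(self):
        with pytest.raises(ValueError):
            assemble_feature_matrix({("A", "pre"): _toy_maps(0)}, ("T1", "FA"))


def _matrix(cols):
    X = np.column_stack(cols)
    idx = pd.DataFrame({"animal_id": "A", "timepoint": "pre",
                        "slice": 0, "row": 0, "col": np.arange(X.shape[0])})
    return FeatureMatrix(X=X, feature_names=tuple(f"f{i}" for i in range(X.shape[1])),
                         index=idx)


class TestNormalize:
    def test_three_point_column(self):
        fm, stats = normalize_features(_matrix([np.array([1.0, 2.0, 3.0])]))
        np.testing.assert_allclose(fm.X[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)
        assert stats.mean[0] == 2.0 and stats.sd[0] == 1.0

    def test_idempotent_and_invertible(self):
        rng = np.random.default_rng(0)
        fm, stats = normalize_features(_matrix([rng.normal(5, 3, 100)]))
        again, stats2 = normalize_features(fm)
        np.testing.assert_allclose(again.X, fm.X, atol=1e-10)
        np.testing.assert_allclose(stats.inverse(fm.X)[:, 0],
                                   stats.mean[0] + fm.X[:, 0] * stats.sd[0])

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2, 50)
        a, _ = normalize_features(_matrix([x]))
        b, _ = normalize_features(_matrix([3.5 * x + 11.0]))
        np.testing.assert_allclose(a.X, b.X, atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            normalize_features(_matrix([np.full(10, 7.0)]))

    def test_output_moments(self):
        rng = np.random.default_rng(2)
        fm, _ = normalize_features(_matrix([rng.uniform(0, 9, 400)]))
        assert abs(fm.X[:, 0].mean()) < 1e-10
        assert abs(fm.X[:, 0].std(ddof=1) - 1.0) < 1e-10


def _blobs(seed=3, n=100, sd=0.3, sep=10.0):
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0, 0.0], [sep, 0.0, 0.0], [0.0, sep, 0.0]])
    X = np.vstack([c + sd * rng.standard_normal((n, 3)) for c in centers])
    return X, np.repeat(np.arange(3), n)


def _partitions_equal(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    pairs_a = a[:, None] == a[None, :]
    pairs_b = b[:, None] == b[None, :]
    return bool(np.array_equal(pairs_a, pairs_b))


class TestISODATA:
    def test_identical_rows_collapse_to_one_cluster(self):
        X = np.zeros((60, 2))
        model = isodata_cluster(X, ISODATAParams(n_initial=4, min_cluster_size=1))
        assert model.n_clusters == 1
        assert (model.labels == 0).all()

    def test_close_blobs_merge(self):
        rng = np.random.default_rng(0)
        X = np.vstack([0.01 * rng.standard_normal((50, 2)),
                       [0.1, 0.0] + 0.01 * rng.standard_normal((50, 2))])
        p = ISODATAParams(n_initial=2, merge_distance=0.5, allow_split=False,
                          min_cluster_size=1)
        model = isodata_cluster(X, p)
        assert model.n_clusters == 1

    def test_elongated_cluster_splits(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([3.0 * rng.standard_normal(400),
                             0.1 * rng.standard_normal(400)])
        p = ISODATAParams(n_initial=1, split_sd=1.0, allow_merge=False,
                          min_cluster_size=10, max_clusters=4)
        model = isodata_cluster(X, p)
        assert model.n_clusters > 1

    def test_final_state_invariants(self):
        X, _ = _blobs()
        p = ISODATAParams(n_initial=10, min_cluster_size=25,
                          split_sd=2.0, merge_distance=2.0)
        model = isodata_cluster(X, p)
        # labels are nearest centroids; centroids are member means; sizes ok
        d2 = ((X[:, None, :] - model.centroids[None]) ** 2).sum(axis=2)
        np.testing.assert_array_equal(model.labels, np.argmin(d2, axis=1))
        for c in range(model.n_clusters):
            np.testing.assert_allclose(model.centroids[c],
                                       X[model.labels == c].mean(axis=0),
                                       atol=1e-10)
        assert (model.sizes >= 25).all()

    def test_objective_monotone_between_structural_events(self):
        X, _ = _blobs(seed=9, sd=1.0, sep=4.0)
        p = ISODATAParams(n_initial=8, min_cluster_size=1,
                          split_sd=1.2, merge_distance=0.8)
        model = isodata_cluster(X, p)
        hist = [h for h in model.history if np.isfinite(h["sse"])]
        for prev, cur in zip(hist, hist[1:]):
            if prev["event"] == "" and cur["event"] == "":
                assert cur["sse"] <= prev["sse"] + 1e-9

    def test_row_permutation_changes_only_numbering(self):
        X, _ = _blobs(seed=5)
        p = ISODATAParams(n_initial=6, min_cluster_size=20,
                          split_sd=2.0, merge_distance=2.0, seed=1)
        base = isodata_cluster(X, p)
        rng = np.random.default_rng(2)
        perm = rng.permutation(X.shape[0])
        permuted = isodata_cluster(X[perm], p)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(perm.size)
        assert _partitions_equal(base.labels, permuted.labels[inv])


class TestAssign:
    @staticmethod
    def _model(centroids):
        d = centroids.shape[1]
        return ClusterModel(feature_names=tuple(f"f{i}" for i in range(d)),
                            stats=NormalizationStats(np.zeros(d), np.ones(d)),
                            centroids=centroids,
                            labels=np.zeros(1, dtype=int))

    def test_training_rows_keep_their_labels(self):
        X, _ = _blobs(seed=7)
        p = ISODATAParams(n_initial=6, min_cluster_size=20,
                          split_sd=2.0, merge_distance=2.0)
        model = isodata_cluster(X, p)
        np.testing.assert_array_equal(
            assign_to_clusters(model, X, already_normalized=True), model.labels)

    def test_equidistant_tie_goes_to_lowest_index(self):
        cents = np.array([[10.0], [9.0], [3.0], [10.0], [10.0], [-3.0]])
        model = self._model(cents)
        # point 0.0 is equidistant to centroids 2 (at 3) and 5 (at -3)
        assert assign_to_clusters(model, np.array([[0.0]]))[0] == 2

    def test_point_at_centroid_gets_that_label(self):
        cents = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 0.0]])
        model = self._model(cents)
        assert assign_to_clusters(model, np.array([[5.0, 5.0]]))[0] == 1

    def test_feature_spec_mismatch_rejected(self):
        model = self._model(np.array([[0.0], [1.0]]))
        fm = _matrix([np.array([0.0, 1.0]), np.array([0.0, 1.0])])
        with pytest.raises(ValueError, match="mismatch"):
            assign_to_clusters(model, fm)


class TestLabelBookkeeping:
    def test_round_trip_through_volumes(self):
        maps = {("A1", "pre"): _toy_maps(0, n_excluded=4),
                ("A1", "post1h"): _toy_maps(1)}
        fm = assemble_feature_matrix(maps, ("T1", "ADC"))
        labels = np.arange(fm.n_rows) % 3
        per_scan = labels_by_scan(fm, labels)
        assert sum(len(v) for v in per_scan.values()) == fm.n_rows
        vol = labels_to_volume(maps[("A1", "pre")], per_scan[("A1", "pre")])
        assert (vol == -1).sum() == 4          # excluded tumor voxels
        assert (vol >= 0).sum() == 28
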