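"""Pooled ISODATA clustering of multiparametric feature vectors.

All included tumor voxels of all animals and time points are pooled into one
feature matrix (rows carry back-references to animal, time point and voxel
coordinates), each feature is normalized to zero mean and unit SD, and the
rows are clustered with the iterative self-organizing (ISODATA) algorithm:
k-means-like nearest-centroid assignment alternating with data-driven
structural moves — clusters below a minimum size are discarded, clusters
whose largest per-dimension SD exceeds a split threshold are split along that
dimension, and centroid pairs closer than a merge threshold are merged — so
the number of clusters is adjusted by the data rather than fixed a priori.

With splitting and merging disabled (and a minimum size of 1) the loop
reduces exactly to Lloyd's k-means, which is used as the test oracle.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mapping import FEATURE_NAMES, ParameterMapSet
from .synthetic import TIMEPOINTS

__all__ = [
    "STUDY_FEATURE_VECTORS", "FeatureMatrix", "NormalizationStats",
    "ISODATAParams", "ClusterModel", "assemble_feature_matrix",
    "normalize_features", "kmeanspp_init", "isodata_cluster",
    "assign_to_clusters", "labels_by_scan", "labels_to_volume",
    "spec_key",
]

#: The eleven feature vectors assessed in the emulated study.
STUDY_FEATURE_VECTORS: tuple[tuple[str, ...], ...] = (
    ("T2",), ("ADC",),
    ("T1", "T2"), ("T2", "ADC"), ("T1", "ADC"), ("ADC", "MTR"),
    ("T1", "T2", "ADC"), ("T2", "ADC", "MTR"), ("T1", "ADC", "MTR"),
    ("T1", "T2", "MTR"),
    ("T1", "T2", "ADC", "MTR"),
)


def spec_key(spec: Sequence[str]) -> str:
    """Canonical string for a feature vector, e.g. ``"T1+T2+ADC"``."""
    return "+".join(spec)


def _validate_spec(spec: Sequence[str]) -> tuple[str, ...]:
    spec = tuple(spec)
    if not spec:
        raise ValueError("feature vector must not be empty")
    for f in spec:
        if f not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {f!r}; expected one of {FEATURE_NAMES}")
    if len(set(spec)) != len(spec):
        raise ValueError("feature vector contains duplicates")
    return spec


@dataclass
class FeatureMatrix:
    """Pooled voxel features with row back-references.

    ``X`` has one row per included tumor voxel over all (animal, time point)
    scans; ``index`` holds the back-references (animal_id, timepoint, slice
    given as the third grid axis, row, col) in the same order.
    """

    X: np.ndarray
    feature_names: tuple[str, ...]
    index: pd.DataFrame

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature matrix must be (n_rows, n_features)")
        if len(self.index) != self.X.shape[0]:
            raise ValueError("index length must match the number of rows")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def scan_slices(self) -> dict[tuple[str, str], np.ndarray]:
        """Row positions per (animal, time point)."""
        groups = self.index.groupby(["animal_id", "timepoint"], sort=False)
        return {key: np.asarray(idx) for key, idx in groups.indices.items()}


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature mean and (sample) SD used for the z-score transform."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def inverse(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.sd + self.mean


def assemble_feature_matrix(maps_by_scan: Mapping[tuple[str, str], ParameterMapSet],
                            spec: Sequence[str]) -> FeatureMatrix:
    """Pool included tumor voxels of all scans into one feature matrix.

    Rows are ordered deterministically by animal id, time point and C-order
    voxel coordinates; excluded voxels never contribute a row.
    """
    spec = _validate_spec(spec)
    order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    keys = sorted(maps_by_scan, key=lambda k: (k[0], order.get(k[1], len(order)), k[1]))

    blocks, records = [], []
    for key in keys:
        maps = maps_by_scan[key]
        if maps is None:
            raise ValueError(f"missing parameter maps for scan {key}")
        included = maps.included_mask
        coords = np.argwhere(included)
        cols = []
        for f in spec:
            vol = maps.feature_volume(f)
            vals = vol[included]
            if np.any(~np.isfinite(vals)):
                raise ValueError(f"non-finite {f} values on included voxels of scan {key}")
            cols.append(vals)
        blocks.append(np.column_stack(cols) if cols else np.empty((0, 0)))
        records.append(pd.DataFrame({
            "animal_id": key[0], "timepoint": key[1],
            "slice": coords[:, 2], "row": coords[:, 0], "col": coords[:, 1],
        }))
    X = np.vstack(blocks) if blocks else np.empty((0, len(spec)))
    index = pd.concat(records, ignore_index=True) if records else pd.DataFrame(
        columns=["animal_id", "timepoint", "slice", "row", "col"])
    return FeatureMatrix(X=X, feature_names=spec, index=index)


def normalize_features(matrix: FeatureMatrix) -> tuple[FeatureMatrix, NormalizationStats]:
    """Z-score each feature column (sample SD, ddof=1).

    Raises on zero-variance columns (degenerate features); the returned
    statistics allow exact inverse transformation.
    """
    X = np.asarray(matrix.X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    if np.any(sd <= 0):
        bad = [matrix.feature_names[i] for i in np.flatnonzero(sd <= 0)]
        raise ValueError(f"zero-variance feature column(s): {bad}")
    stats = NormalizationStats(mean=mean, sd=sd)
    return FeatureMatrix(X=stats.transform(X), feature_names=matrix.feature_names,
                         index=matrix.index), stats


# ---------------------------------------------------------------------------
# ISODATA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ISODATAParams:
    """Tunable ISODATA parameters (all thresholds in normalized space).

    ``min_cluster_size=None`` resolves to ``max(25, 0.0005 * n_rows)`` at fit
    time; ``max_clusters=None`` resolves to twice the initial count. The
    defaults are chosen so that pooled cohort data resolve into tens of
    clusters — fine enough that distinct tissue states (including the
    edematous rim) occupy distinct clusters rather than merging with the
    heterogeneous ablated tissue.
    """

    n_initial: int = 16
    min_cluster_size: int | None = None
    split_sd: float = 0.5
    merge_distance: float = 0.2
    max_merges_per_iteration: int = 2
    max_iterations: int = 200
    tol: float = 1e-4
    seed: int = 0
    allow_split: bool = True
    allow_merge: bool = True
    max_clusters: int | None = None

    def __post_init__(self) -> None:
        if self.n_initial < 1 or self.max_iterations < 1:
            raise ValueError("n_initial and max_iterations must be >= 1")
        if self.split_sd <= 0 or self.merge_distance <= 0 or self.tol <= 0:
            raise ValueError("split_sd, merge_distance and tol must be positive")
        if self.min_cluster_size is not None and self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")

    def resolved_min_size(self, n_rows: int) -> int:
        if self.min_cluster_size is not None:
            return self.min_cluster_size
        return max(25, int(round(0.0005 * n_rows)))

    def resolved_max_clusters(self) -> int:
        return self.max_clusters if self.max_clusters is not None else 2 * self.n_initial


@dataclass
class ClusterModel:
    """Fitted clustering: normalization stats, centroids and row labels."""

    feature_names: tuple[str, ...]
    stats: NormalizationStats
    centroids: np.ndarray          # (k, d), normalized space
    labels: np.ndarray             # (n_rows,)
    history: list[dict] = field(default_factory=list)
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def _nearest(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid labels (ties -> lowest index) and squared distances."""
    d2 = ((X ** 2).sum(axis=1)[:, None] + (centroids ** 2).sum(axis=1)[None, :]
          - 2.0 * X @ centroids.T)
    labels = np.argmin(d2, axis=1)
    return labels, np.maximum(d2[np.arange(X.shape[0]), labels], 0.0)


def _update(X: np.ndarray, labels: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    sizes = np.bincount(labels, minlength=k)
    sums = np.zeros((k, X.shape[1]))
    np.add.at(sums, labels, X)
    centroids = sums / np.maximum(sizes, 1)[:, None]
    return centroids, sizes


def kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: well-spread initial centroids from the data rows."""
    n = X.shape[0]
    if k > n:
        raise ValueError("more initial clusters than rows")
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[i:] = centroids[0]
            break
        probs = d2 / total
        centroids[i] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centroids[i]) ** 2).sum(axis=1))
    return centroids


def _discard_small(X, centroids, min_size):
    """Drop undersized clusters (keeping at least one) and reassign."""
    labels, _ = _nearest(X, centroids)
    while centroids.shape[0] > 1:
        sizes = np.bincount(labels, minlength=centroids.shape[0])
        small = np.flatnonzero(sizes < min_size)
        if small.size == 0:
            break
        if small.size == centroids.shape[0]:
            keep = np.array([int(np.argmax(sizes))])
        else:
            keep = np.flatnonzero(sizes >= min_size)
        centroids = centroids[keep]
        labels, _ = _nearest(X, centroids)
    return centroids, labels


def isodata_cluster(matrix: FeatureMatrix | np.ndarray,
                    params: ISODATAParams,
                    stats: NormalizationStats | None = None,
                    init_centroids: np.ndarray | None = None) -> ClusterModel:
    """Cluster normalized rows with the iterative split/merge scheme.

    Each iteration assigns rows to their nearest centroid, discards clusters
    below the minimum size, recomputes centroids, and then (alternating
    between iterations) either splits clusters whose largest per-dimension SD
    exceeds ``split_sd`` — two new centroids offset by half the threshold
    along that dimension — or merges up to ``max_merges_per_iteration``
    centroid pairs closer than ``merge_distance``. The loop stops when the
    partition is stable with no structural change, when the maximum centroid
    motion falls below ``tol``, or at ``max_iterations`` (flagged in the
    iteration log); a final pure assign/update pass guarantees that every
    row's label is its nearest centroid and every centroid is the mean of its
    members.
    """
    if isinstance(matrix, FeatureMatrix):
        X = np.asarray(matrix.X, dtype=float)
        feature_names = matrix.feature_names
    else:
        X = np.asarray(matrix, dtype=float)
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    n, d = X.shape
    if n < params.n_initial:
        raise ValueError("fewer rows than initial clusters")
    if stats is None:
        stats = NormalizationStats(mean=np.zeros(d), sd=np.ones(d))

    min_size = params.resolved_min_size(n)
    kmax = params.resolved_max_clusters()
    rng = np.random.default_rng(params.seed)
    if init_centroids is not None:
        centroids = np.array(init_centroids, dtype=float, copy=True)
    else:
        centroids = kmeanspp_init(X, params.n_initial, rng)

    history: list[dict] = []
    prev_labels: np.ndarray | None = None
    converged = False
    last_event_iter = -1

    for it in range(params.max_iterations):
        centroids, labels = _discard_small(X, centroids, min_size)
        old = centroids
        centroids, sizes = _update(X, labels, centroids.shape[0])
        motion = float(np.max(np.linalg.norm(centroids - old, axis=1))) \
            if centroids.shape == old.shape else np.inf

        event = ""
        if params.allow_split and it % 2 == 0 and centroids.shape[0] < kmax:
            new_centroids = []
            for c in range(centroids.shape[0]):
                members = X[labels == c]
                if (centroids.shape[0] + len(new_centroids) < kmax
                        and members.shape[0] >= 2 * min_size):
                    sd_dim = members.std(axis=0)
                    dim = int(np.argmax(sd_dim))
                    if sd_dim[dim] > params.split_sd:
                        offset = np.zeros(d)
                        offset[dim] = params.split_sd / 2.0
                        new_centroids.append(centroids[c] + offset)
                        centroids[c] = centroids[c] - offset
                        event = "split"
            if new_centroids:
                centroids = np.vstack([centroids, new_centroids])
        elif params.allow_merge and it % 2 == 1 and centroids.shape[0] > 1:
            diff = centroids[:, None, :] - centroids[None, :, :]
            dist = np.sqrt((diff ** 2).sum(axis=2))
            iu = np.triu_indices(centroids.shape[0], k=1)
            pairs = sorted(zip(dist[iu], iu[0], iu[1]))
            merged: set[int] = set()
            keep = np.ones(centroids.shape[0], dtype=bool)
            n_merged = 0
            for dval, i, j in pairs:
                if dval >= params.merge_distance:
                    break
                if n_merged >= params.max_merges_per_iteration:
                    break
                if i in merged or j in merged:
                    continue
                wi, wj = max(int(sizes[i]), 1), max(int(sizes[j]), 1)
                centroids[i] = (wi * centroids[i] + wj * centroids[j]) / (wi + wj)
                keep[j] = False
                merged.update((i, j))
                n_merged += 1
                event = "merge"
            centroids = centroids[keep]

        sse = float(_nearest(X, centroids)[1].sum())
        history.append({"iteration": it, "n_clusters": int(centroids.shape[0]),
                        "sse": sse, "event": event, "motion": motion})

        if event:
            last_event_iter = it
        # converge only after both the split and the merge phase have been
        # quiet, so a pending structural move cannot be cut off
        if it - last_event_iter >= 2:
            if prev_labels is not None and prev_labels.shape == labels.shape \
                    and np.array_equal(prev_labels, labels):
                converged = True
                break
            if motion < params.tol:
                converged = True
                break
        prev_labels = labels

    if not converged:
        history.append({"iteration": params.max_iterations, "n_clusters":
                        int(centroids.shape[0]), "sse": float("nan"),
                        "event": "max_iterations_reached", "motion": float("nan")})

    # final consistency passes: nearest-centroid labels, mean centroids,
    # sizes >= min_size all hold simultaneously at a Lloyd fixed point
    for _ in range(params.max_iterations):
        centroids, labels = _discard_small(X, centroids, min_size)
        centroids, _ = _update(X, labels, centroids.shape[0])
        new_labels, _ = _nearest(X, centroids)
        if np.array_equal(new_labels, labels):
            break
    labels, _ = _nearest(X, centroids)

    return ClusterModel(feature_names=feature_names, stats=stats,
                        centroids=centroids, labels=labels,
                        history=history, converged=converged)


def assign_to_clusters(model: ClusterModel,
                       features: FeatureMatrix | np.ndarray,
                       already_normalized: bool = False) -> np.ndarray:
    """Label new rows by their nearest model centroid (ties -> lowest index)."""
    if isinstance(features, FeatureMatrix):
        if features.feature_names != tuple(model.feature_names):
            raise ValueError(f"feature spec mismatch: model {model.feature_names}, "
                             f"data {features.feature_names}")
        X = features.X
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != model.centroids.shape[1]:
            raise ValueError("feature dimensionality mismatch")
    if not already_normalized:
        X = model.stats.transform(X)
    labels, _ = _nearest(np.asarray(X, dtype=float), model.centroids)
    return labels


# ---------------------------------------------------------------------------
# label bookkeeping
# ---------------------------------------------------------------------------

def labels_by_scan(matrix: FeatureMatrix,
                   labels: np.ndarray) -> dict[tuple[str, str], np.ndarray]:
    """Split pooled row labels back into per-scan label arrays."""
    labels = np.asarray(labels)
    if labels.shape[0] != matrix.n_rows:
        raise ValueError("labels length must match the feature matrix")
    return {key: labels[rows] for key, rows in matrix.scan_slices().items()}


def labels_to_volume(maps: ParameterMapSet, scan_labels: np.ndarray) -> np.ndarray:
    """Cluster-label volume: cluster id on included voxels, -1 on excluded
    tumor voxels, -2 outside the tumor."""
    included = maps.included_mask
    if int(included.sum()) != scan_labels.shape[0]:
        raise ValueError("label count does not match included voxels")
    vol = np.full(maps.shape, -2, dtype=np.int16)
    vol[maps.tumor_mask] = -1
    vol[included] = scan_labels.astype(np.int16)
    return vol
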