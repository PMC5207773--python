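"""Voxel clustering of striatal input signatures into spatial subdivisions.

The striatum is downsampled to 150 um voxels; each voxel becomes a point
in an n-subregion-dimensional space of ordinal input densities
(0 none, 1 diffuse, 2 moderate, 3 dense).  Voxels are clustered
agglomeratively with average linkage under Spearman rank-correlation
distance (1 - rho); input sources are clustered the same way on the
transposed matrix.  The distance metric itself can be selected by
comparing cophenetic correlation coefficients across candidate metrics.

The agglomeration is implemented here (Lance-Williams average-linkage
update with an explicit lowest-cluster-index tie break) so merge order is
deterministic across platforms even when distances tie; the resulting
linkage matrix uses the standard scipy encoding, so dendrogram cutting
and cophenetic statistics interoperate with ``scipy.cluster.hierarchy``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .core_volumes import BinaryMask, VolumeError, connected_components
from .projection_density import DensityClassMap

DEFAULT_CLUSTER_VOXEL_UM = 150.0


@dataclasses.dataclass
class FeatureMatrix:
    """Coarse striatal voxels (rows) x input sources (columns), ordinal 0..3."""

    data: np.ndarray
    coords: np.ndarray  # (n_rows, 3) coarse voxel indices
    source_names: list[str]
    voxel_um: float
    grid_shape: tuple[int, int, int]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] != self.coords.shape[0]:
            raise VolumeError("feature matrix and coordinate table disagree")
        if self.data.shape[1] != len(self.source_names):
            raise VolumeError("column count must equal number of sources")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    def labels_to_volume(self, labels: np.ndarray) -> np.ndarray:
        vol = np.zeros(self.grid_shape, dtype=np.int32)
        vol[tuple(self.coords.T)] = labels
        return vol


def build_feature_matrix(
    classmaps: dict[str, DensityClassMap],
    striatum: BinaryMask,
    voxel_um: float = DEFAULT_CLUSTER_VOXEL_UM,
) -> FeatureMatrix:
    """Bin fine-grid density classes into coarse clustering voxels.

    Fine voxels are assigned to the coarse bin ``floor(index * fine / coarse)``
    per axis (this also handles non-integral ratios such as 100 -> 150 um,
    where bins alternate between 1 and 2 fine voxels).  The coarse category
    per source is the plurality category over the bin's *striatal* fine
    voxels, with ties going to the higher category; rows are the coarse
    voxels containing at least one striatal fine voxel.
    """
    names = list(classmaps)
    if not names:
        raise VolumeError("need at least one class map")
    first = classmaps[names[0]]
    if first.shape != striatum.values.shape:
        raise VolumeError("class maps and striatum must share the fine grid")
    fine_idx = np.argwhere(striatum.values)
    if fine_idx.shape[0] == 0:
        raise VolumeError("striatum mask contains no voxels")
    vs = np.asarray(striatum.voxel_size_um)
    coarse_idx = np.floor(fine_idx * vs[None, :] / voxel_um + 1e-9).astype(np.int64)
    coarse_shape = tuple(
        int(np.floor((s - 1) * v / voxel_um + 1e-9)) + 1
        for s, v in zip(striatum.values.shape, vs)
    )
    lin = np.ravel_multi_index(tuple(coarse_idx.T), coarse_shape)
    uniq, inv = np.unique(lin, return_inverse=True)
    n_rows = uniq.size
    data = np.zeros((n_rows, len(names)), dtype=np.uint8)
    fine_tuple = tuple(fine_idx.T)
    for j, name in enumerate(names):
        cats = classmaps[name].classes[fine_tuple].astype(np.int64)
        counts = np.bincount(inv * 4 + cats, minlength=n_rows * 4).reshape(n_rows, 4)
        # plurality, ties to the higher category: argmax on reversed columns
        data[:, j] = 3 - counts[:, ::-1].argmax(axis=1)
    coords = np.stack(np.unravel_index(uniq, coarse_shape), axis=1)
    return FeatureMatrix(data, coords, names, voxel_um, coarse_shape)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def spearman_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Square matrix of 1 - Spearman rank correlation between rows.

    Constant (zero-variance) rows have no defined rank correlation; they
    get distance 0 to identical rows and 1 to everything else, so all-zero
    border voxels stay clusterable.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    ranks = rankdata(X, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    ok = norms > 1e-12
    safe = np.where(ok, norms, 1.0)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    D = 1.0 - corr
    # ordinal inputs produce many exact ties; rounding removes float
    # summation-order noise so ties (and hence merge order) are invariant
    # to column permutations
    D = np.round(D, 12)
    np.fill_diagonal(D, 0.0)
    bad = np.nonzero(~ok)[0]
    if bad.size:
        for i in bad:
            same = np.all(X == X[i], axis=1)
            D[i, :] = np.where(same, 0.0, 1.0)
            D[:, i] = D[i, :]
    return np.maximum(D, 0.0)


def distance_matrix(X: np.ndarray, metric: str = "spearman") -> np.ndarray:
    if metric == "spearman":
        return spearman_distance_matrix(X)
    D = squareform(pdist(np.asarray(X, dtype=np.float64), metric=metric))
    return np.nan_to_num(D, nan=1.0)  # constant rows under correlation-like metrics


# ---------------------------------------------------------------------------
# Deterministic average-linkage agglomeration
# ---------------------------------------------------------------------------

def average_linkage(D: np.ndarray) -> np.ndarray:
    """Agglomerative average linkage with lowest-cluster-index tie break.

    Takes a square distance matrix and returns a scipy-format linkage
    matrix Z (rows: left id, right id, merge height, merged size; original
    observations are ids 0..n-1, merges create ids n, n+1, ...).  When
    several pairs tie at the minimal distance, the pair with the
    lexicographically smallest (min id, max id) merges first.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if D.shape != (n, n):
        raise VolumeError("distance matrix must be square")
    if n < 2:
        raise VolumeError("need at least 2 observations to cluster")
    work = D.copy()
    np.fill_diagonal(work, np.inf)
    ids = np.arange(n)
    sizes = np.ones(n, dtype=np.int64)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        m = work.min()
        cand = np.argwhere(np.triu(work == m, k=1))
        # lexicographic tie break on current cluster ids
        key = np.stack(
            [np.minimum(ids[cand[:, 0]], ids[cand[:, 1]]),
             np.maximum(ids[cand[:, 0]], ids[cand[:, 1]])],
            axis=1,
        )
        best = np.lexsort((key[:, 1], key[:, 0]))[0]
        i, j = cand[best]
        id_i, id_j = ids[i], ids[j]
        lo, hi = (id_i, id_j) if id_i < id_j else (id_j, id_i)
        ni, nj = sizes[i], sizes[j]
        Z[step] = (lo, hi, m, ni + nj)
        merged = (ni * work[i] + nj * work[j]) / (ni + nj)
        work[i] = merged
        work[:, i] = merged
        work[i, i] = np.inf
        work[j, :] = np.inf
        work[:, j] = np.inf
        sizes[i] = ni + nj
        ids[i] = n + step
    return Z


@dataclasses.dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy-format Z
    metric: str
    n_items: int
    item_names: list[str] | None = None

    def cophenetic_coefficient(self, D: np.ndarray) -> float:
        c, _ = hierarchy.cophenet(self.linkage, squareform(D, checks=False))
        return float(c)


def cluster_voxels(
    features: FeatureMatrix | np.ndarray,
    metric: str = "spearman",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative dendrogram over feature rows (voxels)."""
    if linkage != "average":
        raise VolumeError("only average linkage is supported")
    X = features.data if isinstance(features, FeatureMatrix) else np.asarray(features)
    D = distance_matrix(X, metric)
    return ClusterResult(average_linkage(D), metric, X.shape[0])


def cluster_sources(
    features: FeatureMatrix | np.ndarray,
    metric: str = "spearman",
    linkage: str = "average",
) -> ClusterResult:
    """Cluster input sources by their striatal target patterns (transposed matrix)."""
    X = features.data if isinstance(features, FeatureMatrix) else np.asarray(features)
    names = features.source_names if isinstance(features, FeatureMatrix) else None
    res = cluster_voxels(X.T, metric=metric, linkage=linkage)
    res.item_names = names
    return res


DEFAULT_METRIC_CANDIDATES = ("spearman", "euclidean", "cityblock", "correlation", "hamming")


def select_distance_metric(
    features: FeatureMatrix | np.ndarray,
    candidates=DEFAULT_METRIC_CANDIDATES,
):
    """Pick the metric whose average-linkage dendrogram best preserves distances.

    Returns ``(best metric name, {metric: cophenetic correlation})``; the
    winner maximizes the cophenetic correlation coefficient (ties go to
    the earlier candidate).
    """
    X = features.data if isinstance(features, FeatureMatrix) else np.asarray(features)
    coeffs = {}
    for metric in candidates:
        D = distance_matrix(X, metric)
        Z = average_linkage(D)
        c, _ = hierarchy.cophenet(Z, squareform(D, checks=False))
        coeffs[metric] = float(c) if np.isfinite(c) else -np.inf
    best = max(coeffs, key=lambda k: coeffs[k])
    return best, coeffs


# ---------------------------------------------------------------------------
# Dendrogram cutting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Parcellation:
    """Flat voxel labels after a dendrogram cut.

    Labels are 1..n_clusters for surviving clusters and 0 for voxels whose
    singleton cluster was dropped.
    """

    labels: np.ndarray
    n_clusters: int
    linkage: np.ndarray
    cut: dict
    singleton_dropped: np.ndarray  # bool per voxel

    def cluster_rows(self, label: int) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]


def cut_dendrogram(
    result: ClusterResult | np.ndarray,
    k: int | None = None,
    height: float | None = None,
    drop_singletons: bool = True,
) -> Parcellation:
    """Cut a dendrogram into flat clusters by count or merge height.

    Clusters containing exactly one voxel are dropped (their voxels are
    flagged unassigned with label 0) and the surviving clusters are
    relabeled 1..m in order of first appearance.
    """
    Z = result.linkage if isinstance(result, ClusterResult) else np.asarray(result)
    n = Z.shape[0] + 1
    if (k is None) == (height is None):
        raise VolumeError("specify exactly one of k or height")
    if k is not None:
        if not 1 <= k <= n:
            raise VolumeError(f"k must lie in [1, {n}], got {k}")
        raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        cut = {"k": int(k)}
    else:
        if height < 0:
            raise VolumeError("height must be >= 0")
        raw = hierarchy.fcluster(Z, t=height, criterion="distance")
        cut = {"height": float(height)}
    labels = np.zeros(n, dtype=np.int64)
    dropped = np.zeros(n, dtype=bool)
    next_label = 1
    seen: dict[int, int] = {}
    counts = np.bincount(raw)
    for i, r in enumerate(raw):
        if drop_singletons and counts[r] == 1:
            dropped[i] = True
            continue
        if r not in seen:
            seen[r] = next_label
            next_label += 1
        labels[i] = seen[r]
    return Parcellation(labels, len(seen), Z, cut, dropped)


def report_contiguity(
    parcellation: Parcellation,
    features: FeatureMatrix,
    connectivity: int = 6,
) -> pd.DataFrame:
    """Per-cluster contiguity on the coarse grid.

    Reports the connected-component count and the fraction of the
    cluster's voxels in its largest component (boundary voxels whose mixed
    input signature matched a non-adjacent cluster appear as small
    satellites).
    """
    rows = []
    for label in range(1, parcellation.n_clusters + 1):
        idx = parcellation.cluster_rows(label)
        if idx.size == 0:
            continue
        vol = np.zeros(features.grid_shape, dtype=bool)
        vol[tuple(features.coords[idx].T)] = True
        comp, count = connected_components(
            BinaryMask(vol, (features.voxel_um,) * 3), connectivity=connectivity
        )
        sizes = np.bincount(comp.labels.ravel())[1:]
        rows.append(
            {
                "cluster": label,
                "voxels": int(idx.size),
                "components": count,
                "largest_fraction": float(sizes.max() / idx.size) if count else 0.0,
            }
        )
    return pd.DataFrame(rows)
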