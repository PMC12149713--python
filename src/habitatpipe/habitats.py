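"""Tumor habitat segmentation by pooled K-means on IVIM parameter maps.

Voxels from the training patients are pooled into one matrix of selected IVIM
channels (default f and D), z-scored with training statistics and clustered
with K-means.  The fitted centroids define population-level habitats that are
then assigned to every tumor by nearest centroid, so habitat identities are
comparable across patients.  Labels are permuted into a fixed physiological
order: label 1 is the cluster with the highest raw perfusion fraction f
(high-perfusion habitat), and the remaining labels follow ascending raw D
(label 2 low-f/low-D = dense cellular tissue, label 3 low-f/high-D =
necrotic-like tissue).

The number of habitats K is selected by bootstrap stability: for each
candidate K the full pooled data is clustered once, then reclustered on B
bootstrap resamples, and the adjusted Rand index between the resample
clustering and the full-data labels (evaluated on the resampled voxels)
measures how reproducible the partition is; the K with the highest mean ARI
wins, smaller K on ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .ivim import IVIMMaps

__all__ = [
    "VoxelFeatureMatrix",
    "HabitatKMeans",
    "HabitatClusterModel",
    "KSelectionReport",
    "pool_voxels",
    "fit_clusters",
    "assign_labels",
    "select_k_bootstrap",
]

DEFAULT_CHANNELS = ("f", "D")


@dataclass
class VoxelFeatureMatrix:
    """Pooled tumor voxels (rows) by IVIM channels (columns), z-scored with
    training-voxel statistics; raw values and row provenance retained."""

    X: np.ndarray                 # normalized, (n_voxels, n_channels)
    raw: np.ndarray               # physical units, same shape
    channels: tuple
    norm_mean: np.ndarray
    norm_std: np.ndarray
    patient_ids: np.ndarray       # per-row provenance
    voxel_index: np.ndarray       # flat voxel index within each patient grid


def pool_voxels(maps_list, channels=DEFAULT_CHANNELS, patient_ids=None,
                stats=None) -> VoxelFeatureMatrix:
    """Stack valid tumor voxels of many patients into one feature matrix.

    Rows with non-finite values (failed fits) are excluded.  Normalization
    statistics are computed on the pooled voxels unless ``stats`` (mean, std)
    from a training pool is supplied.
    """
    if patient_ids is None:
        patient_ids = [str(i) for i in range(len(maps_list))]
    rows, pids, vidx = [], [], []
    for pid, maps in zip(patient_ids, maps_list):
        valid = maps.valid_mask()
        flat = np.flatnonzero(valid.ravel())
        block = np.column_stack([maps.channel(c).ravel()[flat] for c in channels])
        keep = np.isfinite(block).all(axis=1)
        rows.append(block[keep])
        pids.extend([pid] * int(keep.sum()))
        vidx.append(flat[keep])
    raw = np.vstack(rows)
    if raw.shape[0] == 0:
        raise ValueError("no valid voxels to pool")
    if stats is None:
        mean = raw.mean(axis=0)
        std = raw.std(axis=0)
        std = np.where(std > 0, std, 1.0)
    else:
        mean, std = (np.asarray(s, dtype=float) for s in stats)
    X = (raw - mean) / std
    return VoxelFeatureMatrix(X=X, raw=raw, channels=tuple(channels),
                              norm_mean=mean, norm_std=std,
                              patient_ids=np.asarray(pids),
                              voxel_index=np.concatenate(vidx))


def _physiological_order(centroids_raw: np.ndarray, channels) -> np.ndarray:
    """Permutation of cluster indices into physiological label order."""
    channels = list(channels)
    k = centroids_raw.shape[0]
    if "f" in channels and k > 1:
        f_col = channels.index("f")
        first = int(np.argmax(centroids_raw[:, f_col]))
        rest = [i for i in range(k) if i != first]
        if "D" in channels:
            d_col = channels.index("D")
            rest.sort(key=lambda i: centroids_raw[i, d_col])
        else:
            rest.sort(key=lambda i: -centroids_raw[i, f_col])
        return np.array([first] + rest)
    if "D" in channels:
        d_col = channels.index("D")
        return np.argsort(centroids_raw[:, d_col], kind="stable")
    return np.arange(k)


class HabitatKMeans(BaseEstimator, ClusterMixin):
    """K-means habitat clustering with deterministic physiological labels.

    Scikit-learn style estimator operating on a normalized voxel matrix.
    Rows are canonically (lexicographically) sorted before fitting so the
    fitted centroids are invariant to voxel row order.  ``predict`` assigns
    the nearest centroid; exact ties go to the smallest label.

    Parameters
    ----------
    n_clusters : int
        Number of habitats K.
    restarts : int
        Number of k-means++ initializations; the best run by within-cluster
        sum of squares is kept.
    random_state : int
        Seed for the initializations.
    """

    def __init__(self, n_clusters=3, restarts=10, random_state=0,
                 tol=1e-6, max_iter=300):
        self.n_clusters = n_clusters
        self.restarts = restarts
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None, raw_stats=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (voxels x channels)")
        if X.shape[0] < self.n_clusters:
            raise ValueError("fewer voxels than clusters")
        order = np.lexsort(X.T[::-1])  # canonical row order
        km = KMeans(n_clusters=self.n_clusters, init="k-means++",
                    n_init=self.restarts, random_state=self.random_state,
                    tol=self.tol, max_iter=self.max_iter)
        km.fit(X[order])
        self._reorder(km.cluster_centers_, raw_stats)
        self.inertia_ = float(km.inertia_)
        self.labels_ = self.predict(X)
        return self

    def _reorder(self, centers, raw_stats):
        channels = getattr(self, "channels", DEFAULT_CHANNELS)
        if raw_stats is not None:
            mean, std = raw_stats
            raw = centers * std + mean
        else:
            raw = centers
        perm = _physiological_order(raw, channels)
        self.cluster_centers_ = centers[perm]
        self.cluster_centers_raw_ = raw[perm]
        self.label_order_ = perm

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1) + 1  # argmin takes the smallest label on ties


@dataclass
class HabitatClusterModel:
    """Frozen pooled clustering: centroids, normalization and label order."""

    K: int
    channels: tuple
    centroids: np.ndarray         # normalized space, physiological order
    centroids_raw: np.ndarray     # physical units
    label_order: np.ndarray
    norm_mean: np.ndarray
    norm_std: np.ndarray
    seed: int

    def to_json(self, path):
        Path(path).write_text(json.dumps({
            "K": self.K, "channels": list(self.channels),
            "centroids": self.centroids.tolist(),
            "centroids_raw": self.centroids_raw.tolist(),
            "label_order": self.label_order.tolist(),
            "norm_mean": self.norm_mean.tolist(),
            "norm_std": self.norm_std.tolist(), "seed": self.seed}, indent=1))

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(K=d["K"], channels=tuple(d["channels"]),
                   centroids=np.array(d["centroids"]),
                   centroids_raw=np.array(d["centroids_raw"]),
                   label_order=np.array(d["label_order"]),
                   norm_mean=np.array(d["norm_mean"]),
                   norm_std=np.array(d["norm_std"]), seed=d["seed"])


def fit_clusters(voxels: VoxelFeatureMatrix, K: int = 3, seed: int = 0,
                 restarts: int = 10) -> HabitatClusterModel:
    """Fit the pooled habitat K-means and return the frozen cluster model."""
    est = HabitatKMeans(n_clusters=K, restarts=restarts, random_state=seed)
    est.channels = voxels.channels
    est.fit(voxels.X, raw_stats=(voxels.norm_mean, voxels.norm_std))
    return HabitatClusterModel(
        K=K, channels=voxels.channels, centroids=est.cluster_centers_,
        centroids_raw=est.cluster_centers_raw_, label_order=est.label_order_,
        norm_mean=voxels.norm_mean, norm_std=voxels.norm_std, seed=seed)


def assign_labels(maps: IVIMMaps, mask: np.ndarray,
                  model: HabitatClusterModel) -> np.ndarray:
    """Label every valid tumor voxel with its nearest habitat centroid.

    Returns a 3-D integer array: 0 for background, failed fits and
    out-of-mask voxels; 1..K habitat labels elsewhere.  Normalization uses
    the training statistics stored in the model.
    """
    mask = np.asarray(mask).astype(bool)
    valid = mask & maps.valid_mask()
    for c in model.channels:
        valid &= np.isfinite(maps.channel(c))
    if not valid.any():
        raise ValueError("no valid voxels to label")
    feats = np.column_stack([maps.channel(c)[valid] for c in model.channels])
    X = (feats - model.norm_mean) / model.norm_std
    d2 = ((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    labels = np.zeros(mask.shape, dtype=np.int16)
    labels[valid] = np.argmin(d2, axis=1) + 1
    return labels


@dataclass
class KSelectionReport:
    """Bootstrap cluster-stability report used to choose K."""

    candidates: tuple
    mean_ari: dict
    sd_ari: dict
    chosen_k: int
    B: int
    seed: int


def select_k_bootstrap(voxels: VoxelFeatureMatrix | np.ndarray, candidates=(2, 3, 4),
                       B: int = 50, seed: int = 0, restarts: int = 4) -> KSelectionReport:
    """Choose the number of habitats by bootstrap reproducibility.

    For each candidate K the pooled voxels are clustered once; each of B
    bootstrap resamples is reclustered and compared (adjusted Rand index)
    with the full-data partition on the resampled voxels.  The K with the
    highest mean ARI is chosen, preferring smaller K on ties.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if any(k < 2 for k in candidates):
        raise ValueError("candidate K values must be >= 2")
    X = voxels.X if isinstance(voxels, VoxelFeatureMatrix) else np.asarray(voxels, float)
    rng = np.random.default_rng(seed)
    mean_ari, sd_ari = {}, {}
    for K in candidates:
        base = HabitatKMeans(n_clusters=K, restarts=restarts,
                             random_state=seed).fit(X)
        full_labels = base.labels_
        aris = np.empty(B)
        for b in range(B):
            idx = rng.integers(0, X.shape[0], X.shape[0])
            boot = HabitatKMeans(n_clusters=K, restarts=restarts,
                                 random_state=int(rng.integers(2**31 - 1)))
            boot.fit(X[idx])
            aris[b] = adjusted_rand_score(full_labels[idx], boot.predict(X[idx]))
        mean_ari[K] = float(aris.mean())
        sd_ari[K] = float(aris.std())
    best = max(sorted(candidates), key=lambda k: (mean_ari[k], -k))
    return KSelectionReport(candidates=tuple(candidates), mean_ari=mean_ari,
                            sd_ari=sd_ari, chosen_k=int(best), B=B, seed=seed)
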