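"""Clustering engine: twelve model families behind one `fit_model` interface.

Pixel clouds are N x 3 matrices of CIELAB values. Every model, whatever its
native output, is normalised to the same contract: a total partition (labels
in [0, k-1], no noise label) plus k cluster centers expressed in LAB.
Density-based models may leave noise points; those are reassigned to the
nearest center under CIE76. Models whose cost is quadratic in N are fitted
on a seeded subsample and extended to the full cloud by nearest-center
assignment.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.distance import cdist
from sklearn import cluster as _skcluster
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

__all__ = [
    "MODEL_NAMES",
    "ClusterModelConfig",
    "ClusteringResult",
    "ClusteringError",
    "fit_model",
    "kmeans_reference",
    "assign_noise_pixels",
    "pca_project",
    "fuzzy_cmeans",
]

MODEL_NAMES = (
    "kmeans",
    "kmeans_minibatch",
    "kmeans_pca",
    "dbscan",
    "hdbscan",
    "optics_dbscan",
    "ahc",
    "gmm",
    "fuzzy_cmeans",
    "affinity_propagation",
    "mean_shift",
    "spectral",
)

# Quadratic-cost models are fitted on at most this many seeded pixels and
# extended to the rest by nearest-center assignment (override via params
# key "max_fit_points").
_DEFAULT_FIT_CAPS = {
    "spectral": 5000,
    "affinity_propagation": 2000,
    "mean_shift": 5000,
    "ahc": 5000,
    "optics_dbscan": 5000,
}


class ClusteringError(RuntimeError):
    """Raised when a model cannot produce a usable partition."""


@dataclass
class ClusterModelConfig:
    """Configuration for one clustering run.

    ``n_clusters`` is honoured by centroid/partition models; density and
    exemplar models (dbscan, hdbscan, optics_dbscan, affinity_propagation,
    mean_shift) infer the number of clusters and ignore it.
    """

    model_name: str = "kmeans"
    n_clusters: int | None = 4
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.model_name!r}; choose from {MODEL_NAMES}"
            )


@dataclass
class ClusteringResult:
    labels: np.ndarray          # (N,) int, values in [0, k-1]
    centers: np.ndarray         # (k, 3) LAB
    model_name: str
    fit_seconds: float
    converged: bool = True
    extras: dict[str, Any] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.centers.shape[0])


def _as_pixel_matrix(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[-1] == 3:
        arr = arr.reshape(-1, 3)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected an N x 3 pixel matrix, got shape {arr.shape}")
    if arr.shape[0] == 0:
        raise ValueError("empty pixel matrix")
    return arr


def _label_means(pixels: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters densely by first appearance order of sorted unique ids
    and return (dense labels, per-cluster LAB means)."""
    labels = np.asarray(labels)
    uniq = np.unique(labels[labels >= 0])
    if uniq.size == 0:
        raise ClusteringError("model produced no clusters (all points noise)")
    dense = np.full(labels.shape, -1, dtype=int)
    pos = labels >= 0
    dense[pos] = np.searchsorted(uniq, labels[pos])
    centers = np.vstack([pixels[dense == i].mean(axis=0) for i in range(uniq.size)])
    return dense, centers


def assign_noise_pixels(
    labels: np.ndarray, pixels: np.ndarray, centers: np.ndarray
) -> np.ndarray:
    """Replace -1 (noise) labels by the index of the nearest center (CIE76).

    Non-noise labels are returned unchanged. Ties break toward the lowest
    center index.
    """
    centers = np.asarray(centers, dtype=np.float64)
    if centers.size == 0:
        raise ClusteringError("no centers available to absorb noise points")
    labels = np.asarray(labels).copy()
    noise = labels < 0
    if noise.any():
        pix = _as_pixel_matrix(pixels)
        d = cdist(pix[noise], centers)
        labels[noise] = np.argmin(d, axis=1)
    return labels


def pca_project(pixels: np.ndarray, n_components: int) -> np.ndarray:
    """Mean-centered projection of the LAB cloud onto its top principal axes."""
    if not 1 <= n_components <= 3:
        raise ValueError("n_components must be in [1, 3]")
    pix = _as_pixel_matrix(pixels)
    return PCA(n_components=n_components, svd_solver="full").fit_transform(pix)


# ---------------------------------------------------------------------------
# native k-means (Lloyd's algorithm with k-means++ seeding)

def _kmeans_pp_init(pix: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = pix.shape[0]
    centers = np.empty((k, 3))
    centers[0] = pix[rng.integers(n)]
    d2 = np.sum((pix - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a chosen center
            centers[j:] = pix[rng.integers(n, size=k - j)]
            break
        probs = d2 / total
        centers[j] = pix[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((pix - centers[j]) ** 2, axis=1))
    return centers


def _lloyd(pix, centers, max_iter, tol):
    inertia_path = []
    converged = False
    for _ in range(max_iter):
        d2 = cdist(pix, centers, metric="sqeuclidean")
        labels = np.argmin(d2, axis=1)
        inertia_path.append(float(d2[np.arange(len(pix)), labels].sum()))
        new_centers = centers.copy()
        for j in range(centers.shape[0]):
            members = pix[labels == j]
            if len(members):
                new_centers[j] = members.mean(axis=0)
            else:  # empty cluster: reseed at the point farthest from its center
                far = np.argmax(d2[np.arange(len(pix)), labels])
                new_centers[j] = pix[far]
        shift = np.sqrt(np.sum((new_centers - centers) ** 2))
        centers = new_centers
        if shift <= tol:
            converged = True
            break
    d2 = cdist(pix, centers, metric="sqeuclidean")
    labels = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(len(pix)), labels].sum())
    inertia_path.append(inertia)
    return labels, centers, inertia, inertia_path, converged


def kmeans_reference(
    pixels: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> ClusteringResult:
    """Native Lloyd's k-means with k-means++ seeding, best of ``n_init`` restarts.

    Kept as an independently-authored reference against which the library
    k-means is cross-checked; deterministic given ``seed``.
    """
    pix = _as_pixel_matrix(pixels)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > pix.shape[0]:
        raise ValueError(f"k={k} exceeds number of points N={pix.shape[0]}")
    rng = np.random.default_rng(seed)
    best = None
    t0 = time.perf_counter()
    for _ in range(n_init):
        init = _kmeans_pp_init(pix, k, rng)
        labels, centers, inertia, path, conv = _lloyd(pix, init, max_iter, tol)
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia, path, conv)
    labels, centers, inertia, path, conv = best
    # canonical cluster order: by first occurrence in the label vector
    order = []
    for l in labels:
        if l not in order:
            order.append(l)
        if len(order) == k:
            break
    order += [j for j in range(k) if j not in order]
    remap = np.empty(k, dtype=int)
    remap[np.array(order)] = np.arange(k)
    labels = remap[labels]
    centers = centers[np.array(order)]
    return ClusteringResult(
        labels=labels,
        centers=centers,
        model_name="kmeans_reference",
        fit_seconds=time.perf_counter() - t0,
        converged=conv,
        extras={"inertia": inertia, "inertia_path": path},
    )


# ---------------------------------------------------------------------------
# fuzzy C-means (no maintained package ships it; standard Bezdek updates)

def fuzzy_cmeans(
    pixels: np.ndarray,
    c: int,
    m: float = 2.0,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
):
    """Fuzzy C-means: returns (centers, membership U of shape N x c, converged)."""
    pix = _as_pixel_matrix(pixels)
    if c > pix.shape[0]:
        raise ValueError("c exceeds number of points")
    rng = np.random.default_rng(seed)
    u = rng.random((pix.shape[0], c))
    u /= u.sum(axis=1, keepdims=True)
    converged = False
    centers = None
    for _ in range(max_iter):
        um = u ** m
        centers = (um.T @ pix) / um.sum(axis=0)[:, None]
        d = cdist(pix, centers)
        d = np.fmax(d, 1e-12)
        inv = d ** (-2.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        if np.abs(u_new - u).max() < tol:
            u = u_new
            converged = True
            break
        u = u_new
    return centers, u, converged


# ---------------------------------------------------------------------------
# dispatch

def _subsample(pix: np.ndarray, cap: int, seed: int) -> tuple[np.ndarray, np.ndarray | None]:
    n = pix.shape[0]
    if n <= cap:
        return pix, None
    idx = np.random.default_rng(seed).choice(n, size=cap, replace=False)
    idx.sort()
    return pix[idx], idx


def fit_model(pixels: np.ndarray, config: ClusterModelConfig) -> ClusteringResult:
    """Fit the configured model and normalise its output.

    Always returns a total partition with LAB centers; records wall-clock
    fit time. See module docstring for the noise-reassignment and
    subsampling conventions.
    """
    pix = _as_pixel_matrix(pixels)
    name = config.model_name
    k = config.n_clusters
    params = dict(config.params)
    seed = int(config.seed)
    n = pix.shape[0]
    if k is not None and k > n:
        raise ValueError(f"n_clusters={k} exceeds number of pixels N={n}")

    cap = int(params.pop("max_fit_points", _DEFAULT_FIT_CAPS.get(name, n)))
    fit_pix, sub_idx = _subsample(pix, cap, seed)

    extras: dict[str, Any] = {}
    converged = True
    t0 = time.perf_counter()

    if name == "kmeans":
        est = _skcluster.KMeans(
            n_clusters=k, n_init=params.pop("n_init", 10),
            max_iter=params.pop("max_iter", 300), tol=params.pop("tol", 1e-4),
            random_state=seed, **params,
        ).fit(fit_pix)
        labels, centers = est.labels_, est.cluster_centers_
        extras["inertia"] = float(est.inertia_)
    elif name == "kmeans_minibatch":
        est = _skcluster.MiniBatchKMeans(
            n_clusters=k, n_init=params.pop("n_init", 10),
            max_iter=params.pop("max_iter", 300), random_state=seed, **params,
        ).fit(fit_pix)
        labels, centers = est.labels_, est.cluster_centers_
        extras["inertia"] = float(est.inertia_)
    elif name == "kmeans_pca":
        ncomp = int(params.pop("n_components", 2))
        proj = pca_project(fit_pix, ncomp)
        est = _skcluster.KMeans(
            n_clusters=k, n_init=params.pop("n_init", 10), random_state=seed, **params,
        ).fit(proj)
        labels = est.labels_
        labels, centers = _label_means(fit_pix, labels)  # back to LAB space
        extras["n_components"] = ncomp
    elif name == "dbscan":
        est = _skcluster.DBSCAN(
            eps=params.pop("eps", 1.0), min_samples=params.pop("min_samples", 10),
            **params,
        ).fit(fit_pix)
        labels, centers = _label_means(fit_pix, est.labels_)
        labels = assign_noise_pixels(labels, fit_pix, centers)
    elif name == "hdbscan":
        est = _skcluster.HDBSCAN(
            min_cluster_size=params.pop("min_cluster_size", max(25, fit_pix.shape[0] // 100)),
            **params,
        ).fit(fit_pix)
        labels, centers = _label_means(fit_pix, est.labels_)
        labels = assign_noise_pixels(labels, fit_pix, centers)
    elif name == "optics_dbscan":
        est = _skcluster.OPTICS(
            min_samples=params.pop("min_samples", 10),
            cluster_method="dbscan", eps=params.pop("eps", 1.0), **params,
        ).fit(fit_pix)
        labels, centers = _label_means(fit_pix, est.labels_)
        labels = assign_noise_pixels(labels, fit_pix, centers)
    elif name == "ahc":
        est = _skcluster.AgglomerativeClustering(
            n_clusters=k, linkage=params.pop("linkage", "ward"), **params,
        ).fit(fit_pix)
        labels, centers = _label_means(fit_pix, est.labels_)
    elif name == "gmm":
        est = GaussianMixture(
            n_components=k, random_state=seed,
            n_init=params.pop("n_init", 3), **params,
        ).fit(fit_pix)
        labels = est.predict(fit_pix)
        converged = bool(est.converged_)
        labels, centers = _label_means(fit_pix, labels)
    elif name == "fuzzy_cmeans":
        centers, u, converged = fuzzy_cmeans(
            fit_pix, c=k, m=params.pop("m", 2.0), seed=seed, **params,
        )
        labels = np.argmin(cdist(fit_pix, centers), axis=1)  # harden by nearest center
        extras["membership"] = u
        labels, centers = _label_means(fit_pix, labels)
    elif name == "affinity_propagation":
        est = _skcluster.AffinityPropagation(
            damping=params.pop("damping", 0.9), random_state=seed, **params,
        ).fit(fit_pix)
        if est.cluster_centers_indices_ is None or len(est.cluster_centers_indices_) == 0:
            raise ClusteringError("affinity propagation did not converge to exemplars")
        labels, centers = _label_means(fit_pix, est.labels_)
        converged = est.n_iter_ < est.max_iter
    elif name == "mean_shift":
        bw = params.pop("bandwidth", None)
        est = _skcluster.MeanShift(
            bandwidth=bw, bin_seeding=params.pop("bin_seeding", True), **params,
        ).fit(fit_pix)
        labels, centers = _label_means(fit_pix, est.labels_)
    elif name == "spectral":
        est = _skcluster.SpectralClustering(
            n_clusters=k, random_state=seed,
            affinity=params.pop("affinity", "nearest_neighbors"),
            n_neighbors=params.pop("n_neighbors", 10),
            assign_labels=params.pop("assign_labels", "kmeans"), **params,
        ).fit(fit_pix)
        labels, centers = _label_means(fit_pix, est.labels_)
    else:  # pragma: no cover - guarded by ClusterModelConfig
        raise ValueError(f"unknown model {name!r}")

    labels = np.asarray(labels, dtype=int)
    centers = np.asarray(centers, dtype=np.float64)
    if labels.min() < 0:
        labels = assign_noise_pixels(labels, fit_pix, centers)

    if sub_idx is not None:
        # extend the subsample fit to every pixel by nearest LAB center
        labels = np.argmin(cdist(pix, centers), axis=1)

    fit_seconds = time.perf_counter() - t0
    return ClusteringResult(
        labels=labels,
        centers=centers,
        model_name=name,
        fit_seconds=fit_seconds,
        converged=converged,
        extras=extras,
    )
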