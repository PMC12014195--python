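"""Internal clustering validity indices and the model benchmark harness.

The three indices (silhouette, Calinski–Harabasz, Davies–Bouldin) are
implemented here directly — in tests they are cross-checked against both
scikit-learn and naive from-scratch loops — because the benchmark needs
controlled behaviour in the degenerate cases (single cluster, zero within-
cluster scatter, coincident centroids) where library implementations differ.

All distances are Euclidean in CIELAB, the space the clustering runs in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .clustering import ClusterModelConfig, ClusteringResult, fit_model

__all__ = [
    "UndefinedMetricError",
    "QualityReport",
    "silhouette_score",
    "calinski_harabasz",
    "davies_bouldin",
    "benchmark_models",
]


class UndefinedMetricError(ValueError):
    """The index is not defined for this labelling (e.g. a single cluster)."""


def _validate(pixels, labels):
    pix = np.asarray(pixels, dtype=np.float64)
    if pix.ndim == 3:
        pix = pix.reshape(-1, 3)
    lab = np.asarray(labels)
    if pix.shape[0] != lab.shape[0]:
        raise ValueError("pixels and labels disagree in length")
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise UndefinedMetricError("validity indices need at least 2 clusters")
    return pix, lab, uniq


def silhouette_score(
    pixels: np.ndarray,
    labels: np.ndarray,
    sample_size: int | None = 10000,
    seed: int = 0,
) -> float:
    """Mean silhouette s(i) = (b - a) / max(a, b) over (sampled) points.

    a(i) is the mean distance to the other members of i's cluster, b(i) the
    smallest mean distance to any other cluster. Points in singleton clusters
    contribute 0. When ``sample_size`` is smaller than N, s(i) is averaged
    over a seeded sample of points, with distances still taken against the
    full pixel cloud, so sample_size >= N reproduces the exact score.
    """
    pix, lab, uniq = _validate(pixels, labels)
    n = pix.shape[0]
    if sample_size is not None and sample_size < n:
        idx = np.random.default_rng(seed).choice(n, size=sample_size, replace=False)
    else:
        idx = np.arange(n)

    counts = np.array([(lab == u).sum() for u in uniq], dtype=np.float64)
    onehot = (lab[:, None] == uniq[None, :]).astype(np.float64)  # N x k

    svals = np.empty(idx.size)
    chunk = 2048  # bound the pairwise-distance block at chunk x N
    for start in range(0, idx.size, chunk):
        sel = idx[start:start + chunk]
        d = cdist(pix[sel], pix)  # m x N
        sums = d @ onehot          # m x k: total distance to each cluster
        own = np.searchsorted(uniq, lab[sel])
        m = sel.size
        own_count = counts[own]
        a = np.where(
            own_count > 1,
            (sums[np.arange(m), own]) / np.maximum(own_count - 1, 1),
            0.0,
        )
        mean_other = sums / counts[None, :]
        mean_other[np.arange(m), own] = np.inf
        b = mean_other.min(axis=1)
        denom = np.maximum(a, b)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where((own_count > 1) & (denom > 0), (b - a) / denom, 0.0)
        svals[start:start + m] = s
    return float(svals.mean())


def calinski_harabasz(pixels: np.ndarray, labels: np.ndarray) -> float:
    """Variance-ratio criterion [tr(B)/(k-1)] / [tr(W)/(N-k)].

    Returns ``inf`` when the within-cluster scatter is exactly zero
    (perfectly tight clusters), matching the limit of the formula.
    """
    pix, lab, uniq = _validate(pixels, labels)
    n, k = pix.shape[0], uniq.size
    if k >= n:
        raise UndefinedMetricError("Calinski-Harabasz needs N > k")
    gmean = pix.mean(axis=0)
    tr_b = 0.0
    tr_w = 0.0
    for u in uniq:
        members = pix[lab == u]
        c = members.mean(axis=0)
        tr_b += members.shape[0] * float(np.sum((c - gmean) ** 2))
        tr_w += float(np.sum((members - c) ** 2))
    if tr_w == 0.0:
        return math.inf
    return (tr_b / (k - 1)) / (tr_w / (n - k))


def davies_bouldin(pixels: np.ndarray, labels: np.ndarray) -> float:
    """Mean over clusters of the worst (S_i + S_j) / M_ij similarity ratio.

    S is the mean member-to-centroid distance, M the centroid separation.
    Two distinct clusters with coincident centroids make the ratio
    undefined.
    """
    pix, lab, uniq = _validate(pixels, labels)
    k = uniq.size
    centroids = np.vstack([pix[lab == u].mean(axis=0) for u in uniq])
    spread = np.array(
        [cdist(pix[lab == u], centroids[i:i + 1]).mean() for i, u in enumerate(uniq)]
    )
    m = cdist(centroids, centroids)
    off = ~np.eye(k, dtype=bool)
    if np.any(m[off] == 0.0):
        raise UndefinedMetricError(
            "coincident centroids of distinct clusters; Davies-Bouldin undefined"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (spread[:, None] + spread[None, :]) / m
    np.fill_diagonal(ratio, -np.inf)
    return float(ratio.max(axis=1).mean())


@dataclass
class QualityReport:
    model_name: str
    n_clusters_found: int
    silhouette: float | None
    calinski_harabasz: float | None
    davies_bouldin: float | None
    fit_seconds: float
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "k_found": self.n_clusters_found,
            "silhouette": self.silhouette,
            "calinski_harabasz": self.calinski_harabasz,
            "davies_bouldin": self.davies_bouldin,
            "fit_seconds": self.fit_seconds,
            "status": self.status,
        }


def score_result(
    pixels: np.ndarray,
    result: ClusteringResult,
    sample_size: int | None = 10000,
    seed: int = 0,
) -> QualityReport:
    """Compute all three indices for a fitted partition.

    Undefined indices (single cluster, coincident centroids) are recorded as
    None with a note in ``status`` rather than raised, so benchmark tables
    stay complete.
    """
    notes = []
    vals: dict[str, float | None] = {}
    for key, fn in (
        ("silhouette", lambda: silhouette_score(pixels, result.labels, sample_size, seed)),
        ("calinski_harabasz", lambda: calinski_harabasz(pixels, result.labels)),
        ("davies_bouldin", lambda: davies_bouldin(pixels, result.labels)),
    ):
        try:
            vals[key] = fn()
        except UndefinedMetricError as exc:
            vals[key] = None
            notes.append(f"{key} undefined: {exc}")
    status = "ok" if not notes else "; ".join(notes)
    return QualityReport(
        model_name=result.model_name,
        n_clusters_found=result.n_clusters,
        silhouette=vals["silhouette"],
        calinski_harabasz=vals["calinski_harabasz"],
        davies_bouldin=vals["davies_bouldin"],
        fit_seconds=result.fit_seconds,
        status=status,
    )


def benchmark_models(
    pixels: np.ndarray,
    configs: Sequence[ClusterModelConfig],
    sample_size: int | None = 10000,
    seed: int = 0,
) -> list[QualityReport]:
    """Fit every configured model and score it; failures are isolated per row."""
    if not configs:
        raise ValueError("benchmark needs at least one model configuration")
    reports = []
    for cfg in configs:
        try:
            result = fit_model(pixels, cfg)
            reports.append(score_result(pixels, result, sample_size, seed))
        except Exception as exc:  # noqa: BLE001 - sweep must not abort
            reports.append(
                QualityReport(
                    model_name=cfg.model_name,
                    n_clusters_found=0,
                    silhouette=None,
                    calinski_harabasz=None,
                    davies_bouldin=None,
                    fit_seconds=float("nan"),
                    status=f"error: {exc}",
                )
            )
    return reports
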