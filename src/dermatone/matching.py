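"""Cluster-to-palette matching, dominant-tone classification, segmentation.

This is the heart of the pipeline: cluster centers extracted from a skin
photograph are matched to the six FST reference colors by CIE76 distance
(never per-pixel — matching operates on centers only), each cluster's pixel
fraction is tallied, per-class fractions are aggregated across clusters that
share an FST class, and the dominant tone is the class with the largest
aggregated fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.transform import resize as _sk_resize

from .clustering import ClusterModelConfig, fit_model
from .colorspace import resize_image
from .palette import FSTPalette

__all__ = [
    "ClusterMatch",
    "MatchReport",
    "SegmentationMap",
    "match_clusters",
    "cluster_fractions",
    "classify_image",
    "segment_image",
    "sweep_cluster_counts",
]


@dataclass
class ClusterMatch:
    cluster_index: int
    fst_class: int
    delta_e: float
    pixel_fraction: float
    center_lab: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {
            "cluster": self.cluster_index,
            "fst": self.fst_class,
            "delta_e": round(self.delta_e, 6),
            "fraction": round(self.pixel_fraction, 9),
            "center_lab": [round(v, 6) for v in self.center_lab],
        }


@dataclass
class MatchReport:
    matches: list[ClusterMatch]
    dominant_fst: int
    k: int
    image_id: str = ""
    class_fractions: dict[int, float] = field(default_factory=dict)
    model_name: str = "kmeans"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "model": self.model_name,
            "seed": self.seed,
            "k": self.k,
            "dominant_fst": self.dominant_fst,
            "class_fractions": {
                str(c): round(f, 9) for c, f in sorted(self.class_fractions.items())
            },
            "clusters": [m.to_dict() for m in self.matches],
        }


@dataclass
class SegmentationMap:
    label_raster: np.ndarray   # H x W ints in [0, k-1]
    fst_raster: np.ndarray     # H x W ints in 1..6
    legend: dict[int, tuple[int, float]]  # cluster -> (fst_class, fraction)


def match_clusters(
    centers: np.ndarray, palette: FSTPalette
) -> list[tuple[int, float]]:
    """Match each LAB cluster center to its nearest palette entry by CIE76.

    Returns one (fst_class, delta_e) pair per center. Exact distance ties
    break toward the lighter (lower) class.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    d = cdist(centers, palette.lab_array)
    best = np.argmin(d, axis=1)  # argmin takes the first minimum: lighter class
    return [(int(j) + 1, float(d[i, j])) for i, j in enumerate(best)]


def cluster_fractions(labels: np.ndarray, k: int) -> np.ndarray:
    """Pixel fraction of each of the k clusters; fractions sum to 1."""
    lab = np.asarray(labels).ravel()
    if lab.size == 0:
        raise ValueError("empty label vector")
    if lab.min() < 0 or lab.max() >= k:
        raise ValueError("labels must lie in [0, k-1]")
    counts = np.bincount(lab, minlength=k)
    return counts / lab.size


def _dominant_class(matches: list[ClusterMatch]) -> tuple[int, dict[int, float]]:
    """Aggregate fractions per FST class; dominant = largest aggregate.

    Ties break toward the class containing the closer (smaller delta_e)
    cluster match, then toward the lighter class.
    """
    agg: dict[int, float] = {}
    best_de: dict[int, float] = {}
    for m in matches:
        agg[m.fst_class] = agg.get(m.fst_class, 0.0) + m.pixel_fraction
        best_de[m.fst_class] = min(best_de.get(m.fst_class, np.inf), m.delta_e)
    dominant = min(agg, key=lambda c: (-agg[c], best_de[c], c))
    return dominant, agg


def _build_matches(
    centers: np.ndarray, labels: np.ndarray, palette: FSTPalette
) -> list[ClusterMatch]:
    k = centers.shape[0]
    pairs = match_clusters(centers, palette)
    fracs = cluster_fractions(labels, k)
    return [
        ClusterMatch(
            cluster_index=i,
            fst_class=pairs[i][0],
            delta_e=pairs[i][1],
            pixel_fraction=float(fracs[i]),
            center_lab=tuple(float(v) for v in centers[i]),
        )
        for i in range(k)
    ]


def classify_image(
    lab_image: np.ndarray,
    palette: FSTPalette,
    config: ClusterModelConfig | None = None,
    mask: np.ndarray | None = None,
    image_id: str = "",
    max_dim: int = 256,
) -> MatchReport:
    """Classify the dominant skin tone of a LAB photograph.

    Pipeline: optional skin mask -> downscale -> cluster the pixel cloud ->
    match centers to the palette -> aggregate pixel fractions per FST class.
    Deterministic given the config seed.
    """
    cfg = config or ClusterModelConfig()
    img = resize_image(np.asarray(lab_image, dtype=np.float64), max_dim=max_dim)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != np.asarray(lab_image).shape[:2]:
            raise ValueError("mask shape must match the input image")
        if mask.shape != img.shape[:2]:
            mask = _sk_resize(
                mask.astype(float), img.shape[:2], order=0, preserve_range=True
            ) > 0.5
        pixels = img[mask]
        if pixels.size == 0:
            raise ValueError("mask excludes every pixel")
    else:
        pixels = img.reshape(-1, 3)

    result = fit_model(pixels, cfg)
    matches = _build_matches(result.centers, result.labels, palette)
    dominant, agg = _dominant_class(matches)
    _warn_dark_clusters(matches)
    return MatchReport(
        matches=matches,
        dominant_fst=dominant,
        k=result.n_clusters,
        image_id=image_id,
        class_fractions=agg,
        model_name=cfg.model_name,
        seed=cfg.seed,
    )


def _warn_dark_clusters(matches: list[ClusterMatch]) -> None:
    # An unmasked dark background typically shows up as a large near-black
    # cluster; flag it rather than guessing a mask.
    import warnings

    for m in matches:
        if m.center_lab[0] < 20.0 and m.pixel_fraction > 0.2:
            warnings.warn(
                f"cluster {m.cluster_index} is very dark (L*={m.center_lab[0]:.1f}) and "
                f"covers {m.pixel_fraction:.0%} of the image; if this is background, "
                "pass a skin mask",
                stacklevel=3,
            )


def segment_image(
    lab_image: np.ndarray,
    palette: FSTPalette,
    k: int,
    seed: int = 0,
    max_dim: int = 256,
    model_name: str = "kmeans",
) -> SegmentationMap:
    """Cluster a LAB image spatially and relabel every pixel by FST class."""
    if k < 2:
        raise ValueError("segmentation needs k >= 2")
    img = resize_image(np.asarray(lab_image, dtype=np.float64), max_dim=max_dim)
    h, w = img.shape[:2]
    cfg = ClusterModelConfig(model_name=model_name, n_clusters=k, seed=seed)
    result = fit_model(img.reshape(-1, 3), cfg)
    matches = _build_matches(result.centers, result.labels, palette)
    label_raster = result.labels.reshape(h, w)
    fst_of = np.array([m.fst_class for m in matches])
    fst_raster = fst_of[label_raster]
    legend = {m.cluster_index: (m.fst_class, m.pixel_fraction) for m in matches}
    return SegmentationMap(label_raster=label_raster, fst_raster=fst_raster, legend=legend)


def sweep_cluster_counts(
    lab_image: np.ndarray,
    palette: FSTPalette,
    ks: list[int],
    seed: int = 0,
    max_dim: int = 256,
) -> list[tuple[int, SegmentationMap, MatchReport]]:
    """Segment and classify the same image at several cluster counts.

    The headline readout is the per-FST aggregated fraction at each k: as k
    grows, clusters subdivide but their class aggregates stay comparable.
    """
    out = []
    img = resize_image(np.asarray(lab_image, dtype=np.float64), max_dim=max_dim)
    h, w = img.shape[:2]
    for k in ks:
        if k < 2:
            raise ValueError("all ks must be >= 2")
        cfg = ClusterModelConfig(n_clusters=k, seed=seed)
        result = fit_model(img.reshape(-1, 3), cfg)
        matches = _build_matches(result.centers, result.labels, palette)
        dominant, agg = _dominant_class(matches)
        label_raster = result.labels.reshape(h, w)
        fst_of = np.array([m.fst_class for m in matches])
        seg = SegmentationMap(
            label_raster=label_raster,
            fst_raster=fst_of[label_raster],
            legend={m.cluster_index: (m.fst_class, m.pixel_fraction) for m in matches},
        )
        report = MatchReport(
            matches=matches,
            dominant_fst=dominant,
            k=result.n_clusters,
            class_fractions=agg,
            model_name=cfg.model_name,
            seed=seed,
        )
        out.append((k, seg, report))
    return out
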