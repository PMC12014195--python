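"""Seeded generator of skin-like photographs with known FST structure.

The study imagery this stands in for — feet photographed against a black
curtain under controlled lighting, 48 subjects spanning FST I to VI — is not
publicly deposited, so tests and demos run on synthetic scenes instead:
contiguous vertical bands of FST-typical colors with a smooth lightness
gradient, per-pixel sensor noise, and an optional near-black background
band. Band geometry (rather than anatomical shapes) keeps the ground-truth
area fractions exact.

Rendering happens in CIELAB and is converted to 8-bit sRGB at the end, so
the generated files look like ordinary photographs to the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorspace import lab_to_srgb
from .palette import FSTPalette, default_palette

__all__ = ["RegionSpec", "SceneSpec", "render_scene", "generate_cohort"]

_BACKGROUND_LAB = np.array([5.0, 0.0, 0.0])  # near-black curtain


@dataclass
class RegionSpec:
    fst_class: int                  # 1..6
    target_fraction: float          # share of the non-background area
    base_color_jitter: float = 0.0  # CIE76-scale random offset of the region base color

    def __post_init__(self) -> None:
        if not 1 <= self.fst_class <= 6:
            raise ValueError("fst_class must be in 1..6")
        if not 0.0 < self.target_fraction <= 1.0:
            raise ValueError("target_fraction must be in (0, 1]")
        if self.base_color_jitter < 0:
            raise ValueError("base_color_jitter must be >= 0")


@dataclass
class SceneSpec:
    regions: list[RegionSpec]
    height: int = 128
    width: int = 128
    lighting_gradient: float = 6.0   # peak-to-peak L* amplitude, zero-mean across x
    noise_sigma: float = 2.0         # per-LAB-channel Gaussian sensor noise
    background_fraction: float = 0.0  # leftmost columns rendered as dark curtain
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(r.target_fraction for r in self.regions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"region fractions must sum to 1, got {total}")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must be in [0, 1)")
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be >= 1")


def render_scene(
    spec: SceneSpec, palette: FSTPalette | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a scene to (rgb_image, truth_raster, truth_fractions).

    ``truth_raster`` is H x W with the FST class per pixel (0 marks
    background); ``truth_fractions`` is a length-6 vector of realized
    per-class pixel fractions over the non-background area. Deterministic
    given ``spec.seed``.
    """
    pal = palette or default_palette()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    bg_cols = int(round(spec.background_fraction * w))
    region_cols = w - bg_cols
    if region_cols < len(spec.regions):
        raise ValueError("image too narrow for the requested regions")

    # split the non-background columns by cumulative fractions
    cum = np.cumsum([r.target_fraction for r in spec.regions])
    edges = np.concatenate([[0], np.round(cum * region_cols).astype(int)])
    edges[-1] = region_cols

    lab = np.empty((h, w, 3))
    truth = np.zeros((h, w), dtype=int)
    lab[:, :bg_cols] = _BACKGROUND_LAB

    for r, lo, hi in zip(spec.regions, edges[:-1], edges[1:]):
        base = pal.color(r.fst_class).copy()
        if r.base_color_jitter > 0:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            base = base + direction * r.base_color_jitter
        lab[:, bg_cols + lo:bg_cols + hi] = base
        truth[:, bg_cols + lo:bg_cols + hi] = r.fst_class

    # zero-mean linear lighting gradient along x, applied to L* only
    if spec.lighting_gradient != 0.0 and w > 1:
        ramp = (np.arange(w) / (w - 1) - 0.5) * spec.lighting_gradient
        lab[:, :, 0] += ramp[None, :]

    if spec.noise_sigma > 0:
        lab += rng.normal(scale=spec.noise_sigma, size=lab.shape)
    lab[:, :, 0] = np.clip(lab[:, :, 0], 0.0, 100.0)

    rgb = lab_to_srgb(lab)

    skin = truth > 0
    n_skin = skin.sum()
    truth_fractions = np.array(
        [(truth == c).sum() / n_skin for c in range(1, 7)]
    )
    return rgb, truth, truth_fractions


def generate_cohort(
    n: int,
    class_mix: np.ndarray | None = None,
    noise_sigma: float = 2.0,
    seed: int = 0,
    palette: FSTPalette | None = None,
    height: int = 128,
    width: int = 96,
    lighting_gradient: float = 6.0,
) -> list[tuple[np.ndarray, int]]:
    """Generate ``n`` scenes with known dominant FST classes.

    Scenes alternate between a single uniform skin region and a two-region
    layout (75% dominant class, 25% adjacent class), emulating subjects with
    mildly heterogeneous skin tone. Each image's dominant class is drawn from
    ``class_mix`` (default uniform over FST I..VI). Returns a list of
    (rgb_image, true_dominant_fst); per-image seeds derive from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = (
        np.full(6, 1.0 / 6.0)
        if class_mix is None
        else np.asarray(class_mix, dtype=np.float64)
    )
    if mix.shape != (6,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("class_mix must be 6 non-negative reals summing to 1")
    pal = palette or default_palette()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        dominant = int(rng.choice(6, p=mix)) + 1
        img_seed = int(rng.integers(2**31))
        if i % 2 == 0:
            regions = [RegionSpec(fst_class=dominant, target_fraction=1.0)]
        else:
            neighbor = dominant + 1 if dominant < 6 else dominant - 1
            regions = [
                RegionSpec(fst_class=dominant, target_fraction=0.75),
                RegionSpec(fst_class=neighbor, target_fraction=0.25),
            ]
        spec = SceneSpec(
            regions=regions,
            height=height,
            width=width,
            lighting_gradient=lighting_gradient,
            noise_sigma=noise_sigma,
            seed=img_seed,
        )
        rgb, _, _ = render_scene(spec, pal)
        cohort.append((rgb, dominant))
    return cohort
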