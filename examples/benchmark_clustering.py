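"""Compare all twelve clustering model families on one image.

Each model clusters the same LAB pixel cloud; the table reports the three
internal validity indices (higher silhouette and Calinski-Harabasz are
better; lower Davies-Bouldin is better) plus the fit time. Models that fail
or degenerate get a status note instead of aborting the sweep.
"""

import warnings

from dermatone import (
    MODEL_NAMES,
    ClusterModelConfig,
    RegionSpec,
    SceneSpec,
    benchmark_models,
    default_palette,
    render_scene,
    srgb_to_lab,
)

warnings.filterwarnings("ignore")

palette = default_palette()
spec = SceneSpec(
    regions=[RegionSpec(3, 0.6), RegionSpec(4, 0.4)],
    height=64, width=64, lighting_gradient=4.0, noise_sigma=2.0, seed=2,
)
rgb, _, _ = render_scene(spec, palette)
pixels = srgb_to_lab(rgb).reshape(-1, 3)

configs = [ClusterModelConfig(model_name=m, n_clusters=2, seed=0) for m in MODEL_NAMES]
print(f"{'model':22s} {'k':>3s} {'silhouette':>10s} {'C-H':>10s} {'D-B':>6s} {'time':>6s}")
for r in benchmark_models(pixels, configs):
    sil = "--" if r.silhouette is None else f"{r.silhouette:10.3f}"
    ch = "--" if r.calinski_harabasz is None else f"{r.calinski_harabasz:10.0f}"
    db = "--" if r.davies_bouldin is None else f"{r.davies_bouldin:6.2f}"
    print(f"{r.model_name:22s} {r.n_clusters_found:3d} {sil:>10s} {ch:>10s} {db:>6s} "
          f"{r.fit_seconds:5.2f}s  {r.status if r.status != 'ok' else ''}")
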