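"""Classify the dominant skin tone of a photograph.

Renders a synthetic "subject" (a mostly-FST-IV skin patch with sensor noise
and a lighting gradient), then runs the clustering + palette-matching
pipeline on it. With a real photograph, replace the rendered image by
`dermatone.reports.load_rgb("photo.png")`.
"""

import warnings

from dermatone import (
    ClusterModelConfig,
    RegionSpec,
    SceneSpec,
    classify_image,
    default_palette,
    render_scene,
    srgb_to_lab,
)

warnings.filterwarnings("ignore")

palette = default_palette()
spec = SceneSpec(
    regions=[RegionSpec(fst_class=4, target_fraction=1.0)],
    height=128, width=128, lighting_gradient=6.0, noise_sigma=2.0, seed=3,
)
rgb, _, _ = render_scene(spec, palette)

report = classify_image(
    srgb_to_lab(rgb), palette, ClusterModelConfig(n_clusters=4, seed=0)
)

print(f"dominant skin tone: FST {report.dominant_fst}")
for m in report.matches:
    print(
        f"  cluster {m.cluster_index}: FST {m.fst_class}, "
        f"{m.pixel_fraction:.1%} of pixels, Delta-E {m.delta_e:.2f}"
    )
# Each cluster center (a typical tone in the image) is matched to its nearest
# FST reference color by CIE76 distance; the dominant class is the FST class
# covering the largest aggregated pixel fraction. Small Delta-E means the
# cluster sits close to its reference swatch.
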