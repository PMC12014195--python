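# Methods

## Model

The pipeline treats skin-tone grading as nearest-reference classification in
a perceptually motivated color space. A photograph is converted from sRGB to
CIELAB assuming the standard sRGB transfer function, D65 white point and 2°
observer — the defaults for consumer cameras; no color constancy or
white-balance correction is attempted, so input images are assumed to be
reasonably color-managed. In CIELAB, Euclidean distance (the CIE76 ΔE)
approximates perceived color difference, which justifies both the k-means
objective and the matching rule.

The pixel cloud (N×3 after downscaling) is clustered; each cluster center is
matched to the nearest of six FST reference colors by CIE76 — matching
operates on centers only, never per pixel, mirroring the clinician's
chart-to-skin comparison of *typical* tones. Pixel fractions are aggregated
per FST class across clusters sharing a class, and the dominant tone is the
class with the largest aggregate. The per-class aggregate (rather than the
largest single cluster) makes the decision insensitive to how finely a
homogeneous region happens to be subdivided, so the classification is stable
across k — the property the k = 2/3/4 segmentation sweep demonstrates.
Fraction ties break toward the class containing the closer (smaller ΔE)
cluster, then toward the lighter class.

## Parameters that matter

| parameter | default | rationale |
|---|---|---|
| resize `max_dim` | 256 px | keeps clustering desk-fast while preserving tone regions; bilinear, aspect-preserving, downscale only |
| `n_clusters` (k) | 4 | upper end of the explored 2–4 range; per-class aggregation makes results insensitive to the exact choice |
| k-means | k-means++, n_init 10, max_iter 300, tol 1e-4 | standard robust defaults; native reference implementation cross-checked against scikit-learn |
| DBSCAN/OPTICS `eps` | 1.0 (ΔE units), `min_samples` 10 | tuned on the synthetic fixtures so adjacent-class regions at σ=2 noise separate; density methods are sensitive to this and should be re-tuned per imaging setup |
| ITA→FST boundaries | 55, 41, 28, 10, −30 ° | the conventional del Bino banding; configurable because published banding tables differ |
| silhouette `sample_size` | 10 000 (seeded) | exact score on small inputs (sample ≥ N reproduces the full computation; distances are always taken against the full cloud); bounds the O(N²) cost on full-resolution images |

Quadratic-cost models (spectral, affinity propagation, mean shift, AHC,
OPTICS) are fitted on a seeded subsample (5 000 pixels; 2 000 for affinity
propagation) and extended to all pixels by nearest-center assignment;
overridable via the `max_fit_points` parameter. Models that natively emit
noise labels or no centroids are normalised: centers become per-cluster LAB
means, and noise pixels are reassigned to the nearest center, so every
result is a total partition — required for fractions to sum to 1.

## Reference palette and ITA ground truth

The packaged palette (data/fst_palette.json) carries six representative FST
swatches chosen at design time so that each swatch's own ITA falls inside
its own band (60.7°, 46.2°, 28.9°, 11.2°, −22.1°, −67.1°) and adjacent
classes are ≥ 11.5 ΔE apart. It is a reasonable default, not a calibrated
standard: studies with a physical reference chart should either supply their
own JSON table or photograph the chart and call `palette_from_image`, which
recovers the six swatches by k-means (k = 6, centers ordered by descending
L\*) and rejects charts with fewer than six distinguishable colors.

ITA-based labelling is a colorimetric stand-in for device ground truth
(e.g. handheld colorimeters). ITA uses the two-argument arctangent, is
undefined only at (L\* = 50, b\* = 0), and boundary angles are assigned to
the lighter class.

## Synthetic scenes: what they do and do not establish

`render_scene` builds vertical bands of palette colors (exact area
fractions), adds an optional per-region base-color jitter, a zero-mean
linear lightness gradient along x (lighting), i.i.d. Gaussian LAB noise
(sensor), and an optional near-black background band (the curtain in a
controlled imaging setup), then converts to 8-bit sRGB. Defaults: 128 px
scenes, gradient amplitude 6 L\* units, noise σ = 2 ΔE per channel — small
against the ≥ 11.5 ΔE class gaps, emulating controlled-lighting clinical
photography. `generate_cohort` alternates single-region and two-region
(75/25, adjacent classes) subjects with the dominant class drawn from a
configurable mix.

The generator deliberately omits skin texture, specular highlights,
anatomical shape, chromatic lighting casts and camera-specific response.
Green tests therefore establish the *pipeline's* correctness — color math,
clustering contracts, matching, aggregation, scoring — under the stated
noise model; they do not certify accuracy on real photographs, where
white balance and shadows dominate the error budget.

## Numerical choices

- Validity indices are implemented in-package (vectorised) so degenerate
  cases have defined behaviour: a single cluster raises
  `UndefinedMetricError`; zero within-cluster scatter yields C-H = ∞;
  coincident centroids make D-B undefined; singleton clusters contribute
  silhouette 0. The benchmark harness converts these to status-tagged
  sentinel rows instead of aborting. Tests pin all three to naive
  from-scratch implementations (1e-9) and to scikit-learn.
- Argmin ties (matching, noise reassignment) break toward the lowest index,
  i.e. the lighter FST class — determinism.
- All randomness flows through `numpy.random.default_rng(seed)`; report
  files contain no timing fields, so fixed-seed runs are byte-identical
  (timings go to the run logs).
- Out-of-gamut LAB values are clipped on conversion to sRGB; L\* is clipped
  to [0, 100] when rendering noisy scenes.
- Very dark clusters (L\* < 20 covering > 20 % of pixels) trigger a warning
  suggesting a background mask; genuinely dark FST VI skin also trips it,
  which is why it is a warning and not an error.

## Known limitations

- k-means-PCA reduces the 3-D LAB cloud to 2 principal components — the only
  non-trivial reduction of a 3-D space; interpretive, since spatial features
  are not included.
- Density-based models often merge adjacent skin tones into one cluster at
  realistic noise; their rows then carry "undefined" markers for the
  indices. This is a property of the data geometry, not a bug.
- Macro-averaged precision/recall/F1 exclude classes absent from the truth;
  micro averaging is available via `classification_metrics(..., average="micro")`.
- The ±1-tolerance accuracy treats FST as an ordinal scale with unit steps;
  no claim is made that perceptual spacing between classes is uniform.
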