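"""Validate the pipeline on a synthetic cohort with known skin tones.

Generates 48 synthetic subjects spanning FST I-VI, classifies each, and
scores the predictions: exact accuracy, macro precision/recall/F1, and the
clinically-motivated +/-1 tolerance accuracy (a prediction one FST class off
is still acceptable in practice).
"""

import warnings

from dermatone import (
    ClusterModelConfig,
    classify_image,
    default_palette,
    evaluate,
    generate_cohort,
    srgb_to_lab,
)
from dermatone.evaluation import LabeledPredictions

warnings.filterwarnings("ignore")

palette = default_palette()
cohort = generate_cohort(n=48, noise_sigma=2.0, seed=7, palette=palette)

records = []
for i, (rgb, true_fst) in enumerate(cohort):
    rep = classify_image(srgb_to_lab(rgb), palette, ClusterModelConfig(n_clusters=4, seed=1))
    records.append((f"subject_{i:03d}", rep.dominant_fst, true_fst))

report = evaluate(LabeledPredictions(records=records), tolerance=1)
print(f"subjects: {report.n}")
print(f"exact accuracy:        {report.accuracy:.3f}")
print(f"macro precision:       {report.precision_macro:.3f}")
print(f"macro recall:          {report.recall_macro:.3f}")
print(f"macro F1:              {report.f1_macro:.3f}")
print(f"+/-1 tolerance accuracy: {report.tolerance_accuracy:.3f}")
print("confusion matrix (rows = true FST I..VI, columns = predicted):")
print(report.confusion)
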