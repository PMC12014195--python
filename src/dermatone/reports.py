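"""Report writers and end-to-end runners tying the pipeline together.

Each ``run_*`` function is the library-level equivalent of a shell verb:
it loads its inputs, executes the corresponding pipeline stage, and writes
machine-readable reports (JSON, CSV) plus figures (PNG) into an output
directory, together with a log capturing the configuration and seed. The
report files themselves contain no timing information, so repeated runs
with the same seed are byte-identical; wall-clock timings go to the log.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import imageio.v3 as iio
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .clustering import MODEL_NAMES, ClusterModelConfig
from .colorspace import lab_to_srgb, srgb_to_lab
from .evaluation import LabeledPredictions, evaluate
from .matching import MatchReport, classify_image, sweep_cluster_counts
from .palette import FSTPalette, default_palette, load_palette, palette_from_image
from .quality import benchmark_models
from .synthetic import SceneSpec, generate_cohort, render_scene

__all__ = [
    "load_rgb",
    "save_rgb",
    "resolve_palette",
    "run_classify",
    "run_segment",
    "run_benchmark",
    "run_evaluate",
    "run_simulate",
]


def load_rgb(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG photograph as an H x W x 3 uint8 array."""
    arr = iio.imread(path)
    if arr.ndim == 2:  # grayscale: replicate channels
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return np.asarray(arr, dtype=np.uint8)


def save_rgb(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def resolve_palette(source: str | Path | FSTPalette | None, seed: int = 0) -> FSTPalette:
    """Accept a palette object, a JSON table, a palette photograph, or None (default)."""
    if source is None:
        return default_palette()
    if isinstance(source, FSTPalette):
        return source
    path = Path(source)
    if path.suffix.lower() == ".json":
        return load_palette(path)
    return palette_from_image(srgb_to_lab(load_rgb(path)), seed=seed)


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _write_log(out_dir: Path, command: str, config: dict, timing: dict | None = None) -> None:
    log = {
        "command": command,
        "config": config,
        "versions": {
            "python": sys.version.split()[0],
            "dermatone": __version__,
            "numpy": np.__version__,
        },
    }
    if timing:
        log["timing"] = timing
    _write_json(out_dir / f"{command}_log.json", log)


def _match_panel(report: MatchReport, palette: FSTPalette, path: Path) -> None:
    """Side-by-side swatch panel: each cluster color next to its FST match."""
    k = len(report.matches)
    fig, axes = plt.subplots(k, 2, figsize=(4, 1.2 * k), squeeze=False)
    for i, m in enumerate(report.matches):
        pair = [
            np.asarray(m.center_lab),
            palette.color(m.fst_class),
        ]
        for j, lab in enumerate(pair):
            rgb = lab_to_srgb(lab.reshape(1, 1, 3))[0, 0] / 255.0
            axes[i][j].add_patch(plt.Rectangle((0, 0), 1, 1, color=rgb))
            axes[i][j].set_xticks([])
            axes[i][j].set_yticks([])
        axes[i][0].set_ylabel(f"c{m.cluster_index}", rotation=0, labelpad=14, fontsize=8)
        axes[i][1].set_ylabel(
            f"FST {m.fst_class}\n{m.pixel_fraction:.1%}, dE={m.delta_e:.1f}",
            rotation=0, labelpad=34, fontsize=7,
        )
    fig.suptitle(f"dominant: FST {report.dominant_fst}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_classify(
    image: str | Path,
    out_dir: str | Path,
    palette: str | Path | FSTPalette | None = None,
    model: str = "kmeans",
    k: int = 4,
    seed: int = 0,
    mask: np.ndarray | None = None,
    max_dim: int = 256,
    params: dict | None = None,
) -> MatchReport:
    """Classify one photograph; writes report JSON and a swatch panel PNG."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pal = resolve_palette(palette, seed=seed)
    rgb = load_rgb(image)
    lab = srgb_to_lab(rgb)
    cfg = ClusterModelConfig(model_name=model, n_clusters=k, seed=seed, params=params or {})
    report = classify_image(
        lab, pal, cfg, mask=mask, image_id=Path(image).name, max_dim=max_dim
    )
    _write_json(out / "classify_report.json", report.to_dict())
    _match_panel(report, pal, out / "classify_panel.png")
    _write_log(out, "classify", {
        "image": str(image), "model": model, "k": k, "seed": seed, "max_dim": max_dim,
    })
    return report


def run_segment(
    image: str | Path,
    out_dir: str | Path,
    ks: list[int] = (2, 3, 4),
    palette: str | Path | FSTPalette | None = None,
    seed: int = 0,
    max_dim: int = 256,
) -> dict:
    """Segment one photograph at several cluster counts (spatial FST maps).

    Writes, per k: an indexed PNG of the FST raster, a color overlay PNG
    rendering every pixel as its matched palette color, and a JSON legend
    with per-class aggregated fractions.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pal = resolve_palette(palette, seed=seed)
    lab = srgb_to_lab(load_rgb(image))
    results = sweep_cluster_counts(lab, pal, ks=list(ks), seed=seed, max_dim=max_dim)
    payload = {"image_id": Path(image).name, "seed": seed, "sweeps": []}
    for k, seg, report in results:
        overlay = lab_to_srgb(pal.lab_array[seg.fst_raster - 1])
        save_rgb(out / f"segment_k{k}_overlay.png", overlay)
        iio.imwrite(out / f"segment_k{k}_fst.png", seg.fst_raster.astype(np.uint8))
        payload["sweeps"].append({
            "k": k,
            "dominant_fst": report.dominant_fst,
            "class_fractions": {
                str(c): round(f, 9) for c, f in sorted(report.class_fractions.items())
            },
            "legend": {
                str(c): {"fst": cls, "fraction": round(frac, 9)}
                for c, (cls, frac) in sorted(seg.legend.items())
            },
        })
    _write_json(out / "segment_report.json", payload)
    _write_log(out, "segment", {"image": str(image), "ks": list(ks), "seed": seed})
    return payload


def run_benchmark(
    image: str | Path | np.ndarray,
    out_dir: str | Path,
    models: str | list[str] = "all",
    k: int = 4,
    seed: int = 0,
    max_dim: int = 256,
    sample_size: int | None = 10000,
) -> pd.DataFrame:
    """Benchmark clustering models on one image; writes a CSV/JSON table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(image, (str, Path)):
        lab = srgb_to_lab(load_rgb(image))
        image_id = Path(image).name
    else:
        lab = srgb_to_lab(np.asarray(image))
        image_id = "<array>"
    from .colorspace import resize_image

    pixels = resize_image(lab, max_dim=max_dim).reshape(-1, 3)
    names = list(MODEL_NAMES) if models == "all" else list(models)
    configs = [ClusterModelConfig(model_name=m, n_clusters=k, seed=seed) for m in names]
    reports = benchmark_models(pixels, configs, sample_size=sample_size, seed=seed)
    df = pd.DataFrame([r.to_dict() for r in reports])
    df.to_csv(out / "benchmark.csv", index=False)
    _write_json(out / "benchmark.json", {"image_id": image_id, "k": k, "seed": seed,
                                         "rows": df.drop(columns="fit_seconds").to_dict("records")})
    _write_log(out, "benchmark", {"image": image_id, "models": names, "k": k, "seed": seed},
               timing={r.model_name: r.fit_seconds for r in reports})
    return df


def run_evaluate(
    predictions: str | Path | pd.DataFrame,
    out_dir: str | Path,
    tolerance: int = 1,
) -> "EvaluationReport":
    """Score a predictions table (image_id, predicted_fst, true_fst).

    Writes the report JSON and a confusion-matrix heatmap PNG.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = (
        pd.read_csv(predictions)
        if isinstance(predictions, (str, Path))
        else predictions
    )
    data = LabeledPredictions.from_frame(df)
    report = evaluate(data, tolerance=tolerance)
    _write_json(out / "evaluation_report.json", report.to_dict())

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(report.confusion, cmap="Blues")
    ax.set_xlabel("predicted FST")
    ax.set_ylabel("true FST")
    ax.set_xticks(range(6), [str(i) for i in range(1, 7)])
    ax.set_yticks(range(6), [str(i) for i in range(1, 7)])
    for (i, j), v in np.ndenumerate(report.confusion):
        if v:
            ax.text(j, i, str(v), ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out / "confusion.png", dpi=100)
    plt.close(fig)
    _write_log(out, "evaluate", {"tolerance": tolerance, "n": report.n})
    return report


def run_simulate(
    out_dir: str | Path,
    n: int = 48,
    seed: int = 7,
    noise_sigma: float = 2.0,
    palette: str | Path | FSTPalette | None = None,
) -> pd.DataFrame:
    """Write a synthetic cohort of PNGs plus a ground-truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pal = resolve_palette(palette, seed=seed)
    cohort = generate_cohort(n=n, noise_sigma=noise_sigma, seed=seed, palette=pal)
    rows = []
    for i, (rgb, true_fst) in enumerate(cohort):
        name = f"subject_{i:03d}.png"
        save_rgb(out / name, rgb)
        rows.append({"image_id": name, "true_fst": true_fst})
    df = pd.DataFrame(rows)
    df.to_csv(out / "truth.csv", index=False)
    _write_log(out, "simulate", {"n": n, "seed": seed, "noise_sigma": noise_sigma})
    return df
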