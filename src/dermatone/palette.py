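"""The Fitzpatrick Skin Type (FST) palette and ITA-based ground-truth labelling.

The FST scale orders six skin-tone classes from I (lightest) to VI (darkest).
A palette is an ordered table of six CIELAB reference colors, one per class,
either loaded from a JSON table, taken from the packaged default, or derived
from a photograph of a physical six-swatch reference chart by k-means.

Ground truth for validation comes from the Individual Typology Angle,
ITA = arctan((L* - 50) / b*) in degrees: high angles are light skin, low or
negative angles dark skin. The ITA axis is partitioned into the six classes
by five descending angle boundaries (default: the del Bino banding
55, 41, 28, 10, -30).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .colorspace import delta_e_cie76, srgb_to_lab

__all__ = [
    "FSTPalette",
    "ITAThresholds",
    "PaletteError",
    "load_palette",
    "default_palette",
    "palette_from_image",
    "ita_degrees",
    "ita_to_fst",
    "DEFAULT_ITA_BOUNDARIES",
]

DEFAULT_ITA_BOUNDARIES = (55.0, 41.0, 28.0, 10.0, -30.0)


class PaletteError(ValueError):
    """Raised when a palette fails validation."""


@dataclass(frozen=True)
class ITAThresholds:
    """Five strictly decreasing ITA boundaries (degrees) cutting six FST bands."""

    boundaries: tuple[float, ...] = DEFAULT_ITA_BOUNDARIES

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if len(b) != 5 or any(b[i] <= b[i + 1] for i in range(4)):
            raise ValueError("need exactly 5 strictly decreasing ITA boundaries")
        object.__setattr__(self, "boundaries", b)


@dataclass
class FSTPalette:
    """Ordered six-entry FST I..VI palette of CIELAB colors."""

    entries: list[tuple[int, np.ndarray]]
    source: str = "config"
    ita_thresholds: ITAThresholds = field(default_factory=ITAThresholds)

    def __post_init__(self) -> None:
        if len(self.entries) != 6:
            raise PaletteError(f"palette needs exactly 6 entries, got {len(self.entries)}")
        classes = [c for c, _ in self.entries]
        if sorted(classes) != [1, 2, 3, 4, 5, 6]:
            raise PaletteError(f"fst classes must be a permutation of 1..6, got {classes}")
        self.entries = sorted(
            [(int(c), np.asarray(col, dtype=np.float64)) for c, col in self.entries],
            key=lambda e: e[0],
        )
        lvals = [col[0] for _, col in self.entries]
        if any(lvals[i] <= lvals[i + 1] for i in range(5)):
            raise PaletteError(
                f"palette L* must strictly decrease from FST I to VI, got {np.round(lvals, 2)}"
            )

    @property
    def lab_array(self) -> np.ndarray:
        """6 x 3 matrix of LAB colors, row i = FST class i+1."""
        return np.vstack([col for _, col in self.entries])

    def color(self, fst_class: int) -> np.ndarray:
        return self.entries[fst_class - 1][1]


def _palette_from_table(colors: list[dict], space: str, source: str) -> FSTPalette:
    entries = []
    for item in colors:
        cls = int(item["fst"])
        if space == "srgb":
            rgb = np.asarray(item["rgb"], dtype=np.float64).reshape(1, 1, 3)
            lab = srgb_to_lab(rgb.astype(np.uint8))[0, 0]
        elif space == "lab":
            lab = np.asarray(item["lab"], dtype=np.float64)
        else:
            raise PaletteError(f"unknown color space {space!r} (use 'lab' or 'srgb')")
        entries.append((cls, lab))
    return FSTPalette(entries=entries, source=source)


def load_palette(path: str | Path) -> FSTPalette:
    """Load and validate a palette JSON file ({"space": ..., "colors": [...]})."""
    with open(path) as fh:
        doc = json.load(fh)
    return _palette_from_table(doc["colors"], doc.get("space", "lab"), source="config")


def default_palette() -> FSTPalette:
    """The packaged default FST reference palette (see data/fst_palette.json)."""
    doc = json.loads(
        resources.files("dermatone").joinpath("data/fst_palette.json").read_text()
    )
    return _palette_from_table(doc["colors"], doc["space"], source="config")


def palette_from_image(lab_image: np.ndarray, seed: int = 0) -> FSTPalette:
    """Derive a palette from a photograph of a six-swatch FST reference chart.

    The image's pixels are clustered with k-means (k=6); the six centers,
    sorted by descending L*, become FST I..VI. Raises PaletteError when the
    image does not contain six distinguishable swatches (two recovered
    centers within CIE76 of 1).
    """
    from .clustering import kmeans_reference  # local import to avoid a cycle

    pix = np.asarray(lab_image, dtype=np.float64).reshape(-1, 3)
    result = kmeans_reference(pix, k=6, seed=seed)
    centers = result.centers
    order = np.argsort(-centers[:, 0])  # descending lightness
    centers = centers[order]
    for i in range(6):
        for j in range(i + 1, 6):
            if delta_e_cie76(centers[i], centers[j]) < 1.0:
                raise PaletteError(
                    "degenerate palette image: fewer than 6 distinct swatches recovered"
                )
    entries = [(i + 1, centers[i]) for i in range(6)]
    pal = FSTPalette(entries=entries, source="clustered_image")
    return pal


def ita_degrees(color) -> float | np.ndarray:
    """Individual Typology Angle: arctan((L* - 50) / b*), in degrees.

    Uses the two-argument arctangent, so b* = 0 with L* != 50 gives +/-90
    degrees; L* = 50 with b* = 0 is undefined and raises.
    """
    arr = np.asarray(color, dtype=np.float64)
    L = arr[..., 0]
    b = arr[..., 2]
    if np.any((L == 50.0) & (b == 0.0)):
        raise ValueError("ITA undefined for L*=50, b*=0")
    ita = np.degrees(np.arctan2(L - 50.0, b))
    return float(ita) if ita.ndim == 0 else ita


def ita_to_fst(ita, thresholds: ITAThresholds | None = None) -> int | np.ndarray:
    """Map an ITA angle (degrees) to an FST class 1..6.

    Angles above the top boundary are FST I; below the bottom, FST VI. A
    value exactly on a boundary goes to the lighter (lower-numbered) class.
    """
    th = thresholds or ITAThresholds()
    arr = np.asarray(ita, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("ITA must be finite")
    bounds = np.asarray(th.boundaries)
    cls = 1 + np.sum(arr[..., None] < bounds, axis=-1)
    cls = cls.astype(int)
    return int(cls) if cls.ndim == 0 else cls
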