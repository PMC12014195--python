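"""sRGB <-> CIELAB conversions and the CIE76 color difference.

All LAB values use the conventional scaling: L* in [0, 100] for in-gamut
sRGB, a*/b* unbounded chromatic axes. Conversions assume the sRGB transfer
function with a D65 white point and the 2-degree standard observer — the
universal default for consumer photographs.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _color
from skimage.transform import resize as _resize

__all__ = [
    "srgb_to_lab",
    "lab_to_srgb",
    "delta_e_cie76",
    "resize_image",
]


def _check_3channel(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(
            f"expected an H x W x 3 image, got shape {arr.shape}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have H >= 1 and W >= 1")
    return arr


def srgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit sRGB image (H x W x 3, values in [0, 255]) to CIELAB.

    Returns a float64 array of the same shape with channels (L*, a*, b*).
    """
    arr = _check_3channel(image)
    if np.issubdtype(arr.dtype, np.integer):
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("integer sRGB values must lie in [0, 255]")
        arr = arr.astype(np.float64) / 255.0
    else:
        arr = arr.astype(np.float64)
        if arr.max() > 1.0 + 1e-9:  # tolerate float images given on 0-255
            arr = arr / 255.0
        arr = np.clip(arr, 0.0, 1.0)
    return _color.rgb2lab(arr)


def lab_to_srgb(lab: np.ndarray) -> np.ndarray:
    """Convert a CIELAB image back to 8-bit sRGB, clipping out-of-gamut values."""
    arr = _check_3channel(lab).astype(np.float64)
    rgb = _color.lab2rgb(arr)  # clips to [0, 1]
    return np.round(rgb * 255.0).astype(np.uint8)


def delta_e_cie76(c1, c2) -> np.ndarray | float:
    """CIE76 color difference: Euclidean distance in CIELAB.

    Accepts single (L, a, b) triples or broadcastable arrays whose last
    axis is the LAB channel; returns a scalar or an array of distances.
    """
    a = np.asarray(c1, dtype=np.float64)
    b = np.asarray(c2, dtype=np.float64)
    d = np.sqrt(np.sum((a - b) ** 2, axis=-1))
    return float(d) if d.ndim == 0 else d


def resize_image(lab: np.ndarray, max_dim: int = 256) -> np.ndarray:
    """Downscale a LAB image so its longest side equals ``max_dim``.

    Aspect ratio is preserved (bilinear interpolation); images already at
    or below ``max_dim`` are returned unchanged. Upscaling never happens.
    """
    if max_dim < 1:
        raise ValueError("max_dim must be >= 1")
    arr = _check_3channel(lab).astype(np.float64)
    h, w = arr.shape[:2]
    longest = max(h, w)
    if longest <= max_dim:
        return arr
    scale = max_dim / longest
    new_h = max(1, int(round(h * scale)))
    new_w = max(1, int(round(w * scale)))
    # round() keeps the longest side exactly at max_dim
    if h >= w:
        new_h = max_dim
    else:
        new_w = max_dim
    return _resize(
        arr, (new_h, new_w), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
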