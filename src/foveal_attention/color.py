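"""Color machinery shared by the whole pipeline.

Node values travel through the segmentation hierarchy as HSV in cylindrical
coordinates.  Internally a color is stored as a 3-vector *embedding*

    (sx, sy, v) = (S·cos H, S·sin H, V)          S, V scaled to [0, 255]

because (a) the chroma chord distance between two colors is exactly the
Euclidean distance of their (sx, sy) parts, and (b) pixel-count-weighted
means of child nodes become plain weighted vector means, so a uniform image
stays a fixed point of the decimation.

The perceived distance between two colors is

    d = |V_i - V_j| + dc

with dc either the cylindrical chord ``sqrt(S_i² + S_j² − 2·S_i·S_j·cos θ)``
(default; a true metric with d(x, x) = 0) or the raw printed form
``S_i + S_j + 2·S_i·S_j·cos θ`` kept for comparison, θ = |H_i − H_j|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: scale applied to unit-range S and V before thresholding, so that the
#: color-similarity threshold tau_color lives on a [0..255]-normalized range.
WORKING_SCALE = 255.0


@dataclass(frozen=True)
class ColorValue:
    """An HSV color: hue in degrees [0, 360), saturation and value in [0, 1]."""

    h: float
    s: float
    v: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0 and 0.0 <= self.v <= 1.0):
            raise ValueError(f"S and V must lie in [0, 1], got S={self.s}, V={self.v}")

    def embedding(self) -> np.ndarray:
        h = np.deg2rad(self.h)
        return np.array(
            [
                WORKING_SCALE * self.s * np.cos(h),
                WORKING_SCALE * self.s * np.sin(h),
                WORKING_SCALE * self.v,
            ]
        )


def hsv_distance(a: ColorValue, b: ColorValue, form: str = "chord") -> float:
    """Color distance d = dv + dc on the unit scale (S, V in [0, 1]).

    ``form="chord"`` uses the cylindrical chord chroma term (default);
    ``form="printed"`` uses the additive variant, which is *not* zero for
    identical colors and is kept only as a configurable alternative.
    """
    dv = abs(a.v - b.v)
    theta = np.deg2rad(abs(a.h - b.h))
    if form == "chord":
        dc2 = a.s * a.s + b.s * b.s - 2.0 * a.s * b.s * np.cos(theta)
        dc = float(np.sqrt(max(dc2, 0.0)))
    elif form == "printed":
        dc = a.s + b.s + 2.0 * a.s * b.s * float(np.cos(theta))
    else:
        raise ValueError(f"unknown dc form: {form!r}")
    return dv + dc


def embedding_distance(e1: np.ndarray, e2: np.ndarray) -> float:
    """Working-scale distance between two color embeddings (chord form)."""
    dc = float(np.hypot(e1[0] - e2[0], e1[1] - e2[1]))
    return dc + abs(float(e1[2]) - float(e2[2]))


def embedding_distance_many(e: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Vectorized :func:`embedding_distance` of one embedding to many."""
    others = np.atleast_2d(others)
    dc = np.hypot(others[:, 0] - e[0], others[:, 1] - e[1])
    return dc + np.abs(others[:, 2] - e[2])


def embedding_to_hsv(e: np.ndarray) -> ColorValue:
    s = float(np.hypot(e[0], e[1])) / WORKING_SCALE
    h = float(np.rad2deg(np.arctan2(e[1], e[0]))) % 360.0
    v = float(e[2]) / WORKING_SCALE
    return ColorValue(h, min(s, 1.0), min(max(v, 0.0), 1.0))


def rgb_to_hsv_image(rgb: np.ndarray) -> np.ndarray:
    """RGB uint8/float image -> HSV with H in degrees, S, V in [0, 1]."""
    from skimage.color import rgb2hsv

    arr = np.asarray(rgb)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    hsv = rgb2hsv(arr)
    hsv = hsv.astype(np.float64).copy()
    hsv[..., 0] *= 360.0
    return hsv


def hsv_image_to_embedding(hsv: np.ndarray) -> np.ndarray:
    """HSV image (H deg, S, V unit) -> per-pixel working embeddings."""
    h = np.deg2rad(hsv[..., 0])
    s = hsv[..., 1] * WORKING_SCALE
    return np.stack(
        [s * np.cos(h), s * np.sin(h), hsv[..., 2] * WORKING_SCALE], axis=-1
    )


def rgb_to_embedding_image(rgb: np.ndarray) -> np.ndarray:
    return hsv_image_to_embedding(rgb_to_hsv_image(rgb))


# ---------------------------------------------------------------------------
# TSL chrominance space (used by the skin-color feature)
# ---------------------------------------------------------------------------

def rgb_to_tsl(rgb: np.ndarray) -> np.ndarray:
    """Convert RGB (uint8 or unit floats, last axis 3) to (T, S, L).

    T (tint) and S (saturation) depend only on chrominance; L is the usual
    luma 0.299 R + 0.587 G + 0.114 B on the input scale.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    total = r + g + b
    with np.errstate(invalid="ignore", divide="ignore"):
        rn = np.where(total > 0, r / total, 1.0 / 3.0) - 1.0 / 3.0
        gn = np.where(total > 0, g / total, 1.0 / 3.0) - 1.0 / 3.0
    s = np.sqrt(9.0 / 5.0 * (rn * rn + gn * gn))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(gn != 0, rn / np.where(gn != 0, gn, 1.0), 0.0)
    at = np.arctan(ratio) / (2.0 * np.pi)
    t = np.where(gn > 0, at + 0.25, np.where(gn < 0, at + 0.75, 0.0))
    l = 0.299 * r + 0.587 * g + 0.114 * b
    return np.stack([t, s, l], axis=-1)
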