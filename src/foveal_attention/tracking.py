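"""Mean-shift color tracker used for object-based inhibition of return.

Comaniciu-style tracking: the target is a 16×4×4-bin HSV color histogram
weighted by an Epanechnikov kernel over the target window; candidate
locations are scored by the Bhattacharyya coefficient and the window is
shifted to the weighted mean of pixel positions (weights sqrt(q_u/p_u))
until the shift drops below one pixel or 20 iterations pass.  A final
coefficient below the lost-track threshold marks the target dead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .color import rgb_to_hsv_image
from .geometry import Rect

N_H, N_S, N_V = 16, 4, 4
N_BINS = N_H * N_S * N_V
MAX_ITER = 20


def hsv_bin_map(frame: np.ndarray) -> np.ndarray:
    """Per-pixel joint HSV bin index (16 hue × 4 saturation × 4 value)."""
    hsv = rgb_to_hsv_image(frame)
    hb = np.minimum((hsv[..., 0] / 360.0 * N_H).astype(np.int64), N_H - 1)
    sb = np.minimum((hsv[..., 1] * N_S).astype(np.int64), N_S - 1)
    vb = np.minimum((hsv[..., 2] * N_V).astype(np.int64), N_V - 1)
    return (hb * N_S + sb) * N_V + vb


def _kernel_weights(win: Rect) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Epanechnikov profile over the window's normalized coordinates."""
    ys, xs = np.mgrid[win.y0 : win.y1, win.x0 : win.x1]
    cx, cy = (win.x0 + win.x1 - 1) / 2.0, (win.y0 + win.y1 - 1) / 2.0
    nx = (xs - cx) / max(win.w / 2.0, 0.5)
    ny = (ys - cy) / max(win.h / 2.0, 0.5)
    r2 = nx * nx + ny * ny
    return np.maximum(1.0 - r2, 0.0), xs, ys


def color_model(
    frame_bins: np.ndarray, win: Rect, mask: np.ndarray | None = None
) -> np.ndarray:
    """Kernel-weighted, normalized color histogram of a window.

    ``mask`` (full-frame bool) optionally restricts the model to the
    object's own pixels, keeping background colors out of the target
    histogram — the object-based variant used by the attention loop.
    """
    k, _, _ = _kernel_weights(win)
    if mask is not None:
        k = k * mask[win.y0 : win.y1, win.x0 : win.x1]
        if k.sum() <= 0:
            raise ValueError("degenerate window: mask has no pixels inside")
    bins = frame_bins[win.y0 : win.y1, win.x0 : win.x1]
    q = np.bincount(bins.ravel(), weights=k.ravel(), minlength=N_BINS)
    total = q.sum()
    if total <= 0:
        raise ValueError("degenerate window: no kernel mass")
    return q / total


def bhattacharyya(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.sqrt(p * q).sum())


@dataclass
class WorkingMemoryEntry:
    """A recently attended proto-object with its tracker model."""

    object_id: int
    model: np.ndarray  # normalized target histogram
    window: Rect
    centroid: tuple[float, float]
    sal: float = 0.0
    frames_since_attended: int = 0
    alive: bool = True
    similarity: float = 1.0


def _clamp_window(win: Rect, w: int, h: int) -> Rect:
    ww = min(win.w, w)
    wh = min(win.h, h)
    x0 = min(max(win.x0, 0), w - ww)
    y0 = min(max(win.y0, 0), h - wh)
    return Rect(x0, y0, x0 + ww, y0 + wh)


def meanshift_track(
    frame: np.ndarray,
    entry: WorkingMemoryEntry,
    lost_threshold: float = 0.5,
    frame_bins: np.ndarray | None = None,
) -> WorkingMemoryEntry:
    """One tracking update of a working-memory entry on a new frame.

    Mutates and returns ``entry``: new window/centroid and Bhattacharyya
    similarity; ``alive`` cleared when similarity falls below the
    lost-track threshold or the window degenerates.
    """
    h, w = frame.shape[:2]
    if frame_bins is None:
        frame_bins = hsv_bin_map(frame)
    win = _clamp_window(entry.window, w, h)
    if win.w <= 0 or win.h <= 0:
        entry.alive = False
        entry.similarity = 0.0
        return entry
    q = entry.model
    loc = None  # last sub-pixel mean-shift location
    for _ in range(MAX_ITER):
        k, xs, ys = _kernel_weights(win)
        bins = frame_bins[win.y0 : win.y1, win.x0 : win.x1]
        p = np.bincount(bins.ravel(), weights=k.ravel(), minlength=N_BINS)
        psum = p.sum()
        if psum <= 0:
            entry.alive = False
            entry.similarity = 0.0
            return entry
        p /= psum
        with np.errstate(divide="ignore", invalid="ignore"):
            wmap = np.where(p[bins] > 0, np.sqrt(q[bins] / np.maximum(p[bins], 1e-12)), 0.0)
        wmap = wmap * (k > 0)
        wsum = wmap.sum()
        if wsum <= 0:
            break
        nx = float((wmap * xs).sum() / wsum)
        ny = float((wmap * ys).sum() / wsum)
        loc = (nx, ny)
        new = _clamp_window(
            Rect(
                int(round(nx - win.w / 2.0)),
                int(round(ny - win.h / 2.0)),
                int(round(nx - win.w / 2.0)) + win.w,
                int(round(ny - win.h / 2.0)) + win.h,
            ),
            w,
            h,
        )
        # shift measured as the realized (integer) window displacement
        shift = np.hypot(new.x0 - win.x0, new.y0 - win.y0)
        win = new
        if shift < 1.0:
            break
    p = color_model(frame_bins, win)
    entry.window = win
    entry.centroid = loc if loc is not None else (
        (win.x0 + win.x1 - 1) / 2.0,
        (win.y0 + win.y1 - 1) / 2.0,
    )
    entry.similarity = bhattacharyya(p, q)
    if entry.similarity < lost_threshold:
        entry.alive = False
    return entry
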