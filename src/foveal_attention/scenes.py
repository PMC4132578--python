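"""Deterministic synthetic scenes for exercising the attention pipeline.

Generates colored geometric shapes (disc, rectangle, ellipse, bar,
L-polyomino) over flat, gradient or seeded-noise backgrounds, together with
per-pixel depth maps and exact ground-truth label maps.  Anti-aliasing is
deliberately disabled — edges are hard — so the label map is an exact
partition and can serve as segmentation ground truth.  All generators are
pure functions of (spec, seed): the same spec yields byte-identical rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.color import hsv2rgb


@dataclass(frozen=True)
class ShapeSpec:
    """One shape: HSV color (H deg, S, V unit), center (x, y) px, size px.

    ``size`` meaning by kind — disc: radius; rectangle/bar: (width, height);
    ellipse: (semi_a, semi_b); l_polyomino: arm length (arm thickness is a
    third of it).  ``orientation`` in degrees, counter-clockwise.
    """

    kind: str
    color: tuple[float, float, float]
    center: tuple[float, float]
    size: float | tuple[float, float]
    orientation: float = 0.0
    depth: float = 5.0


@dataclass(frozen=True)
class SceneSpec:
    size: tuple[int, int] = (64, 64)  # (width, height)
    background: dict = field(
        default_factory=lambda: {"kind": "flat", "color": (0.0, 0.0, 0.25)}
    )
    shapes: tuple[ShapeSpec, ...] = ()
    background_depth: float = 10.0
    seed: int = 0


def _hsv_to_rgb8(color: tuple[float, float, float]) -> np.ndarray:
    h, s, v = color
    rgb = hsv2rgb(np.array([[[h / 360.0, s, v]]]))[0, 0]
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def _shape_mask(shape: ShapeSpec, w: int, h: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = shape.center
    dx, dy = xx - cx, yy - cy
    ang = np.deg2rad(shape.orientation)
    # rotate into the shape frame (counter-clockwise orientation)
    u = np.cos(ang) * dx + np.sin(ang) * dy
    v = -np.sin(ang) * dx + np.cos(ang) * dy
    kind = shape.kind
    if kind == "disc":
        r = float(np.atleast_1d(shape.size)[0])
        return dx * dx + dy * dy <= r * r
    if kind in ("rectangle", "bar"):
        if np.ndim(shape.size) == 0:
            sw = sh = float(shape.size)
        else:
            sw, sh = (float(x) for x in np.atleast_1d(shape.size)[:2])
        return (np.abs(u) <= sw / 2.0) & (np.abs(v) <= sh / 2.0)
    if kind == "ellipse":
        a, b = np.atleast_1d(shape.size)[:2]
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if kind == "l_polyomino":
        arm = float(np.atleast_1d(shape.size)[0])
        t = arm / 3.0
        vert = (np.abs(u + arm / 2.0 - t / 2.0) <= t / 2.0) & (np.abs(v) <= arm / 2.0)
        horz = (np.abs(v + arm / 2.0 - t / 2.0) <= t / 2.0) & (np.abs(u) <= arm / 2.0)
        return vert | horz
    raise ValueError(f"unknown shape kind: {kind!r}")


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    w, h = spec.size
    bg = spec.background
    kind = bg.get("kind", "flat")
    base = _hsv_to_rgb8(tuple(bg.get("color", (0.0, 0.0, 0.25)))).astype(np.float64)
    img = np.broadcast_to(base, (h, w, 3)).copy()
    if kind == "flat":
        pass
    elif kind == "gradient":
        ramp = np.linspace(0.6, 1.4, w)[None, :, None]
        img = np.clip(img * ramp, 0, 255)
    elif kind == "noise":
        amp = float(bg.get("amplitude", 24.0))
        gran = int(bg.get("granularity", 4))
        gh, gw = -(-h // gran), -(-w // gran)
        coarse = rng.uniform(-amp, amp, size=(gh, gw, 3))
        noise = np.repeat(np.repeat(coarse, gran, axis=0), gran, axis=1)[:h, :w]
        img = np.clip(img + noise, 0, 255)
    else:
        raise ValueError(f"unknown background kind: {kind!r}")
    return img


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a scene -> (RGB uint8 image, float depth map, int label map).

    Labels: 0 = background, i+1 = i-th shape; later shapes occlude earlier
    ones, and labels reflect visibility, so the label map always partitions
    the canvas.
    """
    w, h = spec.size
    rng = np.random.default_rng(spec.seed)
    img = _background(spec, rng)
    depth = np.full((h, w), spec.background_depth, dtype=np.float64)
    labels = np.zeros((h, w), dtype=np.int32)
    for i, shape in enumerate(spec.shapes):
        mask = _shape_mask(shape, w, h)
        img[mask] = _hsv_to_rgb8(shape.color)
        depth[mask] = shape.depth
        labels[mask] = i + 1
    return img.astype(np.uint8), depth, labels


def make_sequence(
    spec: SceneSpec,
    velocities: dict[int, tuple[float, float]],
    n_frames: int,
) -> tuple[list[tuple[np.ndarray, np.ndarray, np.ndarray]], dict[int, list]]:
    """Translate shapes frame by frame -> (frames, ground-truth tracks).

    ``velocities`` maps shape index -> (vx, vy) pixels/frame; unlisted
    shapes stay put.  Tracks record each shape's nominal center per frame.
    A shape whose center leaves the canvas is clipped by rasterization and
    its track entry flagged with ``inside=False``.
    """
    frames, tracks = [], {i: [] for i in range(len(spec.shapes))}
    w, h = spec.size
    for t in range(n_frames):
        shapes = []
        for i, shape in enumerate(spec.shapes):
            vx, vy = velocities.get(i, (0.0, 0.0))
            cx, cy = shape.center[0] + vx * t, shape.center[1] + vy * t
            shapes.append(replace(shape, center=(cx, cy)))
            tracks[i].append(
                {"frame": t, "x": cx, "y": cy, "inside": 0 <= cx < w and 0 <= cy < h}
            )
        frames.append(make_scene(replace(spec, shapes=tuple(shapes))))
    return frames, tracks


def sample_fixations(density: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. (x, y) pixel fixations from a density raster."""
    density = np.asarray(density, dtype=np.float64)
    if density.min() < 0:
        raise ValueError("density must be non-negative")
    total = density.sum()
    if total <= 0:
        raise ValueError("density is identically zero")
    rng = np.random.default_rng(seed)
    flat = density.ravel() / total
    idx = rng.choice(flat.size, size=n, p=flat)
    ys, xs = np.unravel_index(idx, density.shape)
    return np.stack([xs, ys], axis=1).astype(np.int64)
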