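"""Adaptive Cartesian Foveal Geometry (CFG).

A CFG encodes the field of view as a full-resolution rectangular *fovea*
surrounded by ``m`` concentric rings of *rexels* (resolution cells).  Ring
``k`` tiles the annulus between the outer rectangle of ring ``k − 1`` and
its own outer rectangle with square rexels of edge ``ring_scale**k`` pixels,
so each ring halves the linear resolution (default scale 2).  Ring ``m``
always reaches the image border: the coarsest pyramid level built on top of
the CFG (the *waist*) is the first one that encodes the whole field of view.

Geometry conventions: 0-based pixel coordinates, half-open rectangles
``(x0, y0, x1, y1)``.  So that every annulus tiles exactly, all ring
expansions are kept on the ``ring_scale**m`` grid; the image dimensions must
be divisible by ``ring_scale**m`` and fovea corners are snapped to that grid
(:func:`fit_fovea` does the snapping for callers that only know a desired
fixation centroid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .color import rgb_to_embedding_image


class InvalidSpecError(ValueError):
    """Raised when a CFG specification cannot tile the image."""


@dataclass(frozen=True)
class Rect:
    """Half-open rectangle in pixel coordinates."""

    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def w(self) -> int:
        return self.x1 - self.x0

    @property
    def h(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.w * self.h

    def contains(self, other: "Rect") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and other.x1 <= self.x1
            and other.y1 <= self.y1
        )


@dataclass(frozen=True)
class CfgSpec:
    image_size: tuple[int, int]  # (width, height)
    fovea_rect: Rect
    num_rings: int = 2
    ring_scale: int = 2

    def __post_init__(self) -> None:
        w, h = self.image_size
        m, s = self.num_rings, self.ring_scale
        if m < 0 or s < 2:
            raise InvalidSpecError("need num_rings >= 0 and ring_scale >= 2")
        f = self.fovea_rect
        if f.w <= 0 or f.h <= 0:
            raise InvalidSpecError("fovea rectangle is empty")
        if not Rect(0, 0, w, h).contains(f):
            raise InvalidSpecError(f"fovea {f} lies outside the {w}x{h} image")
        unit = s**m
        if f.w % unit or f.h % unit:
            raise InvalidSpecError(
                f"fovea edges ({f.w}x{f.h}) must be divisible by ring_scale^m = {unit}"
            )
        if f.x0 % unit or f.y0 % unit:
            raise InvalidSpecError(f"fovea corner must lie on the {unit}-pixel grid")
        if w % unit or h % unit:
            raise InvalidSpecError(
                f"image size {w}x{h} must be divisible by ring_scale^m = {unit}"
            )
        if m == 0 and (f.w != w or f.h != h):
            raise InvalidSpecError("with no rings the fovea must cover the image")

    def ring_rects(self) -> list[Rect]:
        """Outer rectangles ``r_0 .. r_m`` (``r_0`` = fovea, ``r_m`` = image).

        Per-side expansions grow roughly geometrically with the ring index
        (each ring about doubles the annulus width), snapped to the
        ``ring_scale**m`` grid; the outermost ring absorbs the remainder so
        it reaches the image border exactly.
        """
        w, h = self.image_size
        m, s = self.num_rings, self.ring_scale
        unit = s**m
        f = self.fovea_rect
        margins = {
            "left": f.x0,
            "right": w - f.x1,
            "top": f.y0,
            "bottom": h - f.y1,
        }
        weights = np.array([float(s**k) for k in range(1, m + 1)])
        expansions: dict[str, list[int]] = {}
        for side, margin in margins.items():
            exp, rem = [], margin
            for k in range(1, m + 1):
                if k == m:
                    e = rem
                else:
                    ideal = margin * weights[k - 1] / weights.sum()
                    e = int(round(ideal / unit)) * unit
                    e = max(0, min(e, rem))
                exp.append(e)
                rem -= e
            expansions[side] = exp
        rects = [f]
        for k in range(1, m + 1):
            prev = rects[-1]
            rects.append(
                Rect(
                    prev.x0 - expansions["left"][k - 1],
                    prev.y0 - expansions["top"][k - 1],
                    prev.x1 + expansions["right"][k - 1],
                    prev.y1 + expansions["bottom"][k - 1],
                )
            )
        return rects


@dataclass
class RingGrid:
    """One CFG ring: a coarse grid over its outer rectangle.

    Only cells in the annulus (outside the previous ring's footprint) carry
    rexels; ``mask`` marks them.  ``embedding`` holds the working HSV
    embedding of each rexel (mean RGB of the footprint converted to HSV),
    ``rgb`` the mean RGB (for rendering), ``depth`` the mean depth.
    """

    index: int
    outer: Rect
    inner: Rect
    cell: int
    mask: np.ndarray
    embedding: np.ndarray
    rgb: np.ndarray
    depth: np.ndarray | None

    @property
    def n_rexels(self) -> int:
        return int(self.mask.sum())

    def footprint(self, row: int, col: int) -> Rect:
        x0 = self.outer.x0 + col * self.cell
        y0 = self.outer.y0 + row * self.cell
        return Rect(x0, y0, x0 + self.cell, y0 + self.cell)


@dataclass
class FovealImage:
    """A CFG-encoded image: dense fovea block plus rexel rings."""

    spec: CfgSpec
    fovea_pixels: np.ndarray  # (fh, fw, 3) RGB, verbatim copy
    fovea_embedding: np.ndarray  # (fh, fw, 3) working HSV embedding
    fovea_depth: np.ndarray | None
    rings: list[RingGrid] = field(default_factory=list)

    @property
    def waist_level(self) -> int:
        return self.spec.num_rings


def _block_reduce(img: np.ndarray, rect: Rect, cell: int) -> np.ndarray:
    """Mean over ``cell``-sized blocks of ``img`` restricted to ``rect``."""
    sub = img[rect.y0 : rect.y1, rect.x0 : rect.x1].astype(np.float64)
    gh, gw = rect.h // cell, rect.w // cell
    if sub.ndim == 2:
        return sub.reshape(gh, cell, gw, cell).mean(axis=(1, 3))
    return sub.reshape(gh, cell, gw, cell, -1).mean(axis=(1, 3))


def build_cfg(
    image: np.ndarray,
    spec: CfgSpec,
    depth: np.ndarray | None = None,
) -> FovealImage:
    """Encode a uniform color image (H, W, 3) as a foveal image.

    Each rexel's color is the arithmetic mean RGB of its pixel footprint
    converted to HSV; mean depth likewise; fovea pixels are copied verbatim.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if (w, h) != tuple(spec.image_size):
        raise InvalidSpecError(
            f"spec image_size {spec.image_size} does not match image {w}x{h}"
        )
    if depth is not None and depth.shape[:2] != (h, w):
        raise InvalidSpecError("depth map dimensions differ from the image")

    rects = spec.ring_rects()
    f = spec.fovea_rect
    fov_px = image[f.y0 : f.y1, f.x0 : f.x1].copy()
    fov_emb = rgb_to_embedding_image(fov_px)
    fov_depth = None
    if depth is not None:
        fov_depth = np.asarray(depth, dtype=np.float64)[f.y0 : f.y1, f.x0 : f.x1].copy()

    rings: list[RingGrid] = []
    for k in range(1, spec.num_rings + 1):
        outer, inner = rects[k], rects[k - 1]
        cell = spec.ring_scale**k
        rgb_grid = _block_reduce(image, outer, cell)
        emb_grid = rgb_to_embedding_image(
            rgb_grid / 255.0 if image.dtype == np.uint8 else rgb_grid
        )
        depth_grid = _block_reduce(depth, outer, cell) if depth is not None else None
        gh, gw = outer.h // cell, outer.w // cell
        mask = np.ones((gh, gw), dtype=bool)
        iy0 = (inner.y0 - outer.y0) // cell
        ix0 = (inner.x0 - outer.x0) // cell
        mask[iy0 : iy0 + inner.h // cell, ix0 : ix0 + inner.w // cell] = False
        rings.append(
            RingGrid(
                index=k,
                outer=outer,
                inner=inner,
                cell=cell,
                mask=mask,
                embedding=emb_grid,
                rgb=rgb_grid,
                depth=depth_grid,
            )
        )
    return FovealImage(
        spec=spec,
        fovea_pixels=fov_px,
        fovea_embedding=fov_emb,
        fovea_depth=fov_depth,
        rings=rings,
    )


def cfg_cell_count(spec: CfgSpec) -> int:
    """Total number of cells (fovea pixels + rexels) in the encoding."""
    rects = spec.ring_rects()
    count = spec.fovea_rect.area
    for k in range(1, spec.num_rings + 1):
        cell = spec.ring_scale**k
        count += (rects[k].area - rects[k - 1].area) // (cell * cell)
    return count


def render_foveated(fov: FovealImage) -> np.ndarray:
    """Paint every rexel's footprint with its mean color; fovea verbatim.

    The output raster has the original image dimensions and dtype of the
    fovea pixels.
    """
    w, h = fov.spec.image_size
    out = np.zeros((h, w, 3), dtype=np.float64)
    for ring in reversed(fov.rings):
        up = np.repeat(np.repeat(ring.rgb, ring.cell, axis=0), ring.cell, axis=1)
        out[ring.outer.y0 : ring.outer.y1, ring.outer.x0 : ring.outer.x1] = up
    f = fov.spec.fovea_rect
    out[f.y0 : f.y1, f.x0 : f.x1] = fov.fovea_pixels
    if fov.fovea_pixels.dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out


def fit_fovea(
    image_size: tuple[int, int],
    center: tuple[float, float],
    size: tuple[int, int],
    num_rings: int,
    ring_scale: int = 2,
) -> Rect:
    """Snap a requested fixation centroid + fovea size to a valid CFG fovea.

    The rectangle is grown to the nearest multiple of ``ring_scale**m``,
    clamped inside the image and its corner snapped onto the grid, moving it
    as little as possible from the requested center.
    """
    w, h = image_size
    unit = ring_scale**num_rings
    fw = int(min(max(unit, int(np.ceil(size[0] / unit)) * unit), (w // unit) * unit))
    fh = int(min(max(unit, int(np.ceil(size[1] / unit)) * unit), (h // unit) * unit))
    x0 = int(round((center[0] - fw / 2.0) / unit)) * unit
    y0 = int(round((center[1] - fh / 2.0) / unit)) * unit
    x0 = min(max(x0, 0), w - fw)
    y0 = min(max(y0, 0), h - fh)
    return Rect(x0, y0, x0 + fw, y0 + fh)
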