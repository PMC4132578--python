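"""Perceptual segmentation on the foveal BIP.

Two stages, both driven by the pyramid's pairwise-comparison decimation:

1. **pre-segmentation** — the BIP is built with the plain HSV color
   predicate (distance ≤ tau_color on the [0..255] working range), yielding
   roots that are blobs of uniform color;
2. **perceptual grouping** — the blob-root graph is iteratively contracted
   under a richer distance ``phi`` that mixes global color contrast, the
   support of the shared boundary by Canny edges, and disparity.  Per
   iteration each region may join only its best (phi-argmin) neighbor and
   only if ``phi ≤ tau_percep``; the process stops when the region count is
   stable.  Surviving regions are the *proto-objects*.

Boundary bookkeeping per region pair: ``b_i`` is the perimeter of region i
in pixels, ``b_ij`` the part of it shared with region j and ``c_ij`` the
subset of that shared boundary lying on (or 4-adjacent to) a Canny edge.
Each boundary pixel is attributed to exactly one neighboring region (the
lowest label among its differing neighbors) so that sum_j b_ij ≤ b_i holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .color import ColorValue, embedding_to_hsv
from .geometry import FovealImage, render_foveated
from .pyramid import ColorSimilarity, Pyramid, build_pyramid


@dataclass(frozen=True)
class GroupingParams:
    """All thresholds of the two-stage segmentation.

    tau_color / tau_percep are the figures' working values; alpha and beta
    control the influence of Canny edges in phi; omega1/omega2 weight the
    color and disparity terms.
    """

    tau_color: float = 50.0
    tau_percep: float = 100.0
    alpha: float = 1.0
    beta: float = 1.0
    omega1: float = 0.5
    omega2: float = 0.5
    canny_low: float = 50.0
    canny_high: float = 150.0
    dc_form: str = "chord"  # "chord" | "printed"
    phi_reading: str = "ratio"  # "ratio" | "product" | "split"
    beta_sign: float = 1.0
    connectivity: int = 4
    depth_is_disparity: bool = False

    def __post_init__(self) -> None:
        for name in ("tau_color", "tau_percep", "alpha", "beta", "omega1", "omega2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.omega1 + self.omega2 <= 0:
            raise ValueError("omega1 + omega2 must be positive")


@dataclass
class ProtoObject:
    """A perceptual-grouping root with its base-level statistics."""

    id: int
    mask: np.ndarray  # (H, W) bool
    area: int
    centroid: tuple[float, float]  # (x, y)
    embedding: np.ndarray  # mean working HSV embedding
    depth: float | None
    b: int  # perimeter pixels
    neighbors: dict[int, tuple[int, int]]  # j -> (b_ij, c_ij)

    @property
    def color(self) -> ColorValue:
        return embedding_to_hsv(self.embedding)

    @property
    def intensity(self) -> float:
        """Mean luminosity <I>: the V channel on the [0, 255] scale."""
        return float(self.embedding[2])

    @property
    def saturation(self) -> float:
        """Mean saturation on [0, 1]."""
        return float(np.hypot(self.embedding[0], self.embedding[1])) / 255.0

    def bounding_box(self) -> tuple[int, int, int, int]:
        ys, xs = np.nonzero(self.mask)
        return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


class NotNeighborsError(ValueError):
    pass


def color_similar(
    e_i: np.ndarray, e_j: np.ndarray, tau_color: float, form: str = "chord"
) -> bool:
    """True iff the working-scale HSV distance of two embeddings ≤ tau."""
    return ColorSimilarity(tau_color, form).similar(e_i, e_j)


def presegment(
    fov: FovealImage, params: GroupingParams = GroupingParams()
) -> tuple[Pyramid, np.ndarray]:
    """Color pre-segmentation: build the BIP under the tau_color predicate.

    Returns the pyramid and the compact blob label map (H, W).
    """
    pyr = build_pyramid(
        fov,
        ColorSimilarity(params.tau_color, params.dc_form),
        connectivity=params.connectivity,
    )
    return pyr, pyr.label_map()


def canny_edges(image: np.ndarray, params: GroupingParams = GroupingParams()) -> np.ndarray:
    """Canny edge map of the luminance channel (thresholds on 8-bit scale)."""
    from skimage.feature import canny

    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        lum = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    else:
        lum = arr
    if lum.max() <= 1.0:
        lum = lum * 255.0
    return canny(lum, low_threshold=params.canny_low, high_threshold=params.canny_high)


def boundary_stats(
    labels: np.ndarray, edges: np.ndarray | None = None
) -> tuple[dict[int, int], dict[tuple[int, int], tuple[int, int]]]:
    """Per-region perimeter and per-pair shared-boundary statistics.

    Returns ``(b, pairs)`` with ``b[i]`` the perimeter of region i (pixels of
    i 4-adjacent to a different label or to the image border) and
    ``pairs[(i, j)] = (b_ij, c_ij)``.
    """
    lab = np.asarray(labels)
    h, w = lab.shape
    pad = np.full((h + 2, w + 2), -1, dtype=lab.dtype)
    pad[1:-1, 1:-1] = lab
    center = pad[1:-1, 1:-1]
    shifts = [pad[:-2, 1:-1], pad[2:, 1:-1], pad[1:-1, :-2], pad[1:-1, 2:]]
    differing = [s != center for s in shifts]
    any_diff = np.logical_or.reduce(differing)
    b = {int(i): int(n) for i, n in zip(*np.unique(lab[any_diff], return_counts=True))}
    for i in np.unique(lab):
        b.setdefault(int(i), 0)

    # attribute each boundary pixel to its lowest differing *valid* neighbor
    neigh = np.stack(shifts)
    big = lab.max() + 1 if lab.size else 0
    masked = np.where((neigh != center) & (neigh >= 0), neigh, big)
    attrib = masked.min(axis=0)  # == big where no differing in-image neighbor
    sel = attrib < big
    if edges is not None:
        e = np.asarray(edges, dtype=bool)
        ep = np.zeros((h + 2, w + 2), dtype=bool)
        ep[1:-1, 1:-1] = e
        near_edge = e | ep[:-2, 1:-1] | ep[2:, 1:-1] | ep[1:-1, :-2] | ep[1:-1, 2:]
    else:
        near_edge = np.zeros((h, w), dtype=bool)
    pairs: dict[tuple[int, int], tuple[int, int]] = {}
    if sel.any():
        i_lab = lab[sel].astype(np.int64)
        j_lab = attrib[sel].astype(np.int64)
        on_edge = near_edge[sel]
        keys = i_lab * (big + 1) + j_lab
        uniq, inv = np.unique(keys, return_inverse=True)
        b_counts = np.bincount(inv)
        c_counts = np.bincount(inv, weights=on_edge.astype(np.float64))
        for k, key in enumerate(uniq.tolist()):
            pairs[(int(key // (big + 1)), int(key % (big + 1)))] = (
                int(b_counts[k]),
                int(round(c_counts[k])),
            )
    return b, pairs


def _phi_color_term(
    d: float, b_i: float, b_ij: float, c_ij: float, params: GroupingParams
) -> float:
    edge_pen = params.beta_sign * params.beta * (b_ij - c_ij)
    if params.phi_reading == "ratio":
        return d * b_i / (params.alpha * max(c_ij, 1.0)) + edge_pen
    if params.phi_reading == "product":
        return d * b_i * params.alpha * c_ij + edge_pen
    if params.phi_reading == "split":
        return d * b_i / params.alpha + c_ij + edge_pen
    raise ValueError(f"unknown phi reading: {params.phi_reading!r}")


def phi_distance(
    i: ProtoObject, j: ProtoObject, params: GroupingParams = GroupingParams()
) -> float:
    """Perceptual-grouping distance phi between two neighboring regions.

    Evaluated with the smaller-area region in the role of i (phi is not
    symmetric in b_i); raises :class:`NotNeighborsError` when the regions
    share no boundary.
    """
    small, other = (i, j) if i.area <= j.area else (j, i)
    if other.id in small.neighbors:
        b_ij, c_ij = small.neighbors[other.id]
    elif small.id in other.neighbors:
        # boundary pixels were attributed to the other region's side
        b_ij, c_ij = other.neighbors[small.id]
    else:
        raise NotNeighborsError(f"regions {i.id} and {j.id} share no boundary")
    d = ColorSimilarity(0, params.dc_form).dist(small.embedding, other.embedding)
    term = _phi_color_term(d, small.b, b_ij, c_ij, params)
    phi = params.omega1 * term * term
    if small.depth is not None and other.depth is not None:
        delta_i = 1.0 / small.depth if not params.depth_is_disparity else small.depth
        delta_j = 1.0 / other.depth if not params.depth_is_disparity else other.depth
        phi += params.omega2 * (delta_i - delta_j) ** 2
    return float(phi)


def _region_table(
    labels: np.ndarray,
    values: np.ndarray,
    npix: np.ndarray,
    depths: np.ndarray | None,
    edges: np.ndarray | None,
) -> list[ProtoObject]:
    b, pairs = boundary_stats(labels, edges)
    protos = []
    yy, xx = np.mgrid[0 : labels.shape[0], 0 : labels.shape[1]]
    for k in range(int(labels.max()) + 1):
        mask = labels == k
        area = int(mask.sum())
        neighbors = {
            j: v for (i, j), v in pairs.items() if i == k
        }
        protos.append(
            ProtoObject(
                id=k,
                mask=mask,
                area=area,
                centroid=(float(xx[mask].mean()), float(yy[mask].mean())),
                embedding=values[k],
                depth=None if depths is None else float(depths[k]),
                b=b.get(k, 0),
                neighbors=neighbors,
            )
        )
    return protos


def perceptual_group(
    labels: np.ndarray,
    values: np.ndarray,
    npix: np.ndarray,
    depths: np.ndarray | None,
    edges: np.ndarray,
    params: GroupingParams = GroupingParams(),
) -> tuple[np.ndarray, list[ProtoObject]]:
    """Iterated best-neighbor contraction of the blob graph under phi.

    ``labels`` is a compact blob label map; ``values``/``npix``/``depths``
    are per-blob aggregates (working embeddings, base pixel counts, mean
    depths).  Returns the compact proto-object label map and the
    proto-object records with populated boundary statistics.
    """
    lab = np.asarray(labels).copy()
    vals = np.asarray(values, dtype=np.float64).copy()
    wts = np.asarray(npix, dtype=np.float64).copy()
    dep = None if depths is None else np.asarray(depths, dtype=np.float64).copy()

    while True:
        protos = _region_table(lab, vals, wts, dep, edges)
        n = len(protos)
        by_id = {p.id: p for p in protos}
        # symmetric adjacency (boundary pixels are attributed one-sided)
        adjacency: dict[int, set[int]] = {p.id: set(p.neighbors) for p in protos}
        for p in protos:
            for j in p.neighbors:
                adjacency[j].add(p.id)
        # best-merge proposal per region
        target = {}
        for p in protos:
            best, best_phi = None, None
            for j in sorted(adjacency[p.id]):
                ph = phi_distance(p, by_id[j], params)
                if ph <= params.tau_percep and (best_phi is None or ph < best_phi):
                    best, best_phi = j, ph
            if best is not None:
                target[p.id] = best
        if not target:
            break
        # union-find application of all proposals
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in sorted(target.items()):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
        roots = sorted({find(i) for i in range(n)})
        if len(roots) == n:
            break
        remap = {}
        for i in range(n):
            remap[i] = roots.index(find(i))
        lut = np.array([remap[i] for i in range(n)])
        lab = lut[lab]
        new_vals = np.zeros((len(roots), 3))
        new_wts = np.zeros(len(roots))
        new_dep = None if dep is None else np.zeros(len(roots))
        for i in range(n):
            k = remap[i]
            new_vals[k] += vals[i] * wts[i]
            new_wts[k] += wts[i]
            if dep is not None:
                new_dep[k] += dep[i] * wts[i]
        vals = new_vals / new_wts[:, None]
        if dep is not None:
            dep = new_dep / new_wts
        wts = new_wts

    return lab, _region_table(lab, vals, wts, dep, edges)


@dataclass
class SegmentationResult:
    pyramid: Pyramid
    blob_labels: np.ndarray
    proto_labels: np.ndarray
    protos: list[ProtoObject]
    edges: np.ndarray
    rendered: np.ndarray


def segment_foveal_image(
    fov: FovealImage, params: GroupingParams = GroupingParams()
) -> SegmentationResult:
    """Full two-stage segmentation of a foveal image into proto-objects."""
    pyr, blob_labels = presegment(fov, params)
    rendered = render_foveated(fov)
    edges = canny_edges(rendered, params)
    roots = sorted(pyr.levels[-1].node_ids)
    values = np.array([pyr.nodes[i].value for i in roots])
    npix = np.array([pyr.nodes[i].npix for i in roots], dtype=np.float64)
    root_depths = [pyr.nodes[i].depth for i in roots]
    depths = (
        np.array([d for d in root_depths], dtype=np.float64)
        if all(d is not None for d in root_depths)
        else None
    )
    proto_labels, protos = perceptual_group(
        blob_labels, values, npix, depths, edges, params
    )
    return SegmentationResult(
        pyramid=pyr,
        blob_labels=blob_labels,
        proto_labels=proto_labels,
        protos=protos,
        edges=edges,
        rendered=rendered,
    )
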