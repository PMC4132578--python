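"""Bounded Irregular Pyramid (BIP) over a foveal image.

The BIP mixes a regular 2×2/4 lattice with an irregular adjacency graph.
Each level ``l`` is a graph G_l = (N_l, E_l); N_l holds *regular* nodes
(cells of the incomplete 2×2/4 structure, carrying a homogeneity flag ``h``)
and *irregular* nodes.  A level is reduced to the next by

1. **regular decimation** — a parent regular cell becomes homogeneous
   (h = 1) iff its four child cells exist, are pairwise similar under the
   pairwise comparison predicate ``g`` and are themselves homogeneous;
2. **irregular decimation** — every orphan links to its closest similar
   neighbor (union-find, sequential in ascending node id, argmin ties to the
   lowest id), or founds a new irregular parent;
3. **intra-level arcs** — parents are neighbors iff their reduction windows
   are connected one level below;
4. **ring injection** (levels up to the waist) — the rexels of the CFG ring
   enter the level as homogeneous regular nodes; their adjacency is defined
   through *virtual* reduction windows (the rexel quadrupled one level
   down), which for a spatial base graph is exactly footprint adjacency.

Construction stops when the node count no longer decreases; the receptive
fields of the surviving roots partition the image.

Because the base-level adjacency is pixel adjacency, window-connectivity
propagates to receptive-field adjacency at every level; the builder exploits
this by deriving each level's edge set from a per-pixel *owner map* in one
vectorized pass (:func:`link_intra_level` implements the literal
window-propagation rule and is used as a cross-check in the test-suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .color import embedding_distance, embedding_distance_many
from .geometry import FovealImage, Rect


class ColorSimilarity:
    """Pairwise comparison predicate g: distance of node values ≤ tau.

    The distance is the working-scale HSV distance (value difference plus
    chroma term), evaluated on the (sx, sy, v) embeddings; ``tau = 0``
    with the default chord form degenerates to exact color equality.  The
    additive ``printed`` chroma form is kept for comparison only — it is
    not a metric (nonzero self-distance).
    """

    def __init__(self, tau: float, form: str = "chord"):
        if tau < 0:
            raise ValueError("tau must be non-negative")
        if form not in ("chord", "printed"):
            raise ValueError(f"unknown dc form: {form!r}")
        self.tau = float(tau)
        self.form = form

    def dist(self, v1: np.ndarray, v2: np.ndarray) -> float:
        if self.form == "printed":
            # S_i + S_j + 2·S_i·S_j·cosθ on the working scale, via the dot
            # product of the chroma parts: S_i·S_j·cosθ = (sx, sy)_i·(sx, sy)_j
            s1 = float(np.hypot(v1[0], v1[1]))
            s2 = float(np.hypot(v2[0], v2[1]))
            dc = s1 + s2 + 2.0 * float(v1[0] * v2[0] + v1[1] * v2[1]) / 255.0
            return dc + abs(float(v1[2]) - float(v2[2]))
        return embedding_distance(v1, v2)

    def similar(self, v1: np.ndarray, v2: np.ndarray) -> bool:
        return self.dist(v1, v2) <= self.tau


@dataclass
class PyramidNode:
    id: int
    level: int
    kind: str  # "regular" | "irregular"
    value: np.ndarray  # (sx, sy, v) working HSV embedding
    npix: int
    cx: float
    cy: float
    depth: float | None = None
    h: bool | None = None  # homogeneity flag; regular nodes only
    parent: int | None = None
    window: list[int] = field(default_factory=list)
    grid_pos: tuple[int, int] | None = None
    footprint: Rect | None = None  # base cells (fovea pixels / rexels) only


@dataclass
class LevelGraph:
    level: int
    node_ids: list[int]
    adjacency: dict[int, set[int]]
    grid: np.ndarray | None = None  # (gh, gw) node ids; -1 = absent/dead
    grid_rect: Rect | None = None
    cell: int = 1
    placeholders: list[int] = field(default_factory=list)  # dead regular ids

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def _adjacent_pairs(owner: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Unique ordered pairs (a < b) of distinct non-negative owners that
    touch under the given pixel connectivity."""
    slices = [
        ((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
        ((slice(None, -1), slice(None)), (slice(1, None), slice(None))),
    ]
    if connectivity == 8:
        slices += [
            ((slice(None, -1), slice(None, -1)), (slice(1, None), slice(1, None))),
            ((slice(None, -1), slice(1, None)), (slice(1, None), slice(None, -1))),
        ]
    elif connectivity != 4:
        raise ValueError("connectivity must be 4 or 8")
    chunks = []
    for s1, s2 in slices:
        p, q = owner[s1].ravel(), owner[s2].ravel()
        m = (p != q) & (p >= 0) & (q >= 0)
        if m.any():
            pq = np.stack([p[m], q[m]], axis=1)
            chunks.append(np.sort(pq, axis=1))
    if not chunks:
        return np.empty((0, 2), dtype=np.int64)
    return np.unique(np.concatenate(chunks, axis=0), axis=0)


def link_intra_level(
    edges_lower: np.ndarray | list[tuple[int, int]],
    parent_of: dict[int, int],
) -> set[tuple[int, int]]:
    """Edge set E_{l+1} from E_l: parents are neighbors iff their reduction
    windows contain adjacent children."""
    out: set[tuple[int, int]] = set()
    for a, b in edges_lower:
        pa, pb = parent_of.get(int(a)), parent_of.get(int(b))
        if pa is None or pb is None or pa == pb:
            continue
        out.add((pa, pb) if pa < pb else (pb, pa))
    return out


class Pyramid:
    """The built hierarchy: levels of graphs plus per-level pixel owner maps."""

    def __init__(self, fov: FovealImage, connectivity: int = 4):
        self.fov = fov
        self.waist = fov.waist_level
        self.connectivity = connectivity
        self.nodes: dict[int, PyramidNode] = {}
        self.levels: list[LevelGraph] = []
        self.owner_maps: list[np.ndarray] = []  # (H, W), -1 outside coverage
        self._next_id = 0

    # -- bookkeeping ------------------------------------------------------

    def _new_node(self, **kw) -> PyramidNode:
        node = PyramidNode(id=self._next_id, **kw)
        self.nodes[node.id] = node
        self._next_id += 1
        return node

    def roots(self) -> list[PyramidNode]:
        """Nodes without parents at the top level: proto-object roots."""
        return [self.nodes[i] for i in self.levels[-1].node_ids]

    def label_map(self) -> np.ndarray:
        """Per-pixel root id (compact relabeling in root order)."""
        top = self.owner_maps[-1]
        relabel = {nid: k for k, nid in enumerate(sorted(self.levels[-1].node_ids))}
        out = np.full_like(top, -1)
        for nid, k in relabel.items():
            out[top == nid] = k
        return out

    def to_debug_dict(self) -> dict:
        """JSON-serializable dump of the node table and edge lists."""
        return {
            "waist": self.waist,
            "levels": [
                {
                    "level": lv.level,
                    "n_nodes": lv.n_nodes,
                    "edges": sorted(
                        [sorted([a, b]) for a in lv.adjacency for b in lv.adjacency[a] if a < b]
                    ),
                }
                for lv in self.levels
            ],
            "nodes": {
                str(n.id): {
                    "level": n.level,
                    "kind": n.kind,
                    "h": n.h,
                    "parent": n.parent,
                    "npix": n.npix,
                    "value": [float(x) for x in n.value],
                }
                for n in self.nodes.values()
            },
        }

    # -- base level -------------------------------------------------------

    def _build_base(self) -> None:
        fov = self.fov
        f = fov.spec.fovea_rect
        w, h = fov.spec.image_size
        owner = np.full((h, w), -1, dtype=np.int64)
        ids = np.empty((f.h, f.w), dtype=np.int64)
        emb = fov.fovea_embedding
        for r in range(f.h):
            for c in range(f.w):
                node = self._new_node(
                    level=0,
                    kind="regular",
                    value=emb[r, c].astype(np.float64),
                    npix=1,
                    cx=float(f.x0 + c),
                    cy=float(f.y0 + r),
                    depth=None if fov.fovea_depth is None else float(fov.fovea_depth[r, c]),
                    h=True,
                    grid_pos=(r, c),
                    footprint=Rect(f.x0 + c, f.y0 + r, f.x0 + c + 1, f.y0 + r + 1),
                )
                ids[r, c] = node.id
        owner[f.y0 : f.y1, f.x0 : f.x1] = ids
        level = LevelGraph(
            level=0,
            node_ids=[int(i) for i in ids.ravel()],
            adjacency=self._adjacency_from_owner(owner),
            grid=ids,
            grid_rect=f,
            cell=1,
        )
        self.levels.append(level)
        self.owner_maps.append(owner)

    def _adjacency_from_owner(self, owner: np.ndarray) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {}
        for a, b in _adjacent_pairs(owner, self.connectivity):
            adj.setdefault(int(a), set()).add(int(b))
            adj.setdefault(int(b), set()).add(int(a))
        return adj

    # -- decimation steps -------------------------------------------------

    def _regular_decimation(self, lower: LevelGraph, g, parent_rect: Rect, parent_cell: int):
        """Step 1: 2×2/4 reduction of the regular lattice.

        Returns (parent grid, list of new parent ids, placeholder ids).
        """
        gh = -(-parent_rect.h // parent_cell)
        gw = -(-parent_rect.w // parent_cell)
        pgrid = np.full((gh, gw), -1, dtype=np.int64)
        new_ids: list[int] = []
        placeholders: list[int] = []
        if lower.grid is None:
            return pgrid, new_ids, placeholders
        cgrid, crect = lower.grid, lower.grid_rect
        ch, cw = cgrid.shape
        # offset of the child grid inside the parent grid, in child cells
        oy = (crect.y0 - parent_rect.y0) // lower.cell
        ox = (crect.x0 - parent_rect.x0) // lower.cell
        for gi in range(gh):
            for gj in range(gw):
                ci, cj = 2 * gi - oy, 2 * gj - ox
                if ci < 0 or cj < 0 or ci >= ch or cj >= cw:
                    continue  # entirely outside the child lattice (ring area)
                child_ids = []
                complete = True
                for di in (0, 1):
                    for dj in (0, 1):
                        y, x = ci + di, cj + dj
                        if 0 <= y < ch and 0 <= x < cw and cgrid[y, x] >= 0:
                            child_ids.append(int(cgrid[y, x]))
                        else:
                            complete = False
                if not child_ids:
                    continue
                homogeneous = complete
                if homogeneous:
                    vals = [self.nodes[i].value for i in child_ids]
                    for a in range(4):
                        for b in range(a + 1, 4):
                            if not g.similar(vals[a], vals[b]):
                                homogeneous = False
                                break
                        if not homogeneous:
                            break
                if homogeneous:
                    parent = self._new_node(
                        level=lower.level + 1,
                        kind="regular",
                        value=np.zeros(3),
                        npix=0,
                        cx=0.0,
                        cy=0.0,
                        h=True,
                        grid_pos=(gi, gj),
                    )
                    parent.window = child_ids
                    for i in child_ids:
                        self.nodes[i].parent = parent.id
                    pgrid[gi, gj] = parent.id
                    new_ids.append(parent.id)
                else:
                    # dead placeholder: stored, flagged, never processed
                    dead = self._new_node(
                        level=lower.level + 1,
                        kind="regular",
                        value=np.zeros(3),
                        npix=0,
                        cx=0.0,
                        cy=0.0,
                        h=False,
                        grid_pos=(gi, gj),
                    )
                    placeholders.append(dead.id)
        return pgrid, new_ids, placeholders

    def _irregular_decimation(self, lower: LevelGraph, g) -> list[int]:
        """Step 2: sequential union-find linking of orphans.

        Every node of N_l has a parent afterwards.  Returns new parent ids.
        """
        new_ids: list[int] = []
        for x_id in sorted(lower.node_ids):
            x = self.nodes[x_id]
            if x.parent is not None:
                continue
            neigh = sorted(lower.adjacency.get(x_id, ()))
            best = None
            if neigh:
                if g.form == "chord":
                    vals = np.array([self.nodes[z].value for z in neigh])
                    dists = embedding_distance_many(x.value, vals)
                else:
                    dists = np.array(
                        [g.dist(x.value, self.nodes[z].value) for z in neigh]
                    )
                order = np.lexsort((np.array(neigh), dists))
                for k in order:
                    if dists[k] <= g.tau:
                        best = neigh[int(k)]
                        break  # closest *similar* neighbor
            if best is None:
                parent = self._new_node(
                    level=lower.level + 1,
                    kind="irregular",
                    value=x.value.copy(),
                    npix=0,
                    cx=0.0,
                    cy=0.0,
                )
                parent.window = [x_id]
                x.parent = parent.id
                new_ids.append(parent.id)
                continue
            y = self.nodes[best]
            if y.parent is not None:
                p = self.nodes[y.parent]
                p.window.append(x_id)
                x.parent = p.id
            else:
                p = self._new_node(
                    level=lower.level + 1,
                    kind="irregular",
                    value=x.value.copy(),
                    npix=0,
                    cx=0.0,
                    cy=0.0,
                )
                p.window = [x_id, best]
                x.parent = p.id
                y.parent = p.id
                new_ids.append(p.id)
        return new_ids

    def _recompute_aggregates(self, ids: list[int]) -> None:
        for pid in ids:
            p = self.nodes[pid]
            children = [self.nodes[c] for c in p.window]
            wts = np.array([c.npix for c in children], dtype=np.float64)
            total = wts.sum()
            vals = np.array([c.value for c in children])
            if (vals == vals[0]).all():
                # exact fixed point: identical children keep their value
                # bit-for-bit (a float weighted mean would add noise and
                # break exact-equality predicates at higher levels)
                p.value = vals[0].copy()
            else:
                p.value = (vals * wts[:, None]).sum(axis=0) / total
            p.npix = int(total)
            p.cx = float(sum(c.cx * c.npix for c in children) / total)
            p.cy = float(sum(c.cy * c.npix for c in children) / total)
            if all(c.depth is not None for c in children):
                p.depth = float(sum(c.depth * c.npix for c in children) / total)

    def _inject_ring(self, pgrid: np.ndarray, level_index: int) -> list[int]:
        """Step 4: add the CFG ring's rexels as homogeneous regular nodes."""
        ring = self.fov.rings[level_index - 1]
        new_ids: list[int] = []
        rows, cols = np.nonzero(ring.mask)
        for r, c in zip(rows.tolist(), cols.tolist()):
            fp = ring.footprint(r, c)
            node = self._new_node(
                level=level_index,
                kind="regular",
                value=ring.embedding[r, c].astype(np.float64),
                npix=fp.area,
                cx=(fp.x0 + fp.x1 - 1) / 2.0,
                cy=(fp.y0 + fp.y1 - 1) / 2.0,
                depth=None if ring.depth is None else float(ring.depth[r, c]),
                h=True,
                grid_pos=(r, c),
                footprint=fp,
            )
            pgrid[r, c] = node.id
            new_ids.append(node.id)
        return new_ids

    # -- level loop -------------------------------------------------------

    def _build_level(self, g) -> bool:
        """Build the next level; returns False when the pyramid is stable."""
        lower = self.levels[-1]
        lvl = lower.level + 1
        spec = self.fov.spec
        w, h = spec.image_size
        if lvl <= self.waist:
            parent_rect = spec.ring_rects()[lvl]
            parent_cell = spec.ring_scale**lvl
        else:
            parent_rect = Rect(0, 0, w, h)
            parent_cell = lower.cell * 2

        checkpoint = self._next_id
        pgrid, reg_ids, placeholders = self._regular_decimation(
            lower, g, parent_rect, parent_cell
        )
        irr_ids = self._irregular_decimation(lower, g)
        self._recompute_aggregates(reg_ids + irr_ids)
        # owner map through parent pointers
        lower_owner = self.owner_maps[-1]
        owner = np.full_like(lower_owner, -1)
        mapping = {nid: self.nodes[nid].parent for nid in lower.node_ids}
        ids_arr = np.array(sorted(mapping), dtype=np.int64)
        parents_arr = np.array([mapping[i] for i in ids_arr.tolist()], dtype=np.int64)
        lut_idx = np.searchsorted(ids_arr, lower_owner[lower_owner >= 0])
        owner[lower_owner >= 0] = parents_arr[lut_idx]
        ring_ids: list[int] = []
        if lvl <= self.waist:
            ring_ids = self._inject_ring(pgrid, lvl)
            ring = self.fov.rings[lvl - 1]
            for nid in ring_ids:
                fp = self.nodes[nid].footprint
                owner[fp.y0 : fp.y1, fp.x0 : fp.x1] = nid

        node_ids = sorted(reg_ids + irr_ids + ring_ids)
        stable = lvl > self.waist and len(node_ids) >= lower.n_nodes
        if stable:
            # roll the level back: the hierarchy ends at ``lower``
            for nid in lower.node_ids:
                self.nodes[nid].parent = None
            for nid in range(checkpoint, self._next_id):
                del self.nodes[nid]
            self._next_id = checkpoint
            return False

        level = LevelGraph(
            level=lvl,
            node_ids=node_ids,
            adjacency=self._adjacency_from_owner(owner),
            grid=pgrid,
            grid_rect=parent_rect,
            cell=parent_cell,
            placeholders=placeholders,
        )
        self.levels.append(level)
        self.owner_maps.append(owner)
        return True

    def build(self, g) -> "Pyramid":
        self._build_base()
        max_levels = self.waist + 40
        while len(self.levels) <= max_levels:
            if len(self.levels) - 1 >= self.waist and self.levels[-1].n_nodes == 1:
                break
            if not self._build_level(g):
                break
        return self


def build_pyramid(
    fov: FovealImage, g: ColorSimilarity, connectivity: int = 4
) -> Pyramid:
    """Build the foveal BIP: decimation + ring injection up to the waist,
    pure decimation above, stopping when the node count stabilizes."""
    return Pyramid(fov, connectivity=connectivity).build(g)
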