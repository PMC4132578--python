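"""The active fixation loop: foveate → segment → score → select → inhibit.

One iteration foveates the frame at the current region of interest (ROI),
extracts proto-objects by perceptual foveal segmentation, scores their
saliency, updates the tracked positions of the recently attended objects
held in a bounded working memory (WM), suppresses candidates overlapping
them (object-based inhibition of return) and selects the most salient
survivor as the next ROI.  On the first frame the fovea sits at the image
center.  The fovea for the next iteration is the bounding box of the
selected proto-object, padded and snapped to a valid CFG fovea, so the
attended object is analyzed at full resolution next.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig
from .geometry import Rect, build_cfg, fit_fovea, CfgSpec
from .segmentation import ProtoObject, SegmentationResult, segment_foveal_image
from .saliency import SaliencyResult, compute_saliency
from .tracking import WorkingMemoryEntry, color_model, hsv_bin_map, meanshift_track


class NoRoiError(RuntimeError):
    pass


@dataclass
class FixationRecord:
    frame: int
    x: float
    y: float
    object_id: int
    sal: float


@dataclass
class ScanPath:
    fixations: list[FixationRecord] = field(default_factory=list)

    def centroids(self) -> np.ndarray:
        return np.array([[f.x, f.y] for f in self.fixations], dtype=np.float64)

    def __len__(self) -> int:
        return len(self.fixations)

    def to_records(self) -> list[dict]:
        return [
            {"frame": f.frame, "x": f.x, "y": f.y, "object_id": f.object_id, "sal": f.sal}
            for f in self.fixations
        ]


class WorkingMemory:
    """Bounded store of recently attended objects (oldest evicted first)."""

    def __init__(self, capacity: int = 4, max_age: int | None = None):
        self.capacity = capacity
        self.max_age = max_age
        self.entries: list[WorkingMemoryEntry] = []

    def alive(self) -> list[WorkingMemoryEntry]:
        return [e for e in self.entries if e.alive]

    def add(self, entry: WorkingMemoryEntry) -> None:
        self.entries.append(entry)
        while len(self.entries) > self.capacity:
            self.entries.pop(0)

    def evict_oldest(self) -> None:
        alive = self.alive()
        if alive:
            self.entries.remove(alive[0])

    def age(self) -> None:
        for e in self.entries:
            e.frames_since_attended += 1
            if self.max_age is not None and e.frames_since_attended > self.max_age:
                e.alive = False
        self.entries = [e for e in self.entries if e.alive]

    def __len__(self) -> int:
        return len(self.entries)


def _iou(a: Rect, b: Rect) -> float:
    ix = max(0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def overlap_suppressed(
    p: ProtoObject,
    entry: WorkingMemoryEntry,
    iou_threshold: float = 0.3,
    containment_threshold: float = 0.7,
) -> bool:
    """True iff the candidate occupies the region of an attended object.

    Either the bounding windows overlap substantially (IoU ≥ threshold) or
    the candidate lies mostly inside the attended window (containment ≥
    threshold) — the latter catches small fragments of an already attended
    object that a pure IoU test would miss.
    """
    if not entry.alive:
        return False
    box = Rect(*p.bounding_box())
    if _iou(box, entry.window) >= iou_threshold:
        return True
    ix = max(0, min(box.x1, entry.window.x1) - max(box.x0, entry.window.x0))
    iy = max(0, min(box.y1, entry.window.y1) - max(box.y0, entry.window.y0))
    return box.area > 0 and (ix * iy) / box.area >= containment_threshold


def select_roi(
    protos: list[ProtoObject],
    sal: np.ndarray,
    wm: WorkingMemory,
    iou_threshold: float = 0.3,
) -> ProtoObject:
    """Most salient non-inhibited proto-object.

    Ties broken by larger area, then lower id.  If every candidate is
    suppressed, the oldest WM entry is evicted and selection re-run.
    """
    if not protos:
        raise NoRoiError("no proto-objects to attend")
    while True:
        alive = wm.alive()
        survivors = [
            (p, float(sal[k]))
            for k, p in enumerate(protos)
            if not any(overlap_suppressed(p, e, iou_threshold) for e in alive)
        ]
        if survivors:
            return max(survivors, key=lambda t: (t[1], t[0].area, -t[0].id))[0]
        if not alive:
            # nothing suppresses, yet no survivors: cannot happen, but guard
            raise NoRoiError("selection failed with empty working memory")
        wm.evict_oldest()


@dataclass
class AttentionState:
    """Mutable loop state: current fovea, working memory, scan path."""

    fovea: Rect | None = None
    wm: WorkingMemory | None = None
    scan_path: ScanPath = field(default_factory=ScanPath)
    frame_index: int = 0
    last_segmentation: SegmentationResult | None = None
    last_saliency: SaliencyResult | None = None


@dataclass
class StepResult:
    state: AttentionState
    selected: ProtoObject
    segmentation: SegmentationResult
    saliency: SaliencyResult


def attend_step(
    frame: np.ndarray,
    state: AttentionState,
    config: ModelConfig = ModelConfig(),
    depth: np.ndarray | None = None,
) -> StepResult:
    """One full iteration of the attention loop on one frame."""
    h, w = frame.shape[:2]
    m, s = config.cfg.num_rings, config.cfg.ring_scale
    if state.wm is None:
        state.wm = WorkingMemory(config.attention.capacity, config.attention.max_age)
    if state.fovea is None:
        # first frame: fovea at the image center
        size = (max(w // 4, config.attention.min_fovea[0]),
                max(h // 4, config.attention.min_fovea[1]))
        state.fovea = fit_fovea((w, h), (w / 2.0, h / 2.0), size, m, s)

    spec = CfgSpec((w, h), state.fovea, num_rings=m, ring_scale=s)
    fov = build_cfg(frame, spec, depth=depth)
    seg = segment_foveal_image(fov, config.grouping)
    saliency = compute_saliency(
        seg.protos,
        weights=config.weights,
        skin_model=config.skin,
        depth_is_disparity=config.grouping.depth_is_disparity,
    )

    # keep inhibited locations current, then age the memory
    bins = hsv_bin_map(frame)
    for entry in state.wm.alive():
        meanshift_track(
            frame, entry, config.attention.lost_track_threshold, frame_bins=bins
        )
    state.wm.age()

    selected = select_roi(
        seg.protos, saliency.sal, state.wm, config.attention.iou_threshold
    )
    k = selected.id
    state.scan_path.fixations.append(
        FixationRecord(
            frame=state.frame_index,
            x=selected.centroid[0],
            y=selected.centroid[1],
            object_id=k,
            sal=float(saliency.sal[k]),
        )
    )

    box = Rect(*selected.bounding_box())
    win = Rect(
        max(box.x0, 0), max(box.y0, 0), min(box.x1, w), min(box.y1, h)
    )
    state.wm.add(
        WorkingMemoryEntry(
            object_id=k,
            model=color_model(bins, win, mask=selected.mask),
            window=win,
            centroid=selected.centroid,
            sal=float(saliency.sal[k]),
        )
    )

    pad = config.attention.fovea_padding
    state.fovea = fit_fovea(
        (w, h),
        selected.centroid,
        (max(box.w + 2 * pad, config.attention.min_fovea[0]),
         max(box.h + 2 * pad, config.attention.min_fovea[1])),
        m,
        s,
    )
    state.frame_index += 1
    state.last_segmentation = seg
    state.last_saliency = saliency
    return StepResult(state=state, selected=selected, segmentation=seg, saliency=saliency)


def explore_static(
    image: np.ndarray,
    n_fixations: int,
    config: ModelConfig = ModelConfig(),
    depth: np.ndarray | None = None,
    return_state: bool = False,
):
    """Active exploration of a static image: n re-foveated iterations."""
    state = AttentionState()
    results = []
    for _ in range(max(n_fixations, 0)):
        results.append(attend_step(image, state, config, depth=depth))
    if return_state:
        return state.scan_path, state, results
    return state.scan_path
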