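"""Fixation-prediction evaluation: density maps, shuffled AUC, scan-paths.

The model's "fixations" are regions, not points: a model fixation density
map is the sum of the attended proto-object masks over ``n`` exploration
iterations.  Prediction quality against human eye-tracking data uses

* **shuffled ROC-AUC** — the density map thresholded as a binary classifier
  separating positive samples (fixations on this image) from negatives
  (fixations of the same observers on *other* images), which cancels the
  center bias; computed by the rank-sum (Mann–Whitney) formulation with
  midrank ties;
* **scan-path similarity** — Smith–Waterman local alignment of two ordered
  fixation sequences, with match reward 1 − dist/diag (floored at 0) and a
  constant insertion/deletion penalty (−1/2 by default).  Scores are
  comparable in protocol, not in absolute value, to other alignment-based
  similarity indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import rankdata

from .attention import ScanPath, explore_static
from .config import ModelConfig

FIXATION_COLUMNS = ("image", "subject", "order", "x", "y")


@dataclass
class FixationSet:
    """Human fixations on one image: (x, y) points with subject and order."""

    points: np.ndarray  # (n, 2) x, y
    subjects: np.ndarray
    order: np.ndarray
    image_id: str = ""

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, image_id: str = "") -> "FixationSet":
        return cls(
            points=df[["x", "y"]].to_numpy(dtype=np.float64),
            subjects=df["subject"].to_numpy(),
            order=df["order"].to_numpy(),
            image_id=image_id,
        )

    def scanpath_of(self, subject) -> np.ndarray:
        sel = self.subjects == subject
        return self.points[sel][np.argsort(self.order[sel])]


def model_density_map(
    image: np.ndarray,
    n: int,
    config: ModelConfig = ModelConfig(),
    depth: np.ndarray | None = None,
    sigma: float | None = None,
) -> np.ndarray:
    """Sum of the attended proto-object masks over ``n`` fixations.

    Overlapping revisits accumulate additively; optional Gaussian blur.
    """
    if n < 1:
        raise ValueError("need at least one fixation")
    _, _, results = explore_static(image, n, config, depth=depth, return_state=True)
    density = np.zeros(image.shape[:2], dtype=np.float64)
    for res in results:
        density += res.selected.mask
    if sigma is None:
        sigma = config.evaluation.density_sigma
    if sigma and sigma > 0:
        density = gaussian_filter(density, sigma)
    return density


def _sample_map(density: np.ndarray, points: np.ndarray) -> np.ndarray:
    h, w = density.shape
    xs = np.clip(np.round(points[:, 0]).astype(np.int64), 0, w - 1)
    ys = np.clip(np.round(points[:, 1]).astype(np.int64), 0, h - 1)
    return density[ys, xs]


def shuffled_auc(
    density: np.ndarray,
    positives: FixationSet | np.ndarray,
    negatives: FixationSet | np.ndarray,
) -> float:
    """ROC-AUC separating positive from negative fixations by map value.

    Equivalent to sweeping thresholds over map values; ties midranked.
    """
    pos = positives.points if isinstance(positives, FixationSet) else np.asarray(positives)
    neg = negatives.points if isinstance(negatives, FixationSet) else np.asarray(negatives)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("positive and negative sets must be non-empty")
    vp = _sample_map(density, pos.astype(np.float64))
    vn = _sample_map(density, neg.astype(np.float64))
    ranks = rankdata(np.concatenate([vp, vn]))
    n_pos, n_neg = len(vp), len(vn)
    r_pos = ranks[:n_pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _match_reward(a: np.ndarray, b: np.ndarray, diag: float) -> float:
    return max(0.0, 1.0 - float(np.hypot(a[0] - b[0], a[1] - b[1])) / diag)


def scanpath_similarity(
    a: "ScanPath | np.ndarray",
    b: "ScanPath | np.ndarray",
    gap: float = -0.5,
    image_size: tuple[int, int] | None = None,
) -> float:
    """Smith–Waterman local alignment score of two fixation sequences.

    Match reward 1 − dist/diag floored at 0 (diag = image diagonal; when no
    image size is given, the diagonal of the joint bounding box is used);
    insertions/deletions cost ``gap``.  The empty alignment scores 0, so the
    result is never negative.
    """
    pa = a.centroids() if isinstance(a, ScanPath) else np.asarray(a, dtype=np.float64)
    pb = b.centroids() if isinstance(b, ScanPath) else np.asarray(b, dtype=np.float64)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("scan paths must be non-empty")
    if image_size is not None:
        diag = float(np.hypot(*image_size))
    else:
        allp = np.concatenate([pa, pb])
        span = allp.max(axis=0) - allp.min(axis=0)
        diag = float(np.hypot(*span)) or 1.0
    n, m = len(pa), len(pb)
    H = np.zeros((n + 1, m + 1))
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            H[i, j] = max(
                0.0,
                H[i - 1, j - 1] + _match_reward(pa[i - 1], pb[j - 1], diag),
                H[i - 1, j] + gap,
                H[i, j - 1] + gap,
            )
            best = max(best, H[i, j])
    return best


def evaluate_dataset(
    images: dict[str, np.ndarray],
    fixations: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    n_fixations: int | None = None,
) -> pd.DataFrame:
    """Per-image shuffled AUC and mean scan-path similarity vs all subjects.

    ``fixations`` follows the CSV dialect: columns image, subject, order,
    x, y (0-based pixel coordinates).  Images without fixation data are
    skipped with a warning.  Negatives for an image are the fixations on
    every other image of the set.
    """
    import warnings

    missing = set(fixations.columns).symmetric_difference(FIXATION_COLUMNS)
    if set(FIXATION_COLUMNS) - set(fixations.columns):
        raise ValueError(f"fixation table must have columns {FIXATION_COLUMNS}")
    del missing
    rows = []
    sets = {
        img_id: FixationSet.from_dataframe(grp, img_id)
        for img_id, grp in fixations.groupby("image")
    }
    for img_id, image in sorted(images.items()):
        if img_id not in sets or len(sets[img_id].points) == 0:
            warnings.warn(f"no fixations for image '{img_id}'; skipped")
            continue
        fs = sets[img_id]
        if n_fixations is not None:
            n = n_fixations
        else:
            counts = [np.sum(fs.subjects == s) for s in np.unique(fs.subjects)]
            n = max(1, int(round(float(np.mean(counts)))))
        density = model_density_map(image, n, config)
        negatives = np.concatenate(
            [sets[o].points for o in sets if o != img_id]
        ) if len(sets) > 1 else None
        auc = shuffled_auc(density, fs, negatives) if negatives is not None else np.nan
        path = explore_static(image, n, config)
        h, w = image.shape[:2]
        sims = [
            scanpath_similarity(
                path, fs.scanpath_of(s), config.evaluation.gap, (w, h)
            )
            for s in np.unique(fs.subjects)
        ]
        rows.append(
            {
                "image": img_id,
                "n_fixations": n,
                "shuffled_auc": auc,
                "scanpath_similarity": float(np.mean(sims)),
            }
        )
    return pd.DataFrame(rows)
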