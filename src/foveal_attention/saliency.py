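"""Per-proto-object saliency: seven features combined by weighted sum.

The features follow feature-integration-theory practice: local contrasts
(color, intensity, orientation) of a region against its segmentation
neighbors, plus intrinsic shape and scene cues (roundness, symmetry,
proximity, skin color).  Every feature is normalized per frame to
[0, 255] (x -> 255 · x / max over the frame's proto-objects) and the scalar
saliency is sal_i = λ · f_i with convex weights λ.

When no depth channel is available the proximity feature is dropped and the
remaining weights renormalized, so static image datasets remain scoreable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import hsv2rgb

from .color import ColorValue, embedding_distance, rgb_to_tsl
from .segmentation import ProtoObject

FEATURE_NAMES = ("ColCON", "IntCON", "PROX", "ROUND", "OriCON", "SYMM", "SKN")


class DegenerateRegionError(ValueError):
    pass


@dataclass(frozen=True)
class SaliencyWeights:
    """Convex weights over (ColCON, IntCON, PROX, ROUND, OriCON, SYMM, SKN)."""

    values: tuple[float, ...] = (1 / 7,) * 7
    auto_renormalize: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (7,) or (v < 0).any():
            raise ValueError("need 7 non-negative weights")
        if not np.isclose(v.sum(), 1.0, atol=1e-6):
            if self.auto_renormalize and v.sum() > 0:
                object.__setattr__(self, "values", tuple(v / v.sum()))
            else:
                raise ValueError(f"weights must sum to 1 (got {v.sum():g})")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.float64)

    def without_proximity(self) -> np.ndarray:
        """Weights with PROX dropped and the rest renormalized."""
        v = self.as_array().copy()
        v[FEATURE_NAMES.index("PROX")] = 0.0
        if v.sum() == 0:
            raise ValueError("all weight rests on the unavailable PROX feature")
        return v / v.sum()


# Chrominance statistics of a small synthetic panel of canonical skin-tone
# RGB values converted to TSL; editable defaults, not a fitted model.
DEFAULT_SKIN_MEAN = (0.5023013, 0.15905335)
DEFAULT_SKIN_COV = ((3.4619e-04, 5.7004e-04), (5.7004e-04, 5.56743e-03))


@dataclass(frozen=True)
class SkinModel:
    """TSL chrominance skin model: mean, covariance, Mahalanobis threshold."""

    mean: tuple[float, float] = DEFAULT_SKIN_MEAN
    cov: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_SKIN_COV
    theta: float = 3.0

    def __post_init__(self) -> None:
        c = np.asarray(self.cov, dtype=np.float64)
        if not np.allclose(c, c.T) or np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("covariance must be symmetric positive definite")

    def mahalanobis(self, color: ColorValue) -> float:
        rgb = hsv2rgb(np.array([[[color.h / 360.0, color.s, color.v]]]))[0, 0]
        ts = rgb_to_tsl(rgb)[:2] - np.asarray(self.mean)
        inv = np.linalg.inv(np.asarray(self.cov))
        return float(np.sqrt(ts @ inv @ ts))


@dataclass(frozen=True)
class MomentSet:
    """Central moments of a region mask about its centroid, plus shape stats."""

    mu20: float
    mu02: float
    mu11: float

    @property
    def eccentricity(self) -> float:
        denom = (self.mu20 + self.mu02) ** 2
        if denom == 0:
            return 0.0
        return ((self.mu20 - self.mu02) ** 2 + 4.0 * self.mu11**2) / denom

    @property
    def orientation(self) -> float:
        """Principal-axis angle in degrees, in (−90, 90]; 0 for isotropic."""
        if self.mu20 == self.mu02 and self.mu11 == 0:
            return 0.0
        phi = 0.5 * np.degrees(np.arctan2(2.0 * self.mu11, self.mu20 - self.mu02))
        if phi <= -90.0:
            phi += 180.0
        elif phi > 90.0:
            phi -= 180.0
        return float(phi)


# ---------------------------------------------------------------------------
# individual features (raw values)
# ---------------------------------------------------------------------------

def color_contrast(p: ProtoObject, others: dict[int, ProtoObject]) -> float:
    """Mean color gradient along the boundary, damped by mean saturation.

    ColCON_i = (S_i / b_i) · Σ_j b_ij · d(<C_i>, <C_j>); gray/white/black
    regions (S_i = 0) are suppressed.
    """
    if p.b <= 0:
        raise DegenerateRegionError(f"region {p.id} has empty perimeter")
    acc = sum(
        b_ij * embedding_distance(p.embedding, others[j].embedding)
        for j, (b_ij, _) in p.neighbors.items()
    )
    return p.saturation / p.b * acc


def intensity_contrast(p: ProtoObject, others: dict[int, ProtoObject]) -> float:
    """Mean luminosity gradient along the boundary:
    IntCON_i = (1/b_i) · Σ_j b_ij · |<I_i> − <I_j>|."""
    if p.b <= 0:
        raise DegenerateRegionError(f"region {p.id} has empty perimeter")
    acc = sum(
        b_ij * abs(p.intensity - others[j].intensity)
        for j, (b_ij, _) in p.neighbors.items()
    )
    return acc / p.b


def proximity(p: ProtoObject, depth_is_disparity: bool = False) -> float | None:
    """PROX = 1/depth (or the disparity itself, which is ∝ inverse depth)."""
    if p.depth is None:
        return None
    if depth_is_disparity:
        return float(p.depth)
    if p.depth <= 0:
        return None
    return 1.0 / float(p.depth)


def mask_moments(mask: np.ndarray) -> MomentSet:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise DegenerateRegionError("empty mask")
    x, y = xs.astype(np.float64), ys.astype(np.float64)
    xc, yc = x.mean(), y.mean()
    dx, dy = x - xc, y - yc
    return MomentSet(
        mu20=float((dx * dx).sum()),
        mu02=float((dy * dy).sum()),
        mu11=float((dx * dy).sum()),
    )


def moments_and_roundness(mask: np.ndarray) -> tuple[MomentSet, float]:
    """ROUND = 1 − eccentricity; 1 for a disc (or single pixel), 0 for a line."""
    ms = mask_moments(mask)
    return ms, 1.0 - ms.eccentricity


def _axial_difference(a: float, b: float) -> float:
    """Difference of two axial (180°-periodic) angles, wrapped to [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def orientation_contrast(
    phi_i: float, neighbor_phis: "list[float] | np.ndarray"
) -> float:
    """OriCON_i = Σ_j |φ_i − φ_j| with axial wrapping."""
    return float(sum(_axial_difference(phi_i, pj) for pj in neighbor_phis))


def symmetry(mask: np.ndarray, phi: float) -> float:
    """Maximum mirror symmetry over 4 axes at 0/45/90/135° from φ.

    For each axis through the centroid, the score is the fraction of mask
    pixels whose mirror image across the axis also belongs to the mask; the
    maximum over axes is returned (averaging would let asymmetric axes
    cancel a genuinely symmetric one).
    """
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise DegenerateRegionError("empty mask")
    h, w = mask.shape
    x, y = xs.astype(np.float64), ys.astype(np.float64)
    xc, yc = x.mean(), y.mean()
    dx, dy = x - xc, y - yc
    best = 0.0
    for off in (0.0, 45.0, 90.0, 135.0):
        t = np.deg2rad(phi + off)
        ux, uy = np.cos(t), np.sin(t)
        proj = dx * ux + dy * uy
        rx = 2.0 * proj * ux - dx
        ry = 2.0 * proj * uy - dy
        mx = np.rint(rx + xc).astype(np.int64)
        my = np.rint(ry + yc).astype(np.int64)
        inside = (mx >= 0) & (mx < w) & (my >= 0) & (my < h)
        score = float(mask[my[inside], mx[inside]].sum()) / ys.size
        best = max(best, score)
    return best


def skin_score(color: ColorValue, model: SkinModel = SkinModel()) -> float:
    """255 iff the TSL chrominance is within Θ_skin of the model mean, else 0."""
    return 255.0 if model.mahalanobis(color) <= model.theta else 0.0


# ---------------------------------------------------------------------------
# normalization and combination
# ---------------------------------------------------------------------------

def normalize_features(raw: np.ndarray) -> np.ndarray:
    """Per-frame max normalization of each feature column to [0, 255].

    SKN is already valued in {0, 255} and passes through unchanged (max
    scaling is the identity on it unless all objects score 0, in which case
    the column is zero anyway).  Columns with max 0 map to all zeros; NaN
    entries (unavailable feature) stay NaN.
    """
    raw = np.asarray(raw, dtype=np.float64)
    out = np.zeros_like(raw)
    for k in range(raw.shape[1]):
        col = raw[:, k]
        finite = np.isfinite(col)
        mx = col[finite].max() if finite.any() else 0.0
        if mx > 0:
            out[:, k] = 255.0 * col / mx
        out[:, k][~finite] = np.nan
    return out


def combine_saliency(features: np.ndarray, weights: SaliencyWeights) -> np.ndarray:
    """sal = λ · f per object; PROX-free weights are used when PROX is NaN."""
    f = np.atleast_2d(np.asarray(features, dtype=np.float64))
    lam = weights.as_array()
    if np.isnan(f[:, FEATURE_NAMES.index("PROX")]).any():
        lam = weights.without_proximity()
        f = f.copy()
        f[:, FEATURE_NAMES.index("PROX")] = 0.0
    return f @ lam


def saliency_map(labels: np.ndarray, sal: np.ndarray) -> np.ndarray:
    """Raster where each pixel takes its proto-object's saliency value."""
    lut = np.asarray(sal, dtype=np.float64)
    return lut[np.asarray(labels)]


@dataclass
class SaliencyResult:
    raw: np.ndarray  # (n, 7) raw feature values (NaN where unavailable)
    normalized: np.ndarray  # (n, 7) in [0, 255]
    sal: np.ndarray  # (n,)
    orientations: np.ndarray = field(default_factory=lambda: np.empty(0))


def compute_saliency(
    protos: list[ProtoObject],
    weights: SaliencyWeights = SaliencyWeights(),
    skin_model: SkinModel = SkinModel(),
    depth_is_disparity: bool = False,
) -> SaliencyResult:
    """The full feature battery + weighted combination for one frame."""
    by_id = {p.id: p for p in protos}
    n = len(protos)
    raw = np.zeros((n, 7))
    moments = [moments_and_roundness(p.mask) for p in protos]
    phis = np.array([ms.orientation for ms, _ in moments])
    for k, p in enumerate(protos):
        ms, round_k = moments[k]
        prox = proximity(p, depth_is_disparity)
        neighbor_phis = [phis[j] for j in p.neighbors if j in by_id]
        raw[k] = [
            color_contrast(p, by_id),
            intensity_contrast(p, by_id),
            np.nan if prox is None else prox,
            round_k,
            orientation_contrast(phis[k], neighbor_phis),
            symmetry(p.mask, phis[k]),
            skin_score(p.color, skin_model),
        ]
    normalized = normalize_features(raw)
    sal = combine_saliency(normalized, weights)
    return SaliencyResult(raw=raw, normalized=normalized, sal=sal, orientations=phis)
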