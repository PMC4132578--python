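# Methods

This note records the model as implemented, the parameter choices, the
numerical conventions, and what the synthetic test bed does and does not
establish.

## Foveal geometry

A `CfgSpec` is a fovea rectangle, a ring count `m` and a ring scale `s`
(default 2). Ring `k` (1 ≤ k ≤ m) tiles the annulus between the outer
rectangles `r_{k−1}` and `r_k` with square rexels of edge `s^k` pixels; a
rexel's color is the arithmetic mean RGB of its footprint converted to HSV,
its depth the mean depth. `r_m` always equals the full frame, so pyramid
level `m` — the *waist* — is the first level encoding the whole field of
view.

So that every annulus tiles exactly, all per-side ring expansions are kept
on the `s^m` pixel grid: the frame dimensions must be divisible by `s^m`
(validated, an error otherwise), fovea corners and edge lengths are snapped
to that grid (`fit_fovea` does this for arbitrary requested fixation
centroids, moving the rectangle as little as possible), and the expansion
of each ring grows roughly geometrically (ring k takes a share ∝ `s^k` of
the remaining margin, rounded to the grid; the outermost ring absorbs the
remainder). When the fovea touches the frame border the margins there are
zero and a ring may not expand on that side; containment of successive
rings is then non-strict by necessity.

## Pyramid values and color arithmetic

Node values are HSV in cylindrical coordinates, stored as the embedding
`(S·cos H, S·sin H, V)` with S and V scaled to [0, 255]. Two properties
motivate this: the chroma chord distance
`sqrt(S_i² + S_j² − 2 S_i S_j cos θ)` is exactly the Euclidean distance of
the `(sx, sy)` parts, and pixel-count-weighted merging of children becomes
a plain weighted vector mean. The full color distance is `d = dc + |ΔV|`.
The additive chroma form `S_i + S_j + 2 S_i S_j cos θ` is available via
`dc_form: printed` but is not a metric (nonzero self-distance) and is not
used by default.

One numerical guard matters: when all children of a parent carry exactly
the same value, the parent keeps that value bit-for-bit instead of taking
the weighted float mean. Without this, 1e−16 rounding noise breaks the
fixed point of uniform regions and defeats exact-equality predicates
(τ = 0), under which segmentation must reduce to 4-connected component
labeling.

Decimation order and tie-breaks: orphans are processed in ascending node
id (raster order at creation); the closest-similar-neighbor argmin breaks
distance ties toward the lowest neighbor id. Base connectivity is
4-adjacency (8 available via configuration). Because base adjacency is
spatial, window-connectivity is equivalent to receptive-field adjacency at
every level; the builder computes each level's edge set from a per-pixel
owner map in one vectorized pass, and the literal window-propagation rule
(`link_intra_level`) is kept and cross-checked against it in the tests.
Construction stops at the first level (above the waist) whose node count
does not decrease; that level is rolled back and the previous level's
nodes are the roots.

## Segmentation parameters

| parameter | default | meaning |
|---|---|---|
| `tau_color` | 50 | color pre-segmentation threshold on the [0..255] working distance |
| `tau_percep` | 100 | grouping threshold on ϕ |
| `alpha`, `beta` | 1, 1 | Canny-edge influence in ϕ |
| `omega1`, `omega2` | 0.5, 0.5 | color vs disparity weighting in ϕ |
| `canny_low/high` | 50 / 150 | hysteresis thresholds on 8-bit luminance |

The working thresholds 50/100 are the values the segmentation figures use;
Canny hysteresis defaults follow common 8-bit practice and are
configurable. The first ϕ term as typeset is ambiguous; the default
reading is `d·b_i/(α·max(c_ij, 1))` (the floor avoids division by zero
when no Canny pixel supports the boundary), with `product` and `split`
readings selectable, and the sign of the β term configurable. ϕ is not
symmetric in `b_i`; it is always evaluated with the smaller-area region in
the role of i, which makes grouping deterministic. Grouping itself is the
same closest-similar-neighbor discipline as the pyramid: per iteration
each region may join only its ϕ-argmin neighbor and only if ϕ ≤ τ_percep,
iterated until the region count is stable — an explicit union-find
contraction of the root graph rather than a re-instantiated pyramid, which
is algorithmically equivalent and simpler to account for.

Boundary statistics: `b_i` counts pixels of region i 4-adjacent to another
label or to the frame border. Each boundary pixel is attributed to exactly
one neighboring region (the lowest differing neighbor label), which
guarantees `Σ_j b_ij ≤ b_i`; the pair lookup falls back to the opposite
attribution direction where needed. `c_ij` is the subset of the shared
boundary on or 4-adjacent to a Canny edge pixel. Canny runs on the
luminance of the re-rendered foveated frame, so peripheral edges align
with rexel boundaries by construction.

## Saliency

Raw features follow the definitions in the README; numerical conventions:

- **Moments/orientation.** Central moments are computed from mask pixel
  coordinates; a single-pixel mask has eccentricity 0 (roundness 1) and an
  isotropic mask (μ20 = μ02, μ11 = 0) orientation 0 by convention.
  Orientation is `½·atan2(2μ11, μ20 − μ02)` in (−90°, 90°]; orientation
  differences are axial (wrapped to [0°, 90°]). Note image y grows
  downward, so a shape drawn at +30° reports −30° in this convention;
  contrasts are unaffected.
- **Symmetry** is whole-region mirror-pixel counting across four axes at
  0/45/90/135° from the region's orientation, through the centroid, with
  nearest-pixel rounding of the reflected coordinates; the maximum over
  axes is taken (averaging would let asymmetric axes cancel a genuinely
  symmetric one). Equivalent to summing a scan-line symmetry count over
  all lines perpendicular to the axis. Computed on region membership, not
  gray levels.
- **Skin color.** The region's mean color is converted to TSL; the feature
  is 255 iff the Mahalanobis distance of (T, S) to the model mean is ≤
  Θ_skin (default 3.0). The shipped mean/covariance are statistics of a
  small synthetic panel of canonical skin-tone RGB values — editable
  configuration defaults, not a fitted model.
- **Normalization** is per frame: `x ↦ 255·x/max(x)` over the frame's
  proto-objects, zero column if the max is 0. When no depth channel
  exists, proximity is dropped and the remaining weights renormalized, so
  static RGB datasets remain scoreable. Per-sequence normalization was
  considered and rejected: it would couple a frame's saliency to the past.

## Attention loop

The first frame is fixated with a centered fovea (a quarter of the frame,
snapped); afterwards the fovea is the selected proto-object's bounding box
padded by 8 px and snapped to a valid CFG fovea. Working memory holds 4
entries by default (the 3–5 range of short-term visual memory), evicting
the oldest; entries optionally expire after `max_age` fixations, otherwise
they live until the tracker loses them.

Suppression: a candidate is inhibited if its bounding box has IoU ≥ 0.3
with a live entry's tracked window **or** lies mostly inside it
(intersection/candidate-area ≥ 0.7). The containment clause is needed
because foveal re-segmentation splits peripheral objects into fragments;
a fragment of an attended object has tiny IoU with the attended window yet
plainly occupies the same region. If every candidate is suppressed the
oldest entry is evicted and selection re-run. Ties in saliency go to the
larger region, then the lower id.

Tracker: target model = 16×4×4-bin joint HSV histogram of the object's
own pixels (the proto-object mask restricts the kernel — keeping
background out of the model is what gives mean-shift its pull), weighted
by an Epanechnikov kernel over the window; candidate weights
`sqrt(q_u/p_u)`; the window moves to the weighted mean position until the
realized integer window displacement is < 1 px or 20 iterations. The
reported centroid is the final sub-pixel mean-shift location (the integer
window alone would quantize a systematic half-pixel-to-one-pixel lag).
A final Bhattacharyya coefficient < 0.5 marks the entry dead.

## Evaluation

Model fixation density maps are sums of attended proto-object masks
(optionally Gaussian-blurred). Shuffled AUC uses the rank-sum formulation
with midrank ties — equivalent to sweeping thresholds over map values and
invariant under monotone transforms; negatives are fixations on the other
images of the set, which cancels center bias. Scan-path similarity is
Smith–Waterman local alignment with match reward `max(0, 1 − dist/diag)`
and gap penalty −1/2; scores are comparable in protocol, not in absolute
value, to other alignment-based similarity indices, since the reward
scaling is ours.

## Synthetic scenes: what they do and do not show

The generator renders hard-edged geometric shapes (disc, rectangle,
ellipse, bar, L-polyomino) over flat, gradient or seeded block-noise
backgrounds, with per-shape depth and optional per-frame translation, and
emits exact label maps — byte-identical for identical (spec, seed). This
gives exact ground truth for partitions, shape moments, steering, IOR and
tracking. It does **not** emulate natural-image statistics: no texture
gradients, shading, occlusion ambiguity, sensor noise or soft edges.
Passing tests therefore establish the correctness of the machinery and
its qualitative behaviors (coverage, steering, center-bias cancellation),
not fixation-prediction accuracy on natural photographs, which requires
eye-tracking datasets outside this package's scope.

Problem sizes used by the test-suite and acceptance script — 64×64 to
96×96 scenes, 16×16 foveae with two rings, 30–50 scenes per property,
2000+2000 points for the exchangeable-AUC check, 20-frame tracking at
3 px/frame — were chosen as the smallest sizes at which every property is
measured well away from its discretization floor.

## Known limitations

- Ring tiling requires frame dimensions divisible by `ring_scale^m`;
  arbitrary frames need cropping/padding or a smaller `m`.
- Asymmetric per-side subdivision factors of the adaptive geometry are not
  exposed; only the symmetric ring scale is.
- `PROX` uses 1/mean(depth) rather than mean(1/depth); for thin depth
  distributions the difference is negligible.
- Proto-object ids are per-frame; cross-frame identity exists only through
  working-memory tracking.
- The grouping contraction is greedy; raising τ_percep is monotone on the
  fixtures tested but is not a proven invariant for adversarial inputs.
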