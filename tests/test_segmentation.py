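import numpy as np
import pytest

from foveal_attention import (
    GroupingParams,
    boundary_stats,
    canny_edges,
    perceptual_group,
    phi_distance,
    presegment,
    segment_foveal_image,
)
from foveal_attention.color import ColorValue, hsv_distance
from foveal_attention.segmentation import (
    NotNeighborsError,
    ProtoObject,
    color_similar,
)

from conftest import centered_foveal, full_fovea, labels_equivalent, random_mosaic


# ---------------------------------------------------------------------------
# HSV distance (Eqs. of the cylindrical color metric)
# ---------------------------------------------------------------------------

class TestHsvDistance:
    def test_identity_is_zero(self):
        c = ColorValue(200.0, 0.7, 0.4)
        assert hsv_distance(c, c) == 0.0

    def test_value_difference_only(self):
        a, b = ColorValue(90.0, 0.5, 0.2), ColorValue(90.0, 0.5, 0.9)
        assert hsv_distance(a, b) == pytest.approx(0.7)

    def test_opposite_hues_full_saturation(self):
        # chord form: sqrt(1 + 1 - 2 cos 180°) = 2
        a, b = ColorValue(0.0, 1.0, 0.5), ColorValue(180.0, 1.0, 0.5)
        assert hsv_distance(a, b) == pytest.approx(2.0)

    def test_symmetry(self):
        a, b = ColorValue(10.0, 0.3, 0.8), ColorValue(300.0, 0.9, 0.1)
        assert hsv_distance(a, b) == pytest.approx(hsv_distance(b, a))

    def test_printed_form_violates_identity(self):
        c = ColorValue(120.0, 0.5, 0.5)
        assert hsv_distance(c, c, form="printed") > 0

    def test_threshold_is_inclusive(self):
        a = ColorValue(0.0, 0.0, 0.0)
        b = ColorValue(0.0, 0.0, 100.0 / 255.0)  # working distance exactly 100
        assert color_similar(a.embedding(), b.embedding(), 100.0)
        assert not color_similar(a.embedding(), b.embedding(), 99.9)


# ---------------------------------------------------------------------------
# pre-segmentation
# ---------------------------------------------------------------------------

class TestPresegment:
    def test_uniform_image_one_blob(self):
        img = np.full((32, 32, 3), 90, dtype=np.uint8)
        _, labels = presegment(full_fovea(img))
        assert labels.max() == 0

    def test_two_tone_image_two_blobs(self):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        img[:, :16] = (255, 0, 0)
        img[:, 16:] = (0, 255, 0)
        _, labels = presegment(full_fovea(img))
        assert labels.max() == 1

    def test_mosaic_equals_connected_components(self):
        from test_pyramid import connected_components_by_color

        rng = np.random.default_rng(11)
        img = random_mosaic(rng, size=32, n_colors=3, blocks=8)
        _, labels = presegment(full_fovea(img), GroupingParams(tau_color=1e-9))
        assert labels_equivalent(labels, connected_components_by_color(img))


# ---------------------------------------------------------------------------
# Canny edges
# ---------------------------------------------------------------------------

class TestCanny:
    def test_constant_image_no_edges(self):
        img = np.full((32, 32, 3), 77, dtype=np.uint8)
        assert not canny_edges(img).any()

    def test_step_edge_contour(self):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        img[:, 16:] = 200
        edges = canny_edges(img)
        cols = np.nonzero(edges.any(axis=0))[0]
        assert len(cols) > 0 and set(cols) <= {15, 16}

    def test_disc_edge_count_near_circumference(self):
        from foveal_attention.scenes import SceneSpec, ShapeSpec, make_scene

        r = 20
        spec = SceneSpec(
            size=(96, 96),
            shapes=(ShapeSpec("disc", (0.0, 0.0, 0.9), (48, 48), r),),
        )
        img, _, _ = make_scene(spec)
        count = int(canny_edges(img).sum())
        assert count == pytest.approx(2 * np.pi * r, rel=0.15)


# ---------------------------------------------------------------------------
# boundary statistics
# ---------------------------------------------------------------------------

def brute_force_boundary(labels, edges=None):
    """Per-pixel oracle mirroring the one-neighbor attribution rule."""
    h, w = labels.shape
    b = {int(i): 0 for i in np.unique(labels)}
    pairs = {}
    if edges is None:
        edges = np.zeros((h, w), bool)
    near = np.zeros((h, w), bool)
    for y in range(h):
        for x in range(w):
            if edges[y, x]:
                for dy, dx in ((0, 0), (0, 1), (0, -1), (1, 0), (-1, 0)):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w:
                        near[yy, xx] = True
    for y in range(h):
        for x in range(w):
            me = int(labels[y, x])
            neigh = []
            border = False
            for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    if labels[yy, xx] != me:
                        neigh.append(int(labels[yy, xx]))
                else:
                    border = True
            if neigh or border:
                b[me] += 1
            if neigh:
                j = min(neigh)
                bij, cij = pairs.get((me, j), (0, 0))
                pairs[(me, j)] = (bij + 1, cij + (1 if near[y, x] else 0))
    return b, pairs


class TestBoundaryStats:
    def test_half_plane_split(self):
        labels = np.zeros((10, 8), dtype=int)
        labels[:, 4:] = 1
        b, pairs = boundary_stats(labels)
        assert pairs[(0, 1)][0] == 10 and pairs[(1, 0)][0] == 10
        labels_v = np.zeros((6, 8), dtype=int)
        labels_v[3:, :] = 1
        _, pairs_v = boundary_stats(labels_v)
        assert pairs_v[(0, 1)][0] == 8 and pairs_v[(1, 0)][0] == 8

    def test_no_edges_means_zero_canny_overlap(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, size=(12, 12))
        _, pairs = boundary_stats(labels, edges=np.zeros((12, 12), bool))
        assert all(c == 0 for _, c in pairs.values())

    def test_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 3, size=(16, 16))
        edges = rng.random((16, 16)) < 0.2
        b, pairs = boundary_stats(labels, edges)
        ob, opairs = brute_force_boundary(labels, edges)
        assert b == ob
        assert pairs == opairs

    def test_pair_sums_bounded_by_perimeter(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 4, size=(20, 20))
        b, pairs = boundary_stats(labels)
        for i in np.unique(labels):
            total = sum(v[0] for (a, j), v in pairs.items() if a == i)
            assert total <= b[int(i)]


# ---------------------------------------------------------------------------
# phi distance
# ---------------------------------------------------------------------------

def make_proto(pid, area, emb, depth, b, neighbors, mask=None):
    if mask is None:
        mask = np.zeros((4, 4), bool)
        mask[0, :2] = True
    return ProtoObject(
        id=pid,
        mask=mask,
        area=area,
        centroid=(0.0, 0.0),
        embedding=np.asarray(emb, float),
        depth=depth,
        b=b,
        neighbors=neighbors,
    )


class TestPhiDistance:
    def test_identical_regions_zero(self):
        e = [10.0, 5.0, 100.0]
        i = make_proto(0, 10, e, 3.0, 20, {1: (20, 20)})
        j = make_proto(1, 20, e, 3.0, 20, {0: (20, 20)})
        assert phi_distance(i, j) == 0.0

    def test_disparity_only(self):
        p = GroupingParams(omega1=0.0, omega2=1.0, depth_is_disparity=True)
        i = make_proto(0, 10, [0, 0, 0], 10.0, 20, {1: (20, 20)})
        j = make_proto(1, 20, [0, 0, 0], 4.0, 20, {0: (20, 20)})
        assert phi_distance(i, j, p) == pytest.approx(36.0)

    def test_worked_example_default_reading(self):
        # d = 10, b_i = 40, c_ij = b_ij = 20, alpha=1, beta=0 -> (10·40/20)² = 400
        p = GroupingParams(alpha=1.0, beta=0.0, omega1=1.0, omega2=0.0)
        i = make_proto(0, 10, [0, 0, 0], None, 40, {1: (20, 20)})
        j = make_proto(1, 20, [0, 0, 10.0], None, 60, {0: (20, 20)})
        assert phi_distance(i, j, p) == pytest.approx(400.0)

    def test_not_neighbors_raises(self):
        i = make_proto(0, 10, [0, 0, 0], None, 10, {})
        j = make_proto(1, 20, [0, 0, 0], None, 10, {})
        with pytest.raises(NotNeighborsError):
            phi_distance(i, j)

    def test_smaller_area_takes_role_of_i(self):
        p = GroupingParams(alpha=1.0, beta=0.0, omega1=1.0, omega2=0.0)
        i = make_proto(0, 10, [0, 0, 0], None, 40, {1: (20, 20)})
        j = make_proto(1, 99, [0, 0, 10.0], None, 1000, {0: (20, 20)})
        assert phi_distance(i, j, p) == phi_distance(j, i, p) == pytest.approx(400.0)


# ---------------------------------------------------------------------------
# perceptual grouping
# ---------------------------------------------------------------------------

class TestPerceptualGroup:
    def _blob_inputs(self, labels, colors, depths=None):
        k = labels.max() + 1
        values = np.asarray(colors, float)
        npix = np.array([(labels == i).sum() for i in range(k)], float)
        return labels, values, npix, depths

    def test_dissimilar_blobs_are_fixed_point(self):
        labels = np.zeros((8, 8), int)
        labels[:, 4:] = 1
        args = self._blob_inputs(labels, [[0, 0, 0], [0, 0, 255]])
        out, protos = perceptual_group(
            *args, edges=np.zeros((8, 8), bool), params=GroupingParams(tau_percep=10)
        )
        assert len(protos) == 2 and labels_equivalent(out, labels)

    def test_same_color_blobs_merge_without_edge(self):
        labels = np.zeros((8, 8), int)
        labels[:, 4:] = 1
        args = self._blob_inputs(labels, [[0, 0, 100.0], [0, 0, 100.0]])
        out, protos = perceptual_group(
            *args,
            edges=np.zeros((8, 8), bool),
            params=GroupingParams(beta=0.0, tau_percep=100.0),
        )
        assert len(protos) == 1

    def test_infinite_threshold_merges_connected_image(self):
        rng = np.random.default_rng(3)
        labels = np.repeat(np.arange(4), 16).reshape(8, 8)
        colors = rng.uniform(0, 255, size=(4, 3))
        args = self._blob_inputs(labels, colors)
        out, protos = perceptual_group(
            *args,
            edges=np.zeros((8, 8), bool),
            params=GroupingParams(tau_percep=np.inf),
        )
        assert len(protos) == 1

    def test_depth_invariance_when_omega2_zero(self):
        labels = np.zeros((8, 8), int)
        labels[:, 4:] = 1
        colors = [[0, 0, 100.0], [0, 0, 140.0]]
        p = GroupingParams(beta=0.0, omega1=1.0, omega2=0.0, tau_percep=1e9)
        outs = []
        for depths in (np.array([1.0, 1.0]), np.array([1.0, 9.0])):
            args = self._blob_inputs(labels, colors, depths)
            out, _ = perceptual_group(*args, edges=np.zeros((8, 8), bool), params=p)
            outs.append(out)
        assert np.array_equal(outs[0], outs[1])

    def test_raising_threshold_never_splits(self):
        rng = np.random.default_rng(4)
        labels = np.repeat(rng.integers(0, 5, size=(4, 4)), 2, 0).repeat(2, 1)
        # compact labels
        _, labels = np.unique(labels, return_inverse=True)
        labels = labels.reshape(8, 8)
        colors = rng.uniform(0, 255, (labels.max() + 1, 3))
        edges = np.zeros((8, 8), bool)
        counts = []
        for tau in (10.0, 1e3, 1e5, np.inf):
            args = self._blob_inputs(labels, colors)
            _, protos = perceptual_group(
                *args, edges=edges, params=GroupingParams(tau_percep=tau)
            )
            counts.append(len(protos))
        assert counts == sorted(counts, reverse=True)


class TestFullSegmentation:
    def test_masks_partition_image(self, two_object_scene):
        img, depth, _ = two_object_scene
        seg = segment_foveal_image(centered_foveal(img, 2, 16, depth=depth))
        total = np.zeros(img.shape[:2], int)
        for p in seg.protos:
            total += p.mask
        assert (total == 1).all()
        assert sum(p.area for p in seg.protos) == img.shape[0] * img.shape[1]

    def test_neighbor_stats_consistent(self, two_object_scene):
        img, depth, _ = two_object_scene
        seg = segment_foveal_image(centered_foveal(img, 2, 16, depth=depth))
        for p in seg.protos:
            assert sum(bij for bij, _ in p.neighbors.values()) <= p.b
            for j, (bij, cij) in p.neighbors.items():
                assert cij <= bij
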