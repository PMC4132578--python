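import numpy as np
import pytest

from foveal_attention import CfgSpec, Rect, build_cfg, fit_fovea
from foveal_attention.scenes import SceneSpec, ShapeSpec, make_scene


@pytest.fixture
def two_object_scene():
    """Red disc (near) and green rectangle (far) on a flat background."""
    spec = SceneSpec(
        size=(64, 64),
        shapes=(
            ShapeSpec("disc", (0.0, 1.0, 1.0), (20, 20), 8, depth=2.0),
            ShapeSpec("rectangle", (120.0, 1.0, 0.9), (46, 44), (14, 10), depth=6.0),
        ),
        seed=1,
    )
    return make_scene(spec)


@pytest.fixture
def three_object_scene():
    """Three well-separated colored shapes for IOR coverage tests."""
    spec = SceneSpec(
        size=(96, 96),
        shapes=(
            ShapeSpec("disc", (0.0, 1.0, 1.0), (20, 20), 9, depth=3.0),
            ShapeSpec("rectangle", (120.0, 1.0, 0.9), (72, 24), (16, 14), depth=4.0),
            ShapeSpec("ellipse", (240.0, 1.0, 0.9), (48, 74), (11, 7), depth=5.0),
        ),
        seed=2,
    )
    return make_scene(spec)


@pytest.fixture
def steering_scene():
    """Near muted disc vs far high-contrast rectangle (depth steering).

    With equal feature weights the far rectangle's strong color contrast
    wins; with the proximity weight raised to 0.5 (rest 0.5/6) the nearer
    disc wins.
    """
    spec = SceneSpec(
        size=(96, 96),
        shapes=(
            ShapeSpec("disc", (220.0, 0.5, 0.8), (28, 64), 10, depth=1.5),
            ShapeSpec("rectangle", (0.0, 1.0, 1.0), (66, 28), (20, 16), depth=8.0),
        ),
        seed=3,
    )
    return make_scene(spec)


def random_mosaic(rng, size=32, n_colors=3, blocks=4):
    """Blocky random color field (exact colors, no noise)."""
    palette = np.array(
        [[255, 0, 0], [0, 160, 0], [0, 64, 255], [255, 255, 0], [160, 0, 160]],
        dtype=np.uint8,
    )[:n_colors]
    coarse = rng.integers(0, n_colors, size=(size // blocks, size // blocks))
    idx = np.repeat(np.repeat(coarse, blocks, axis=0), blocks, axis=1)
    return palette[idx]


def centered_foveal(image, num_rings=2, fovea=16, depth=None):
    h, w = image.shape[:2]
    rect = fit_fovea((w, h), (w / 2, h / 2), (fovea, fovea), num_rings)
    spec = CfgSpec((w, h), rect, num_rings=num_rings)
    return build_cfg(image, spec, depth=depth)


def full_fovea(image, depth=None):
    """Degenerate CFG: no rings, fovea covers the whole image."""
    h, w = image.shape[:2]
    spec = CfgSpec((w, h), Rect(0, 0, w, h), num_rings=0)
    return build_cfg(image, spec, depth=depth)


def labels_equivalent(a, b):
    """True iff two label maps define the same partition (up to relabeling)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    pairs = np.stack([a.ravel(), b.ravel()], axis=1)
    uniq = np.unique(pairs, axis=0)
    return (
        len(np.unique(uniq[:, 0])) == len(uniq) == len(np.unique(uniq[:, 1]))
    )
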