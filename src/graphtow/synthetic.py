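"""Synthetic fixtures: test images, colored point clouds, feature blobs.

Every generator is a pure function of its :class:`FixtureConfig` - the seed
is mandatory and repeated calls are bit-identical. The fixtures emulate the
kinds of data the solvers target: piecewise-constant and textured images
with missing regions (inpainting), colored geometric point clouds with
scribbles (colorization/segmentation), and multi-class Gaussian feature
clouds emulating a cytology-style morphology table (about ten descriptors
per cell, four classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.datasets import make_blobs

__all__ = [
    "FixtureConfig",
    "generate_test_image",
    "generate_blob_features",
    "generate_point_cloud",
]

IMAGE_KINDS = ("ramp_image", "two_tone_image", "textured_image", "holed_image")


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of a synthetic fixture; ``seed`` is mandatory.

    ``separation`` is the ratio of inter-centroid distance to within-class
    standard deviation for ``blob_features``. ``hole`` is the side of the
    centred square of removed pixels for ``holed_image``.
    """

    kind: str = "holed_image"
    seed: int = 0
    height: int = 24
    width: int = 24
    noise: float = 0.0
    hole: int = 8
    n_samples: int = 400
    n_features: int = 10
    n_classes: int = 4
    separation: float = 6.0
    n_points: int = 300

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _base_image(cfg: FixtureConfig, rng: np.random.Generator) -> np.ndarray:
    H, W = cfg.height, cfg.width
    if cfg.kind == "ramp_image":
        img = np.tile(np.linspace(0.0, 1.0, W), (H, 1))
    elif cfg.kind in ("two_tone_image", "holed_image"):
        img = np.full((H, W), 0.2)
        img[:, W // 2:] = 0.8
    elif cfg.kind == "textured_image":
        rr, cc = np.mgrid[0:H, 0:W]
        img = 0.5 + 0.25 * np.sin(2 * np.pi * rr / 6) * np.cos(2 * np.pi * cc / 6)
    else:
        raise ValueError(f"unknown image kind: {cfg.kind!r}")
    if cfg.noise > 0:
        img = np.clip(img + cfg.noise * rng.standard_normal(img.shape), 0.0, 1.0)
    return img


def generate_test_image(cfg: FixtureConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(image, mask, ground_truth); mask marks removed pixels.

    For ``holed_image`` a ``hole`` x ``hole`` square is zeroed out, centred
    in the left tone (vertically centred), so the missing region's boundary
    carries a single tone; the ground truth is the complete image. For the
    other kinds the mask is empty and truth equals the image.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = _base_image(cfg, rng)
    mask = np.zeros(truth.shape, dtype=bool)
    if cfg.kind == "holed_image":
        if cfg.hole >= min(cfg.height, cfg.width // 2):
            raise ValueError("hole larger than the left tone")
        r0 = (cfg.height - cfg.hole) // 2
        c0 = (cfg.width // 2 - cfg.hole) // 2
        mask[r0:r0 + cfg.hole, c0:c0 + cfg.hole] = True
    image = truth.copy()
    image[mask] = 0.0
    return image, mask, truth


def generate_blob_features(cfg: FixtureConfig) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian classes at the configured separation.

    Unit within-class standard deviation; random unit-sphere centroids are
    rescaled so the *minimum* pairwise centroid distance equals
    ``separation``. Returns (features, labels).
    """
    rng = np.random.default_rng(cfg.seed)
    c, d = cfg.n_classes, cfg.n_features
    if c == 1:
        centers = np.zeros((1, d))
    else:
        centers = rng.standard_normal((c, d))
        dists = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        min_d = dists[np.triu_indices(c, 1)].min()
        centers *= cfg.separation / min_d
    X, y = make_blobs(n_samples=cfg.n_samples, centers=centers, cluster_std=1.0,
                      random_state=np.random.RandomState(cfg.seed))
    return X, y


def generate_point_cloud(cfg: FixtureConfig):
    """Plane patch + well-separated sphere, one colour scribble each.

    Returns ``(xyz, rgb, seed_vertices, seed_colors, primitive_labels)``;
    the scribbles are 5 random vertices per primitive carrying its colour.
    """
    rng = np.random.default_rng(cfg.seed)
    n_half = cfg.n_points // 2
    plane = np.c_[rng.uniform(-1, 1, (n_half, 2)), np.zeros(n_half)]
    dirs = rng.standard_normal((cfg.n_points - n_half, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    sphere = dirs * 0.8 + np.array([6.0, 0.0, 2.0])  # far from the plane
    xyz = np.vstack([plane, sphere])
    labels = np.r_[np.zeros(n_half, int), np.ones(cfg.n_points - n_half, int)]
    palette = np.array([[0.9, 0.2, 0.1], [0.1, 0.4, 0.9]])
    rgb = palette[labels]
    if cfg.noise > 0:
        xyz = xyz + cfg.noise * rng.standard_normal(xyz.shape)
    seed_vertices = np.concatenate([
        rng.choice(np.flatnonzero(labels == l), size=min(5, (labels == l).sum()),
                   replace=False)
        for l in (0, 1)
    ])
    seed_colors = palette[labels[seed_vertices]]
    return xyz, rgb, seed_vertices, seed_colors, labels
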