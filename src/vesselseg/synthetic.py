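"""Synthetic fundus-style image/mask pairs.

Real retinal photographs show dark, bifurcating vessels of decreasing
calibre on a bright, unevenly illuminated background with sensor noise.
This module grows random binary vessel trees as width-decaying polyline
strokes, rasterises them with soft (anti-aliased) edges, and composes
them with a smooth illumination field plus Gaussian noise, so that every
downstream stage (preprocessing, augmentation, training, evaluation) can
be exercised without any external dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["VesselSimConfig", "ImageSample", "generate_sample", "generate_dataset"]


@dataclass(frozen=True)
class VesselSimConfig:
    """Parameters of the synthetic vascular-tree generator.

    Attributes
    ----------
    image_size : (H, W) in pixels, each >= 32.
    n_trees : number of root vessels grown from the image border.
    branch_depth : maximum recursion level; each level bifurcates once.
    root_width_px : half-width of a root vessel in pixels.
    width_decay : multiplicative half-width factor per branch level, in (0, 1).
    branch_angle_deg : mean absolute deviation of a child's direction from
        its parent's, in degrees.
    vessel_contrast : fractional intensity drop of vessel pixels relative
        to the local background, in (0, 1].
    illumination_gradient : peak-to-trough variation of the smooth
        background field on the [0, 1] intensity scale.
    noise_sigma : standard deviation of additive Gaussian sensor noise.
    seed : base RNG seed; combined with the sample index so that every
        sample is individually reproducible.
    """

    image_size: tuple[int, int] = (128, 128)
    n_trees: int = 3
    branch_depth: int = 4
    root_width_px: float = 3.0
    width_decay: float = 0.7
    branch_angle_deg: float = 35.0
    vessel_contrast: float = 0.35
    illumination_gradient: float = 0.25
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError(f"image_size must be at least (32, 32), got {self.image_size}")
        if not (0.0 < self.width_decay < 1.0):
            raise ValueError(f"width_decay must be in (0, 1), got {self.width_decay}")
        if not (0.0 < self.vessel_contrast <= 1.0):
            raise ValueError(f"vessel_contrast must be in (0, 1], got {self.vessel_contrast}")
        if self.root_width_px <= 0:
            raise ValueError(f"root_width_px must be positive, got {self.root_width_px}")
        if self.n_trees < 0 or self.branch_depth < 0:
            raise ValueError("n_trees and branch_depth must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be non-negative, got {self.noise_sigma}")
        if not (0.0 <= self.illumination_gradient <= 1.0):
            raise ValueError("illumination_gradient must lie in [0, 1]")


@dataclass
class ImageSample:
    """An image, its binary vessel mask, and an optional field-of-view ROI.

    ``image`` is a 2-D grayscale or H x W x 3 RGB float array on [0, 1];
    ``mask`` is a 2-D {0, 1} array of the same height/width, 1 = vessel.
    When ``roi`` is present it marks the informative region and the mask
    is contained in it.
    """

    image: np.ndarray
    mask: np.ndarray
    sample_id: str
    roi: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} disagree in shape"
            )
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary (values in {0, 1})")
        if self.roi is not None:
            if self.roi.shape != self.mask.shape:
                raise ValueError("roi shape must match mask shape")
            if ((self.mask == 1) & (self.roi == 0)).any():
                raise ValueError("mask must be contained in roi")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _segment_coverage(canvas: np.ndarray, p0: np.ndarray, p1: np.ndarray, half_width: float) -> None:
    """Accumulate soft coverage of a thick segment (capsule) into ``canvas``.

    Coverage at a pixel is clip(half_width + 0.5 - distance_to_segment, 0, 1),
    i.e. a 1-pixel anti-aliased edge around the stroke.
    """
    h, w = canvas.shape
    pad = half_width + 1.5
    r0 = max(int(np.floor(min(p0[0], p1[0]) - pad)), 0)
    r1 = min(int(np.ceil(max(p0[0], p1[0]) + pad)) + 1, h)
    c0 = max(int(np.floor(min(p0[1], p1[1]) - pad)), 0)
    c1 = min(int(np.ceil(max(p0[1], p1[1]) + pad)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1, dtype=float), np.arange(c0, c1, dtype=float), indexing="ij")
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0.0:
        dist = np.hypot(rr - p0[0], cc - p0[1])
    else:
        t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / len2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))
    cov = np.clip(half_width + 0.5 - dist, 0.0, 1.0)
    np.maximum(canvas[r0:r1, c0:c1], cov, out=canvas[r0:r1, c0:c1])


def _grow_branch(
    canvas: np.ndarray,
    pos: np.ndarray,
    angle: float,
    half_width: float,
    level: int,
    config: VesselSimConfig,
    node_key: tuple[int, ...],
    index: int,
) -> None:
    """Recursively grow one branch and its two children.

    Each tree node draws its randomness from an RNG keyed by the node's
    position in the tree, so raising ``branch_depth`` extends existing
    trees instead of reshuffling them: the depth-d mask is a subset of
    the depth-(d+1) mask for the same seed.
    """
    if level >= config.branch_depth or half_width < 0.3:
        return
    rng = np.random.default_rng((config.seed, index, 977, *node_key))
    h, w = canvas.shape
    scale = min(h, w)
    seg_len = scale * float(rng.uniform(0.12, 0.22)) * (0.85 ** level)
    n_steps = 3
    p = pos.copy()
    a = angle
    for _ in range(n_steps):
        a += float(rng.normal(0.0, np.deg2rad(6.0)))  # gentle curvature jitter
        q = p + (seg_len / n_steps) * np.array([np.sin(a), np.cos(a)])
        _segment_coverage(canvas, p, q, half_width)
        p = q
    if not (-0.2 * h <= p[0] <= 1.2 * h and -0.2 * w <= p[1] <= 1.2 * w):
        return  # wandered far outside the frame; children would be invisible
    spread = np.deg2rad(config.branch_angle_deg)
    for child, sign in enumerate((-1.0, 1.0)):
        da = sign * abs(float(rng.normal(spread, spread / 3.0)))
        _grow_branch(
            canvas, p, a + da, half_width * config.width_decay,
            level + 1, config, node_key + (child,), index,
        )


def _vessel_coverage(config: VesselSimConfig, index: int) -> np.ndarray:
    """Soft [0, 1] vessel coverage map for sample ``index``."""
    h, w = config.image_size
    canvas = np.zeros((h, w), dtype=np.float64)
    for tree in range(config.n_trees):
        rng = np.random.default_rng((config.seed, index, 131, tree))
        side = int(rng.integers(0, 4))
        u = float(rng.uniform(0.15, 0.85))
        if side == 0:  # top
            pos, angle = np.array([0.0, u * w]), 0.0
        elif side == 1:  # bottom
            pos, angle = np.array([h - 1.0, u * w]), np.pi
        elif side == 2:  # left
            pos, angle = np.array([u * h, 0.0]), np.pi / 2
        else:  # right
            pos, angle = np.array([u * h, w - 1.0]), -np.pi / 2
        angle += float(rng.uniform(-0.4, 0.4))
        _grow_branch(canvas, pos, angle, config.root_width_px, 0, config, (tree,), index)
    return canvas


def _background(config: VesselSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency illumination field spanning illumination_gradient."""
    h, w = config.image_size
    rr, cc = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w), indexing="ij")
    theta = float(rng.uniform(0, 2 * np.pi))
    lin = rr * np.sin(theta) + cc * np.cos(theta)
    center = rng.uniform(-0.5, 0.5, size=2)
    radial = np.hypot(rr - center[0], cc - center[1])
    mix = float(rng.uniform(0.3, 0.7))
    fld = mix * lin + (1.0 - mix) * (1.0 - radial)
    lo, hi = fld.min(), fld.max()
    if hi > lo:
        fld = (fld - lo) / (hi - lo) - 0.5
    else:
        fld = np.zeros_like(fld)
    return 0.7 + config.illumination_gradient * fld


def generate_sample(config: VesselSimConfig, index: int) -> ImageSample:
    """Generate the ``index``-th synthetic sample under ``config``.

    Deterministic: the pair (config.seed, index) fully determines the
    output. The mask is the soft coverage map thresholded at 0.5, which
    keeps mask and image geometrically aligned.
    """
    if index < 0:
        raise ValueError(f"index must be non-negative, got {index}")
    coverage = _vessel_coverage(config, index)
    rng = np.random.default_rng((config.seed, index, 547))
    bg = _background(config, rng)
    image = bg - config.vessel_contrast * bg * coverage
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    mask = (coverage >= 0.5).astype(np.uint8)
    return ImageSample(image=image, mask=mask, sample_id=f"synth_{index:04d}")


def generate_dataset(
    config: VesselSimConfig,
    n: int,
    out_dir: str | Path,
    split: str = "train",
    index_offset: int = 0,
):
    """Write ``n`` samples as 8-bit PNGs plus a JSON manifest; return the manifest.

    ``index_offset`` shifts the sample indices so that disjoint train and
    test sets can be drawn from one seeded stream.
    """
    from . import io_formats

    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    mask_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n):
        sample = generate_sample(config, index_offset + i)
        image_path = img_dir / f"{sample.sample_id}.png"
        mask_path = mask_dir / f"{sample.sample_id}_mask.png"
        io_formats.write_image(image_path, sample.image)
        io_formats.write_mask(mask_path, sample.mask)
        entries.append(
            io_formats.ManifestEntry(
                sample_id=sample.sample_id,
                image_path=str(image_path.relative_to(out_dir)),
                mask_path=str(mask_path.relative_to(out_dir)),
                roi_path=None,
                split=split,
            )
        )
    manifest = io_formats.DatasetManifest(entries=entries, root=out_dir)
    io_formats.save_manifest(manifest, out_dir / "manifest.json")
    return manifest
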