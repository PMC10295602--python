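"""Geometric training-set augmentation.

A training set of a few dozen annotated images is expanded to a fixed
target size (e.g. 20 sources -> 2000 images) with random rotations,
translations and horizontal/vertical flips. The same geometric
transform is applied to the image (bilinear interpolation), and to the
mask and ROI (nearest-neighbour, so labels stay binary); regions moved
in from outside the frame are filled with background (0). The expanded
set is materialised on disk so that a dataset size is a reproducible
artifact rather than a property of a sampling loop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .synthetic import ImageSample

__all__ = [
    "AugmentConfig",
    "TransformParams",
    "random_transform_params",
    "apply_transform",
    "augment_to_count",
    "augment_dataset",
]


@dataclass(frozen=True)
class AugmentConfig:
    """target_count includes the untransformed originals; rotations are
    uniform on [-rotation_range_deg, +rotation_range_deg]; shifts are
    uniform fractions of the image side, up to shift_fraction."""

    target_count: int
    rotation_range_deg: float = 30.0
    shift_fraction: float = 0.1
    allow_hflip: bool = True
    allow_vflip: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rotation_range_deg <= 180.0):
            raise ValueError(f"rotation_range_deg must be in [0, 180], got {self.rotation_range_deg}")
        if not (0.0 <= self.shift_fraction <= 0.5):
            raise ValueError(f"shift_fraction must be in [0, 0.5], got {self.shift_fraction}")
        if self.target_count < 1:
            raise ValueError("target_count must be positive")


@dataclass(frozen=True)
class TransformParams:
    angle_deg: float
    dy: float  # row shift in pixels
    dx: float  # column shift in pixels
    hflip: bool
    vflip: bool

    @property
    def is_identity(self) -> bool:
        return (
            self.angle_deg == 0.0 and self.dy == 0.0 and self.dx == 0.0
            and not self.hflip and not self.vflip
        )


def random_transform_params(
    rng: np.random.Generator, config: AugmentConfig, side: float
) -> TransformParams:
    """Draw one transform: angle ~ U(-r, r), shifts ~ U(-s, s) * side,
    flips ~ Bernoulli(1/2) where allowed."""
    r = config.rotation_range_deg
    s = config.shift_fraction * side
    return TransformParams(
        angle_deg=float(rng.uniform(-r, r)),
        dy=float(rng.uniform(-s, s)),
        dx=float(rng.uniform(-s, s)),
        hflip=bool(rng.random() < 0.5) if config.allow_hflip else False,
        vflip=bool(rng.random() < 0.5) if config.allow_vflip else False,
    )


def _warp(arr: np.ndarray, params: TransformParams, order: int) -> np.ndarray:
    """Flip, then rotate about the image centre and translate.

    Implemented as the inverse affine map in index coordinates:
    in = R(-theta) @ (out - centre - t) + centre, with fill value 0.
    A 180-degree rotation reduces to an exact index reversal, so the
    transform is an exact involution there regardless of ``order``.
    """
    if params.hflip:
        arr = arr[:, ::-1]
    if params.vflip:
        arr = arr[::-1, :]
    if params.angle_deg == 0.0 and params.dy == 0.0 and params.dx == 0.0:
        return np.ascontiguousarray(arr)
    h, w = arr.shape[:2]
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    theta = np.deg2rad(params.angle_deg)
    rot_inv = np.array([[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]])
    # snap float noise at multiples of 90 degrees (sin(pi) ~ 1e-16) so that
    # e.g. a 180-degree rotation is an exact index reversal, not a resampling
    rot_inv[np.abs(rot_inv) < 1e-12] = 0.0
    rot_inv[np.abs(rot_inv - 1.0) < 1e-12] = 1.0
    rot_inv[np.abs(rot_inv + 1.0) < 1e-12] = -1.0
    offset = centre - rot_inv @ (centre + np.array([params.dy, params.dx]))

    def warp_plane(plane: np.ndarray) -> np.ndarray:
        return ndimage.affine_transform(
            plane.astype(np.float64), rot_inv, offset=offset, order=order,
            mode="constant", cval=0.0, prefilter=False,
        )

    if arr.ndim == 3:
        return np.stack([warp_plane(arr[:, :, c]) for c in range(arr.shape[2])], axis=2)
    return warp_plane(arr)


def apply_transform(sample: ImageSample, params: TransformParams) -> ImageSample:
    """Apply one transform identically to image, mask and ROI."""
    if params.is_identity:
        return sample
    image = np.clip(_warp(sample.image, params, order=1), 0.0, 1.0)
    mask = _warp(sample.mask, params, order=0).astype(np.uint8)
    roi = _warp(sample.roi, params, order=0).astype(np.uint8) if sample.roi is not None else None
    if roi is not None:
        mask &= roi
    return ImageSample(image=image, mask=mask, roi=roi, sample_id=sample.sample_id)


def augment_to_count(samples: Sequence[ImageSample], config: AugmentConfig) -> list[ImageSample]:
    """Return exactly ``target_count`` samples: every original plus
    transformed copies drawn by cycling the source list with fresh
    random parameters. Replica ids record their provenance."""
    if not samples:
        raise ValueError("source sample list is empty")
    n = len(samples)
    if config.target_count < n:
        raise ValueError(f"target_count {config.target_count} < number of sources {n}")
    rng = np.random.default_rng(config.seed)
    out = list(samples)
    for k in range(config.target_count - n):
        src = samples[k % n]
        side = min(src.shape)
        params = random_transform_params(rng, config, side)
        aug = apply_transform(src, params)
        out.append(replace(aug, sample_id=f"{src.sample_id}~aug{k:05d}"))
    return out


def augment_dataset(manifest, config: AugmentConfig, out_dir: str | Path):
    """Materialise an augmented manifest on disk (PNG images/masks + JSON)."""
    from . import io_formats

    out_dir = Path(out_dir)
    sources = manifest.load_samples()
    split_of = {e.sample_id: e.split for e in manifest.entries}
    augmented = augment_to_count(sources, config)
    entries = []
    for sample in augmented:
        image_path = out_dir / "images" / f"{sample.sample_id}.png"
        mask_path = out_dir / "masks" / f"{sample.sample_id}_mask.png"
        io_formats.write_image(image_path, sample.image)
        io_formats.write_mask(mask_path, sample.mask)
        roi_rel = None
        if sample.roi is not None:
            roi_path = out_dir / "masks" / f"{sample.sample_id}_roi.png"
            io_formats.write_mask(roi_path, sample.roi)
            roi_rel = str(roi_path.relative_to(out_dir))
        source_id = sample.sample_id.split("~aug")[0]
        entries.append(
            io_formats.ManifestEntry(
                sample_id=sample.sample_id,
                image_path=str(image_path.relative_to(out_dir)),
                mask_path=str(mask_path.relative_to(out_dir)),
                roi_path=roi_rel,
                split=split_of.get(source_id, "train"),
            )
        )
    new_manifest = io_formats.DatasetManifest(entries=entries, root=out_dir)
    io_formats.save_manifest(new_manifest, out_dir / "manifest.json")
    return new_manifest
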