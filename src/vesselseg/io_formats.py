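"""Image, mask and manifest I/O.

Everything handed to downstream modules is normalised at this boundary:
intensity arrays are float64 on [0, 1] (whatever the on-disk bit depth),
masks are strictly binary uint8, and coordinates are row-major with the
origin at the top-left. Three on-disk layouts are understood: the JSON
manifest written by :mod:`vesselseg.synthetic`, the DRIVE-style directory
tree (``images/*.tif`` paired with ``1st_manual/*.gif`` and an optional
``mask/*.gif`` field-of-view ROI, keyed by numeric filename prefix) and
the ROSE-style tree (``img/`` and ``gt/`` with matching stems).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ManifestEntry",
    "DatasetManifest",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "load_manifest",
    "save_manifest",
]

_VALID_SPLITS = {"train", "test"}


@dataclass
class ManifestEntry:
    sample_id: str
    image_path: str
    mask_path: str
    roi_path: Optional[str] = None
    split: str = "train"


@dataclass
class DatasetManifest:
    """A validated list of image/mask(/ROI) file triplets under ``root``."""

    entries: list[ManifestEntry]
    root: Path

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_ids in manifest: {dupes}")
        for e in self.entries:
            if e.split not in _VALID_SPLITS:
                raise ValueError(f"invalid split {e.split!r} for sample {e.sample_id!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(
            entries=[e for e in self.entries if e.split == split], root=self.root
        )

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.root / p

    def load_sample(self, entry: ManifestEntry):
        """Read one entry into an in-memory :class:`~vesselseg.synthetic.ImageSample`."""
        from .synthetic import ImageSample

        image = read_image(self.resolve(entry.image_path))
        mask = read_mask(self.resolve(entry.mask_path))
        roi = read_mask(self.resolve(entry.roi_path)) if entry.roi_path else None
        if roi is not None:
            mask = mask * roi  # clip stray annotation pixels outside the FOV
        return ImageSample(image=image, mask=mask, roi=roi, sample_id=entry.sample_id)

    def load_samples(self, split: Optional[str] = None):
        entries = self.entries if split is None else self.subset(split).entries
        return [self.load_sample(e) for e in entries]

    def validate_paths(self) -> None:
        missing = []
        for e in self.entries:
            for p in (e.image_path, e.mask_path, e.roi_path):
                if p is not None and not self.resolve(p).exists():
                    missing.append(str(self.resolve(p)))
        if missing:
            raise FileNotFoundError("manifest references missing files: " + ", ".join(missing))


def read_image(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF/GIF/JPEG into a float array on [0, 1].

    Grayscale and palette images collapse to 2-D; RGB stays H x W x 3
    (an alpha channel, if any, is dropped). Integer bit depths are
    normalised by their type maximum.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise ValueError(f"unreadable image {path} (format {path.suffix!r}): {exc}") from exc
    if arr.ndim == 4 and arr.shape[0] == 1:  # single-frame GIF/TIFF RGB stacks
        arr = arr[0]
    if arr.ndim == 3 and arr.shape[0] == 1 and arr.shape[-1] not in (3, 4):
        arr = arr[0]  # single-frame grayscale stack
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        elif arr.shape[2] == 3 and np.array_equal(arr[:, :, 0], arr[:, :, 1]) and np.array_equal(
            arr[:, :, 1], arr[:, :, 2]
        ):
            arr = arr[:, :, 0]  # gray stored as replicated RGB (palette GIFs)
    if arr.ndim not in (2, 3):
        raise ValueError(f"unsupported image dimensionality {arr.shape} in {path}")
    return np.clip(arr, 0.0, 1.0)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float array as 8-bit PNG (lossless)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 255).astype(np.uint8))


def read_mask(path: str | Path, positive_threshold: float = 0.5) -> np.ndarray:
    """Read an annotation file and binarise at ``positive_threshold``.

    The file is read like an image (so {0, 255} GIF labels become
    {0, 1}); multi-channel files are collapsed to their first channel
    before thresholding. Values strictly greater than the threshold map
    to 1.
    """
    arr = read_image(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr > positive_threshold).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    write_image(path, np.asarray(mask, dtype=np.float64))


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "samples": [
            {
                "id": e.sample_id,
                "image_path": e.image_path,
                "mask_path": e.mask_path,
                **({"roi_path": e.roi_path} if e.roi_path else {}),
                "split": e.split,
            }
            for e in manifest.entries
        ]
    }
    path.write_text(json.dumps(payload, indent=2))


def _load_json_manifest(path: Path) -> DatasetManifest:
    if path.is_dir():
        path = path / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"manifest file not found: {path}")
    payload = json.loads(path.read_text())
    entries = [
        ManifestEntry(
            sample_id=s["id"],
            image_path=s["image_path"],
            mask_path=s["mask_path"],
            roi_path=s.get("roi_path"),
            split=s.get("split", "train"),
        )
        for s in payload["samples"]
    ]
    return DatasetManifest(entries=entries, root=path.parent)


_NUM_PREFIX = re.compile(r"^(\d+)")


def _numeric_prefix(path: Path) -> Optional[str]:
    m = _NUM_PREFIX.match(path.name)
    return m.group(1) if m else None


def _load_drive_manifest(root: Path, split: str) -> DatasetManifest:
    """Pair images/*.tif with 1st_manual/*.gif (+ optional mask/*.gif ROI)."""
    img_dir = root / "images"
    man_dir = root / "1st_manual"
    roi_dir = root / "mask"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"drive_style layout needs an images/ directory under {root}")
    masks = {_numeric_prefix(p): p for p in sorted(man_dir.glob("*.gif"))} if man_dir.is_dir() else {}
    rois = {_numeric_prefix(p): p for p in sorted(roi_dir.glob("*.gif"))} if roi_dir.is_dir() else {}
    entries, unpaired = [], []
    for img in sorted(img_dir.glob("*.tif")):
        key = _numeric_prefix(img)
        if key is None or key not in masks:
            unpaired.append(str(img))
            continue
        roi = rois.get(key)
        entries.append(
            ManifestEntry(
                sample_id=key,
                image_path=str(img.relative_to(root)),
                mask_path=str(masks[key].relative_to(root)),
                roi_path=str(roi.relative_to(root)) if roi else None,
                split=split,
            )
        )
    if unpaired:
        raise ValueError("images without a manual annotation: " + ", ".join(unpaired))
    return DatasetManifest(entries=entries, root=root)


def _load_rose_manifest(root: Path, split: str) -> DatasetManifest:
    """Pair img/<stem>.* with gt/<stem>.* by shared filename stem."""
    img_dir = root / "img"
    gt_dir = root / "gt"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"rose_style layout needs an img/ directory under {root}")
    gts = {p.stem: p for p in sorted(gt_dir.iterdir())} if gt_dir.is_dir() else {}
    entries, unpaired = [], []
    for img in sorted(img_dir.iterdir()):
        if img.stem not in gts:
            unpaired.append(str(img))
            continue
        entries.append(
            ManifestEntry(
                sample_id=img.stem,
                image_path=str(img.relative_to(root)),
                mask_path=str(gts[img.stem].relative_to(root)),
                split=split,
            )
        )
    if unpaired:
        raise ValueError("images without a ground-truth mask: " + ", ".join(unpaired))
    return DatasetManifest(entries=entries, root=root)


def load_manifest(path_or_dir: str | Path, layout: str = "json", split: str = "train") -> DatasetManifest:
    """Load and validate a dataset manifest.

    ``layout`` selects the pairing rule: ``json`` (manifest file or a
    directory containing ``manifest.json``), ``drive_style`` or
    ``rose_style`` (directory trees; ``split`` tags all entries). A
    missing vessel mask for an image is an error; a missing ROI is not.
    """
    path = Path(path_or_dir)
    if layout == "json":
        manifest = _load_json_manifest(path)
    elif layout == "drive_style":
        manifest = _load_drive_manifest(path, split)
    elif layout == "rose_style":
        manifest = _load_rose_manifest(path, split)
    else:
        raise ValueError(f"unknown layout {layout!r}; expected json, drive_style or rose_style")
    manifest.validate_paths()
    return manifest
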