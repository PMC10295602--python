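"""Improved U-Net for vessel segmentation.

The network is a U-shaped encoder–decoder with three modifications to
the plain U-Net:

* every plain double-convolution is replaced by a **residual block**
  (two 3x3 conv -> batch-norm -> ReLU stages with an additive shortcut
  joining in before the final activation; the shortcut is the identity
  when channel counts match and a 1x1 projection otherwise);
* the deepest feature map passes through an **inception bottleneck**:
  parallel 1x1 / 3x3 / 5x5 convolution branches (each conv -> BN ->
  ReLU), channel-concatenated and projected back by a 1x1 conv -> BN ->
  ReLU;
* each decoder stage uses a **full-scale skip connection**: it fuses
  feature maps from *every* scale — all encoder levels at or above the
  target resolution (max-pooled down by the required power of two) and
  all deeper decoder/bottleneck maps (bilinearly upsampled by 2x/4x/8x)
  — so a decoder stage at depth L always sees exactly L sources. Each
  source is mapped to a common ``fusion_channels`` width by a 3x3 conv
  -> BN -> ReLU, concatenated, and digested by a residual block.

Channel widths follow the standard U-Net doubling rule:
``base_channels * 2**(level-1)`` at encoder level ``level``; the decoder
stage at level ``t`` outputs the same width as encoder level ``t``. A
1x1 convolution plus sigmoid produces the per-pixel vessel probability
at the input resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "ResidualBlock",
    "InceptionBottleneck",
    "FullScaleFusion",
    "VesselSegModel",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    depth: number of encoder levels L; input sides must divide 2**depth.
    base_channels: width at full resolution, doubling per level.
    bottleneck_channels: output width of the inception bottleneck
        (defaults to the deepest encoder width).
    fusion_channels: per-source width inside each full-scale fusion.
    in_channels: 1 for grayscale input, 3 for RGB.
    """

    depth: int = 4
    base_channels: int = 32
    bottleneck_channels: Optional[int] = None
    fusion_channels: int = 32
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError(f"depth must be >= 2, got {self.depth}")
        if self.base_channels < 1 or self.fusion_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.in_channels not in (1, 3):
            raise ValueError(f"in_channels must be 1 or 3, got {self.in_channels}")
        if self.bottleneck_channels is not None and self.bottleneck_channels < 1:
            raise ValueError("bottleneck_channels must be positive")

    def encoder_channels(self, level: int) -> int:
        """Width of encoder level ``level`` (1-based, 1 = full resolution)."""
        return self.base_channels * 2 ** (level - 1)

    @property
    def resolved_bottleneck_channels(self) -> int:
        return (
            self.bottleneck_channels
            if self.bottleneck_channels is not None
            else self.encoder_channels(self.depth)
        )

    @property
    def divisor(self) -> int:
        return 2 ** self.depth

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class ResidualBlock(nn.Module):
    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_channels, out_channels, 3, rng)
        self.bn1 = nn.BatchNorm2d(out_channels)
        self.conv2 = nn.Conv2d(out_channels, out_channels, 3, rng)
        self.bn2 = nn.BatchNorm2d(out_channels)
        self.projection = (
            nn.Conv2d(in_channels, out_channels, 1, rng) if in_channels != out_channels else None
        )

    def forward(self, x: Tensor) -> Tensor:
        y = nn.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        shortcut = self.projection(x) if self.projection is not None else x
        return nn.relu(nn.add(y, shortcut))


class InceptionBottleneck(nn.Module):
    """Parallel 1x1 / 3x3 / 5x5 branches, concatenated and 1x1-projected."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.branches = [nn.ConvBNReLU(in_channels, out_channels, k, rng) for k in (1, 3, 5)]
        self.project = nn.ConvBNReLU(3 * out_channels, out_channels, 1, rng)
        self.pre_projection_channels = 3 * out_channels

    def forward(self, x: Tensor) -> Tensor:
        merged = nn.concat([branch(x) for branch in self.branches])
        assert merged.shape[1] == self.pre_projection_channels
        return self.project(merged)


class FullScaleFusion(nn.Module):
    """One decoder stage: resize every scale to the target, fuse, digest.

    ``source_specs`` records, per source, the encoder/decoder level it
    taps and the resize applied: ("down", f) is f-fold max pooling,
    ("up", f) is f-fold bilinear upsampling, ("same", 1) no resize.
    """

    def __init__(self, config: ModelConfig, target_level: int, rng: np.random.Generator):
        super().__init__()
        L = config.depth
        if not (1 <= target_level <= L - 1):
            raise ValueError(f"target_level must be in [1, {L - 1}], got {target_level}")
        self.target_level = target_level
        self.source_specs: list[tuple[int, str, int]] = []
        self.adapters: list[nn.ConvBNReLU] = []
        for s in range(1, L + 1):
            if s <= target_level:
                src_ch = config.encoder_channels(s)
                kind, factor = ("same", 1) if s == target_level else ("down", 2 ** (target_level - s))
            elif s < L:
                src_ch = config.encoder_channels(s)  # decoder level s outputs encoder-level width
                kind, factor = "up", 2 ** (s - target_level)
            else:
                src_ch = config.resolved_bottleneck_channels
                kind, factor = "up", 2 ** (s - target_level)
            self.source_specs.append((s, kind, factor))
            self.adapters.append(nn.ConvBNReLU(src_ch, config.fusion_channels, 3, rng))
        self.fuse = ResidualBlock(
            L * config.fusion_channels, config.encoder_channels(target_level), rng
        )

    def forward(self, encoder_maps: list[Tensor], deeper_maps: dict[int, Tensor]) -> Tensor:
        """``encoder_maps[i]`` is level i+1; ``deeper_maps[s]`` the decoder
        (or bottleneck) output at level s > target."""
        pieces = []
        for (level, kind, factor), adapter in zip(self.source_specs, self.adapters):
            if kind == "up":
                if level not in deeper_maps:
                    raise ValueError(f"missing decoder/bottleneck map for level {level}")
                src = deeper_maps[level]
            else:
                src = encoder_maps[level - 1]
            if kind == "down":
                src = nn.max_pool2d(src, factor)
            elif kind == "up":
                src = nn.upsample_bilinear(src, factor)
            pieces.append(adapter(src))
        return self.fuse(nn.concat(pieces))


class VesselSegModel(nn.Module):
    """Residual U-Net with inception bottleneck and full-scale skips."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        L = config.depth
        self.encoder_blocks = []
        prev = config.in_channels
        for level in range(1, L + 1):
            self.encoder_blocks.append(ResidualBlock(prev, config.encoder_channels(level), rng))
            prev = config.encoder_channels(level)
        self.bottleneck = InceptionBottleneck(
            config.encoder_channels(L), config.resolved_bottleneck_channels, rng
        )
        # decoder stages built deepest-first (level L-1 .. 1)
        self.decoder_stages = [FullScaleFusion(config, t, rng) for t in range(L - 1, 0, -1)]
        self.head = nn.Conv2d(config.encoder_channels(1), 1, 1, rng)

    # -- structure ----------------------------------------------------------
    def decoder_stage(self, target_level: int) -> FullScaleFusion:
        return self.decoder_stages[self.config.depth - 1 - target_level]

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4:
            raise ValueError(f"expected 2-D, 3-D or NCHW input, got shape {x.shape}")
        n, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ValueError(f"model expects {self.config.in_channels} channels, got {c}")
        d = self.config.divisor
        if h % d or w % d:
            raise ValueError(
                f"spatial dims {(h, w)} must be divisible by 2**depth = {d}; "
                "reflect-pad the input (see train_eval.pad_to_divisible)"
            )
        return x

    def encoder_forward(self, x: np.ndarray | Tensor) -> list[Tensor]:
        """Return all L encoder maps, level 1 (full res) to L (deepest)."""
        t = x if isinstance(x, Tensor) else Tensor(self._check_input(x))
        maps = []
        for i, block in enumerate(self.encoder_blocks):
            if i > 0:
                t = nn.max_pool2d(t, 2)
            t = block(t)
            maps.append(t)
        return maps

    def forward_logits(self, x: np.ndarray | Tensor) -> Tensor:
        encoder_maps = self.encoder_forward(x)
        L = self.config.depth
        deeper: dict[int, Tensor] = {L: self.bottleneck(encoder_maps[-1])}
        for stage in self.decoder_stages:  # L-1 down to 1
            deeper[stage.target_level] = stage(encoder_maps, deeper)
        return self.head(deeper[1])

    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        """Per-pixel vessel probability map, shape (N, 1, H, W), values in (0, 1)."""
        return nn.sigmoid(self.forward_logits(x))

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map for one 2-D (or HxWx3) image of arbitrary size.

        The image is reflect-padded to the next multiple of 2**depth,
        run in evaluation mode, and the prediction cropped back.
        """
        from .train_eval import pad_to_divisible

        was_training = self.training
        self.eval()
        try:
            if image.ndim == 3 and image.shape[2] == 3:
                padded, (h, w) = pad_to_divisible(image, self.config.divisor)
                x = padded.transpose(2, 0, 1)[None]
            else:
                padded, (h, w) = pad_to_divisible(image, self.config.divisor)
                x = padded[None, None]
            out = self.forward(x).data[0, 0]
            return out[:h, :w].astype(np.float64)
        finally:
            self.train(was_training)


def build_model(config: ModelConfig, seed: int = 0) -> VesselSegModel:
    return VesselSegModel(config, seed=seed)


def save_checkpoint(model: VesselSegModel, path: str | Path) -> None:
    """Write weights as .npz with a JSON sidecar of the architecture config."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(model.config.to_dict(), indent=2))


def load_checkpoint(path: str | Path, seed: int = 0) -> VesselSegModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"checkpoint sidecar not found: {sidecar}")
    config = ModelConfig.from_dict(json.loads(sidecar.read_text()))
    model = VesselSegModel(config, seed=seed)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
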