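"""Segmentation architectures and the Dice loss.

Two networks are provided, mirroring the clinical configuration:

* a 2-D U-Net with a ResNet34-style residual encoder of depth 5
  (stage channels 3, 64, 64, 128, 256, 512) and the standard U-Net decoder
  with 256, 128, 64, 32 and 16 channels, ReLU activations, sigmoid head;
* a 3-D U-Net of depth 5 whose channels start at 2 in the first stage and
  double per stage (2, 4, 8, 16, 32), LeakyReLU activations and 60%
  dropout in the first stage.

Both are built on the package's numpy autodiff toolkit, so scaled-down
variants (``width_multiplier`` and reduced residual block counts) train on
a plain CPU.  Grayscale slices are replicated to 3 input channels to honour
the encoder's 3-channel input width.  ImageNet-pretrained encoder weights
are not redistributable here; requesting ``pretrained=True`` falls back to
random initialization with a warning.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .core import BinaryMask
from .errors import ShapeError

__all__ = [
    "ModelConfig2D", "ModelConfig3D", "build_unet2d", "build_unet3d",
    "dice_loss", "dsc_binary", "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig2D:
    encoder: str = "resnet34"
    depth: int = 5
    decoder_channels: tuple[int, ...] = (256, 128, 64, 32, 16)
    activation: str = "relu"
    pretrained: bool = False
    width_multiplier: float = 1.0
    encoder_blocks: tuple[int, ...] = (3, 4, 6, 3)

    @property
    def encoder_channels(self) -> tuple[int, ...]:
        c1 = self._scale(64)
        return (3, c1, c1, self._scale(128), self._scale(256), self._scale(512))

    def _scale(self, c: int) -> int:
        return max(int(round(c * self.width_multiplier)), 2)

    def scaled_decoder_channels(self) -> tuple[int, ...]:
        return tuple(self._scale(c) for c in self.decoder_channels)

    def validate(self) -> None:
        if self.depth != 5 or len(self.decoder_channels) != 5:
            raise ValueError("the 2D U-Net uses a fixed depth of 5")
        if len(self.encoder_blocks) != 4:
            raise ValueError("encoder_blocks must list 4 stages")


@dataclass(frozen=True)
class ModelConfig3D:
    depth: int = 5
    first_stage_channels: int = 2
    activation: str = "leaky_relu"
    negative_slope: float = 0.01
    dropout_p_first_stage: float = 0.6

    @property
    def stage_channels(self) -> tuple[int, ...]:
        return tuple(self.first_stage_channels * 2**i for i in range(self.depth))

    def validate(self) -> None:
        if self.depth < 2:
            raise ValueError("3D U-Net needs at least 2 stages")
        if not 0.0 <= self.dropout_p_first_stage < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")


class _ConvBnAct(nn.Module):
    def __init__(self, cin, cout, ndim, rng, kernel=3, stride=1,
                 activation="relu", negative_slope=0.01):
        super().__init__()
        self.conv = nn.Conv(cin, cout, kernel, ndim, stride=stride, rng=rng)
        self.bn = nn.BatchNorm(cout)
        self.act = nn.ReLU() if activation == "relu" \
            else nn.LeakyReLU(negative_slope)

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class _ResidualBlock(nn.Module):
    """Basic (two 3x3 convs) residual block with optional projection shortcut."""

    def __init__(self, cin, cout, rng, stride=1):
        super().__init__()
        self.conv1 = nn.Conv(cin, cout, 3, 2, stride=stride, rng=rng)
        self.bn1 = nn.BatchNorm(cout)
        self.conv2 = nn.Conv(cout, cout, 3, 2, rng=rng)
        self.bn2 = nn.BatchNorm(cout)
        self.proj = None
        if stride != 1 or cin != cout:
            self.proj = nn.Sequential(
                nn.Conv(cin, cout, 1, 2, stride=stride, padding=0, rng=rng),
                nn.BatchNorm(cout))

    def forward(self, x):
        identity = self.proj(x) if self.proj is not None else x
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        return (out + identity).relu()


class _DecoderBlock(nn.Module):
    def __init__(self, cin, cskip, cout, ndim, rng, activation="relu"):
        super().__init__()
        self.up = nn.Upsample(2)
        self.conv1 = _ConvBnAct(cin + cskip, cout, ndim, rng, activation=activation)
        self.conv2 = _ConvBnAct(cout, cout, ndim, rng, activation=activation)

    def forward(self, x, skip):
        x = self.up(x)
        if skip is not None:
            x = nn.concat([x, skip], axis=1)
        return self.conv2(self.conv1(x))


class UNet2D(nn.Module):
    """ResNet-encoder U-Net mapping (N, 3, H, W) slices to probabilities."""

    def __init__(self, config: ModelConfig2D, seed: int = 0):
        super().__init__()
        config.validate()
        if config.pretrained:
            warnings.warn(
                "no pretrained encoder weights are available in this build; "
                "falling back to random initialization", stacklevel=2)
        self.config = config
        rng = np.random.default_rng(seed)
        enc = config.encoder_channels  # (3, c1, c1, c2, c3, c4)
        self.stem = _ConvBnAct(enc[0], enc[1], 2, rng, kernel=7, stride=2)
        self.pool = nn.MaxPool(2)
        stage_specs = list(zip(
            (enc[1], enc[2], enc[3], enc[4]),
            (enc[2], enc[3], enc[4], enc[5]),
            (1, 2, 2, 2), config.encoder_blocks))
        self.stages = nn.Sequential(*[
            nn.Sequential(*(
                [_ResidualBlock(cin, cout, rng, stride=stride)]
                + [_ResidualBlock(cout, cout, rng) for _ in range(blocks - 1)]
            )) for cin, cout, stride, blocks in stage_specs])
        dec = config.scaled_decoder_channels()
        skips = (enc[4], enc[3], enc[2], enc[1], enc[0])
        ins = (enc[5],) + dec[:-1]
        self.decoder = nn.Sequential(*[
            _DecoderBlock(cin, cskip, cout, 2, rng)
            for cin, cskip, cout in zip(ins, skips, dec)])
        self.head = nn.Conv(dec[-1], 1, 1, 2, padding=0, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ShapeError("2D U-Net expects (N, 3, H, W) input")
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ShapeError(
                f"input {h}x{w} not divisible by 32 (5-level encoder)")
        f0 = x
        f1 = self.stem(x)
        feats = [f0, f1]
        y = self.pool(f1)
        for stage in self.stages.layers:
            y = stage(y)
            feats.append(y)
        # feats: [input, stem, s1, s2, s3, s4]; bottleneck is s4
        skips = [feats[4], feats[3], feats[2], feats[1], feats[0]]
        d = feats[5]
        for block, skip in zip(self.decoder.layers, skips):
            d = block(d, skip)
        return self.head(d).sigmoid()

    def stage_channel_counts(self) -> tuple[int, ...]:
        return self.config.encoder_channels


class UNet3D(nn.Module):
    """Depth-5 3D U-Net mapping (N, 1, D, H, W) volumes to probabilities."""

    def __init__(self, config: ModelConfig3D, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        act = dict(activation=config.activation,
                   negative_slope=config.negative_slope)
        chans = config.stage_channels
        enc_stages = []
        cin = 1
        for i, c in enumerate(chans):
            layers = [_ConvBnAct(cin, c, 3, rng, **act),
                      _ConvBnAct(c, c, 3, rng, **act)]
            if i == 0 and config.dropout_p_first_stage > 0:
                layers.append(nn.Dropout(config.dropout_p_first_stage,
                                         rng=np.random.default_rng(seed + 1)))
            enc_stages.append(nn.Sequential(*layers))
            cin = c
        self.encoder = nn.Sequential(*enc_stages)
        self.pool = nn.MaxPool(2)
        # decoder mirrors the encoder channel sequence
        dec_blocks = []
        for i in range(len(chans) - 2, -1, -1):
            dec_blocks.append(
                _DecoderBlock(chans[i + 1], chans[i], chans[i], 3, rng,
                              activation=config.activation))
        self.decoder = nn.Sequential(*dec_blocks)
        self.head = nn.Conv(chans[0], 1, 1, 3, padding=0, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.ndim != 5 or x.shape[1] != 1:
            raise ShapeError("3D U-Net expects (N, 1, D, H, W) input")
        depth_pools = self.config.depth - 1
        for s in x.shape[2:]:
            if s % 2**depth_pools:
                raise ShapeError(
                    f"spatial size {s} not divisible by 2^{depth_pools}")
        feats = []
        y = x
        for i, stage in enumerate(self.encoder.layers):
            y = stage(y)
            if i < len(self.encoder.layers) - 1:
                feats.append(y)
                y = self.pool(y)
        for block, skip in zip(self.decoder.layers, reversed(feats)):
            y = block(y, skip)
        return self.head(y).sigmoid()

    def stage_channel_counts(self) -> tuple[int, ...]:
        return self.config.stage_channels


def build_unet2d(config: ModelConfig2D | None = None, seed: int = 0) -> UNet2D:
    return UNet2D(config or ModelConfig2D(), seed=seed)


def build_unet3d(config: ModelConfig3D | None = None, seed: int = 0) -> UNet3D:
    return UNet3D(config or ModelConfig3D(), seed=seed)


# -- loss ------------------------------------------------------------------

def _as_array(x) -> np.ndarray:
    if isinstance(x, BinaryMask):
        return x.values.astype(np.float32)
    if isinstance(x, nn.Tensor):
        return x.data
    return np.asarray(x, dtype=np.float32)


def dice_loss(pred, target, eps: float = 1.0):
    """Soft Dice loss ``1 - (2|X.Y| + eps) / (|X| + |Y| + eps)``.

    ``pred`` may be an autodiff Tensor (training path, differentiable) or a
    plain probability array; ``target`` is a binary array or mask.  The
    smoothing term ``eps`` stabilises empty masks; with ``eps=0`` and binary
    inputs the value is exactly ``1 - DSC``.
    """
    tgt = _as_array(target)
    if isinstance(pred, nn.Tensor):
        if pred.shape != tgt.shape:
            raise ShapeError(f"shape mismatch {pred.shape} vs {tgt.shape}")
        tgt_t = nn.Tensor(tgt)
        inter = (pred * tgt_t).sum()
        denom = pred.sum() + float(tgt.sum()) + eps
        return 1.0 - (2.0 * inter + eps) / denom
    p = _as_array(pred)
    if p.shape != tgt.shape:
        raise ShapeError(f"shape mismatch {p.shape} vs {tgt.shape}")
    inter = float((p * tgt).sum())
    return 1.0 - (2.0 * inter + eps) / (float(p.sum()) + float(tgt.sum()) + eps)


def dsc_binary(pred, target) -> float:
    """Hard Dice similarity coefficient on binary inputs (empty-empty -> 1)."""
    p = _as_array(pred) > 0.5
    t = _as_array(target) > 0.5
    if p.shape != t.shape:
        raise ShapeError(f"shape mismatch {p.shape} vs {t.shape}")
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(model, path) -> None:
    """Serialise weights (npz) plus an architecture-descriptor JSON."""
    path = Path(path)
    np.savez_compressed(path, **model.state_dict())
    descriptor = {
        "architecture": type(model).__name__,
        "config": dataclasses.asdict(model.config),
    }
    path.with_suffix(".json").write_text(json.dumps(descriptor, indent=1))


def load_checkpoint(path, seed: int = 0):
    path = Path(path)
    descriptor = json.loads(path.with_suffix(".json").read_text())
    cfg = descriptor["config"]
    for key in ("decoder_channels", "encoder_blocks"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    if descriptor["architecture"] == "UNet2D":
        model = UNet2D(ModelConfig2D(**cfg), seed=seed)
    elif descriptor["architecture"] == "UNet3D":
        model = UNet3D(ModelConfig3D(**cfg), seed=seed)
    else:
        raise ValueError(f"unknown architecture {descriptor['architecture']!r}")
    npz_path = path if path.name.endswith(".npz") else Path(str(path) + ".npz")
    with np.load(npz_path) as data:
        model.load_state_dict(dict(data))
    return model
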