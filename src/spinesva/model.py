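"""ResUNet landmark-heatmap network and its declarative architecture trace.

The default network is a 31-convolution residual U-Net: a head block (C1), a
downsampling path (C2-C5) that halves height and width four times, an
upsampling path (C6-C9) that restores them with non-learnable bilinear
upsampling and encoder skip connections, and a tail (C10) that emits one
regression heatmap per landmark.  A plain 12-convolution UNet is included as
the complexity baseline.

Blocks
------
* ``CONV``       - 3x3 conv, group norm, ReLU (the last tail conv is linear).
* ``Res``        - two conv/GN stages with an identity skip added before the
                   final ReLU.
* ``Res-Down``   - as Res, but the first 3x3 conv and the 1x1 skip projection
                   use stride 2, halving height and width.
* ``Res-Down-C`` - as Res-Down with stride 1 everywhere; the 1x1 projection
                   only reduces the channel count (used after skip
                   concatenation on the upsampling path).
* ``Upsampling`` - bilinear, factor 2, no learnable parameters.

Encoder and decoder levels are merged by channel concatenation; each block's
output width follows the architecture table regardless of the merged input
width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from .engine import BilinearUpsample2x, Conv2d, GroupNorm, MaxPool2x, Parameter, ReLU

__all__ = [
    "BlockSpec",
    "LayerTrace",
    "ModelConfig",
    "ResUNet",
    "UNet12",
    "build_model",
    "count_conv_layers",
    "load_checkpoint",
    "save_checkpoint",
    "trace_shapes",
]


@dataclass(frozen=True)
class ModelConfig:
    input_height: int = 768
    input_width: int = 448
    input_channels: int = 1
    base_filters: int = 64
    output_channels: int = 2
    norm_groups: int = 32
    variant: Literal["resunet31", "unet12"] = "resunet31"

    def __post_init__(self) -> None:
        if self.input_height % 16 or self.input_width % 16:
            raise ValueError(
                f"input dims must be divisible by 16 (four spatial halvings), "
                f"got {self.input_height}x{self.input_width}"
            )
        if self.base_filters < 2 or self.base_filters % 2:
            raise ValueError(f"base_filters must be an even count >= 2, got {self.base_filters}")
        for c in self.normalized_channel_counts():
            if c % self.norm_groups:
                raise ValueError(
                    f"norm_groups={self.norm_groups} does not divide normalized "
                    f"channel count {c}"
                )

    @property
    def head_mid_channels(self) -> int:
        """Width of the penultimate tail conv: f/2, floored at 2.

        At the default width (64 -> 32) this is exactly the architecture
        table's value; the floor only matters for heavily reduced desk-scale
        models, where a single-channel head path would bottleneck both
        landmark maps through one feature.
        """
        return max(self.base_filters // 2, 2)

    def normalized_channel_counts(self) -> tuple[int, ...]:
        """Channel widths of every group-normalized layer for this variant."""
        f = self.base_filters
        if self.variant == "resunet31":
            return (f, 2 * f, 4 * f, 8 * f, self.head_mid_channels)
        return (f, 2 * f, 4 * f, self.head_mid_channels)


@dataclass(frozen=True)
class BlockSpec:
    kind: Literal["CONV", "Res", "Res-Down", "Res-Down-C", "Upsampling"]
    conv3_count: int
    conv1_count: int
    out_channels: int


@dataclass
class LayerTrace:
    """Per-block output shapes, one row per architecture-table row."""

    rows: list[tuple[str, str, tuple[str | int, int, int, int]]] = field(default_factory=list)

    def shapes(self) -> list[tuple[int, int, int]]:
        return [(h, w, c) for _, _, (_, h, w, c) in self.rows]


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------


class _ConvBlock:
    """3x3 conv -> GN -> ReLU; the linear variant omits normalization/activation."""

    kind = "CONV"

    def __init__(self, cin, cout, groups, rng, linear=False, name="conv"):
        self.conv = Conv2d(cin, cout, 3, rng=rng, name=name)
        self.linear = linear
        if not linear:
            self.gn = GroupNorm(cout, groups, name=name)
            self.act = ReLU()
        self.out_channels = cout

    def params(self):
        ps = self.conv.params()
        if not self.linear:
            ps += self.gn.params()
        return ps

    def conv_layers(self):
        return [self.conv]

    def forward(self, x):
        y = self.conv.forward(x)
        if self.linear:
            return y
        return self.act.forward(self.gn.forward(y))

    def backward(self, dy):
        if not self.linear:
            dy = self.gn.backward(self.act.backward(dy))
        return self.conv.backward(dy)


class _ResBlock:
    """Residual block: conv/GN/ReLU -> conv/GN, add skip, final ReLU.

    ``stride=2`` with a 1x1 projection gives Res-Down; ``stride=1`` with a
    projection gives Res-Down-C (channel reduction only); no projection and
    stride 1 is the plain Res block with an identity skip.
    """

    def __init__(self, cin, cout, groups, rng, stride=1, project=False, name="res"):
        if stride == 2 and not project:
            raise ValueError("stride-2 residual blocks require a 1x1 projection skip")
        if cin != cout and not project:
            raise ValueError("channel-changing residual blocks require a projection skip")
        self.kind = (
            "Res" if not project else ("Res-Down" if stride == 2 else "Res-Down-C")
        )
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng, name=f"{name}.conv1")
        self.gn1 = GroupNorm(cout, groups, name=f"{name}.gn1")
        self.act1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng=rng, name=f"{name}.conv2")
        self.gn2 = GroupNorm(cout, groups, name=f"{name}.gn2")
        self.skip = (
            Conv2d(cin, cout, 1, stride=stride, rng=rng, name=f"{name}.skip")
            if project
            else None
        )
        self.act_out = ReLU()
        self.out_channels = cout

    def params(self):
        ps = (
            self.conv1.params()
            + self.gn1.params()
            + self.conv2.params()
            + self.gn2.params()
        )
        if self.skip is not None:
            ps += self.skip.params()
        return ps

    def conv_layers(self):
        convs = [self.conv1, self.conv2]
        if self.skip is not None:
            convs.append(self.skip)
        return convs

    def forward(self, x):
        t = self.act1.forward(self.gn1.forward(self.conv1.forward(x)))
        t = self.gn2.forward(self.conv2.forward(t))
        s = self.skip.forward(x) if self.skip is not None else x
        return self.act_out.forward(t + s)

    def backward(self, dy):
        dsum = self.act_out.backward(dy)
        dt = self.conv2.backward(self.gn2.backward(dsum))
        dx = self.conv1.backward(self.gn1.backward(self.act1.backward(dt)))
        if self.skip is not None:
            dx = dx + self.skip.backward(dsum)
        else:
            dx = dx + dsum
        return dx


class _Upsample:
    kind = "Upsampling"

    def __init__(self, channels):
        self.up = BilinearUpsample2x()
        self.out_channels = channels

    def params(self):
        return []

    def conv_layers(self):
        return []

    def forward(self, x):
        return self.up.forward(x)

    def backward(self, dy):
        return self.up.backward(dy)


_BLOCK_CONV_COUNTS = {
    "CONV": (1, 0),
    "Res": (2, 0),
    "Res-Down": (2, 1),
    "Res-Down-C": (2, 1),
    "Upsampling": (0, 0),
}


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


class ResUNet:
    """31-convolution residual U-Net mapping N x H x W x 1 to N x H x W x K heatmaps."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        if config.variant != "resunet31":
            raise ValueError("ResUNet requires variant='resunet31'")
        self.config = config
        rng = np.random.default_rng(seed)
        f, g, cin, cout = (
            config.base_filters,
            config.norm_groups,
            config.input_channels,
            config.output_channels,
        )
        self.c1_conv = _ConvBlock(cin, f, g, rng, name="c1.conv")
        self.c1_res = _ResBlock(f, f, g, rng, name="c1.res")
        self.c2_down = _ResBlock(f, 2 * f, g, rng, stride=2, project=True, name="c2.down")
        self.c2_res = _ResBlock(2 * f, 2 * f, g, rng, name="c2.res")
        self.c3_down = _ResBlock(2 * f, 4 * f, g, rng, stride=2, project=True, name="c3.down")
        self.c4_down = _ResBlock(4 * f, 8 * f, g, rng, stride=2, project=True, name="c4.down")
        self.c5_down = _ResBlock(8 * f, 8 * f, g, rng, stride=2, project=True, name="c5.down")
        self.c5_res = _ResBlock(8 * f, 8 * f, g, rng, name="c5.res")
        self.c6_up = _Upsample(8 * f)
        self.c7_redc = _ResBlock(16 * f, 4 * f, g, rng, project=True, name="c7.redc")
        self.c7_up = _Upsample(4 * f)
        self.c8_redc = _ResBlock(8 * f, 2 * f, g, rng, project=True, name="c8.redc")
        self.c8_up = _Upsample(2 * f)
        self.c9_redc = _ResBlock(4 * f, f, g, rng, project=True, name="c9.redc")
        self.c9_up = _Upsample(f)
        fmid = config.head_mid_channels
        self.c10_conv1 = _ConvBlock(2 * f, f, g, rng, name="c10.conv1")
        self.c10_conv2 = _ConvBlock(f, fmid, g, rng, name="c10.conv2")
        self.c10_head = _ConvBlock(fmid, cout, g, rng, linear=True, name="c10.head")
        # Small-scale head init: the regression targets are tiny relative to
        # unit-variance features, and a full-scale random head produces a large
        # initial error whose fastest descent direction is to kill the output
        # path entirely (a dead attractor).  Scaling the head keeps the initial
        # output near zero while leaving gradients nonzero.
        self.c10_head.conv.weight.value *= 0.01
        self._blocks = [
            ("C1", self.c1_conv),
            ("C1", self.c1_res),
            ("C2", self.c2_down),
            ("C2", self.c2_res),
            ("C3", self.c3_down),
            ("C4", self.c4_down),
            ("C5", self.c5_down),
            ("C5", self.c5_res),
            ("C6", self.c6_up),
            ("C7", self.c7_redc),
            ("C7", self.c7_up),
            ("C8", self.c8_redc),
            ("C8", self.c8_up),
            ("C9", self.c9_redc),
            ("C9", self.c9_up),
            ("C10", self.c10_conv1),
            ("C10", self.c10_conv2),
            ("C10", self.c10_head),
        ]
        self.observed_shapes: list[tuple[int, int, int]] | None = None

    # -- plumbing ----------------------------------------------------------
    def params(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for _, b in self._blocks:
            ps += b.params()
        return ps

    def conv_layers(self) -> list[Conv2d]:
        convs: list[Conv2d] = []
        for _, b in self._blocks:
            convs += b.conv_layers()
        return convs

    def blocks(self) -> list[tuple[str, object]]:
        return list(self._blocks)

    # -- forward/backward --------------------------------------------------
    def forward(self, x: np.ndarray, record_shapes: bool = False) -> np.ndarray:
        self._check_input(x)
        x = np.ascontiguousarray(x.transpose(0, 3, 1, 2))  # NHWC -> NCHW internal
        shapes: list[tuple[int, int, int]] = []

        def rec(t):
            if record_shapes:
                shapes.append((t.shape[2], t.shape[3], t.shape[1]))
            return t

        s1 = rec(self.c1_res.forward(rec(self.c1_conv.forward(x))))
        s2 = rec(self.c2_res.forward(rec(self.c2_down.forward(s1))))
        s3 = rec(self.c3_down.forward(s2))
        s4 = rec(self.c4_down.forward(s3))
        t = rec(self.c5_res.forward(rec(self.c5_down.forward(s4))))
        t = rec(self.c6_up.forward(t))
        self._cat_widths = []
        t = rec(self.c7_redc.forward(self._cat(t, s4)))
        t = rec(self.c7_up.forward(t))
        t = rec(self.c8_redc.forward(self._cat(t, s3)))
        t = rec(self.c8_up.forward(t))
        t = rec(self.c9_redc.forward(self._cat(t, s2)))
        t = rec(self.c9_up.forward(t))
        t = rec(self.c10_conv1.forward(self._cat(t, s1)))
        t = rec(self.c10_conv2.forward(t))
        out = rec(self.c10_head.forward(t))
        if record_shapes:
            self.observed_shapes = shapes
        return out.transpose(0, 2, 3, 1)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def _cat(self, up: np.ndarray, skip: np.ndarray) -> np.ndarray:
        self._cat_widths.append(up.shape[1])
        return np.concatenate([up, skip], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy.transpose(0, 3, 1, 2))  # NHWC -> NCHW internal
        w7, w8, w9, w10 = self._cat_widths
        d = self.c10_conv2.backward(self.c10_head.backward(dy))
        d = self.c10_conv1.backward(d)
        d, ds1 = d[:, :w10], d[:, w10:]
        d = self.c9_redc.backward(self.c9_up.backward(d))
        d, ds2 = d[:, :w9], d[:, w9:]
        d = self.c8_redc.backward(self.c8_up.backward(d))
        d, ds3 = d[:, :w8], d[:, w8:]
        d = self.c7_redc.backward(self.c7_up.backward(d))
        d, ds4 = d[:, :w7], d[:, w7:]
        d = self.c5_down.backward(self.c5_res.backward(self.c6_up.backward(d)))
        d = self.c4_down.backward(d + ds4)
        d = self.c3_down.backward(d + ds3)
        d = self.c2_down.backward(self.c2_res.backward(d + ds2))
        d = self.c1_conv.backward(self.c1_res.backward(d + ds1))
        return d.transpose(0, 2, 3, 1)

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[-1] != self.config.input_channels:
            raise ValueError(
                f"expected N x H x W x {self.config.input_channels} input, got {x.shape}"
            )
        if x.shape[1] % 16 or x.shape[2] % 16:
            raise ValueError(f"spatial dims must be divisible by 16, got {x.shape[1:3]}")


class UNet12:
    """Plain 12-convolution UNet baseline: two max-pool halvings, GN/ReLU, no residual skips.

    Layout: two convs per level on a 3-level encoder/decoder (2+2+2 down,
    2+2 up with concatenated skips) plus a two-conv head, 12 convolutions in
    total.  Downsampling is 2x2 max pooling; upsampling is bilinear.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        if config.variant != "unet12":
            raise ValueError("UNet12 requires variant='unet12'")
        self.config = config
        rng = np.random.default_rng(seed)
        f, g, cin, cout = (
            config.base_filters,
            config.norm_groups,
            config.input_channels,
            config.output_channels,
        )
        self.e1a = _ConvBlock(cin, f, g, rng, name="e1a")
        self.e1b = _ConvBlock(f, f, g, rng, name="e1b")
        self.pool1 = MaxPool2x()
        self.e2a = _ConvBlock(f, 2 * f, g, rng, name="e2a")
        self.e2b = _ConvBlock(2 * f, 2 * f, g, rng, name="e2b")
        self.pool2 = MaxPool2x()
        self.b1 = _ConvBlock(2 * f, 4 * f, g, rng, name="b1")
        self.b2 = _ConvBlock(4 * f, 4 * f, g, rng, name="b2")
        self.up2 = BilinearUpsample2x()
        self.d2a = _ConvBlock(6 * f, 2 * f, g, rng, name="d2a")
        self.d2b = _ConvBlock(2 * f, 2 * f, g, rng, name="d2b")
        self.up1 = BilinearUpsample2x()
        self.d1a = _ConvBlock(3 * f, f, g, rng, name="d1a")
        self.d1b = _ConvBlock(f, f, g, rng, name="d1b")
        fmid = config.head_mid_channels
        self.h1 = _ConvBlock(f, fmid, g, rng, name="h1")
        self.head = _ConvBlock(fmid, cout, g, rng, linear=True, name="head")
        self.head.conv.weight.value *= 0.01  # small-scale head init, as in ResUNet
        self._conv_blocks = [
            self.e1a, self.e1b, self.e2a, self.e2b, self.b1, self.b2,
            self.d2a, self.d2b, self.d1a, self.d1b, self.h1, self.head,
        ]

    def params(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for b in self._conv_blocks:
            ps += b.params()
        return ps

    def conv_layers(self) -> list[Conv2d]:
        convs: list[Conv2d] = []
        for b in self._conv_blocks:
            convs += b.conv_layers()
        return convs

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x.transpose(0, 3, 1, 2))  # NHWC -> NCHW internal
        s1 = self.e1b.forward(self.e1a.forward(x))
        s2 = self.e2b.forward(self.e2a.forward(self.pool1.forward(s1)))
        t = self.b2.forward(self.b1.forward(self.pool2.forward(s2)))
        t = np.concatenate([self.up2.forward(t), s2], axis=1)
        self._w2 = t.shape[1] - s2.shape[1]
        t = self.d2b.forward(self.d2a.forward(t))
        t = np.concatenate([self.up1.forward(t), s1], axis=1)
        self._w1 = t.shape[1] - s1.shape[1]
        t = self.d1b.forward(self.d1a.forward(t))
        return self.head.forward(self.h1.forward(t)).transpose(0, 2, 3, 1)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy.transpose(0, 3, 1, 2))  # NHWC -> NCHW internal
        d = self.h1.backward(self.head.backward(dy))
        d = self.d1a.backward(self.d1b.backward(d))
        d, ds1 = d[:, : self._w1], d[:, self._w1 :]
        d = self.d2a.backward(self.d2b.backward(self.up1.backward(d)))
        d, ds2 = d[:, : self._w2], d[:, self._w2 :]
        d = self.pool2.backward(self.b1.backward(self.b2.backward(self.up2.backward(d))))
        d = self.pool1.backward(self.e2a.backward(self.e2b.backward(d + ds2)))
        return self.e1a.backward(self.e1b.backward(d + ds1)).transpose(0, 2, 3, 1)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def build_model(config: ModelConfig, seed: int = 0) -> ResUNet | UNet12:
    """Instantiate the configured network variant with seeded He-uniform weights."""
    if config.variant == "resunet31":
        return ResUNet(config, seed=seed)
    if config.variant == "unet12":
        return UNet12(config, seed=seed)
    raise ValueError(f"unknown variant {config.variant!r}")


def count_conv_layers(model: ResUNet | UNet12) -> int:
    """Number of 3x3 plus 1x1 convolutional layers in the built model."""
    return len(model.conv_layers())


def _resunet_trace_rows(config: ModelConfig, height: int, width: int):
    f, cout = config.base_filters, config.output_channels
    h, w = height, width
    rows = [
        ("C1", "CONV", (h, w, f)),
        ("C1", "Res", (h, w, f)),
        ("C2", "Res-Down", (h // 2, w // 2, 2 * f)),
        ("C2", "Res", (h // 2, w // 2, 2 * f)),
        ("C3", "Res-Down", (h // 4, w // 4, 4 * f)),
        ("C4", "Res-Down", (h // 8, w // 8, 8 * f)),
        ("C5", "Res-Down", (h // 16, w // 16, 8 * f)),
        ("C5", "Res", (h // 16, w // 16, 8 * f)),
        ("C6", "Upsampling", (h // 8, w // 8, 8 * f)),
        ("C7", "Res-Down-C", (h // 8, w // 8, 4 * f)),
        ("C7", "Upsampling", (h // 4, w // 4, 4 * f)),
        ("C8", "Res-Down-C", (h // 4, w // 4, 2 * f)),
        ("C8", "Upsampling", (h // 2, w // 2, 2 * f)),
        ("C9", "Res-Down-C", (h // 2, w // 2, f)),
        ("C9", "Upsampling", (h, w, f)),
        ("C10", "CONV", (h, w, f)),
        ("C10", "CONV", (h, w, config.head_mid_channels)),
        ("C10", "CONV", (h, w, cout)),
    ]
    return rows


def _unet12_trace_rows(config: ModelConfig, height: int, width: int):
    f, cout = config.base_filters, config.output_channels
    h, w = height, width
    return [
        ("L1", "CONV", (h, w, f)),
        ("L1", "CONV", (h, w, f)),
        ("L2", "CONV", (h // 2, w // 2, 2 * f)),
        ("L2", "CONV", (h // 2, w // 2, 2 * f)),
        ("L3", "CONV", (h // 4, w // 4, 4 * f)),
        ("L3", "CONV", (h // 4, w // 4, 4 * f)),
        ("L2'", "CONV", (h // 2, w // 2, 2 * f)),
        ("L2'", "CONV", (h // 2, w // 2, 2 * f)),
        ("L1'", "CONV", (h, w, f)),
        ("L1'", "CONV", (h, w, f)),
        ("head", "CONV", (h, w, config.head_mid_channels)),
        ("head", "CONV", (h, w, cout)),
    ]


def trace_shapes(
    model: ResUNet | UNet12, input_shape: tuple[int, int, int] | None = None
) -> LayerTrace:
    """Per-block output shapes (one row per architecture-table row).

    ``input_shape`` is (H, W, C); defaults to the model's configured input.
    The trace is derived from the block arithmetic; tests cross-check it
    against the shapes a real forward pass records.
    """
    config = model.config
    if input_shape is None:
        input_shape = (config.input_height, config.input_width, config.input_channels)
    h, w, c = input_shape
    if h % 16 or w % 16:
        raise ValueError(f"input dims must be divisible by 16, got {h}x{w}")
    if c != config.input_channels:
        raise ValueError(f"expected {config.input_channels} input channels, got {c}")
    rows_hw = (
        _resunet_trace_rows(config, h, w)
        if config.variant == "resunet31"
        else _unet12_trace_rows(config, h, w)
    )
    return LayerTrace(
        rows=[(lvl, blk, ("N", hh, ww, cc)) for lvl, blk, (hh, ww, cc) in rows_hw]
    )


def block_conv_counts(kind: str) -> tuple[int, int]:
    """(number of 3x3 convs, number of 1x1 convs) for a block kind."""
    return _BLOCK_CONV_COUNTS[kind]


# ---------------------------------------------------------------------------
# checkpoints: .npz weights + YAML config sidecar
# ---------------------------------------------------------------------------


def save_checkpoint(model: ResUNet | UNet12, path: str | Path, seed: int = 0) -> Path:
    """Write weights to ``<path>.npz`` and the config to ``<path>.yaml``."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path.with_suffix(".npz"), **arrays)
    cfg = {
        "model": {
            "input_height": model.config.input_height,
            "input_width": model.config.input_width,
            "input_channels": model.config.input_channels,
            "base_filters": model.config.base_filters,
            "output_channels": model.config.output_channels,
            "norm_groups": model.config.norm_groups,
            "variant": model.config.variant,
        },
        "seed": seed,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(cfg))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> ResUNet | UNet12:
    path = Path(path)
    cfg = yaml.safe_load(path.with_suffix(".yaml").read_text())
    config = ModelConfig(**cfg["model"])
    model = build_model(config, seed=int(cfg.get("seed", 0)))
    with np.load(path.with_suffix(".npz")) as data:
        params = model.params()
        if len(data.files) != len(params):
            raise ValueError(
                f"checkpoint has {len(data.files)} arrays, model expects {len(params)}"
            )
        for i, p in enumerate(params):
            arr = data[f"p{i}"]
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for parameter {i}: {arr.shape} vs {p.value.shape}")
            p.value = arr.astype(np.float32)
    return model
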