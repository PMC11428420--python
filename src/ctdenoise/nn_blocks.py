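"""Reusable network operators: anti-aliased down-sampling (blur-then-subsample),
sub-pixel up/down shuffling, spectral/instance/batch-normalized conv blocks,
channel and spatial squeeze-excitation gates, residual blocks, and the
hierarchical feature aggregator that fuses residual features with a 1x1
convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .autodiff import Tensor, as_tensor, concatenate, conv2d, pad2d
from .layers import (
    BatchNorm2d,
    Conv2d,
    Identity,
    InstanceNorm2d,
    LeakyReLU,
    Module,
    Parameter,
    SpectralNorm,
)

__all__ = [
    "BlockConfig",
    "make_blur_kernel",
    "blurpool",
    "BlurPool",
    "pixel_shuffle",
    "pixel_unshuffle",
    "PixelShuffle",
    "ConvBlock",
    "CSEGate",
    "SSEGate",
    "SCSEBlock",
    "ResidualBlock",
    "HFSModule",
]

_SUPPORTED_BLUR_SIZES = (2, 3, 4, 5)
_SCSE_MODES = ("cse", "sse", "scse", "none")
_SCSE_COMBINE = ("max", "add", "multiply")


@dataclass
class BlockConfig:
    width: int = 64
    negative_slope: float = 0.2
    blur_size: int = 3
    scse_mode: str = "scse"
    scse_reduction: int = 2
    scse_combine: str = "max"

    def __post_init__(self):
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if self.blur_size not in _SUPPORTED_BLUR_SIZES:
            raise ValueError(f"blur_size must be one of {_SUPPORTED_BLUR_SIZES}")
        if self.scse_mode not in _SCSE_MODES:
            raise ValueError(f"scse_mode must be one of {_SCSE_MODES}")
        if self.scse_combine not in _SCSE_COMBINE:
            raise ValueError(f"scse_combine must be one of {_SCSE_COMBINE}")
        if self.scse_mode in ("cse", "scse") and self.width % self.scse_reduction:
            raise ValueError("scse_reduction must divide width")


def make_blur_kernel(size: int) -> np.ndarray:
    """Normalized separable binomial blur kernel (outer product of a
    binomial row of order size-1)."""
    if size not in _SUPPORTED_BLUR_SIZES:
        raise ValueError(f"blur kernel size must be one of {_SUPPORTED_BLUR_SIZES}")
    row = np.array([comb(size - 1, i, exact=True) for i in range(size)], dtype=np.float64)
    kernel = np.outer(row, row)
    return kernel / kernel.sum()


def blurpool(x: Tensor | np.ndarray, stride: int = 2, blur_size: int = 3) -> Tensor:
    """Anti-aliased down-sampling: blur under reflection padding, then
    subsample every stride-th row/column starting at index 0.

    Accepts NCHW input; output spatial size is ceil(input / stride) and the
    channel count is unchanged.  A constant map stays constant because the
    kernel is normalized.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    x = as_tensor(x)
    if x.ndim != 4:
        raise ValueError("blurpool expects NCHW input")
    n, c, h, w = x.shape
    if h < blur_size or w < blur_size:
        raise ValueError("spatial extent must be >= blur_size")
    kernel = make_blur_kernel(blur_size).astype(x.dtype)
    # depthwise: fold channels into the batch axis, convolve with one kernel
    flat = x.reshape(n * c, 1, h, w)
    pt = (blur_size - 1) // 2
    pb = blur_size - 1 - pt
    padded = pad2d(flat, (pt, pb, pt, pb), mode="reflect")
    out = conv2d(padded, Tensor(kernel.reshape(1, 1, blur_size, blur_size)),
                 stride=stride)
    ho, wo = out.shape[-2], out.shape[-1]
    return out.reshape(n, c, ho, wo)


class BlurPool(Module):
    def __init__(self, stride: int = 2, blur_size: int = 3):
        super().__init__()
        self.stride = stride
        self.blur_size = blur_size

    def forward(self, x: Tensor) -> Tensor:
        return blurpool(x, self.stride, self.blur_size)


def pixel_shuffle(x: Tensor | np.ndarray, r: int) -> Tensor:
    """Rearrange (N, C*r^2, H, W) -> (N, C, H*r, W*r).

    Output channel c at (r*h + i, r*w + j) takes input channel c*r^2 + i*r + j
    at (h, w); exact inverse of :func:`pixel_unshuffle`.
    """
    x = as_tensor(x)
    n, cr2, h, w = x.shape
    if r < 1:
        raise ValueError("upscale factor must be >= 1")
    if cr2 % (r * r):
        raise ValueError(f"channels ({cr2}) not divisible by r^2 ({r * r})")
    c = cr2 // (r * r)
    out = x.reshape(n, c, r, r, h, w)
    out = out.transpose(0, 1, 4, 2, 5, 3)  # (n, c, h, r, w, r)
    return out.reshape(n, c, h * r, w * r)


def pixel_unshuffle(x: Tensor | np.ndarray, r: int) -> Tensor:
    """Exact inverse of :func:`pixel_shuffle`."""
    x = as_tensor(x)
    n, c, hr, wr = x.shape
    if r < 1:
        raise ValueError("downscale factor must be >= 1")
    if hr % r or wr % r:
        raise ValueError("spatial extent not divisible by r")
    h, w = hr // r, wr // r
    out = x.reshape(n, c, h, r, w, r)
    out = out.transpose(0, 1, 3, 5, 2, 4)  # (n, c, r, r, h, w)
    return out.reshape(n, c * r * r, h, w)


class PixelShuffle(Module):
    def __init__(self, r: int):
        super().__init__()
        self.r = r

    def forward(self, x: Tensor) -> Tensor:
        return pixel_shuffle(x, self.r)


class ConvBlock(Module):
    """Conv (optionally spectrally normalized) -> norm -> LeakyReLU.

    Spatial size is preserved (padding = kernel // 2).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 negative_slope: float = 0.2, use_spectral_norm: bool = True,
                 norm: str = "instance"):
        super().__init__()
        conv = Conv2d(in_channels, out_channels, kernel_size,
                      padding=kernel_size // 2)
        self.conv = SpectralNorm(conv) if use_spectral_norm else conv
        if norm == "instance":
            self.norm = InstanceNorm2d(out_channels)
        elif norm == "batch":
            self.norm = BatchNorm2d(out_channels)
        elif norm == "none":
            self.norm = Identity()
        else:
            raise ValueError(f"unknown norm {norm!r}")
        self.act = LeakyReLU(negative_slope)

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.norm(self.conv(x)))


class CSEGate(Module):
    """Channel squeeze-excitation: global average pool -> bottleneck ->
    sigmoid -> per-channel multiplicative gate."""

    def __init__(self, channels: int, reduction: int = 2):
        super().__init__()
        if channels % reduction:
            raise ValueError("reduction must divide channels")
        hidden = channels // reduction
        rng = np.random.default_rng(2)
        s1 = 1.0 / np.sqrt(channels)
        s2 = 1.0 / np.sqrt(hidden)
        self.w1 = Parameter(rng.uniform(-s1, s1, (channels, hidden)))
        self.b1 = Parameter(np.zeros(hidden))
        self.w2 = Parameter(rng.uniform(-s2, s2, (hidden, channels)))
        self.b2 = Parameter(np.zeros(channels))

    def gate(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3))  # (N, C)
        hidden = (pooled @ self.w1 + self.b1).relu()
        g = (hidden @ self.w2 + self.b2).sigmoid()  # (N, C)
        n, c = g.shape
        return g.reshape(n, c, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class SSEGate(Module):
    """Spatial squeeze-excitation: 1x1 conv to one channel -> sigmoid ->
    spatial gate broadcast over channels."""

    def __init__(self, channels: int):
        super().__init__()
        self.conv = Conv2d(channels, 1, kernel_size=1)

    def gate(self, x: Tensor) -> Tensor:
        return self.conv(x).sigmoid()  # (N, 1, H, W)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class SCSEBlock(Module):
    """Combined channel + spatial squeeze-excitation.

    ``mode`` selects the cse or sse branch alone (ablation arms) or both;
    branch outputs are combined elementwise (max by default).
    """

    def __init__(self, channels: int, cfg: BlockConfig):
        super().__init__()
        self.mode = cfg.scse_mode
        self.combine = cfg.scse_combine
        if self.mode in ("cse", "scse"):
            self.cse = CSEGate(channels, cfg.scse_reduction)
        if self.mode in ("sse", "scse"):
            self.sse = SSEGate(channels)

    def forward(self, x: Tensor) -> Tensor:
        if self.mode == "none":
            return x
        if self.mode == "cse":
            return self.cse(x)
        if self.mode == "sse":
            return self.sse(x)
        a = self.cse(x)
        b = self.sse(x)
        if self.combine == "max":
            # max(a,b) = a + relu(b - a), differentiable a.e.
            return a + (b - a).relu()
        if self.combine == "add":
            return a + b
        if self.combine == "multiply":
            return a * b
        raise ValueError(f"unknown combine mode {self.combine!r}")


class ResidualBlock(Module):
    """conv_block -> conv (no activation) -> scSE, added back onto the input.

    ``forward`` returns ``(trunk, residual_feature)`` so the aggregator can
    fuse residual features across blocks; ``trunk - x == residual_feature``.
    """

    def __init__(self, cfg: BlockConfig, use_spectral_norm: bool = True):
        super().__init__()
        c = cfg.width
        self.block1 = ConvBlock(c, c, negative_slope=cfg.negative_slope,
                                use_spectral_norm=use_spectral_norm)
        self.conv2 = Conv2d(c, c, kernel_size=3, padding=1)
        self.scse = SCSEBlock(c, cfg)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        res = self.scse(self.conv2(self.block1(x)))
        return x + res, res


class HFSModule(Module):
    """Hierarchical feature aggregator over three residual blocks.

    The blocks run sequentially; their three residual features are
    concatenated with the last trunk output (4C channels), fused back to C
    channels by a 1x1 convolution, and added to the module input.  With the
    fuse convolution zero-initialized the module is exactly the identity.
    """

    def __init__(self, cfg: BlockConfig, n_blocks: int = 3,
                 use_spectral_norm: bool = True):
        super().__init__()
        self.n_blocks = n_blocks
        self.blocks = [ResidualBlock(cfg, use_spectral_norm) for _ in range(n_blocks)]
        for i, b in enumerate(self.blocks):
            setattr(self, f"block{i}", b)
        self.fuse = Conv2d(cfg.width * (n_blocks + 1), cfg.width, kernel_size=1)

    def zero_init_fuse(self) -> None:
        self.fuse.weight.data = np.zeros_like(self.fuse.weight.data)
        self.fuse.bias.data = np.zeros_like(self.fuse.bias.data)

    def forward(self, x: Tensor) -> Tensor:
        trunk = x
        residuals = []
        for block in self.blocks:
            trunk, res = block(trunk)
            residuals.append(res)
        fused = self.fuse(concatenate(residuals + [trunk], axis=1))
        return x + fused
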