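"""Multi-scale patch discriminator bank.

Three discriminators judge realism at full, half and quarter input sizes
(512/256/128 at training resolution).  Each one stacks: a first block of
spectrally normalized conv -> batch norm -> LeakyReLU -> anti-aliased pool,
further blocks of the same layout without the batch norm, and a final head of
rows-only zero padding followed by a 4x4 stride-1 convolution to one channel.
Down-sampling again happens only through the blur-then-subsample pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, pad2d
from .ct_io import CTImage
from .layers import BatchNorm2d, Conv2d, LeakyReLU, Module, SpectralNorm
from .nn_blocks import BlurPool

__all__ = [
    "DiscriminatorConfig",
    "ScaleDiscriminator",
    "DiscriminatorBank",
    "make_multiscale_inputs",
    "multiscale_scores",
    "score_map_size",
]


@dataclass
class DiscriminatorConfig:
    n_scales: int = 3
    input_size: int = 512            # size of the largest (D1) input
    base_width: int = 64
    n_blocks: int = 4                # down-sampling blocks per scale
    blur_size: int = 3
    negative_slope: float = 0.2
    input_mode: str = "random_crop"  # or "pyramid"

    def __post_init__(self):
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.input_mode not in ("random_crop", "pyramid"):
            raise ValueError("input_mode must be 'random_crop' or 'pyramid'")
        if self.input_size % (2 ** (self.n_scales - 1)):
            raise ValueError("input_size must be divisible by 2^(n_scales-1)")

    @property
    def input_sizes(self) -> tuple[int, ...]:
        """Strictly decreasing per-scale input sizes (full, half, quarter...)."""
        return tuple(self.input_size // (2 ** i) for i in range(self.n_scales))


class _DiscBlock(Module):
    """SN conv (stride 1) -> optional batch norm -> LeakyReLU -> blurpool."""

    def __init__(self, in_channels: int, out_channels: int,
                 cfg: DiscriminatorConfig, with_batchnorm: bool):
        super().__init__()
        # reflect padding keeps constant inputs constant through the stack
        self.conv = SpectralNorm(Conv2d(in_channels, out_channels, 3, padding=1,
                                        pad_mode="reflect"))
        self.with_batchnorm = with_batchnorm
        if with_batchnorm:
            self.bn = BatchNorm2d(out_channels)
        self.act = LeakyReLU(cfg.negative_slope)
        self.pool = BlurPool(stride=2, blur_size=cfg.blur_size)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.with_batchnorm:
            y = self.bn(y)
        return self.pool(self.act(y))


class ScaleDiscriminator(Module):
    """One patch discriminator; emits a spatial score map."""

    def __init__(self, cfg: DiscriminatorConfig, in_channels: int = 1):
        super().__init__()
        self.cfg = cfg
        self.blocks: list[_DiscBlock] = []
        w_in = in_channels
        w_out = cfg.base_width
        for i in range(cfg.n_blocks):
            block = _DiscBlock(w_in, w_out, cfg, with_batchnorm=(i == 0))
            setattr(self, f"block{i}", block)
            self.blocks.append(block)
            w_in = w_out
            w_out = min(w_out * 2, cfg.base_width * 8)
        # rows-only zero padding, then 4x4 stride-1 conv to one channel
        self.head = SpectralNorm(Conv2d(w_in, 1, kernel_size=4, padding=0))

    def forward(self, x: Tensor, probability: bool = True) -> Tensor:
        x = as_tensor(x)
        for block in self.blocks:
            x = block(x)
        x = pad2d(x, (1, 1, 0, 0), mode="zero")  # pad 1 on top and bottom only
        logits = self.head(x)
        return logits.sigmoid() if probability else logits


def score_map_size(input_size: int, n_blocks: int) -> tuple[int, int]:
    """Closed-form output spatial size of :class:`ScaleDiscriminator`.

    Each block preserves size through its padded conv then halves it
    (ceil) through the pool; the head pads rows by 1+1 and applies a 4x4
    stride-1 valid convolution.
    """
    h = w = input_size
    for _ in range(n_blocks):
        h = -(-h // 2)
        w = -(-w // 2)
    return (h + 2 - 4 + 1, w - 4 + 1)


def make_multiscale_inputs(img: CTImage | np.ndarray, cfg: DiscriminatorConfig,
                           rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """Produce the per-scale discriminator inputs for one image.

    random_crop mode: scale 1 sees the full image; smaller scales see random
    crops of the stated sizes at native resolution.  pyramid mode: successive
    anti-aliased down-scalings.
    """
    if rng is None:
        rng = np.random.default_rng()
    pixels = img.pixels if isinstance(img, CTImage) else np.asarray(img)
    h, w = pixels.shape
    sizes = tuple(h // (2 ** i) for i in range(cfg.n_scales))
    outputs = [pixels]
    if cfg.input_mode == "random_crop":
        for size in sizes[1:]:
            if size > min(h, w):
                raise ValueError(f"crop size {size} exceeds image {(h, w)}")
            r = int(rng.integers(0, h - size + 1))
            c = int(rng.integers(0, w - size + 1))
            outputs.append(pixels[r:r + size, c:c + size].copy())
    else:
        from .nn_blocks import blurpool

        current = pixels
        for _ in sizes[1:]:
            t = blurpool(current.reshape(1, 1, *current.shape), stride=2,
                         blur_size=cfg.blur_size)
            current = t.numpy().reshape(t.shape[-2], t.shape[-1])
            outputs.append(current)
    return outputs


def multiscale_inputs_tensor(x: Tensor, cfg: DiscriminatorConfig,
                             rng: np.random.Generator | None = None) -> list[Tensor]:
    """Tensor twin of :func:`make_multiscale_inputs` (NCHW in, gradients flow
    through the crops so the generator can be trained through them)."""
    if rng is None:
        rng = np.random.default_rng()
    x = as_tensor(x)
    if x.ndim != 4:
        raise ValueError("expected NCHW input")
    h, w = x.shape[-2], x.shape[-1]
    sizes = tuple(h // (2 ** i) for i in range(cfg.n_scales))
    outputs = [x]
    if cfg.input_mode == "random_crop":
        for size in sizes[1:]:
            r = int(rng.integers(0, h - size + 1))
            c = int(rng.integers(0, w - size + 1))
            outputs.append(x[:, :, r:r + size, c:c + size])
    else:
        from .nn_blocks import blurpool

        current = x
        for _ in sizes[1:]:
            current = blurpool(current, stride=2, blur_size=cfg.blur_size)
            outputs.append(current)
    return outputs


class DiscriminatorBank(Module):
    """N discriminators, one per scale, applied to their own inputs."""

    def __init__(self, cfg: DiscriminatorConfig, in_channels: int = 1):
        super().__init__()
        self.cfg = cfg
        self.scales: list[ScaleDiscriminator] = []
        for i in range(cfg.n_scales):
            d = ScaleDiscriminator(cfg, in_channels)
            setattr(self, f"d{i + 1}", d)
            self.scales.append(d)

    def forward(self, inputs: list, probability: bool = True) -> list[Tensor]:
        if len(inputs) != self.cfg.n_scales:
            raise ValueError(
                f"expected {self.cfg.n_scales} inputs, got {len(inputs)}"
            )
        scores = []
        for d, x in zip(self.scales, inputs):
            x = as_tensor(x)
            if x.ndim == 2:
                x = x.reshape(1, 1, *x.shape)
            scores.append(d(x, probability=probability))
        return scores


def multiscale_scores(bank: DiscriminatorBank, img: CTImage | np.ndarray,
                      cfg: DiscriminatorConfig | None = None,
                      rng: np.random.Generator | None = None,
                      probability: bool = True) -> list[Tensor]:
    """Apply the bank to per-scale inputs of one image; list ordered D1..DN."""
    cfg = cfg or bank.cfg
    inputs = make_multiscale_inputs(img, cfg, rng)
    return bank(inputs, probability=probability)
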