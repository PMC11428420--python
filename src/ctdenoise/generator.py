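"""Anti-aliased image-to-image generator.

Layout: reflection-padded 7x7 head -> encoder stages (spectrally normalized
stride-1 conv, instance norm, LeakyReLU, blur-then-subsample) with width
doubling -> hierarchical feature aggregator core -> decoder stages
(spectrally normalized conv expanding channels by r^2, instance norm,
LeakyReLU, sub-pixel shuffle) -> reflection-padded 7x7 tail with sigmoid.
Down-sampling happens only through the anti-aliased pool; no bare strided
convolution appears anywhere in the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, pad2d
from .ct_io import CTImage, DomainTag
from .layers import Conv2d, InstanceNorm2d, LeakyReLU, Module, SpectralNorm
from .nn_blocks import BlockConfig, BlurPool, HFSModule, PixelShuffle

__all__ = ["GeneratorConfig", "Generator", "build_generator", "generator_forward"]


@dataclass
class GeneratorConfig:
    in_channels: int = 1
    base_width: int = 64
    n_down: int = 2
    n_hfs: int = 3
    upscale_factor: int = 2
    blur_size: int = 3
    negative_slope: float = 0.2
    scse_mode: str = "scse"
    scse_reduction: int = 2
    scse_combine: str = "max"
    head_kernel: int = 7
    # start every HFS module as the identity map (zero 1x1 fuse conv);
    # applied after weight initialization
    zero_init_hfs_fuse: bool = False
    # multiply the tail conv weights by this factor after initialization;
    # < 1 starts the sigmoid output near mid-range, avoiding the saturation
    # trap that can stall short training runs
    tail_init_scale: float = 1.0

    def __post_init__(self):
        if self.upscale_factor ** self.n_down != 2 ** self.n_down and self.upscale_factor != 2:
            # decoder must undo the encoder's total stride-2 down-sampling
            raise ValueError(
                "upscale_factor^n_down must recover the encoder down-sampling "
                "(encoder stages use stride 2, so upscale_factor must be 2)"
            )
        if self.base_width < 1 or self.n_down < 1 or self.n_hfs < 1:
            raise ValueError("base_width, n_down and n_hfs must be >= 1")


class _Reflect7Conv(Module):
    """Reflection padding followed by a kxk convolution (stride 1)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 7):
        super().__init__()
        self.kernel = kernel
        self.conv = Conv2d(in_channels, out_channels, kernel, padding=0)

    def forward(self, x: Tensor) -> Tensor:
        p = self.kernel // 2
        return self.conv(pad2d(x, (p, p, p, p), mode="reflect"))


class _EncoderStage(Module):
    """Spectral-norm conv (stride 1) -> instance norm -> LeakyReLU -> blurpool."""

    def __init__(self, in_channels: int, out_channels: int, cfg: GeneratorConfig):
        super().__init__()
        self.conv = SpectralNorm(Conv2d(in_channels, out_channels, 3, padding=1))
        self.norm = InstanceNorm2d(out_channels)
        self.act = LeakyReLU(cfg.negative_slope)
        self.pool = BlurPool(stride=2, blur_size=cfg.blur_size)

    def forward(self, x: Tensor) -> Tensor:
        return self.pool(self.act(self.norm(self.conv(x))))


class _DecoderStage(Module):
    """Spectral-norm conv expanding channels x r^2 -> instance norm ->
    LeakyReLU -> sub-pixel shuffle."""

    def __init__(self, in_channels: int, out_channels: int, cfg: GeneratorConfig):
        super().__init__()
        r = cfg.upscale_factor
        self.conv = SpectralNorm(
            Conv2d(in_channels, out_channels * r * r, 3, padding=1)
        )
        self.norm = InstanceNorm2d(out_channels * r * r)
        self.act = LeakyReLU(cfg.negative_slope)
        self.shuffle = PixelShuffle(r)

    def forward(self, x: Tensor) -> Tensor:
        return self.shuffle(self.act(self.norm(self.conv(x))))


class Generator(Module):
    def __init__(self, cfg: GeneratorConfig):
        super().__init__()
        self.cfg = cfg
        w = cfg.base_width
        self.head = _Reflect7Conv(cfg.in_channels, w, cfg.head_kernel)
        self.head_norm = InstanceNorm2d(w)
        self.head_act = LeakyReLU(cfg.negative_slope)

        self.encoder_stages: list[_EncoderStage] = []
        widths = [w * (2 ** i) for i in range(cfg.n_down + 1)]
        for i in range(cfg.n_down):
            stage = _EncoderStage(widths[i], widths[i + 1], cfg)
            setattr(self, f"enc{i}", stage)
            self.encoder_stages.append(stage)

        core_width = widths[-1]
        block_cfg = BlockConfig(width=core_width,
                                negative_slope=cfg.negative_slope,
                                blur_size=cfg.blur_size,
                                scse_mode=cfg.scse_mode,
                                scse_reduction=cfg.scse_reduction,
                                scse_combine=cfg.scse_combine)
        self.hfs_modules: list[HFSModule] = []
        for i in range(cfg.n_hfs):
            mod = HFSModule(block_cfg)
            setattr(self, f"hfs{i}", mod)
            self.hfs_modules.append(mod)

        self.decoder_stages: list[_DecoderStage] = []
        for i in range(cfg.n_down):
            stage = _DecoderStage(widths[cfg.n_down - i], widths[cfg.n_down - i - 1], cfg)
            setattr(self, f"dec{i}", stage)
            self.decoder_stages.append(stage)

        self.tail = _Reflect7Conv(w, 1, cfg.head_kernel)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if x.ndim != 4:
            raise ValueError("generator expects NCHW input")
        h, w = x.shape[-2], x.shape[-1]
        factor = 2 ** self.cfg.n_down
        if h % factor or w % factor:
            raise ValueError(
                f"input size {(h, w)} not divisible by 2^n_down = {factor}"
            )
        y = self.head_act(self.head_norm(self.head(x)))
        for stage in self.encoder_stages:
            y = stage(y)
        for mod in self.hfs_modules:
            y = mod(y)
        for stage in self.decoder_stages:
            y = stage(y)
        return self.tail(y).sigmoid()


def build_generator(cfg: GeneratorConfig | None = None) -> Generator:
    return Generator(cfg or GeneratorConfig())


def generator_forward(G: Generator, img: CTImage) -> CTImage:
    """Run a normalized slice through the generator.

    Deterministic given weights: instance normalization uses per-sample
    statistics, so no global state is consulted.
    """
    if not img.normalized:
        raise ValueError("generator_forward expects a min-max normalized image")
    h, w = img.pixels.shape
    dtype = G.head.conv.weight.dtype
    x = Tensor(img.pixels.reshape(1, 1, h, w).astype(dtype))
    was_training = G.training
    G.eval()
    try:
        from .autodiff import no_grad

        with no_grad():
            out = G(x).numpy().reshape(h, w)
    finally:
        G.train(was_training)
    return CTImage(pixels=out, domain_tag=DomainTag.GENERATED, normalized=True,
                   background_value=img.background_value,
                   source_id=img.source_id, norm_min=img.norm_min,
                   norm_max=img.norm_max)
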