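"""CT slice I/O, min-max normalization, ROI masking and patch sampling.

The scan cylinder of a reconstructed CT slice is surrounded by a sentinel
intensity (``background_value``, conventionally -2048); the ROI mask and the
rejection-sampled patch extraction below confine training and evaluation to
the anatomy inside the cylinder.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dicom import read_dicom, write_dicom

__all__ = [
    "DomainTag",
    "CTImage",
    "Patch",
    "ConstantImageError",
    "PatchSamplingError",
    "minmax_normalize",
    "denormalize",
    "compute_roi_mask",
    "sample_patch",
    "read_image",
    "write_image",
]

DEFAULT_BACKGROUND = -2048.0


class DomainTag(str, enum.Enum):
    LOW_DOSE = "low_dose"
    STANDARD_DOSE = "standard_dose"
    GENERATED = "generated"
    CLEAN_REFERENCE = "clean_reference"


class ConstantImageError(ValueError):
    """Raised when min-max normalization meets a constant image."""


class PatchSamplingError(RuntimeError):
    """Raised when no admissible patch is found within ``max_attempts``."""


@dataclass
class CTImage:
    """One 2D grayscale slice with domain bookkeeping.

    ``pixels`` are HU-like raw intensities, or values in [0, 1] when
    ``normalized`` is set; ``norm_min``/``norm_max`` retain the raw range so
    the normalization is invertible.
    """

    pixels: np.ndarray
    domain_tag: DomainTag = DomainTag.LOW_DOSE
    normalized: bool = False
    background_value: float = DEFAULT_BACKGROUND
    source_id: str = ""
    norm_min: float | None = None
    norm_max: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if isinstance(self.domain_tag, str) and not isinstance(self.domain_tag, DomainTag):
            self.domain_tag = DomainTag(self.domain_tag)
        self.validate()

    def validate(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        h, w = self.pixels.shape
        if h < 1 or w < 1:
            raise ValueError("image dimensions must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.normalized:
            lo, hi = self.pixels.min(), self.pixels.max()
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(
                    f"normalized image outside [0,1]: range [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class Patch:
    """A square crop of a CT slice."""

    pixels: np.ndarray
    origin: tuple[int, int]
    foreground_fraction: float
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        h, w = self.pixels.shape
        if h != w:
            raise ValueError("patch must be square")
        if not 0.0 <= self.foreground_fraction <= 1.0:
            raise ValueError("foreground_fraction must be in [0, 1]")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def minmax_normalize(img: CTImage) -> CTImage:
    """Map pixel values to [0, 1] via (X - min) / (max - min).

    The raw min/max are retained on the result for :func:`denormalize`.
    """
    lo = float(img.pixels.min())
    hi = float(img.pixels.max())
    if hi <= lo:
        raise ConstantImageError(
            f"cannot min-max normalize a constant image (value {lo}, "
            f"source {img.source_id or '<unknown>'})"
        )
    pixels = (img.pixels - lo) / (hi - lo)
    return replace(img, pixels=pixels, normalized=True, norm_min=lo, norm_max=hi)


def denormalize(img: CTImage, orig_min: float | None = None,
                orig_max: float | None = None) -> CTImage:
    """Invert :func:`minmax_normalize` given the original intensity range."""
    if not img.normalized:
        raise ValueError("denormalize expects a normalized image")
    if orig_min is None:
        orig_min = img.norm_min
    if orig_max is None:
        orig_max = img.norm_max
    if orig_min is None or orig_max is None:
        raise ValueError("original min/max unknown; pass orig_min/orig_max")
    if orig_max <= orig_min:
        raise ValueError(f"orig_max ({orig_max}) must exceed orig_min ({orig_min})")
    pixels = img.pixels * (orig_max - orig_min) + orig_min
    return replace(img, pixels=pixels, normalized=False, norm_min=None, norm_max=None)


def compute_roi_mask(img: CTImage, tol: float = 1.0) -> np.ndarray:
    """Boolean mask of the scan cylinder: pixel > background_value + tol.

    Contract: applied to raw (unnormalized) intensities; normalization
    destroys the background sentinel.
    """
    if img.normalized:
        raise ValueError("compute_roi_mask operates on raw intensities")
    return img.pixels > (img.background_value + tol)


def sample_patch(img: CTImage, mask: np.ndarray, size: int = 128,
                 min_foreground_frac: float = 0.5,
                 rng: np.random.Generator | None = None,
                 max_attempts: int = 100) -> Patch:
    """Rejection-sample a square patch whose ROI coverage meets the threshold.

    Top-left corners are drawn uniformly over all in-bounds positions; a draw
    is rejected when the fraction of mask-true pixels inside the patch falls
    below ``min_foreground_frac``.
    """
    if rng is None:
        rng = np.random.default_rng()
    h, w = img.pixels.shape
    if size > min(h, w):
        raise ValueError(f"patch size {size} exceeds image extent {(h, w)}")
    if not 0.0 <= min_foreground_frac <= 1.0:
        raise ValueError("min_foreground_frac must be in [0, 1]")
    if mask.shape != img.pixels.shape:
        raise ValueError("mask shape must match image shape")

    area = float(size * size)
    for _ in range(max_attempts):
        r = int(rng.integers(0, h - size + 1))
        c = int(rng.integers(0, w - size + 1))
        frac = float(mask[r:r + size, c:c + size].sum()) / area
        if frac >= min_foreground_frac:
            return Patch(
                pixels=img.pixels[r:r + size, c:c + size].copy(),
                origin=(r, c),
                foreground_fraction=frac,
                source_id=img.source_id,
            )
    raise PatchSamplingError(
        f"no patch with foreground fraction >= {min_foreground_frac} found in "
        f"{max_attempts} attempts (size {size}, source "
        f"{img.source_id or '<unknown>'})"
    )


# -- file I/O -------------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        return "dicom"
    if suffix == ".png":
        return "png"
    if suffix == ".npz":
        return "npz"
    raise ValueError(f"cannot infer image format from {path}")


def read_image(path, fmt: str | None = None,
               domain_tag: DomainTag = DomainTag.LOW_DOSE,
               background_value: float = DEFAULT_BACKGROUND) -> CTImage:
    """Read a CT slice from DICOM, PNG or NPZ.

    DICOM rescale slope/intercept are applied so pixels come back in HU.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    fmt = _infer_format(path, fmt)
    if fmt == "dicom":
        pixels, _ = read_dicom(path)
    elif fmt == "png":
        import imageio.v3 as iio

        pixels = np.asarray(iio.imread(path), dtype=np.float64)
        if pixels.ndim == 3:
            raise ValueError(f"expected grayscale PNG, got shape {pixels.shape}: {path}")
    elif fmt == "npz":
        with np.load(path) as data:
            if "pixels" in data:
                pixels = data["pixels"]
            else:
                pixels = data[data.files[0]]
        pixels = np.asarray(pixels, dtype=np.float64)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return CTImage(pixels=pixels, domain_tag=domain_tag,
                   background_value=background_value, source_id=str(path))


def write_image(img: CTImage, path, fmt: str | None = None,
                png_bits: int = 16) -> None:
    """Write a CT slice; NPZ round-trips bit-exactly, PNG to declared depth."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "npz":
        np.savez(path, pixels=img.pixels,
                 normalized=np.asarray(img.normalized),
                 background_value=np.asarray(img.background_value))
    elif fmt == "png":
        import imageio.v3 as iio

        if png_bits not in (8, 16):
            raise ValueError("png_bits must be 8 or 16")
        lo, hi = img.pixels.min(), img.pixels.max()
        span = hi - lo if hi > lo else 1.0
        maxval = 2 ** png_bits - 1
        scaled = np.round((img.pixels - lo) / span * maxval)
        dtype = np.uint8 if png_bits == 8 else np.uint16
        iio.imwrite(path, scaled.astype(dtype))
    elif fmt == "dicom":
        write_dicom(path, img.pixels)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
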