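"""Synthetic unpaired low-dose / standard-dose CT phantom generator.

Each phantom is an elliptical "body" on a sentinel background, optionally
ringed by a high-intensity rim (bone analog), containing a random number of
elliptical "organs" at distinct intensities.  Dose-dependent noise is applied
in the image domain: zero-mean Gaussian plus signal-dependent (Poisson-like)
noise, both with standard deviation scaling as sqrt(reference_dose / dose),
plus low-dose directional streaks.  The reference dose is 150 mA, so the
standard-dose rendering uses ``gaussian_sigma_ref`` exactly and the low-dose
rendering (30 mA) is sqrt(5) times noisier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ct_io import CTImage, DomainTag, DEFAULT_BACKGROUND

__all__ = [
    "PhantomSpec",
    "UnpairedDataset",
    "generate_clean_phantom",
    "apply_dose_noise",
    "make_unpaired_dataset",
    "REFERENCE_DOSE_MA",
    "LOW_DOSE_MA",
    "STANDARD_DOSE_MA",
]

REFERENCE_DOSE_MA = 150.0
LOW_DOSE_MA = 30.0
STANDARD_DOSE_MA = 150.0


@dataclass
class PhantomSpec:
    image_size: int = 512
    n_organs_range: tuple[int, int] = (2, 5)
    background_value: float = DEFAULT_BACKGROUND
    body_intensity_range: tuple[float, float] = (20.0, 80.0)
    organ_intensity_range: tuple[float, float] = (120.0, 400.0)
    rim_intensity_range: tuple[float, float] = (700.0, 1200.0)
    with_rim: bool = True
    dose_mA: float = STANDARD_DOSE_MA
    gaussian_sigma_ref: float = 10.0
    poisson_coeff: float = 0.5
    streak_amplitude: float = 12.0
    streak_dose_threshold: float = 100.0
    n_streaks: int = 4
    # detector/reconstruction dynamic range (12-bit CT analog); noisy
    # renderings are clipped into it.  None disables clipping.
    clip_range: tuple[float, float] | None = (-2048.0, 2047.0)
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.dose_mA <= 0:
            raise ValueError("dose_mA must be positive")
        for name in ("n_organs_range", "body_intensity_range",
                     "organ_intensity_range", "rim_intensity_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (lo <= hi)")
        if self.streak_amplitude < 0:
            raise ValueError("streak_amplitude must be >= 0")


def _ellipse_mask(size: int, cy: float, cx: float, ay: float, ax: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def generate_clean_phantom(spec: PhantomSpec,
                           rng: np.random.Generator | None = None,
                           source_id: str = "phantom",
                           ) -> tuple[CTImage, list[dict]]:
    """Draw one clean phantom; returns the image plus per-shape metadata."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    pixels = np.full((n, n), spec.background_value, dtype=np.float64)
    shapes: list[dict] = []

    cy = n / 2 + rng.uniform(-0.04, 0.04) * n
    cx = n / 2 + rng.uniform(-0.04, 0.04) * n
    ay = rng.uniform(0.30, 0.42) * n
    ax = rng.uniform(0.30, 0.42) * n
    body_val = rng.uniform(*spec.body_intensity_range)

    if spec.with_rim:
        rim_val = rng.uniform(*spec.rim_intensity_range)
        rim_thickness = max(2.0, 0.02 * n)
        rim = _ellipse_mask(n, cy, cx, ay + rim_thickness, ax + rim_thickness)
        pixels[rim] = rim_val
        shapes.append({"kind": "rim", "center": (cy, cx),
                       "axes": (ay + rim_thickness, ax + rim_thickness),
                       "intensity": rim_val})

    body = _ellipse_mask(n, cy, cx, ay, ax)
    pixels[body] = body_val
    shapes.append({"kind": "body", "center": (cy, cx), "axes": (ay, ax),
                   "intensity": body_val})

    lo_n, hi_n = spec.n_organs_range
    n_organs = int(rng.integers(lo_n, hi_n + 1))
    placed: list[tuple[float, float, float]] = []  # (cy, cx, bounding radius)
    for i in range(n_organs):
        for attempt in range(300):
            # organs shrink over retries so crowded layouts still resolve
            shrink = max(1.0 - attempt / 120.0, 0.12)
            oa_y = rng.uniform(0.04, 0.13) * n * shrink
            oa_x = rng.uniform(0.04, 0.13) * n * shrink
            if oa_y >= ay or oa_x >= ax:
                continue  # organ cannot exceed the body
            # keep the organ ellipse inside the body ellipse: place its center
            # so that center + axes stays within a shrunken body
            margin_y = ay - oa_y
            margin_x = ax - oa_x
            ocy = cy + rng.uniform(-0.8, 0.8) * margin_y
            ocx = cx + rng.uniform(-0.8, 0.8) * margin_x
            # conservative containment check on the organ's bounding box corners
            corners_ok = all(
                ((py - cy) / ay) ** 2 + ((px - cx) / ax) ** 2 <= 1.0
                for py in (ocy - oa_y, ocy + oa_y)
                for px in (ocx - oa_x, ocx + oa_x)
            )
            if not corners_ok:
                continue
            # organs must not overlap: conservative bounding-circle test
            radius = max(oa_y, oa_x)
            if any(np.hypot(ocy - py, ocx - px) <= radius + pr + 1.0
                   for py, px, pr in placed):
                continue
            placed.append((ocy, ocx, radius))
            organ_val = rng.uniform(*spec.organ_intensity_range)
            organ = _ellipse_mask(n, ocy, ocx, oa_y, oa_x)
            pixels[organ] = organ_val
            shapes.append({"kind": "organ", "center": (ocy, ocx),
                           "axes": (oa_y, oa_x), "intensity": organ_val})
            break
        else:
            raise RuntimeError(
                f"could not place organ {i} inside the body after 300 retries"
            )

    if spec.clip_range is not None:
        fg = pixels > spec.background_value
        pixels = np.where(fg, np.clip(pixels, *spec.clip_range), pixels)
    img = CTImage(pixels=pixels, domain_tag=DomainTag.CLEAN_REFERENCE,
                  background_value=spec.background_value, source_id=source_id)
    return img, shapes


def _streak_pattern(size: int, amplitude: float, n_streaks: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Zero-mean oriented streak noise: 1D correlated profiles swept along
    random directions, mimicking photon-starvation streak artifacts."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    yy -= size / 2
    xx -= size / 2
    pattern = np.zeros((size, size))
    n_bins = 2 * size
    for _ in range(n_streaks):
        theta = rng.uniform(0, np.pi)
        profile = rng.normal(size=n_bins)
        # smooth the profile so streaks are a few pixels wide
        kernel = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
        kernel /= kernel.sum()
        profile = np.convolve(profile, kernel, mode="same")
        profile -= profile.mean()
        t = yy * np.sin(theta) + xx * np.cos(theta)  # signed distance coord
        idx = np.clip((t + size).astype(int), 0, n_bins - 1)
        pattern += profile[idx]
    if n_streaks > 0:
        pattern *= amplitude / max(pattern.std(), 1e-12)
    return pattern


def apply_dose_noise(clean: CTImage, dose_mA: float, spec: PhantomSpec,
                     rng: np.random.Generator | None = None) -> CTImage:
    """Render a clean phantom at a given tube current.

    Noise std scales as sqrt(reference_dose / dose); the background outside
    the scan cylinder stays exactly at ``background_value``.
    """
    if dose_mA <= 0:
        raise ValueError("dose_mA must be positive")
    if clean.domain_tag is not DomainTag.CLEAN_REFERENCE:
        raise ValueError("apply_dose_noise expects a clean_reference image")
    if clean.normalized:
        raise ValueError("apply_dose_noise expects raw intensities")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    scale = np.sqrt(REFERENCE_DOSE_MA / dose_mA)
    sigma = spec.gaussian_sigma_ref * scale
    pixels = clean.pixels.copy()
    fg = pixels > spec.background_value

    noise = rng.normal(0.0, sigma, pixels.shape)
    # Poisson-like: std grows with signal above the cylinder minimum
    signal = np.clip(pixels - pixels[fg].min() if fg.any() else pixels, 0.0, None)
    noise += rng.normal(size=pixels.shape) * spec.poisson_coeff * np.sqrt(signal) * scale
    if dose_mA < spec.streak_dose_threshold and spec.streak_amplitude > 0:
        noise += _streak_pattern(pixels.shape[0], spec.streak_amplitude,
                                 spec.n_streaks, rng)
    noisy = pixels + noise
    if spec.clip_range is not None:
        noisy = np.clip(noisy, spec.clip_range[0], spec.clip_range[1])
    pixels = np.where(fg, noisy, spec.background_value)

    tag = DomainTag.LOW_DOSE if dose_mA < spec.streak_dose_threshold else DomainTag.STANDARD_DOSE
    return CTImage(pixels=pixels, domain_tag=tag,
                   background_value=spec.background_value,
                   source_id=f"{clean.source_id}@{dose_mA:g}mA")


@dataclass
class UnpairedDataset:
    low_dose: list[CTImage]
    standard_dose: list[CTImage]
    paired_eval: list[tuple[CTImage, CTImage]]  # (clean, low-dose rendering)

    def training_source_ids(self) -> tuple[set, set]:
        low = {img.source_id.split("@")[0] for img in self.low_dose}
        std = {img.source_id.split("@")[0] for img in self.standard_dose}
        return low, std


def make_unpaired_dataset(spec: PhantomSpec, n_low: int, n_std: int,
                          seed: int | None = None,
                          n_paired_eval: int = 4) -> UnpairedDataset:
    """Generate disjoint low-dose and standard-dose phantom sets.

    The two training sets come from disjoint clean phantoms (unpaired by
    construction).  A small held-out paired set (clean + its low-dose
    rendering) is produced for evaluation only.
    """
    if n_low < 1 or n_std < 1:
        raise ValueError("n_low and n_std must be >= 1")
    if seed is None:
        seed = spec.seed
    root = np.random.default_rng(seed)

    low_imgs: list[CTImage] = []
    for i in range(n_low):
        clean, _ = generate_clean_phantom(spec, root, source_id=f"low-{seed}-{i}")
        low_imgs.append(apply_dose_noise(clean, LOW_DOSE_MA, spec, root))

    std_imgs: list[CTImage] = []
    for i in range(n_std):
        clean, _ = generate_clean_phantom(spec, root, source_id=f"std-{seed}-{i}")
        std_imgs.append(apply_dose_noise(clean, STANDARD_DOSE_MA, spec, root))

    paired: list[tuple[CTImage, CTImage]] = []
    for i in range(n_paired_eval):
        clean, _ = generate_clean_phantom(spec, root, source_id=f"eval-{seed}-{i}")
        paired.append((clean, apply_dose_noise(clean, LOW_DOSE_MA, spec, root)))

    ds = UnpairedDataset(low_imgs, std_imgs, paired)
    low_ids, std_ids = ds.training_source_ids()
    assert not (low_ids & std_ids), "unpaired sets must not share phantoms"
    return ds
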