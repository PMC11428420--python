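"""Improved precision/recall for generative models via k-NN manifolds.

Each feature set's support is approximated by the union of hyperspheres
centered on its points with radius equal to the distance to the k-th nearest
neighbor (self excluded).  Precision is the fraction of generated features
falling inside the real manifold; recall is the fraction of real features
inside the generated manifold.  Membership uses the boundary-inclusive test
||phi - phi'||_2 <= radius(phi') for at least one phi'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .ct_io import CTImage, Patch, compute_roi_mask, sample_patch

__all__ = [
    "FeatureSet",
    "PRResult",
    "extract_features",
    "knn_radius",
    "in_manifold",
    "improved_precision",
    "improved_recall",
    "evaluate_pr",
]

DEFAULT_K = 3


@dataclass
class FeatureSet:
    matrix: np.ndarray  # (n, d)
    source: str = "real"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2D (n x d)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PRResult:
    precision: float
    recall: float
    k: int
    n_real: int
    n_gen: int
    truncation_psi: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.precision <= 1.0 and 0.0 <= self.recall <= 1.0):
            raise ValueError("precision and recall must be in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "k": self.k,
            "n_real": self.n_real,
            "n_gen": self.n_gen,
            "truncation_psi": self.truncation_psi,
        }


# -- feature extraction ---------------------------------------------------


def _to_array(image) -> np.ndarray:
    if isinstance(image, (CTImage, Patch)):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


def _resize(a: np.ndarray, size: int) -> np.ndarray:
    from skimage.transform import resize

    if a.shape == (size, size):
        return a
    return resize(a, (size, size), order=1, mode="reflect", anti_aliasing=True)


def _patch_stats_vector(a: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(a)
    gm = np.hypot(gy, gx)
    qs = np.percentile(a, [5, 25, 50, 75, 95])
    return np.concatenate([
        [a.mean(), a.std(), a.min(), a.max()],
        qs,
        [gm.mean(), gm.std()],
    ])


def extract_features(images: list, extractor: str = "random_projection",
                     dim: int = 64, resize_to: int = 32,
                     projection_seed: int = 1234,
                     source: str = "real") -> FeatureSet:
    """One d-vector per image.

    ``random_projection``: images resized to a fixed grid, flattened, and
    multiplied by a seeded Gaussian matrix (no downloads, deterministic).
    ``patch_stats``: intensity and gradient summary statistics.
    ``inception_mid``: requires pretrained weights and a deep-learning
    runtime, neither of which is available offline; raises with pointers to
    the offline alternatives.
    """
    if not images:
        raise ValueError("empty image list")
    if extractor == "inception_mid":
        raise RuntimeError(
            "inception_mid needs pretrained InceptionV3 weights which are not "
            "available offline; use extractor='random_projection' or "
            "'patch_stats' instead"
        )
    arrays = [_to_array(img) for img in images]
    if extractor == "random_projection":
        rng = np.random.default_rng(projection_seed)
        proj = rng.normal(size=(resize_to * resize_to, dim)) / np.sqrt(dim)
        rows = [
            _resize(a, resize_to).reshape(-1) @ proj for a in arrays
        ]
    elif extractor == "patch_stats":
        rows = [_patch_stats_vector(a) for a in arrays]
    else:
        raise ValueError(f"unknown extractor {extractor!r}")
    return FeatureSet(np.vstack(rows), source=source)


# -- k-NN manifold ---------------------------------------------------------


def knn_radius(features: FeatureSet | np.ndarray, k: int = DEFAULT_K) -> np.ndarray:
    """Distance from each row to its k-th nearest neighbor, self excluded."""
    m = features.matrix if isinstance(features, FeatureSet) else np.asarray(features)
    n = m.shape[0]
    if k >= n:
        raise ValueError(f"k ({k}) must be < number of points ({n})")
    d = cdist(m, m)
    np.fill_diagonal(d, np.inf)
    # k-th nearest among the others = (k-1)-th index of the sorted row
    part = np.partition(d, k - 1, axis=1)
    return part[:, k - 1]


def in_manifold(phi: np.ndarray, features: FeatureSet | np.ndarray,
                k: int = DEFAULT_K, radii: np.ndarray | None = None) -> int:
    """1 iff ``phi`` lies within the k-NN hypersphere of >= 1 row (boundary
    counts as inside)."""
    m = features.matrix if isinstance(features, FeatureSet) else np.asarray(features)
    if radii is None:
        radii = knn_radius(m, k)
    dist = np.linalg.norm(m - np.asarray(phi)[None, :], axis=1)
    return int(np.any(dist <= radii))


def _membership_fraction(queries: np.ndarray, support: np.ndarray, k: int) -> float:
    radii = knn_radius(support, k)
    d = cdist(queries, support)
    return float(np.mean(np.any(d <= radii[None, :], axis=1)))


def improved_precision(phi_real: FeatureSet | np.ndarray,
                       phi_gen: FeatureSet | np.ndarray,
                       k: int = DEFAULT_K) -> float:
    """Fraction of generated features inside the real k-NN manifold."""
    r = phi_real.matrix if isinstance(phi_real, FeatureSet) else np.asarray(phi_real)
    g = phi_gen.matrix if isinstance(phi_gen, FeatureSet) else np.asarray(phi_gen)
    if k >= r.shape[0]:
        raise ValueError("real set too small for k")
    return _membership_fraction(g, r, k)


def improved_recall(phi_real: FeatureSet | np.ndarray,
                    phi_gen: FeatureSet | np.ndarray,
                    k: int = DEFAULT_K) -> float:
    """Fraction of real features inside the generated k-NN manifold."""
    r = phi_real.matrix if isinstance(phi_real, FeatureSet) else np.asarray(phi_real)
    g = phi_gen.matrix if isinstance(phi_gen, FeatureSet) else np.asarray(phi_gen)
    if k >= g.shape[0]:
        raise ValueError("generated set too small for k")
    return _membership_fraction(r, g, k)


# -- end-to-end protocol ----------------------------------------------------


def _collect_patches(images: list[CTImage], n_patches: int, patch_size: int,
                     min_foreground_frac: float, rng: np.random.Generator,
                     roi_tol: float) -> list[Patch]:
    patches: list[Patch] = []
    masks = [compute_roi_mask(img, tol=roi_tol) for img in images]
    i = 0
    while len(patches) < n_patches:
        img = images[i % len(images)]
        mask = masks[i % len(images)]
        patches.append(sample_patch(img, mask, size=patch_size,
                                    min_foreground_frac=min_foreground_frac,
                                    rng=rng))
        i += 1
    return patches


def _normalize_patch(pixels: np.ndarray) -> np.ndarray:
    lo, hi = pixels.min(), pixels.max()
    if hi <= lo:
        return np.zeros_like(pixels)
    return (pixels - lo) / (hi - lo)


def evaluate_pr(real_images: list[CTImage], gen_images: list[CTImage],
                k: int = DEFAULT_K, patch_size: int = 128, n_patches: int = 64,
                extractor: str = "random_projection",
                truncation_psi: float | None = None,
                rng: np.random.Generator | None = None,
                min_foreground_frac: float = 0.5, roi_tol: float = 1.0,
                feature_dim: int = 64, normalize_patches: bool = True) -> PRResult:
    """Patch-protocol precision/recall between two raw-intensity image sets.

    ROI-restricted patches are rejection-sampled from each set, min-max
    normalized (the evaluation's standardization step, so intensity offsets
    and scale do not dominate the feature distances), embedded, and scored.
    When ``truncation_psi`` < 1, generated features are filtered to those
    within the psi-quantile of distance to the real feature mean before
    scoring (a translation-setting reading of the truncation trick).
    """
    if rng is None:
        rng = np.random.default_rng()
    # both sets sample with identically seeded streams so that identical
    # image lists produce identical patches (self-comparison gives 1.0/1.0)
    patch_seed = int(rng.integers(2 ** 63))
    real_patches = _collect_patches(real_images, n_patches, patch_size,
                                    min_foreground_frac,
                                    np.random.default_rng(patch_seed), roi_tol)
    gen_patches = _collect_patches(gen_images, n_patches, patch_size,
                                   min_foreground_frac,
                                   np.random.default_rng(patch_seed), roi_tol)
    if normalize_patches:
        real_patches = [_normalize_patch(p.pixels) for p in real_patches]
        gen_patches = [_normalize_patch(p.pixels) for p in gen_patches]
    phi_r = extract_features(real_patches, extractor, dim=feature_dim, source="real")
    phi_g = extract_features(gen_patches, extractor, dim=feature_dim, source="generated")

    g = phi_g.matrix
    if truncation_psi is not None and truncation_psi < 1.0:
        center = phi_r.matrix.mean(axis=0)
        dist = np.linalg.norm(g - center[None, :], axis=1)
        cutoff = np.quantile(dist, truncation_psi)
        g = g[dist <= cutoff]
        if g.shape[0] <= k:
            raise ValueError(
                f"truncation psi={truncation_psi} left {g.shape[0]} generated "
                f"features; need more than k={k}"
            )
    precision = improved_precision(phi_r.matrix, g, k)
    recall = improved_recall(phi_r.matrix, g, k)
    return PRResult(precision=precision, recall=recall, k=k,
                    n_real=phi_r.n, n_gen=g.shape[0],
                    truncation_psi=truncation_psi)
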