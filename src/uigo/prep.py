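"""Preprocessing: normalization, grayscale conversion, edge-preserving
denoising, augmentation, and train/val/test apportionment.

The canonical order, applied slice-by-slice, is

    min-max normalize -> grayscale (if RGB) -> bilateral filter ->
    Gaussian blur -> resize/crop -> augmentation (training rows only) ->
    z-score standardization

The bilateral filter combines a spatial Gaussian kernel
``exp(-d^2 / (2 sigma_s^2))`` with a range kernel on intensity differences
``exp(-(I(a,b) - I(x,y))^2 / (2 sigma_r^2))`` and normalizes by the total
weight, so each output pixel is a convex combination of its window.

Splits use largest-remainder apportionment of n * (train, val, test) with ties
broken in favor of later-listed splits, which reproduces the published
70/20/10 instance counts exactly (e.g. 201 -> 141/40/20, 2658 -> 1860/532/266).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import transform as sktransform

from .phantom_forge import PhantomSample

logger = logging.getLogger("uigo.prep")

__all__ = [
    "BilateralParams",
    "AugmentationPlan",
    "SplitRatios",
    "min_max_normalize",
    "to_grey",
    "bilateral",
    "gaussian_blur",
    "zscore",
    "augment",
    "split_counts",
    "assign_splits",
    "resize_to",
]

GREY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class BilateralParams:
    sigma_s: float = 1.5        # spatial scale, pixels
    sigma_r: float = 0.1        # range scale, intensity units
    window_radius: int | None = None   # default ceil(2*sigma_s)

    def radius(self) -> int:
        r = self.window_radius if self.window_radius is not None else math.ceil(2 * self.sigma_s)
        return max(int(r), 1)

    def validate(self) -> None:
        if self.sigma_s <= 0 or self.sigma_r <= 0:
            raise ValueError(
                f"bilateral sigmas must be positive, got sigma_s={self.sigma_s}, "
                f"sigma_r={self.sigma_r}")


@dataclass(frozen=True)
class AugmentationPlan:
    rotations: tuple[float, ...] = (80.0, 90.0, 180.0, 270.0)
    hflip: bool = True
    vflip: bool = True
    contrast_range: tuple[float, float] = (0.9, 1.1)
    scale_range: tuple[float, float] = (0.95, 1.05)
    apply_probability: float = 0.5


@dataclass(frozen=True)
class SplitRatios:
    train: float = 0.7
    val: float = 0.2
    test: float = 0.1

    def __post_init__(self):
        for frac in (self.train, self.val, self.test):
            if not 0.0 < frac < 1.0:
                raise ValueError(f"split fraction {frac} not in (0,1)")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.train, self.val, self.test)


# -- intensity ops ------------------------------------------------------------

def min_max_normalize(img: np.ndarray) -> np.ndarray:
    """Rescale to [0,1] via (i - i_min)/(i_max - i_min); constant -> zeros."""
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def to_grey(rgb: np.ndarray) -> np.ndarray:
    """Luma-weighted grayscale 0.299 R' + 0.587 G' + 0.114 B'."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected (H,W,3) array, got shape {rgb.shape}")
    r, g, b = GREY_WEIGHTS
    return r * rgb[:, :, 0] + g * rgb[:, :, 1] + b * rgb[:, :, 2]


def bilateral(img: np.ndarray, p: BilateralParams) -> np.ndarray:
    """Edge-preserving bilateral filter (vectorized over window offsets).

    Output pixel (x,y) = sum over neighbors (a,b) of
    I(a,b) * exp(-((a-x)^2+(b-y)^2)/(2 sigma_s^2))
           * exp(-(I(a,b)-I(x,y))^2 / (2 sigma_r^2)),
    normalized by the summed weights.  Borders use reflect padding.
    """
    p.validate()
    img = np.asarray(img, dtype=np.float64)
    rad = p.radius()
    padded = np.pad(img, rad, mode="reflect")
    h, w = img.shape
    acc = np.zeros_like(img)
    norm = np.zeros_like(img)
    two_ss = 2.0 * p.sigma_s ** 2
    two_sr = 2.0 * p.sigma_r ** 2
    for dy in range(-rad, rad + 1):
        for dx in range(-rad, rad + 1):
            ws = math.exp(-(dy * dy + dx * dx) / two_ss)
            shifted = padded[rad + dy:rad + dy + h, rad + dx:rad + dx + w]
            wr = np.exp(-((shifted - img) ** 2) / two_sr)
            weight = ws * wr
            acc += weight * shifted
            norm += weight
    return acc / norm


def gaussian_blur(img: np.ndarray, sigma: float, radius: int | None = None) -> np.ndarray:
    """Separable Gaussian convolution, normalized over a ceil(2*sigma) window
    by default, with reflect-padded borders.

    The window and border conventions match :func:`bilateral`, so the
    bilateral filter converges to this blur exactly as sigma_r grows.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if radius is None:
        radius = max(math.ceil(2 * sigma), 1)
    return ndimage.gaussian_filter(np.asarray(img, dtype=np.float64), sigma,
                                   mode="mirror", radius=radius)


def zscore(img: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1; constant images map to zeros."""
    img = np.asarray(img, dtype=np.float64)
    sd = img.std()
    if sd == 0:
        logger.warning("zscore: constant image, returning zeros")
        return np.zeros_like(img)
    return (img - img.mean()) / sd


def resize_to(img: np.ndarray, size: int, is_mask: bool = False) -> np.ndarray:
    """Resize to size x size; nearest-neighbor for masks, bilinear otherwise."""
    if img.shape[:2] == (size, size):
        return img
    order = 0 if is_mask else 1
    out = sktransform.resize(img, (size, size), order=order, mode="reflect",
                             anti_aliasing=not is_mask, preserve_range=True)
    return out.astype(img.dtype) if is_mask else out


# -- augmentation -------------------------------------------------------------

def _rotate_pair(image: np.ndarray, mask: np.ndarray, angle: float):
    """Rotate image (bilinear) and mask (nearest) by `angle` degrees."""
    if angle % 90 == 0:
        k = int(angle // 90) % 4
        return np.rot90(image, k).copy(), np.rot90(mask, k).copy()
    img_r = sktransform.rotate(image, angle, order=1, mode="reflect", preserve_range=True)
    msk_r = sktransform.rotate(mask.astype(float), angle, order=0, mode="constant",
                               cval=0, preserve_range=True).astype(mask.dtype)
    return img_r, msk_r


def augment(sample: PhantomSample, plan: AugmentationPlan, seed: int) -> list[PhantomSample]:
    """Expand one sample into its augmented variants.

    Geometric transforms (rotations, flips, scaling) are applied identically
    to image and label map, the mask with nearest-neighbor interpolation;
    contrast scaling touches the image only.  Each configured transform fires
    independently with ``plan.apply_probability`` except the rotations, which
    each always contribute one variant (they are the enumerated inventory).
    """
    rng = np.random.default_rng(seed)
    out: list[PhantomSample] = []

    def emit(img, msk):
        out.append(PhantomSample(image=np.ascontiguousarray(img),
                                 label_map=np.ascontiguousarray(msk),
                                 tumor_count=sample.tumor_count))

    for angle in plan.rotations:
        img_r, msk_r = rotate_sample(sample, angle, plan)
        emit(img_r, msk_r)
    if plan.hflip and rng.random() < plan.apply_probability:
        emit(sample.image[:, ::-1], sample.label_map[:, ::-1])
    if plan.vflip and rng.random() < plan.apply_probability:
        emit(sample.image[::-1, :], sample.label_map[::-1, :])
    if rng.random() < plan.apply_probability:
        factor = rng.uniform(*plan.contrast_range)
        emit(np.clip(sample.image * factor, 0.0, 1.0), sample.label_map.copy())
    if rng.random() < plan.apply_probability:
        factor = rng.uniform(*plan.scale_range)
        h, w = sample.label_map.shape
        img_s = sktransform.rescale(sample.image, factor, order=1, mode="reflect",
                                    preserve_range=True, channel_axis=None)
        msk_s = sktransform.rescale(sample.label_map.astype(float), factor, order=0,
                                    mode="constant", preserve_range=True).astype(np.uint8)
        img_s = _center_fit(img_s, h, w)
        msk_s = _center_fit(msk_s, h, w)
        emit(img_s, msk_s)
    return out


def rotate_sample(sample: PhantomSample, angle: float, plan: AugmentationPlan):
    if angle not in plan.rotations:
        raise ValueError(f"rotation angle {angle} not in plan {plan.rotations}")
    return _rotate_pair(sample.image, sample.label_map, angle)


def _center_fit(arr: np.ndarray, h: int, w: int) -> np.ndarray:
    """Center-crop or zero-pad `arr` back to (h, w)."""
    out = np.zeros((h, w), dtype=arr.dtype)
    ah, aw = arr.shape[:2]
    sy, sx = max((ah - h) // 2, 0), max((aw - w) // 2, 0)
    dy, dx = max((h - ah) // 2, 0), max((w - aw) // 2, 0)
    ch, cw = min(ah, h), min(aw, w)
    out[dy:dy + ch, dx:dx + cw] = arr[sy:sy + ch, sx:sx + cw]
    return out


# -- splitting ----------------------------------------------------------------

def split_counts(n: int, r: SplitRatios = SplitRatios()) -> tuple[int, int, int]:
    """Largest-remainder apportionment of n into (train, val, test) counts.

    Each split gets floor(n * fraction); leftover units go to the largest
    fractional remainders, ties resolved in favor of later-listed splits.
    """
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    fracs = r.as_tuple()
    raw = [n * f for f in fracs]
    counts = [int(math.floor(x)) for x in raw]
    remainders = [x - c for x, c in zip(raw, counts)]
    leftover = n - sum(counts)
    # sort by (remainder, index) descending: later index wins ties
    order = sorted(range(3), key=lambda i: (remainders[i], i), reverse=True)
    for i in order[:leftover]:
        counts[i] += 1
    return tuple(counts)  # type: ignore[return-value]


def assign_splits(manifest: pd.DataFrame, r: SplitRatios = SplitRatios(),
                  seed: int = 0) -> pd.DataFrame:
    """Return a copy of the manifest with the split column filled.

    Rows are permuted with the given seed and assigned contiguously to
    train/val/test in the counts given by :func:`split_counts`.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    n = len(manifest)
    n_train, n_val, n_test = split_counts(n, r)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[perm[:n_train]] = "train"
    labels[perm[n_train:n_train + n_val]] = "val"
    labels[perm[n_train + n_val:]] = "test"
    out = manifest.copy()
    out["split"] = labels
    return out
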