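"""Deterministic liver/tumor phantom generator.

Produces 2-D grayscale (or lightly tinted RGB) slices containing an elliptical
"liver" region with 0-3 tumor blobs of contrasting intensity, plus a matching
label map {0=background, 1=liver, 2=tumor}.  Every downstream stage —
preprocessing, segmentation training, region features, classification — can be
exercised on these phantoms with no external data.

Tumor blobs are discs deformed by a low-frequency radial perturbation (at most
20% of the radius) so that boundary-sensitive losses see irregular shapes; each
blob is rejected-and-resampled until it lies entirely inside the liver ellipse.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "forge_sample",
    "forge_dataset",
    "load_manifest",
    "read_image",
    "read_mask",
]


class GeometryError(ValueError):
    """A tumor cannot be placed inside the liver under the given spec."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom slice.

    Intensities are on the unit scale; geometry is in pixels.  ``n_tumors`` may
    be an int or an inclusive (lo, hi) range sampled per slice.
    """

    height: int = 64
    width: int = 64
    liver_axes: tuple[float, float] = (22.0, 16.0)
    liver_center_jitter: float = 4.0
    n_tumors: int | tuple[int, int] = (0, 3)
    tumor_radius_range: tuple[float, float] = (3.0, 7.0)
    tumor_contrast: float = 0.25
    background_level: float = 0.15
    liver_level: float = 0.55
    noise_sd: float = 0.04
    rgb: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError(f"phantom must be at least 16x16, got {self.height}x{self.width}")
        lo, hi = self.tumor_radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad tumor_radius_range {self.tumor_radius_range}")
        if hi >= min(self.liver_axes):
            raise GeometryError(
                f"max tumor radius {hi} does not fit inside liver semi-axes {self.liver_axes}")
        if min(self.liver_axes) <= 0:
            raise GeometryError(f"liver axes must be positive, got {self.liver_axes}")
        if not -0.5 <= self.tumor_contrast <= 0.5:
            raise ValueError(f"tumor_contrast must be in [-0.5, 0.5], got {self.tumor_contrast}")

    def tumor_count_range(self) -> tuple[int, int]:
        if isinstance(self.n_tumors, int):
            return self.n_tumors, self.n_tumors
        lo, hi = self.n_tumors
        if not (0 <= lo <= hi <= 3):
            raise ValueError(f"n_tumors range must lie in [0,3], got {self.n_tumors}")
        return lo, hi


@dataclass
class PhantomSample:
    image: np.ndarray          # (H,W) or (H,W,3) float in [0,1]
    label_map: np.ndarray      # (H,W) uint8 in {0,1,2}
    has_tumor: bool = field(init=False)
    tumor_count: int = 0

    def __post_init__(self):
        self.has_tumor = bool((self.label_map == 2).any())
        if self.label_map.shape != self.image.shape[:2]:
            raise ValueError("label_map dimensions must equal image dimensions")


def _blob_mask(h: int, w: int, cy: float, cx: float, radius: float,
               rng: np.random.Generator) -> np.ndarray:
    """Disc at (cy,cx) with a 3-harmonic radial perturbation <= 20% of radius."""
    amp = rng.uniform(0.05, 0.20, size=3) * radius
    phase = rng.uniform(0, 2 * np.pi, size=3)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    r_edge = radius + sum(a * np.cos((k + 1) * theta + p)
                          for k, (a, p) in enumerate(zip(amp, phase)))
    return dy ** 2 + dx ** 2 <= r_edge ** 2


def forge_sample(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom slice from `spec` (bit-reproducible per seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    a, b = spec.liver_axes

    jy = rng.uniform(-spec.liver_center_jitter, spec.liver_center_jitter)
    jx = rng.uniform(-spec.liver_center_jitter, spec.liver_center_jitter)
    cy, cx = h / 2.0 + jy, w / 2.0 + jx

    yy, xx = np.mgrid[0:h, 0:w]
    liver = ((yy - cy) / b) ** 2 + ((xx - cx) / a) ** 2 <= 1.0

    lo, hi = spec.tumor_count_range()
    n_tumors = int(rng.integers(lo, hi + 1))

    label = np.zeros((h, w), dtype=np.uint8)
    label[liver] = 1
    placed = 0
    attempts = 0
    while placed < n_tumors:
        attempts += 1
        if attempts > 200:
            raise GeometryError(
                f"could not place tumor {placed + 1}/{n_tumors} inside the liver "
                f"(radius range {spec.tumor_radius_range}, liver axes {spec.liver_axes})")
        radius = rng.uniform(*spec.tumor_radius_range)
        # sample centers within the shrunken ellipse so the blob can fit
        t = rng.uniform(0, 2 * np.pi)
        u = np.sqrt(rng.uniform())
        ty = cy + u * max(b - 1.3 * radius, 0.0) * np.sin(t)
        tx = cx + u * max(a - 1.3 * radius, 0.0) * np.cos(t)
        blob = _blob_mask(h, w, ty, tx, radius, rng)
        if not blob.any() or not (blob <= liver).all():
            continue
        label[blob] = 2
        placed += 1

    image = np.full((h, w), spec.background_level, dtype=np.float64)
    image[label >= 1] = spec.liver_level
    image[label == 2] = spec.liver_level + spec.tumor_contrast
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=(h, w))
    image = np.clip(image, 0.0, 1.0)

    if spec.rgb:
        tint = np.array([1.05, 1.0, 0.95])
        image = np.clip(image[:, :, None] * tint[None, None, :], 0.0, 1.0)

    return PhantomSample(image=image, label_map=label, tumor_count=placed)


def _write_png(path: Path, array: np.ndarray, bits: int = 8) -> None:
    if bits == 16:
        arr = np.round(array * 65535).astype(np.uint16)
        mode = "I;16"
        if arr.ndim == 3:
            raise ValueError("16-bit RGB PNG not supported")
        Image.fromarray(arr, mode=mode).save(path)
    else:
        arr = np.round(array * 255).astype(np.uint8)
        Image.fromarray(arr).save(path)


def forge_dataset(spec: PhantomSpec, n: int, out_dir: str | Path) -> pd.DataFrame:
    """Write `n` image/mask PNG pairs plus a CSV manifest; returns the manifest.

    Sample i is generated with seed ``spec.seed + i`` so the dataset is
    reproducible while each slice differs.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    msk_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    msk_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for i in range(n):
        sub = replace(spec, seed=spec.seed + i)
        sample = forge_sample(sub)
        sid = f"phantom_{i:05d}"
        img_path = img_dir / f"{sid}.png"
        msk_path = msk_dir / f"{sid}.png"
        _write_png(img_path, sample.image)
        Image.fromarray(sample.label_map).save(msk_path)
        rows.append({"id": sid,
                     "image_path": str(img_path.relative_to(out_dir)),
                     "mask_path": str(msk_path.relative_to(out_dir)),
                     "has_tumor": sample.has_tumor,
                     "split": ""})
    manifest = pd.DataFrame(rows, columns=["id", "image_path", "mask_path", "has_tumor", "split"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_manifest(out_dir: str | Path) -> pd.DataFrame:
    out_dir = Path(out_dir)
    return pd.read_csv(out_dir / "manifest.csv", keep_default_na=False,
                       dtype={"split": str}, converters={"has_tumor": lambda s: s == "True"})


def read_image(root: str | Path, rel_path: str) -> np.ndarray:
    """Load a PNG/TIFF slice back to unit-scale floats."""
    img = Image.open(Path(root) / rel_path)
    arr = np.asarray(img)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype in (np.uint16, np.int32):
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64)


def read_mask(root: str | Path, rel_path: str) -> np.ndarray:
    arr = np.asarray(Image.open(Path(root) / rel_path))
    return arr.astype(np.uint8)


def manifest_checksum(manifest: pd.DataFrame) -> str:
    return hashlib.sha256(manifest.to_csv(index=False).encode()).hexdigest()
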