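"""Stage 2: region features from predicted masks, and boosted classification.

Each 8-connected component of a predicted tumor mask yields one feature row —
geometry (area, perimeter, centroid, bounding box, eccentricity, solidity),
first-order intensity statistics (mean, SD, skewness, kurtosis) and four
gray-level co-occurrence texture statistics (contrast, homogeneity, energy,
correlation; offset 1 pixel, 0 degrees).  A sample-level row aggregates the
components (count, total/max area, features of the largest component) and is
what the classifier consumes: the desk-scale task is tumor present vs absent
per slice.

The classifier is a LightGBM gradient-boosted tree ensemble with the printed
booster settings (learning rate 0.05, max depth 6, 40 leaves, feature fraction
0.9, bagging fraction 0.8), trained on the GO-selected feature columns and
evaluated with stratified 5-fold cross-validation.

Bounding boxes use half-open [min, max) coordinates, 0-based, row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import regionprops

from . import metrics as uigo_metrics

__all__ = [
    "RegionFeatureRow",
    "BoosterConfig",
    "FEATURE_COLUMNS",
    "extract_features",
    "sample_feature_row",
    "train_classifier",
    "predict",
    "synthetic_feature_table",
]

# the versioned 16-feature set used for classification masks
FEATURE_COLUMNS = [
    "area", "perimeter", "mean_intensity", "sd_intensity",
    "eccentricity", "solidity", "skewness", "kurtosis",
    "glcm_contrast", "glcm_homogeneity", "glcm_energy", "glcm_correlation",
    "component_count", "total_area", "max_component_area", "has_regions",
]

_GLCM_LEVELS = 32


@dataclass
class RegionFeatureRow:
    sample_id: str
    component_id: int
    area: int
    perimeter: float
    mean_intensity: float
    sd_intensity: float
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]       # (min_row, min_col, max_row, max_col), half-open
    eccentricity: float
    solidity: float
    skewness: float
    kurtosis: float
    glcm_contrast: float
    glcm_homogeneity: float
    glcm_energy: float
    glcm_correlation: float


@dataclass(frozen=True)
class BoosterConfig:
    learning_rate: float = 0.05
    max_depth: int = 6
    num_leaves: int = 40
    feature_fraction: float = 0.9
    bagging_fraction: float = 0.8
    n_rounds: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.num_leaves > 2 ** self.max_depth:
            raise ValueError(
                f"num_leaves {self.num_leaves} exceeds 2^max_depth = {2 ** self.max_depth}")

    def lgb_params(self) -> dict:
        return dict(
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            num_leaves=self.num_leaves,
            feature_fraction=self.feature_fraction,
            bagging_fraction=self.bagging_fraction,
            bagging_freq=1,
            n_estimators=self.n_rounds,
            random_state=self.seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbosity=-1,
            min_child_samples=5,
        )


def _glcm_stats(image: np.ndarray, mask: np.ndarray) -> tuple[float, float, float, float]:
    """Co-occurrence texture at offset 1 px, 0 deg, restricted to the mask.

    In-region intensities are quantized to 32 levels; out-of-region pixels are
    mapped to a reserved level whose co-occurrence row/column is discarded
    before normalization (the standard masked-GLCM construction).
    """
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        quant = np.floor((image - lo) / (hi - lo) * (_GLCM_LEVELS - 1)).astype(int)
        quant = np.clip(quant, 0, _GLCM_LEVELS - 1)
    else:
        quant = np.zeros_like(image, dtype=int)
    levels = quant + 1                  # reserve level 0 for outside-the-mask
    levels[~mask] = 0
    glcm = graycomatrix(levels.astype(np.uint8), distances=[1], angles=[0],
                        levels=_GLCM_LEVELS + 1, symmetric=True, normed=False)
    sub = glcm[1:, 1:, :, :].astype(float)
    total = sub.sum()
    if total == 0:                      # single-pixel-wide region: no pairs
        return 0.0, 1.0, 1.0, 0.0
    sub /= total
    contrast = float(graycoprops(sub, "contrast")[0, 0])
    homogeneity = float(graycoprops(sub, "homogeneity")[0, 0])
    energy = float(graycoprops(sub, "energy")[0, 0])
    correlation = float(graycoprops(sub, "correlation")[0, 0])
    return contrast, homogeneity, energy, correlation


def extract_features(image: np.ndarray, pred_mask: np.ndarray,
                     sample_id: str = "sample",
                     min_component_area: int = 5) -> list[RegionFeatureRow]:
    """One feature row per 8-connected component of area >= min_component_area."""
    image = np.asarray(image, dtype=np.float64)
    pred_mask = np.asarray(pred_mask).astype(bool)
    if image.shape != pred_mask.shape:
        raise ValueError(f"shape mismatch {image.shape} vs {pred_mask.shape}")
    labeled, _ = ndimage.label(pred_mask, structure=np.ones((3, 3), dtype=int))
    rows: list[RegionFeatureRow] = []
    for prop in regionprops(labeled, intensity_image=image):
        if prop.area < min_component_area:
            continue
        comp_mask = labeled == prop.label
        vals = image[comp_mask]
        sd = float(vals.std())
        skew = float(stats.skew(vals)) if sd > 0 else 0.0
        kurt = float(stats.kurtosis(vals)) if sd > 0 else 0.0
        contrast, homogeneity, energy, correlation = _glcm_stats(image, comp_mask)
        rows.append(RegionFeatureRow(
            sample_id=sample_id,
            component_id=int(prop.label),
            area=int(prop.area),
            perimeter=float(prop.perimeter),
            mean_intensity=float(vals.mean()),
            sd_intensity=sd,
            centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            bbox=tuple(int(v) for v in prop.bbox),
            eccentricity=float(prop.eccentricity),
            solidity=float(prop.solidity),
            skewness=skew,
            kurtosis=kurt,
            glcm_contrast=contrast,
            glcm_homogeneity=homogeneity,
            glcm_energy=energy,
            glcm_correlation=correlation,
        ))
    return rows


def sample_feature_row(rows: list[RegionFeatureRow]) -> dict:
    """Aggregate component rows into one per-sample feature vector.

    Empty prediction: all-zero features with has_regions = 0.
    """
    if not rows:
        return {col: 0.0 for col in FEATURE_COLUMNS}
    largest = max(rows, key=lambda r: r.area)
    out = {
        "area": float(largest.area),
        "perimeter": largest.perimeter,
        "mean_intensity": largest.mean_intensity,
        "sd_intensity": largest.sd_intensity,
        "eccentricity": largest.eccentricity,
        "solidity": largest.solidity,
        "skewness": largest.skewness,
        "kurtosis": largest.kurtosis,
        "glcm_contrast": largest.glcm_contrast,
        "glcm_homogeneity": largest.glcm_homogeneity,
        "glcm_energy": largest.glcm_energy,
        "glcm_correlation": largest.glcm_correlation,
        "component_count": float(len(rows)),
        "total_area": float(sum(r.area for r in rows)),
        "max_component_area": float(largest.area),
        "has_regions": 1.0,
    }
    return out


def train_classifier(features: pd.DataFrame, labels: np.ndarray,
                     cfg: BoosterConfig = BoosterConfig(),
                     feature_mask: list[str] | None = None,
                     cv_folds: int = 5):
    """Train the boosted classifier on the masked columns.

    Returns (fitted model, CV report dict with per-fold and mean metrics).
    The fold count is clamped to the minority-class size; with fewer than two
    members per class the CV block is skipped and flagged in the report.
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if feature_mask is None:
        feature_mask = list(features.columns)
    if not feature_mask:
        raise ValueError("feature_mask is empty")
    unknown = [c for c in feature_mask if c not in features.columns]
    if unknown:
        raise ValueError(f"unknown feature names in mask: {unknown}")
    X = features[feature_mask].reset_index(drop=True).astype(float)

    minority = int(np.bincount(y).min())
    n_splits = min(cv_folds, minority)
    if n_splits < 2:
        model = lgb.LGBMClassifier(**cfg.lgb_params())
        model.fit(X, y)
        model._uigo_feature_mask = list(feature_mask)
        return model, {"folds": [], "mean": {}, "std": {},
                       "feature_mask": list(feature_mask),
                       "cv_skipped": "minority class too small"}

    folds = []
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=cfg.seed)
    for train_idx, val_idx in skf.split(X, y):
        model = lgb.LGBMClassifier(**cfg.lgb_params())
        model.fit(X.iloc[train_idx], y[train_idx])
        prob = model.predict_proba(X.iloc[val_idx])[:, 1]
        pred = (prob >= 0.5).astype(int)
        rep = uigo_metrics.scalar_metrics(_label_confusion(pred, y[val_idx]))
        auc_val, auc_flags = uigo_metrics.auc(prob, y[val_idx])
        folds.append({"accuracy": rep.accuracy, "precision": rep.precision,
                      "recall": rep.recall, "f1": rep.f1,
                      "specificity": rep.specificity, "mcc": rep.mcc,
                      "auc": auc_val if not auc_flags else np.nan})
    cv = pd.DataFrame(folds)
    report = {"folds": folds,
              "mean": cv.mean(numeric_only=True).to_dict(),
              "std": cv.std(numeric_only=True).to_dict(),
              "feature_mask": list(feature_mask)}

    model = lgb.LGBMClassifier(**cfg.lgb_params())
    model.fit(X, y)
    model._uigo_feature_mask = list(feature_mask)
    return model, report


def _label_confusion(pred: np.ndarray, target: np.ndarray):
    return uigo_metrics.confusion(pred.astype(bool), target.astype(bool))


def predict(model, features: pd.DataFrame) -> np.ndarray:
    """Per-sample class probabilities, columns ordered (class 0, class 1)."""
    mask = getattr(model, "_uigo_feature_mask", list(features.columns))
    missing = [c for c in mask if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    if len(features) == 0:
        return np.zeros((0, 2))
    return model.predict_proba(features[mask].astype(float))


def synthetic_feature_table(n: int = 240, d: int = 20, n_informative: int = 5,
                            effect: float = 2.0, seed: int = 0):
    """Planted-informative-feature table for wrapper-selection studies.

    The first `n_informative` columns shift by `effect` standard deviations
    between the two balanced classes; the rest are pure noise.  Returns
    (DataFrame with columns f00..f{d-1}, labels, list of informative names).
    """
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], [n - n // 2, n // 2])
    rng.shuffle(y)
    X = rng.normal(size=(n, d))
    X[:, :n_informative] += effect * y[:, None]
    cols = [f"f{j:02d}" for j in range(d)]
    return pd.DataFrame(X, columns=cols), y, cols[:n_informative]
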