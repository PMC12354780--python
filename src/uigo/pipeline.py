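"""Pipeline orchestration: preprocessing application, segmentation training,
K-fold evaluation, qualitative overlays, and the resumable end-to-end run.

Stages (each resumable from its artifacts on disk):

    forge -> split -> train segmenter -> predict masks -> region features ->
    GO feature selection -> boosted classifier -> evaluation summary

Training minimizes the tri-composite loss with Adam, monitors validation Dice,
keeps the best-validation checkpoint, stops early on stagnation, and halves
the learning rate on plateau.  Runs are single-threaded and fully seeded, so a
repeated run with the same configuration is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image, ImageDraw

from . import lesion_stage2, losses, metrics, prep
from .autodiff import Adam
from .gravity_opt import GOConfig, select_features
from .phantom_forge import (PhantomSpec, forge_dataset, load_manifest,
                            read_image, read_mask)
from .uigo_net import NetConfig, UIGONet, build

logger = logging.getLogger("uigo.pipeline")

__all__ = [
    "TrainConfig",
    "PrepSettings",
    "FoldReport",
    "preprocess_slice",
    "build_arrays",
    "train_segmenter",
    "predict_masks",
    "kfold",
    "overlay",
    "run_pipeline",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    early_stop_patience: int = 15
    lr_reduce_on_plateau: bool = True
    lr_reduce_factor: float = 0.5
    lr_reduce_patience: int = 5
    seed: int = 0

    def validate(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.early_stop_patience >= self.epochs and self.epochs > 1:
            logger.debug("early_stop_patience >= epochs; early stopping cannot fire")


@dataclass(frozen=True)
class PrepSettings:
    sigma_s: float = 1.5
    sigma_r: float = 0.1
    blur_sigma: float = 0.5
    input_size: int = 64
    denoise: bool = True


@dataclass
class FoldReport:
    per_fold: list[dict]
    stats: pd.DataFrame           # rows: mean/std/min/5%/50%/75%/max per metric
    assignment: pd.DataFrame      # columns: id, fold


# -- preprocessing application ------------------------------------------------

def preprocess_slice(image: np.ndarray, settings: PrepSettings) -> np.ndarray:
    """Canonical chain: min-max -> grayscale -> bilateral -> blur -> resize -> z-score."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = prep.to_grey(np.stack([prep.min_max_normalize(img[:, :, c])
                                     for c in range(3)], axis=2))
    else:
        img = prep.min_max_normalize(img)
    if settings.denoise:
        img = prep.bilateral(img, prep.BilateralParams(settings.sigma_s, settings.sigma_r))
        img = prep.gaussian_blur(img, settings.blur_sigma)
    img = prep.resize_to(img, settings.input_size)
    return prep.zscore(img)


def build_arrays(root: Path, manifest: pd.DataFrame, settings: PrepSettings,
                 augment_plan: prep.AugmentationPlan | None = None,
                 augment_splits: tuple[str, ...] = ("train",),
                 seed: int = 0):
    """Preprocessed image/mask arrays plus provenance ids per row.

    Augmentation (when a plan is given) is applied only to rows whose split is
    in `augment_splits`; augmented variants keep the source row's id with an
    ``#augN`` suffix so leakage is auditable.
    """
    images, masks, ids, splits = [], [], [], []
    for row_index, (_, row) in enumerate(manifest.iterrows()):
        image = read_image(root, row["image_path"])
        mask = read_mask(root, row["mask_path"])
        mask = prep.resize_to(mask, settings.input_size, is_mask=True)
        img = preprocess_slice(image, settings)
        images.append(img)
        masks.append(mask)
        ids.append(row["id"])
        splits.append(row["split"])
        if augment_plan is not None and row["split"] in augment_splits:
            from .phantom_forge import PhantomSample
            sample = PhantomSample(image=np.clip(img - img.min(), 0, None) /
                                   max(img.max() - img.min(), 1e-12),
                                   label_map=mask)
            variants = prep.augment(sample, augment_plan,
                                    seed=(seed + 7919 * (row_index + 1)) % (2 ** 31))
            for j, var in enumerate(variants):
                images.append(prep.zscore(var.image))
                masks.append(var.label_map)
                ids.append(f"{row['id']}#aug{j}")
                splits.append(row["split"])
    return (np.stack(images), np.stack(masks), np.array(ids), np.array(splits))


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(net: UIGONet, path: Path, extra: dict | None = None) -> None:
    """Single-file .npz: parameters + BN running stats + embedded config."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(net.parameters())}
    for i, bn in enumerate(_batchnorms(net)):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    meta = {"config": net.config.__dict__.copy(), "extra": extra or {}}
    meta["config"]["inception_kernels"] = list(net.config.inception_kernels)
    arrays["meta_json"] = np.frombuffer(json.dumps(meta, default=str).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _batchnorms(net: UIGONet):
    from .autodiff import BatchNorm2d
    seen = []
    stack = list(net.modules())
    for module in stack:
        for attr in vars(module).values():
            _collect_bns(attr, seen)
    return seen


def _collect_bns(obj, out):
    from .autodiff import BatchNorm2d
    if isinstance(obj, BatchNorm2d):
        out.append(obj)
    elif isinstance(obj, list):
        for item in obj:
            _collect_bns(item, out)
    elif hasattr(obj, "__dict__") and obj.__class__.__module__.startswith("uigo"):
        for attr in vars(obj).values():
            _collect_bns(attr, out)


def load_checkpoint(path: Path) -> UIGONet:
    data = np.load(path)
    meta = json.loads(bytes(data["meta_json"]).decode())
    cfg_dict = meta["config"]
    cfg_dict["inception_kernels"] = tuple(cfg_dict["inception_kernels"])
    net = UIGONet(NetConfig(**cfg_dict))
    for i, p in enumerate(net.parameters()):
        p.data = data[f"param_{i}"].copy()
    for i, bn in enumerate(_batchnorms(net)):
        bn.running_mean = data[f"bn_mean_{i}"].copy()
        bn.running_var = data[f"bn_var_{i}"].copy()
    return net


# -- training -----------------------------------------------------------------

def _val_dice_iou(net: UIGONet, images: np.ndarray, masks: np.ndarray,
                  batch_size: int = 16) -> tuple[float, float]:
    dices, ious = [], []
    for start in range(0, len(images), batch_size):
        batch = images[start:start + batch_size]
        probs = net.forward(batch, training=False).data[:, 0]
        for prob, mask in zip(probs, masks[start:start + batch_size]):
            d, i = metrics.dice_iou(prob >= 0.5, mask == 2)
            dices.append(d)
            ious.append(i)
    return float(np.mean(dices)), float(np.mean(ious))


def train_segmenter(images: np.ndarray, masks: np.ndarray, splits: np.ndarray,
                    net_config: NetConfig, train_config: TrainConfig = TrainConfig(),
                    weights: losses.LossWeights = losses.LossWeights(),
                    focal: losses.FocalParams = losses.FocalParams(),
                    history_path: Path | None = None):
    """Train the segmentation network on the train split, monitoring val Dice.

    `masks` are label maps {0,1,2}; the training target is the tumor class.
    Returns (best-validation network, history DataFrame).
    """
    train_config.validate()
    tr = splits == "train"
    va = splits == "val"
    if not tr.any() or not va.any():
        raise ValueError("need non-empty train and val splits")
    x_tr, y_tr = images[tr], (masks[tr] == 2).astype(np.float64)
    x_va, m_va = images[va], masks[va]

    net, _ = build(net_config)
    params = net.parameters()
    opt = Adam(params, lr=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)

    best_dice, best_state, best_bn = -1.0, None, None
    stagnant, lr_stagnant = 0, 0
    rows = []
    n = len(x_tr)
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        comps_sum = {"focal": 0.0, "dice": 0.0, "hausdorff": 0.0}
        total_sum, n_batches = 0.0, 0
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            pred = net.forward(x_tr[idx], training=True, rng=rng)
            target = y_tr[idx][:, None, :, :]
            loss, comps = losses.composite_loss(pred, target, weights, focal,
                                                per_sample=True)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, batch {start}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k in comps_sum:
                comps_sum[k] += comps[k]
            total_sum += float(loss.data)
            n_batches += 1

        val_dice, val_iou = _val_dice_iou(net, x_va, m_va)
        improved = val_dice > best_dice
        if improved:
            best_dice = val_dice
            best_state = [p.data.copy() for p in params]
            best_bn = [(bn.running_mean.copy(), bn.running_var.copy())
                       for bn in _batchnorms(net)]
            stagnant, lr_stagnant = 0, 0
        else:
            stagnant += 1
            lr_stagnant += 1
        rows.append({"epoch": epoch,
                     "train_focal": comps_sum["focal"] / n_batches,
                     "train_dice": comps_sum["dice"] / n_batches,
                     "train_hausdorff": comps_sum["hausdorff"] / n_batches,
                     "train_total": total_sum / n_batches,
                     "val_dice": val_dice, "val_iou": val_iou,
                     "best_val_dice": best_dice, "lr": opt.lr})
        logger.info("epoch %d: train loss %.4f, val dice %.4f (best %.4f)",
                    epoch, total_sum / n_batches, val_dice, best_dice)
        if (train_config.lr_reduce_on_plateau
                and lr_stagnant >= train_config.lr_reduce_patience):
            opt.lr *= train_config.lr_reduce_factor
            lr_stagnant = 0
            logger.info("reduced learning rate to %g", opt.lr)
        if stagnant >= train_config.early_stop_patience:
            logger.info("early stopping at epoch %d", epoch)
            break

    if best_state is not None:
        for p, data in zip(params, best_state):
            p.data = data
        for bn, (mean, var) in zip(_batchnorms(net), best_bn):
            bn.running_mean, bn.running_var = mean, var
    history = pd.DataFrame(rows)
    if history_path is not None:
        history.to_csv(history_path, index=False)
    return net, history


def predict_masks(net: UIGONet, images: np.ndarray, batch_size: int = 16,
                  threshold: float = 0.5):
    """(probabilities, binary masks) for a stack of preprocessed slices."""
    probs = []
    for start in range(0, len(images), batch_size):
        out = net.forward(images[start:start + batch_size], training=False)
        probs.append(out.data[:, 0])
    prob = np.concatenate(probs) if probs else np.zeros((0,) + images.shape[1:])
    return prob, prob >= threshold


# -- K-fold harness -----------------------------------------------------------

def kfold(manifest: pd.DataFrame, k: int, runner, seed: int = 0,
          stratify_on: str = "has_tumor") -> FoldReport:
    """Stratified K-fold: `runner(train_df, val_df) -> dict of metrics`.

    Every sample validates exactly once; the report aggregates mean, std, min,
    5%, 50%, 75% and max per metric.
    """
    n = len(manifest)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    from sklearn.model_selection import StratifiedKFold

    strat = manifest[stratify_on].to_numpy() if stratify_on in manifest else np.zeros(n)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold, assignment = [], np.empty(n, dtype=int)
    for fold, (tr_idx, va_idx) in enumerate(skf.split(np.zeros(n), strat)):
        assignment[va_idx] = fold
        result = runner(manifest.iloc[tr_idx], manifest.iloc[va_idx])
        result = {"fold": fold, **result}
        per_fold.append(result)
    df = pd.DataFrame(per_fold).set_index("fold")
    stats = df.agg(["mean", "std", "min",
                    lambda s: s.quantile(0.05),
                    lambda s: s.quantile(0.50),
                    lambda s: s.quantile(0.75),
                    "max"])
    stats.index = ["mean", "std", "min", "5%", "50%", "75%", "max"]
    return FoldReport(per_fold=per_fold, stats=stats,
                      assignment=pd.DataFrame({"id": manifest["id"].to_numpy(),
                                               "fold": assignment}))


# -- overlays -----------------------------------------------------------------

def overlay(image: np.ndarray, pred: np.ndarray, truth: np.ndarray,
            out_path: Path) -> Path:
    """Write a qualitative overlay: truth contour (green), predicted tumor
    shading (red), and a bounding box (yellow) per predicted tumor component."""
    from scipy import ndimage as ndi

    if image.shape != pred.shape or image.shape != truth.shape:
        raise ValueError("image, pred and truth must share a shape")
    base = prep.min_max_normalize(image)
    rgb = np.stack([base] * 3, axis=2)
    pred_t = pred == 2 if pred.max() > 1 else pred.astype(bool)
    truth_t = truth == 2 if truth.max() > 1 else truth.astype(bool)
    rgb[pred_t] = 0.6 * rgb[pred_t] + 0.4 * np.array([1.0, 0.1, 0.1])
    contour = truth_t & ~ndi.binary_erosion(truth_t)
    rgb[contour] = [0.1, 1.0, 0.1]
    img = Image.fromarray((np.clip(rgb, 0, 1) * 255).astype(np.uint8))
    draw = ImageDraw.Draw(img)
    labeled, n_comp = ndi.label(pred_t, structure=np.ones((3, 3), dtype=int))
    for comp in range(1, n_comp + 1):
        ys, xs = np.where(labeled == comp)
        # half-open bbox drawn as inclusive pixel rectangle
        draw.rectangle([int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max())],
                       outline=(255, 255, 0))
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    img.save(out_path)
    return out_path


# -- end-to-end run -----------------------------------------------------------

def _spec_from_config(cfg: dict) -> PhantomSpec:
    forge_cfg = dict(cfg.get("forge", {}))
    forge_cfg.pop("n", None)
    for key in ("liver_axes", "tumor_radius_range", "n_tumors"):
        if key in forge_cfg and isinstance(forge_cfg[key], list):
            forge_cfg[key] = tuple(forge_cfg[key])
    return PhantomSpec(seed=cfg.get("seed", 0), **forge_cfg)


def run_pipeline(config_path: str | Path, force: bool = False,
                 out_dir: str | Path | None = None) -> dict:
    """Execute forge -> ... -> evaluate from a YAML config; resumable.

    `out_dir` overrides the config's output directory (the summary content is
    independent of where artifacts live).  Returns the summary dict, also
    written to <out_dir>/summary.json.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    seed = int(cfg.get("seed", 0))
    out_dir = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    data_dir = out_dir / "data"

    def stage_done(path: Path) -> bool:
        return path.exists() and not force

    # 1. forge
    manifest_path = data_dir / "manifest.csv"
    if not stage_done(manifest_path):
        logger.info("stage forge: generating %d phantoms", cfg["forge"]["n"])
        forge_dataset(_spec_from_config(cfg), cfg["forge"]["n"], data_dir)
    manifest = load_manifest(data_dir)

    # 2. split
    split_path = out_dir / "manifest_split.csv"
    if not stage_done(split_path):
        ratios = prep.SplitRatios(*cfg.get("prep", {}).get("split", [0.7, 0.2, 0.1]))
        manifest = prep.assign_splits(manifest, ratios, seed=seed)
        manifest.to_csv(split_path, index=False)
    manifest = pd.read_csv(split_path, converters={"has_tumor": lambda s: s == "True"})

    prep_cfg = cfg.get("prep", {})
    settings = PrepSettings(
        sigma_s=prep_cfg.get("sigma_s", 1.5), sigma_r=prep_cfg.get("sigma_r", 0.1),
        blur_sigma=prep_cfg.get("blur_sigma", 0.5),
        input_size=cfg.get("model", {}).get("input_size", 64),
        denoise=prep_cfg.get("denoise", True))
    plan = None
    if prep_cfg.get("augment", False):
        plan = prep.AugmentationPlan(rotations=tuple(prep_cfg.get("rotations",
                                                                  (80, 90, 180, 270))))
    images, masks, ids, splits = build_arrays(data_dir, manifest, settings,
                                              augment_plan=plan, seed=seed)

    # 3. train segmenter
    ckpt_path = out_dir / "checkpoint.npz"
    model_cfg = dict(cfg.get("model", {}))
    if "inception_kernels" in model_cfg:
        model_cfg["inception_kernels"] = tuple(model_cfg["inception_kernels"])
    net_config = NetConfig(seed=seed, **model_cfg)
    if not stage_done(ckpt_path):
        train_cfg = TrainConfig(seed=seed, **cfg.get("train", {}))
        loss_cfg = cfg.get("loss", {})
        weights = losses.LossWeights(w_focal=loss_cfg.get("w_focal", 0.27),
                                     w_dice=loss_cfg.get("w_dice", 0.69),
                                     w_hausdorff=loss_cfg.get("w_hausdorff", 0.04))
        focal = losses.FocalParams(alpha=loss_cfg.get("focal_alpha", 0.25),
                                   gamma=loss_cfg.get("focal_gamma", 2.0))
        logger.info("stage train_segmenter")
        net, _ = train_segmenter(images, masks, splits, net_config, train_cfg,
                                 weights, focal, history_path=out_dir / "history.csv")
        save_checkpoint(net, ckpt_path)
    net = load_checkpoint(ckpt_path)

    # 4-5. predict + features (original rows only; augmented variants are
    # training-time material, not evaluation samples)
    feat_path = out_dir / "features.csv"
    keep = np.array(["#aug" not in str(i) for i in ids])
    if not stage_done(feat_path):
        logger.info("stage features")
        prob, pred_bin = predict_masks(net, images[keep])
        rows = []
        for i, sid in enumerate(ids[keep]):
            regions = lesion_stage2.extract_features(images[keep][i], pred_bin[i],
                                                     sample_id=str(sid))
            row = lesion_stage2.sample_feature_row(regions)
            row["id"] = str(sid)
            rows.append(row)
        feats = pd.DataFrame(rows)
        feats.to_csv(feat_path, index=False)
    feats = pd.read_csv(feat_path)
    merged = feats.merge(manifest[["id", "has_tumor", "split"]], on="id")

    # 6. GO feature selection on the train split
    mask_path = out_dir / "feature_mask.json"
    go_cfg = cfg.get("go", {})
    feature_cols = lesion_stage2.FEATURE_COLUMNS
    if not stage_done(mask_path):
        logger.info("stage feature selection")
        tr = merged[merged["split"] == "train"]
        scorer = _make_cv_scorer(seed)
        go = GOConfig(population=go_cfg.get("population", 15),
                      iterations=go_cfg.get("iterations", 20),
                      mode="binary", seed=seed,
                      patience=go_cfg.get("patience", None))
        sel_mask, _ = select_features(tr[feature_cols], tr["has_tumor"].to_numpy(int),
                                      scorer, go,
                                      sparsity=go_cfg.get("sparsity", 0.05))
        mask_path.write_text(json.dumps(
            [c for c, m in zip(feature_cols, sel_mask) if m]))
    selected = json.loads(mask_path.read_text())

    # 7. classifier
    clf_cfg = cfg.get("classifier", {})
    booster = lesion_stage2.BoosterConfig(seed=seed, **clf_cfg)
    tr = merged[merged["split"] == "train"]
    model, cv_report = lesion_stage2.train_classifier(
        tr[feature_cols], tr["has_tumor"].to_numpy(int), booster, selected)
    model.booster_.save_model(str(out_dir / "classifier.txt"))

    # 8. evaluate
    summary = {"config": str(config_path), "seed": seed,
               "selected_features": selected,
               "classifier_cv": {"mean": cv_report["mean"], "std": cv_report["std"]}}
    prob, pred_bin = predict_masks(net, images[keep])
    id_to_idx = {str(sid): i for i, sid in enumerate(ids[keep])}
    for split in ("val", "test"):
        rows_split = manifest[manifest["split"] == split]
        reports = []
        for _, row in rows_split.iterrows():
            i = id_to_idx[row["id"]]
            rep = metrics.evaluate_masks(pred_bin[i], masks[keep][i] == 2,
                                         scores=prob[i], seed=seed)
            values = rep.as_dict()
            # flagged-undefined metrics (e.g. recall on a tumor-free slice)
            # are excluded from the aggregate rather than averaged as zeros
            for name in list(values):
                flag = "recall_undefined" if name == "sensitivity" else f"{name}_undefined"
                if flag in rep.flags or (
                        name == "auc" and "auc_single_class" in rep.flags):
                    values[name] = np.nan
            reports.append(values)
        agg = pd.DataFrame(reports).mean().to_dict()
        summary[f"segmentation_{split}"] = agg
    te = merged[merged["split"] == "test"]
    if len(te) and te["has_tumor"].nunique() > 1:
        probs = lesion_stage2.predict(model, te[feature_cols])[:, 1]
        pred_lbl = (probs >= 0.5).astype(int)
        rep = metrics.scalar_metrics(metrics.confusion(pred_lbl.astype(bool),
                                                       te["has_tumor"].to_numpy(bool)))
        auc_val, _ = metrics.auc(probs, te["has_tumor"].to_numpy(int))
        summary["classification_test"] = {**rep.as_dict(), "auc": auc_val}

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True,
                                                     default=float))
    logger.info("pipeline complete: %s", out_dir / "summary.json")
    return summary


def _make_cv_scorer(seed: int):
    """3-fold CV error of a small LightGBM booster, for wrapper selection."""
    from sklearn.model_selection import StratifiedKFold
    import lightgbm as lgb

    def scorer(X: np.ndarray, y: np.ndarray) -> float:
        frame = pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        errs = []
        for tr_idx, va_idx in skf.split(frame, y):
            model = lgb.LGBMClassifier(n_estimators=25, learning_rate=0.1,
                                       num_leaves=15, min_child_samples=5,
                                       deterministic=True, force_row_wise=True,
                                       n_jobs=1, random_state=seed, verbosity=-1)
            model.fit(frame.iloc[tr_idx], y[tr_idx])
            errs.append(1.0 - model.score(frame.iloc[va_idx], y[va_idx]))
        return float(np.mean(errs))

    return scorer
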