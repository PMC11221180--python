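"""End-to-end orchestration on phantom data.

``run_pipeline`` wires every stage together: phantom generation →
stratified train/test split → preprocessing (histogram equalization +
downsampling) → U-Net lung segmentation → fragmentation-guided mask
repair → six-subregion partitioning → profusion classification
(single-model route) and/or whole-image cascade staging → rule-based
aggregation → ordinal evaluation.  Every stage writes its artifacts
under the run directory and the run manifest records the config hash
and seed, so a rerun with the same configuration reproduces the
predictions bit-identically.

Large opacities (which alone define stage III in the rule route) are
flagged by a simple detector: after masking, any very bright connected
region whose area exceeds a multiple of the largest admissible small
opacity is counted as a large opacity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, maskops, metrics, phantom, preprocess, segmentation
from .staging import stage_from_profusions

__all__ = ["RunConfig", "split_dataset", "detect_large_opacity", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "runs/phantom"
    n_phantoms: int = 60
    phantom_size: int = 128          # phantom render resolution
    seg_size: int = 128              # U-Net input resolution
    crop_size: int = 32              # subregion crop resolution for the classifier
    cascade_size: int = 64           # whole-image resolution for the cascade nets
    route: str = "both"              # single | cascade | both
    test_ratio: float = 0.2
    seg_epochs: int = 6
    clf_epochs: int = 12
    cascade_epochs: int = 10
    lr: float = 1e-3                 # desk-scale optimizer step size
    folds: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.route not in ("single", "cascade", "both"):
            raise ValueError(f"route must be single/cascade/both, got {self.route!r}")
        if not 0 < self.test_ratio < 1:
            raise ValueError("test_ratio must lie in (0,1)")
        if self.n_phantoms < 10:
            raise ValueError("need at least 10 phantoms for a split")


def split_dataset(manifest: pd.DataFrame, ratio: float, seed: int = 0):
    """Stratified (by stage) train/test split; ``ratio`` is the test fraction.

    Per-stratum test counts are the rounded exact fraction (within 1).
    Strata with fewer than two items go entirely to training, with a
    warning.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0,1)")
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    rng = np.random.default_rng(seed)
    test_idx = []
    for stage, group in manifest.groupby("stage"):
        if len(group) < 2:
            log.warning("stage %s has < 2 items; keeping in training set", stage)
            continue
        n_test = int(round(len(group) * ratio))
        n_test = min(max(n_test, 0), len(group) - 1)
        chosen = rng.choice(group.index.to_numpy(), size=n_test, replace=False)
        test_idx.extend(chosen.tolist())
    test_mask = manifest.index.isin(test_idx)
    return manifest[~test_mask].copy(), manifest[test_mask].copy()


def detect_large_opacity(image: np.ndarray, mask: np.ndarray,
                         brightness: float | None = None,
                         min_area_frac: float = 0.006) -> bool:
    """Heuristic large-opacity flag: a big, very bright blob inside the lungs.

    Operates on the raw (non-equalized) intensity image.  The default
    brightness threshold sits midway between the small-opacity plateau
    and the large-opacity plateau of the phantom intensity model, so
    only large opacities (plus rare noise excursions, removed by the
    area requirement) exceed it.
    """
    from skimage import measure
    if brightness is None:
        base = phantom.PhantomSpec().lung_level
        brightness = base + (phantom.OPACITY_CONTRAST + phantom.LARGE_OPACITY_CONTRAST) / 2
    bright = (image > brightness) & mask.astype(bool)
    lab = measure.label(bright)
    if lab.max() == 0:
        return False
    areas = np.bincount(lab.ravel())[1:]
    return bool(areas.max() >= min_area_frac * image.size)


def _derive_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def _subregion_crops(image: np.ndarray, mask: np.ndarray, crop_size: int):
    """Masked subregion crops resized to the classifier resolution."""
    regions = maskops.partition_six(mask, image)
    crops = []
    for key in maskops.SUBREGION_KEYS:
        crop = regions.crops[key]
        crops.append(preprocess.downsample(crop.astype(np.float32), crop_size))
    return crops


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full phantom pipeline; returns the run summary dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(json.dumps(asdict(cfg), sort_keys=True).encode()).hexdigest()[:16]
    seeds = _derive_seeds(cfg.seed, 8)

    # --- stage 1: phantoms -------------------------------------------------
    log.info("pipeline: generating %d phantoms", cfg.n_phantoms)
    spec_rng = np.random.default_rng(seeds[0])
    samples, rows = [], []
    for i in range(cfg.n_phantoms):
        spec = phantom.random_spec(int(spec_rng.integers(0, 2 ** 31 - 1)),
                                   image_size=cfg.phantom_size)
        s = phantom.generate_phantom(spec)
        samples.append(s)
        rows.append({"index": i, **dict(zip(maskops.SUBREGION_KEYS, s.profusions)),
                     "large_opacity": int(s.large_opacity), "stage": int(s.stage)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)

    train_df, test_df = split_dataset(manifest, cfg.test_ratio, seeds[1])
    train_df.to_csv(out / "train_manifest.csv", index=False)
    test_df.to_csv(out / "test_manifest.csv", index=False)

    # --- stage 2: preprocess ----------------------------------------------
    def prep(img):
        eq = preprocess.equalize_histogram(img.astype(np.float32))
        return preprocess.downsample(eq, cfg.seg_size)

    images = {i: prep(samples[i].image) for i in manifest["index"]}
    raw_images = {i: preprocess.downsample(samples[i].image, cfg.seg_size)
                  for i in manifest["index"]}
    masks = {i: preprocess.downsample(samples[i].mask.astype(np.float32), cfg.seg_size) > 0.5
             for i in manifest["index"]}

    # --- stage 3: segmentation --------------------------------------------
    tr_idx = train_df["index"].tolist()
    te_idx = test_df["index"].tolist()
    n_val = max(2, len(tr_idx) // 5)
    seg_val, seg_train = tr_idx[:n_val], tr_idx[n_val:]
    unet = segmentation.build_unet(segmentation.UNetConfig(
        depth=3, base_channels=8, input_size=cfg.seg_size, seed=seeds[2]))
    seg_report = segmentation.train_segmenter(
        unet, [(images[i], masks[i]) for i in seg_train],
        [(images[i], masks[i]) for i in seg_val],
        epochs=cfg.seg_epochs, lr=cfg.lr, seed=seeds[2], target_iou=0.97)
    log.info("pipeline: segmentation best val IoU %.3f", seg_report.best_val_iou)

    # --- stage 4: predict + repair + partition -----------------------------
    pred_masks, repair_log = {}, []
    for i in te_idx:
        pm = segmentation.predict_mask(unet, images[i])
        cs = maskops.extract_contours(pm)
        size = None
        if cs.n >= 2:
            size = maskops.select_operator_size(cs.n, maskops.fragmentation_factor(cs))
            pm = maskops.repair_mask(pm, size)
        repair_log.append({"index": i, "contours": cs.n, "operator": size,
                           "iou_vs_truth": segmentation.iou(pm, masks[i])})
        pred_masks[i] = pm
    pd.DataFrame(repair_log).to_csv(out / "repair_log.csv", index=False)

    # --- stage 5: profusion classifier (single route) ----------------------
    results = pd.DataFrame({"index": te_idx}).set_index("index")
    results["true_stage"] = [int(samples[i].stage) for i in te_idx]
    summary: dict = {"config_hash": cfg_hash, "seed": cfg.seed,
                     "segmentation_val_iou": seg_report.best_val_iou,
                     "n_train": len(tr_idx), "n_test": len(te_idx)}

    if cfg.route in ("single", "both"):
        # crops are taken from the raw-intensity image: per-image global
        # equalization of the two-level phantom remaps intensities by label
        # content and would confound the classifier (see docs/methods.md)
        n_clf_val = max(2, len(tr_idx) // 5)
        clf_val_idx, clf_tr_idx = tr_idx[:n_clf_val], tr_idx[n_clf_val:]
        crops, levels = [], []
        for i in clf_tr_idx:
            crops.extend(_subregion_crops(raw_images[i], masks[i], cfg.crop_size))
            levels.extend(samples[i].profusions)
        val_crops, val_levels = [], []
        for i in clf_val_idx:
            val_crops.extend(_subregion_crops(raw_images[i], masks[i], cfg.crop_size))
            val_levels.extend(samples[i].profusions)
        levels = np.asarray(levels)
        # oversample minority grades so the net cannot collapse to grade 0
        bal_rng = np.random.default_rng(seeds[3] + 1)
        counts = np.bincount(levels, minlength=4)
        bal_idx = []
        for c in np.flatnonzero(counts):
            ic = np.flatnonzero(levels == c)
            bal_idx.extend(ic.tolist())
            bal_idx.extend(bal_rng.choice(ic, counts.max() - len(ic), replace=True).tolist())
        bal_idx = np.asarray(bal_idx)
        scale_cfg = classify.CompoundScalingConfig(
            depth_factor=1.0, width_factor=0.25, resolution=cfg.crop_size)
        tc = classify.TrainConfig(batch_size=32, init_lr=cfg.lr, epochs=cfg.clf_epochs,
                                  folds=cfg.folds, seed=seeds[3], max_iterations=10 ** 6)
        clf = classify.build_profusion_net(scale_cfg, seed=seeds[4])
        curves = classify.train_simple(clf, [crops[i] for i in bal_idx], levels[bal_idx],
                                       tc, val_images=val_crops, val_labels=val_levels)
        summary["profusion_val_acc"] = curves["val_acc"][-1] if curves["val_acc"] else None

        rule_stages = []
        for i in te_idx:
            mask_i = pred_masks[i] if pred_masks[i].any() else masks[i]
            test_crops = _subregion_crops(raw_images[i], mask_i, cfg.crop_size)
            pred_levels = classify.predict(clf, test_crops)
            large = detect_large_opacity(raw_images[i], mask_i)
            rule_stages.append(int(stage_from_profusions(
                [int(v) for v in pred_levels], large)))
        results["rule_stage"] = rule_stages
        cm = metrics.confusion(results["true_stage"], results["rule_stage"])
        rep = metrics.basic_metrics(cm)
        rep.qwk = metrics.qwk(cm) if cm.sum() else None
        summary["single_route"] = {"confusion": cm.tolist(), **rep.to_dict()}

    # --- stage 6: cascade route --------------------------------------------
    if cfg.route in ("cascade", "both"):
        casc_images = {i: preprocess.downsample(raw_images[i], cfg.cascade_size)
                       for i in manifest["index"]}
        y_stage = {i: int(samples[i].stage) for i in manifest["index"]}
        tc = classify.TrainConfig(batch_size=8, init_lr=cfg.lr, epochs=cfg.cascade_epochs,
                                  folds=2, seed=seeds[5], max_iterations=10 ** 6)

        def fit(indices, labels, seed):
            # oversample the minority class so tiny binary tasks cannot collapse
            labels = np.asarray(labels)
            rng = np.random.default_rng(seed)
            idx = np.arange(len(labels))
            counts = np.bincount(labels, minlength=2)
            if counts.min() == 0:
                raise ValueError("cascade training set lacks one binary class")
            minority = int(counts.argmin())
            extra = rng.choice(idx[labels == minority], counts.max() - counts.min(), replace=True)
            idx = np.concatenate([idx, extra])
            net = classify.build_binary_net(resolution=cfg.cascade_size, seed=seed)
            return classify.train_binary(net, [casc_images[indices[i]] for i in idx],
                                         labels[idx], tc)

        s1 = fit(tr_idx, [int(y_stage[i] > 0) for i in tr_idx], seeds[6])
        diseased = [i for i in tr_idx if y_stage[i] > 0]
        s2 = fit(diseased, [int(y_stage[i] == 3) for i in diseased], seeds[6] + 1)
        mid = [i for i in tr_idx if y_stage[i] in (1, 2)]
        s3 = fit(mid, [int(y_stage[i] == 2) for i in mid], seeds[6] + 2)
        cascade = classify.CascadeModel(stage1=s1, stage2=s2, stage3=s3)
        results["cascade_stage"] = [
            int(classify.cascade_predict(cascade, casc_images[i])) for i in te_idx]
        cm = metrics.confusion(results["true_stage"], results["cascade_stage"])
        rep = metrics.basic_metrics(cm)
        rep.qwk = metrics.qwk(cm)
        summary["cascade_route"] = {"confusion": cm.tolist(), **rep.to_dict()}

    results.reset_index().to_csv(out / "predictions.csv", index=False)
    with open(out / "metrics.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
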