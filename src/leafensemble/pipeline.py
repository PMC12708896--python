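"""Workflow orchestration: generate -> segment -> classify -> fuse ->
evaluate, with checkpoint reuse keyed on config fingerprints.

Checkpoints are a JSON manifest (component, architecture, config hash,
seed, epoch) next to an ``.npz`` weight blob; a stage is skipped when a
manifest with a matching hash and an intact blob already exists.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np

from .classification import build_classifier, predict_probabilities, train_classifier
from .config import RunConfig, config_fingerprint
from .evaluation import grad_cam
from .fusion import (FusionWeights, optimize_fusion_weights,
                     uniform_fusion_accuracy)
from .preprocess import augment_stream
from .segmentation import (SegEnsembleConfig, build_segmenter,
                           combine_probability_maps, extract_roi,
                           train_segmenter)
from .synthetic import generate_leaf_dataset
from ._autograd import Tensor

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model, out_dir: Path, name: str, *, component: str,
                    architecture: str, config, seed: int, epoch: int) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = out_dir / f"{name}.npz"
    np.savez(blob, **model.state_dict())
    manifest = {
        "component": component,
        "architecture": architecture,
        "config_hash": config_fingerprint(config),
        "seed": seed,
        "epoch": epoch,
        "blob": blob.name,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / f"{name}.json").write_text(json.dumps(manifest, indent=1))
    return blob


def load_checkpoint(model, out_dir: Path, name: str, config) -> bool:
    """Load weights into ``model`` if a checkpoint with a matching config
    hash exists and its blob is intact; returns True on success."""
    man_path = out_dir / f"{name}.json"
    blob_path = out_dir / f"{name}.npz"
    if not man_path.exists() or not blob_path.exists():
        return False
    try:
        manifest = json.loads(man_path.read_text())
        if manifest.get("config_hash") != config_fingerprint(config):
            logger.warning("checkpoint %s stale (config changed); retraining", name)
            return False
        with np.load(blob_path) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return True
    except Exception as exc:     # corrupt blob or manifest
        logger.warning("checkpoint %s unreadable (%s); retraining", name, exc)
        return False


# --------------------------------------------------------------------------
# data plumbing


def split_dataset(samples, seed: int, fractions=(0.6, 0.2, 0.2)):
    """Deterministic stratified-ish train/val/test split."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(samples))
    n_train = int(len(samples) * fractions[0])
    n_val = int(len(samples) * fractions[1])
    pick = lambda ids: [samples[i] for i in ids]
    return (pick(idx[:n_train]), pick(idx[n_train:n_train + n_val]),
            pick(idx[n_train + n_val:]))


def segment_rois(samples, segmenters, ensemble: SegEnsembleConfig,
                 roi_pad: float = 0.1, batch_size: int = 32) -> np.ndarray:
    """Ensemble-segment every sample and return the stack of ROI crops
    (resized back to the input size so classifier shapes are stable)."""
    images = np.stack([s.image for s in samples])
    size = images.shape[1]
    x = images.transpose(0, 3, 1, 2).astype(np.float32)
    member_maps = []
    for model in segmenters:
        model.eval()
        outs = [model.forward(Tensor(x[i:i + batch_size])).data
                for i in range(0, len(x), batch_size)]
        member_maps.append(np.concatenate(outs, axis=0))
    rois = []
    for i, img in enumerate(images):
        maps = [mm[i] for mm in member_maps]
        score = combine_probability_maps(maps, ensemble)
        mask = (score >= ensemble.threshold).astype(np.uint8)
        rois.append(extract_roi(img, mask, roi_pad, size))
    return np.stack(rois)


# --------------------------------------------------------------------------
# the full run


def run_pipeline(config: RunConfig, *, explain: bool = False,
                 heatmap_count: int = 8) -> dict:
    """Execute every stage in order, reusing matching checkpoints.

    Returns the run report (also written to ``output_dir/report.json``).
    """
    out = Path(config.output_dir)
    ckpt = out / "checkpoints"
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "files": [], "seed": config.seed}
    t_start = time.time()

    # -- stage: generate ----------------------------------------------------
    t0 = time.time()
    samples = generate_leaf_dataset(config.dataset)
    if config.use_augmentation:
        samples = samples + augment_stream(samples, config.augment)
    train_set, val_set, test_set = split_dataset(samples, config.seed)
    report["stages"]["generate"] = {
        "n_total": len(samples), "n_train": len(train_set),
        "n_val": len(val_set), "n_test": len(test_set),
        "seconds": round(time.time() - t0, 2),
    }

    # -- stage: train segmenters --------------------------------------------
    segmenters = []
    for arch, arch_cfg, tr_cfg in (("unet", config.unet, config.seg_train),
                                   ("swin", config.swin, config.swin_train)):
        t0 = time.time()
        model = build_segmenter(arch, tr_cfg.seed,
                                unet_config=config.unet, swin_config=config.swin)
        key = (arch_cfg, tr_cfg, config.dataset)
        if load_checkpoint(model, ckpt, arch, key):
            info = {"reused_checkpoint": True}
        else:
            model, hist = train_segmenter(train_set, arch, tr_cfg,
                                          unet_config=config.unet,
                                          swin_config=config.swin, model=model)
            save_checkpoint(model, ckpt, arch, component="segmenter",
                            architecture=arch, config=key, seed=tr_cfg.seed,
                            epoch=tr_cfg.epochs)
            info = {"reused_checkpoint": False,
                    "final_val_dice": hist["val_dice"][-1],
                    "final_val_loss": hist["val_loss"][-1]}
        info["seconds"] = round(time.time() - t0, 2)
        report["stages"][f"train-seg-{arch}"] = info
        segmenters.append(model)

    # -- stage: ROI extraction ----------------------------------------------
    t0 = time.time()
    roi_train = segment_rois(train_set, segmenters, config.ensemble)
    roi_val = segment_rois(val_set, segmenters, config.ensemble)
    roi_test = segment_rois(test_set, segmenters, config.ensemble)
    report["stages"]["extract-roi"] = {"seconds": round(time.time() - t0, 2)}
    y_train = np.asarray([s.label for s in train_set])
    y_val = np.asarray([s.label for s in val_set])
    y_test = np.asarray([s.label for s in test_set])

    # -- stage: train classifiers -------------------------------------------
    classifiers = []
    for arch, arch_cfg, tr_cfg in (
            ("coatnet", config.coatnet, config.clf_train),
            ("enhanced", config.enhanced, config.enhanced_train)):
        t0 = time.time()
        model = build_classifier(arch, tr_cfg.seed,
                                 coatnet_config=config.coatnet,
                                 enhanced_config=config.enhanced)
        key = (arch_cfg, tr_cfg, config.dataset, config.ensemble)
        if load_checkpoint(model, ckpt, arch, key):
            info = {"reused_checkpoint": True}
        else:
            model, hist = train_classifier(None, arch, tr_cfg,
                                           coatnet_config=config.coatnet,
                                           enhanced_config=config.enhanced,
                                           model=model, images=roi_train,
                                           labels=y_train)
            save_checkpoint(model, ckpt, arch, component="classifier",
                            architecture=arch, config=key, seed=tr_cfg.seed,
                            epoch=tr_cfg.epochs)
            info = {"reused_checkpoint": False,
                    "final_val_acc": hist["val_acc"][-1]}
        info["seconds"] = round(time.time() - t0, 2)
        report["stages"][f"train-clf-{arch}"] = info
        classifiers.append(model)

    # -- stage: fuse ---------------------------------------------------------
    t0 = time.time()
    val_probs = [predict_probabilities(m, roi_val) for m in classifiers]
    weights, trace = optimize_fusion_weights(val_probs, y_val, config.lfhba)
    report["stages"]["fuse"] = {
        "weights": weights.w.tolist(),
        "val_fused_accuracy": -trace.best_fitness[-1],
        "val_uniform_accuracy": uniform_fusion_accuracy(val_probs, y_val),
        "evaluations": trace.evaluations,
        "seconds": round(time.time() - t0, 2),
    }
    _write_json(out / "fusion_weights.json", {"w": weights.w.tolist()})
    _write_json(out / "fusion_trace.json",
                {"best_fitness": trace.best_fitness,
                 "evaluations": trace.evaluations})
    report["files"] += ["fusion_weights.json", "fusion_trace.json"]

    # -- stage: evaluate -----------------------------------------------------
    t0 = time.time()
    result = _evaluate_split(test_set, roi_test, y_test, classifiers, weights)
    report["stages"]["evaluate"] = {
        "fused_accuracy": result["fused_accuracy"],
        "member_accuracies": result["member_accuracies"],
        "auc_macro": result["auc_macro"],
        "metrics": result["metrics"].as_dict(),
        "seconds": round(time.time() - t0, 2),
    }
    np.savetxt(out / "confusion_matrix.csv", result["confusion"].counts,
               fmt="%d", delimiter=",")
    _write_json(out / "metrics.json", result["metrics"].as_dict())
    report["files"] += ["confusion_matrix.csv", "metrics.json"]

    # -- stage: explain (optional) -------------------------------------------
    if explain:
        t0 = time.time()
        gallery = out / "heatmaps"
        gallery.mkdir(exist_ok=True)
        from PIL import Image

        for i, s in enumerate(test_set[:heatmap_count]):
            hm = grad_cam(classifiers[0], s.image, s.label)
            arr = (hm.values * 255).astype(np.uint8)
            Image.fromarray(arr).save(gallery / f"cam_{i}_class{s.label}.png")
            report["files"].append(f"heatmaps/cam_{i}_class{s.label}.png")
        report["stages"]["explain"] = {"count": min(heatmap_count, len(test_set)),
                                       "seconds": round(time.time() - t0, 2)}

    report["total_seconds"] = round(time.time() - t_start, 2)
    report["files"] = [f for f in report["files"] if (out / f).exists()]
    _write_json(out / "report.json", report)
    return report


def _evaluate_split(samples, rois, labels, classifiers, weights: FusionWeights):
    from .evaluation import compute_metrics, confusion, roc_auc
    from .fusion import fuse_predictions

    n_classes = (classifiers[0].config.n_classes
                 if hasattr(classifiers[0], "config")
                 else classifiers[0].base.config.n_classes)
    prob_mats = [predict_probabilities(m, rois) for m in classifiers]
    fused = fuse_predictions(prob_mats, weights)
    pred = fused.argmax(axis=1)
    cm = confusion(labels, pred, n_classes)
    aucs, macro_auc = roc_auc(labels, fused, n_classes)
    return {
        "metrics": compute_metrics(cm),
        "confusion": cm,
        "auc_per_class": aucs,
        "auc_macro": macro_auc,
        "member_accuracies": [float((m.argmax(1) == labels).mean())
                              for m in prob_mats],
        "fused_accuracy": float((pred == labels).mean()),
        "probabilities": prob_mats,
        "fused_probabilities": fused,
    }


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
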