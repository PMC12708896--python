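"""Evaluation: confusion matrices, one-vs-rest metric suite, ROC/AUC,
Grad-CAM heatmaps, and the end-to-end pipeline scorer.

Per-class metrics are one-vs-rest from the confusion matrix: accuracy
(TP+TN)/(TP+TN+FP+FN), recall TP/(TP+FN), specificity TN/(TN+FP),
precision TP/(TP+FP) and F1 = 2PR/(P+R), each macro-averaged
(unweighted mean over classes) by default; zero-denominator cells are
defined as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor
from .fusion import FusionWeights, fuse_predictions
from .synthetic import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray     # K x K, rows = true class, columns = predicted

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValidationError("confusion matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    per_class: dict[str, np.ndarray] = field(default_factory=dict)
    averaging_mode: str = "macro"

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "specificity": self.specificity,
            "f1": self.f1, "averaging_mode": self.averaging_mode,
            "per_class": {k: v.tolist() for k, v in self.per_class.items()},
        }


def confusion(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """counts[i, j] = number of samples with true class i predicted j."""
    t = np.asarray(y_true, dtype=np.int64)
    p = np.asarray(y_pred, dtype=np.int64)
    if t.shape != p.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    if t.size and (t.min() < 0 or t.max() >= n_classes or
                   p.min() < 0 or p.max() >= n_classes):
        raise ValidationError(f"labels out of range [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def _safe_div(num, den):
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


def compute_metrics(cm: ConfusionMatrix, mode: str = "macro") -> MetricsReport:
    """One-vs-rest metric suite from a confusion matrix.

    ``mode='macro'`` is the unweighted mean over classes; ``'micro'``
    pools the one-vs-rest counts before dividing.
    """
    if cm.total == 0:
        raise ValidationError("compute_metrics: empty confusion matrix")
    c = cm.counts.astype(np.float64)
    n = c.sum()
    tp = np.diag(c)
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = n - tp - fn - fp
    per = {
        "accuracy": _safe_div(tp + tn, tp + tn + fp + fn),
        "recall": _safe_div(tp, tp + fn),
        "specificity": _safe_div(tn, tn + fp),
        "precision": _safe_div(tp, tp + fp),
    }
    per["f1"] = _safe_div(2.0 * per["precision"] * per["recall"],
                          per["precision"] + per["recall"])
    absent = (tp + fn == 0) & (tp + fp == 0)
    if absent.any():
        logger.info("classes never present nor predicted: %s",
                    np.nonzero(absent)[0].tolist())
    if mode == "macro":
        agg = {k: float(v.mean()) for k, v in per.items()}
    elif mode == "micro":
        prec = _safe_div(tp.sum(), tp.sum() + fp.sum())
        rec = _safe_div(tp.sum(), tp.sum() + fn.sum())
        agg = {
            "accuracy": float(_safe_div((tp + tn).sum(), n * len(tp))),
            "recall": float(rec),
            "specificity": float(_safe_div(tn.sum(), tn.sum() + fp.sum())),
            "precision": float(prec),
            "f1": float(_safe_div(2 * prec * rec, prec + rec)),
        }
    else:
        raise ValidationError(f"unknown averaging mode '{mode}'")
    return MetricsReport(per_class=per, averaging_mode=mode, **agg)


def roc_auc(y_true, scores, n_classes: int):
    """One-vs-rest ROC AUC per class (trapezoidal) plus the macro mean
    over classes present in ``y_true``; absent classes are excluded and
    reported as NaN."""
    from sklearn.metrics import roc_auc_score

    t = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    if s.shape != (len(t), n_classes):
        raise ValidationError(f"scores must be n x {n_classes}")
    aucs = np.full(n_classes, np.nan)
    for k in range(n_classes):
        pos = t == k
        if pos.all() or not pos.any():
            logger.info("roc_auc: class %d absent from one side, skipped", k)
            continue
        aucs[k] = roc_auc_score(pos.astype(int), s[:, k])
    macro = float(np.nanmean(aucs)) if np.isfinite(aucs).any() else float("nan")
    return aucs, macro


# --------------------------------------------------------------------------
# Grad-CAM


@dataclass
class HeatMap:
    values: np.ndarray
    target_class: int
    layer: str


def grad_cam(model, image: np.ndarray, target_class: int,
             layer: str | None = None) -> HeatMap:
    """Gradient-weighted class activation map.

    Channel weights are the spatial mean of the gradient of the target
    class logit with respect to the chosen feature map; the heatmap is
    the rectified weighted channel sum, bilinearly upsampled to the input
    size and max-normalized to [0, 1] (an all-zero map stays all-zero).
    """
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim != 3:
        raise ValidationError("grad_cam expects a single H x W x 3 image")
    h, w = arr.shape[:2]
    x = Tensor(arr.transpose(2, 0, 1)[None])
    model.eval()
    logits = model.logits(x)
    if layer is None:
        layer = model.default_cam_layer
    feats = model._features
    if layer not in feats:
        raise ValidationError(
            f"unknown layer '{layer}'; available: {sorted(feats)}")
    fmap = feats[layer]
    onehot = np.zeros_like(logits.data)
    onehot[0, target_class] = 1.0
    logits.backward(onehot)
    if fmap.grad is None:
        raise ValidationError(f"layer '{layer}' is not part of the forward graph")
    weights = fmap.grad.mean(axis=(2, 3))                 # (1, C)
    cam = np.maximum((weights[:, :, None, None] * fmap.data).sum(axis=1), 0.0)
    cam_t = Tensor(cam[:, None]).upsample_bilinear(h, w).data[0, 0]
    peak = cam_t.max()
    if peak > 0:
        cam_t = cam_t / peak
    return HeatMap(values=cam_t.astype(np.float32), target_class=int(target_class),
                   layer=layer)


# --------------------------------------------------------------------------
# end-to-end evaluation


def evaluate_pipeline(samples, segmenters, classifiers, weights: FusionWeights,
                      ensemble_config=None, roi_pad: float = 0.1,
                      roi_size: int | None = None, batch_size: int = 32):
    """Segmentation ensemble -> ROI extraction -> classifiers -> fusion
    -> metrics.

    ``samples``: list of SyntheticSample; ``segmenters``: list of trained
    segmentation models (may be empty to classify whole images);
    ``classifiers``: list of trained classifier models.  Returns a dict
    with the fused MetricsReport, per-classifier reports, the confusion
    matrix and ROC points.
    """
    from .classification import predict_probabilities
    from .segmentation import SegEnsembleConfig, combine_probability_maps, extract_roi

    if ensemble_config is None:
        ensemble_config = SegEnsembleConfig()
    labels = np.asarray([s.label for s in samples])
    n_classes = classifiers[0].config.n_classes if hasattr(
        classifiers[0], "config") else classifiers[0].base.config.n_classes
    images = np.stack([s.image for s in samples])
    if segmenters:
        rois = []
        for img in images:
            maps = [_seg_forward(m, img) for m in segmenters]
            score = combine_probability_maps(maps, ensemble_config)
            mask = (score >= ensemble_config.threshold).astype(np.uint8)
            rois.append(extract_roi(img, mask, roi_pad,
                                    roi_size or img.shape[0]))
        clf_inputs = np.stack(rois)
    else:
        clf_inputs = images
    prob_mats = [predict_probabilities(m, clf_inputs, batch_size=batch_size)
                 for m in classifiers]
    fused = fuse_predictions(prob_mats, weights)
    pred = fused.argmax(axis=1)
    cm = confusion(labels, pred, n_classes)
    report = compute_metrics(cm)
    aucs, macro_auc = roc_auc(labels, fused, n_classes)
    member_reports = []
    for mat in prob_mats:
        mcm = confusion(labels, mat.argmax(axis=1), n_classes)
        member_reports.append(compute_metrics(mcm))
    return {
        "metrics": report,
        "confusion": cm,
        "auc_per_class": aucs,
        "auc_macro": macro_auc,
        "member_metrics": member_reports,
        "member_accuracies": [float((m.argmax(1) == labels).mean())
                              for m in prob_mats],
        "fused_accuracy": float((pred == labels).mean()),
        "probabilities": prob_mats,
        "fused_probabilities": fused,
    }


def _seg_forward(model, image: np.ndarray) -> np.ndarray:
    x = Tensor(np.asarray(image, dtype=np.float32).transpose(2, 0, 1)[None])
    return model.forward(x).data[0]
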