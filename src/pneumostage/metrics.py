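"""Ordinal-classification evaluation: confusion matrices, QWK, ROC/AUC, stability.

All scalar metrics derive from a confusion matrix with **rows = actual**
class and **columns = predicted** class, class order Normal, I, II, III.
Accuracy is the trace over the total; per-class precision/recall/F1 are
one-vs-rest.  Ordinal agreement uses the quadratic weighted kappa

    κ = 1 − Σ w_ij O_ij / Σ w_ij E_ij,     w_ij = (i−j)² / (K−1)²,

where ``O`` is the observed matrix and ``E`` the outer product of its
margins divided by n (expected counts under chance agreement with the
same margins).  κ is 1 for any purely diagonal matrix, 0 when O = E, and
invariant under transposition because the weights are symmetric.

The module also ships golden fixtures: the confusion matrices and
per-stage metric tables reported for the clinical cohort (498
radiographs, 100-image test split; 193 subregion-level decisions for
the multi-stage route) whose design this package follows.  Two printed
cells of the multi-stage table are internally inconsistent with its own
confusion matrix; these are recorded in ``EXPECTED_DISCREPANCIES``
rather than silently corrected, and tests assert the recomputed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "STAGE_NAMES", "MetricReport", "confusion", "basic_metrics", "qwk",
    "roc_auc", "stability_analysis", "load_fixture_confusion",
    "load_fixture_stage_metrics", "EXPECTED_DISCREPANCIES",
]

STAGE_NAMES = ("Normal", "StageI", "StageII", "StageIII")

#: printed reference cells that do NOT recompute from their own confusion
#: matrix; keys are (fixture, cell), values are (printed, recomputed_from_matrix)
EXPECTED_DISCREPANCIES = {
    ("multistage", "qwk"): (0.94, 0.9226),
    ("multistage", "precision_StageI"): (0.82, 0.90),
    # printed F1 appears truncated: 2*(44/51)*(44/47) / ((44/51)+(44/47)) = 0.898
    ("singlemodel", "f1_Normal"): (0.89, 0.90),
}


@dataclass
class MetricReport:
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    qwk: float | None = None
    auc: float | None = None
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "qwk": self.qwk,
            "auc": self.auc,
            "undefined": self.undefined,
        }


def confusion(y_true, y_pred, n_classes: int = 4) -> np.ndarray:
    """Count matrix: counts[a, p] = #{i : true_i = a, pred_i = p}."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length non-empty 1-D sequences")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _check_cm(cm) -> np.ndarray:
    cm = np.asarray(cm, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any() or cm.sum() < 1:
        raise ValueError("confusion matrix must be non-negative with total >= 1")
    return cm


def basic_metrics(cm, class_names=STAGE_NAMES) -> MetricReport:
    """Accuracy plus one-vs-rest precision/recall/F1 per class.

    A zero denominator (class never predicted, or absent) yields 0 for
    that ratio and the affected quantity is listed in ``undefined``.
    """
    cm = _check_cm(cm)
    names = list(class_names)[: cm.shape[0]]
    total = cm.sum()
    acc = float(np.trace(cm) / total)
    prec, rec, f1, undef = {}, {}, {}, []
    for i, name in enumerate(names):
        col, row, diag = cm[:, i].sum(), cm[i, :].sum(), cm[i, i]
        if col > 0:
            prec[name] = float(diag / col)
        else:
            prec[name] = 0.0
            undef.append(f"precision_{name}")
        if row > 0:
            rec[name] = float(diag / row)
        else:
            rec[name] = 0.0
            undef.append(f"recall_{name}")
        denom = prec[name] + rec[name]
        if denom > 0:
            f1[name] = 2 * prec[name] * rec[name] / denom
        else:
            f1[name] = 0.0
            undef.append(f"f1_{name}")
    return MetricReport(accuracy=acc, precision=prec, recall=rec, f1=f1, undefined=undef)


def qwk(cm) -> float:
    """Quadratic weighted kappa of a K×K confusion matrix (see module docstring)."""
    cm = _check_cm(cm)
    k = cm.shape[0]
    if k < 2:
        raise ValueError("QWK needs at least 2 classes")
    n = cm.sum()
    rows, cols = cm.sum(axis=1), cm.sum(axis=0)
    if (np.count_nonzero(rows) <= 1) and (np.count_nonzero(cols) <= 1):
        raise ValueError("QWK undefined: all mass in a single class margin")
    i, j = np.indices((k, k))
    w = (i - j) ** 2 / (k - 1) ** 2
    expected = np.outer(rows, cols) / n
    denom = (w * expected).sum()
    if denom == 0:
        raise ValueError("QWK undefined: zero expected disagreement")
    return float(1.0 - (w * cm).sum() / denom)


def roc_auc(y_true, scores):
    """ROC points by threshold sweep and AUC by the trapezoid rule.

    The AUC equals the tie-aware Mann–Whitney statistic
    P(score⁺ > score⁻) + ½·P(tie).  Both classes must be present.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if set(np.unique(y_true)) != {0, 1}:
        raise ValueError("roc_auc needs both binary classes present")
    fpr, tpr, thresh = _sk_roc_curve(y_true, scores)
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


def stability_analysis(predict_fn, images, blur_radii, noise_props, seed: int = 0) -> np.ndarray:
    """Prediction consistency under Gaussian blur and additive Gaussian noise.

    ``predict_fn(img) -> label`` is evaluated on each clean image and on
    every (blur radius, noise proportion) perturbation of it; cell
    ``[i, j]`` is the fraction of images whose perturbed prediction
    matches the clean one.  Noise proportion is the noise standard
    deviation as a fraction of the [0,1] intensity range.  The
    (radius 0, proportion 0) cell is the identity perturbation and is 1
    by construction.
    """
    images = [np.asarray(im, dtype=np.float32) for im in images]
    if not images:
        raise ValueError("stability analysis needs at least one image")
    rng = np.random.default_rng(seed)
    clean = [predict_fn(im) for im in images]
    out = np.zeros((len(blur_radii), len(noise_props)))
    for i, radius in enumerate(blur_radii):
        for j, prop in enumerate(noise_props):
            agree = 0
            for im, ref in zip(images, clean):
                pert = ndimage.gaussian_filter(im, radius) if radius > 0 else im
                if prop > 0:
                    pert = np.clip(pert + rng.normal(0, prop, im.shape), 0, 1).astype(np.float32)
                agree += predict_fn(pert) == ref
            out[i, j] = agree / len(images)
    return out


def _fixture_path(name: str):
    return resources.files("pneumostage.fixtures") / name


def load_fixture_confusion(which: str) -> np.ndarray:
    """Load a reference confusion matrix ('singlemodel' or 'multistage')."""
    if which not in ("singlemodel", "multistage"):
        raise ValueError("which must be 'singlemodel' or 'multistage'")
    df = pd.read_csv(_fixture_path(f"{which}_confusion.csv"), index_col=0)
    return df.to_numpy(dtype=np.int64)


def load_fixture_stage_metrics(which: str) -> pd.DataFrame:
    """Load the printed per-stage precision/recall/F1 table for a route."""
    if which not in ("singlemodel", "multistage"):
        raise ValueError("which must be 'singlemodel' or 'multistage'")
    return pd.read_csv(_fixture_path(f"{which}_stage_metrics.csv"), index_col=0)
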