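"""Segmentation loss and evaluation metric."""

from __future__ import annotations

import numpy as np

__all__ = ["cross_entropy_loss", "miou"]


def cross_entropy_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy between per-point class scores and true labels.

    ``scores`` are raw logits (N x C); the loss is the mean over points of
    ``-log softmax(z)[true class]``.
    """
    z = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if z.ndim != 2:
        raise ValueError("scores must be N x C")
    if y.shape[0] != z.shape[0]:
        raise ValueError("labels length must match score rows")
    if y.min() < 0 or y.max() >= z.shape[1]:
        raise ValueError(f"labels must lie in [0, {z.shape[1]})")
    shifted = z - z.max(axis=1, keepdims=True)
    log_probs = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    return float(-log_probs[np.arange(len(y)), y].mean())


def miou(pred: np.ndarray, truth: np.ndarray, num_classes: int) -> float:
    """Mean intersection-over-union in percent.

    Per class k: ``IoU_k = TP_k / (TP_k + FP_k + FN_k)``; the mean over the
    ``num_classes`` classes is scaled by 100.  A class absent from both the
    prediction and the truth (0/0) counts as IoU 1.
    """
    p = np.asarray(pred).ravel()
    t = np.asarray(truth).ravel()
    if p.shape != t.shape:
        raise ValueError("pred and truth must have the same length")
    if num_classes < 1:
        raise ValueError("num_classes must be >= 1")
    for name, v in (("pred", p), ("truth", t)):
        if v.min() < 0 or v.max() >= num_classes:
            raise ValueError(f"{name} classes must lie in [0, {num_classes})")
    conf = np.bincount(t * num_classes + p, minlength=num_classes**2).reshape(
        num_classes, num_classes
    )
    tp = np.diag(conf).astype(float)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    denom = tp + fp + fn
    iou = np.where(denom > 0, tp / np.where(denom > 0, denom, 1.0), 1.0)
    return float(iou.mean() * 100.0)
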