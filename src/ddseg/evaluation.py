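"""Inference and overlap metrics (DC, IoU, sensitivity, precision).

Inference uses only the encoder and decoder-1: decoder-2 and the
discriminators are never evaluated, so a checkpoint without them predicts
identically. Metrics follow the usual pixel-count definitions; slices where
a ratio is undefined (empty ground truth for sensitivity, empty prediction
for precision) return ``None`` and are excluded from dataset aggregation.
Aggregation is the arithmetic mean of per-slice metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .networks import Generator, forward_generator

__all__ = [
    "MetricsReport",
    "predict_mask",
    "dice_coefficient",
    "iou",
    "sensitivity",
    "precision",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class MetricsReport:
    dc: float
    iou: float
    trp: Optional[float]
    ppv: Optional[float]
    n_items: int

    def as_dict(self):
        return {"dc": self.dc, "iou": self.iou, "trp": self.trp, "ppv": self.ppv, "n_items": self.n_items}


def predict_mask(gen: Generator, image, threshold: float = 0.5) -> np.ndarray:
    """Binarise the decoder-1 heat map at ``threshold`` (strict >)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly in (0, 1)")
    was_training = gen.training
    gen.eval()
    try:
        out = forward_generator(gen, image, with_boundary=False)
    finally:
        gen.train(was_training)
    heat = np.asarray(out.heat_map)
    mask = (heat > threshold).astype(np.uint8)
    if np.ndim(image) == 2:
        return mask[0, 0]
    return mask[:, 0]


def _binary(a, name):
    arr = np.asarray(a)
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return arr.astype(bool)


def _counts(pred, gt):
    p = _binary(pred, "pred")
    g = _binary(gt, "gt")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    return tp, fp, fn


def dice_coefficient(pred, gt) -> float:
    """DC = 2|v.h| / (|v| + |h|); 1 when both masks are empty."""
    tp, fp, fn = _counts(pred, gt)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def iou(pred, gt) -> float:
    """IoU = |v.h| / |v u h|; 1 when both masks are empty."""
    tp, fp, fn = _counts(pred, gt)
    union = tp + fp + fn
    return 1.0 if union == 0 else tp / union


def sensitivity(pred, gt) -> Optional[float]:
    """TRP = TP / (TP + FN); None (undefined) when the ground truth is empty."""
    tp, _, fn = _counts(pred, gt)
    if tp + fn == 0:
        return None
    return tp / (tp + fn)


def precision(pred, gt) -> Optional[float]:
    """PPV = TP / (TP + FP); None (undefined) when the prediction is empty."""
    tp, fp, _ = _counts(pred, gt)
    if tp + fp == 0:
        return None
    return tp / (tp + fp)


def evaluate_dataset(gen: Generator, test_items, threshold: float = 0.5) -> MetricsReport:
    """Per-slice metrics, arithmetic-mean aggregated (None items dropped per metric)."""
    items = list(test_items)
    if not items:
        raise ValueError("evaluate_dataset: empty test set")
    dcs, ious, trps, ppvs = [], [], [], []
    for image, gt in items:
        pred = predict_mask(gen, np.asarray(image), threshold)
        dcs.append(dice_coefficient(pred, gt))
        ious.append(iou(pred, gt))
        t = sensitivity(pred, gt)
        if t is not None:
            trps.append(t)
        p = precision(pred, gt)
        if p is not None:
            ppvs.append(p)
    return MetricsReport(
        dc=float(np.mean(dcs)),
        iou=float(np.mean(ious)),
        trp=float(np.mean(trps)) if trps else None,
        ppv=float(np.mean(ppvs)) if ppvs else None,
        n_items=len(items),
    )
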