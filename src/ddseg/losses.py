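"""The six training losses and the weighted generator objective.

Supervised side (source domain only): soft dice on the decoder-1 heat map
and a mean-squared boundary loss between the Sobel boundary map of
decoder-2 and the Sobel label of the ground truth. Adversarial side: the
generator minimises -log D(.) on target-domain score maps (labels flipped),
while each discriminator minimises its own source-vs-target cross-entropy.

All functions accept either plain NumPy arrays (returning floats, as used
in evaluation and tests) or autodiff tensors (returning tensors, as used in
training) — the arithmetic is written once over the common operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

__all__ = [
    "LossWeights",
    "DICE_SMOOTH",
    "dice_loss",
    "segmentation_loss",
    "boundary_loss",
    "adversarial_loss",
    "classification_loss",
    "generator_objective",
]

DICE_SMOOTH = 1e-6


@dataclass(frozen=True)
class LossWeights:
    """Objective weights: L = Lseg + lb*Lb + le*Ladv_e + ld*Ladv_d."""

    lambda_b: float = 0.2
    lambda_adv_e: float = 0.0005
    lambda_adv_d: float = 0.003

    def __post_init__(self):
        if min(self.lambda_b, self.lambda_adv_e, self.lambda_adv_d) < 0:
            raise ValueError("loss weights must be non-negative")


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _sum(x, axis=None):
    return x.sum(axis=axis) if isinstance(x, Tensor) else np.sum(x, axis=axis)


def _mean(x):
    return x.mean() if isinstance(x, Tensor) else float(np.mean(x))


def _log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def _shape(x):
    return x.data.shape if isinstance(x, Tensor) else np.asarray(x).shape


def _scalar(x):
    return x if isinstance(x, Tensor) else float(x)


def _check_shapes(a, b, what):
    if _shape(a) != _shape(b):
        raise ValueError(f"{what}: shape mismatch {_shape(a)} vs {_shape(b)}")


def dice_loss(heat, mask, smooth: float = DICE_SMOOTH):
    """Soft dice loss 1 - (2|v.h| + eps) / (|v| + |h| + eps) over one image."""
    _check_shapes(heat, mask, "dice_loss")
    hdata = heat.data if isinstance(heat, Tensor) else np.asarray(heat)
    if hdata.size and (hdata.min() < 0 or hdata.max() > 1):
        raise ValueError("heat map values must lie in [0, 1]")
    inter = _sum(heat * mask)
    total = _sum(heat) + _sum(mask)
    return 1.0 - (2.0 * inter + smooth) / (total + smooth)


def segmentation_loss(heats, masks, smooth: float = DICE_SMOOTH):
    """Per-image soft dice averaged over the batch (leading axis)."""
    n = _shape(heats)[0]
    if n == 0:
        raise ValueError("segmentation_loss: empty batch")
    _check_shapes(heats, masks, "segmentation_loss")
    if _is_tensor(heats, masks):
        total = dice_loss(_index(heats, 0), _index(masks, 0), smooth)
        for i in range(1, n):
            total = total + dice_loss(_index(heats, i), _index(masks, i), smooth)
        return total * (1.0 / n)
    return float(np.mean([dice_loss(heats[i], masks[i], smooth) for i in range(n)]))


def _index(x, i):
    """Select item i along the leading axis (autodiff-aware)."""
    if not isinstance(x, Tensor):
        return np.asarray(x)[i]
    data = x.data[i]

    def back(g, x=x, i=i):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[i] = g
            x._accum(full)

    from .autograd import _node

    return _node(data, (x,), back)


def boundary_loss(boundary_map, boundary_label):
    """Mean squared error between boundary map b and Sobel label z."""
    _check_shapes(boundary_map, boundary_label, "boundary_loss")
    diff = boundary_map - boundary_label
    return _mean(diff * diff)


def _check_scores(scores):
    data = scores.data if isinstance(scores, Tensor) else np.asarray(scores)
    if data.size == 0:
        raise ValueError("empty score map")
    if data.min() <= 0.0 or data.max() >= 1.0:
        raise ValueError("domain scores must lie strictly in (0, 1)")


def adversarial_loss(scores):
    """Generator-side loss on TARGET-domain scores with flipped labels.

    mean over score-map locations of -log D(.): low when the discriminator
    is fooled into calling target outputs 'source'.
    """
    _check_scores(scores)
    return _mean(-_log(scores))


def classification_loss(scores_source, scores_target):
    """Discriminator loss with true labels: -log D on source, -log(1-D) on target."""
    _check_scores(scores_source)
    _check_scores(scores_target)
    return _mean(-_log(scores_source)) + _mean(-_log(1.0 - scores_target))


def generator_objective(l_seg, l_b, l_adv_e, l_adv_d, w: LossWeights = LossWeights()):
    """Weighted generator objective Lseg + lb*Lb + le*Ladv_e + ld*Ladv_d.

    The discriminators' classification losses are bookkept separately: they
    update only the discriminators, so they do not enter the generator's
    minimised objective.
    """
    for name, v in (("l_seg", l_seg), ("l_b", l_b), ("l_adv_e", l_adv_e), ("l_adv_d", l_adv_d)):
        val = v.data if isinstance(v, Tensor) else v
        if np.any(np.asarray(val) < 0):
            raise ValueError(f"{name} must be non-negative")
    return (
        _scalar(l_seg)
        + w.lambda_b * _scalar(l_b)
        + w.lambda_adv_e * _scalar(l_adv_e)
        + w.lambda_adv_d * _scalar(l_adv_d)
    )
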