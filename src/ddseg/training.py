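"""Five-step alternating training for dual-discriminator domain adaptation.

Each iteration consumes one source batch (images, masks, boundary labels)
and one target batch (images only) and performs, in order:

1. segmentation: soft dice on source heat maps -> update encoder + decoder-1;
2. boundary: MSE between the Sobel boundary map of decoder-2 and the Sobel
   label -> update encoder + decoder-2;
3. adversarial: -log D(.) on target score maps with flipped domain labels,
   weighted by lambda_adv_e / lambda_adv_d -> update encoder + decoder-1;
4. feature-level classification: cross-entropy with true domain labels on
   detached bottleneck features -> update De only;
5. output-level classification: same on detached heat maps -> update Dd only.

Modes: ``supervised`` runs steps 1-2 and builds no discriminators;
``uda_output`` runs 1, 2, the output half of 3, and 5 (only Dd exists);
``dd_uda`` runs all five. ``boundary_enabled=False`` drops decoder-2 and
step 2 in any mode.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .autograd import Adam, Tensor
from .losses import (
    LossWeights,
    adversarial_loss,
    boundary_loss,
    classification_loss,
    segmentation_loss,
)
from .networks import (
    Discriminator,
    DiscriminatorConfig,
    Generator,
    GeneratorConfig,
    save_checkpoint,
    sobel_tensor,
)

__all__ = [
    "TrainConfig",
    "LossRecord",
    "Trainer",
    "pair_batches",
    "recalibrate_batchnorm",
    "train",
]

MODES = ("supervised", "uda_output", "dd_uda")

LOG_COLUMNS = ("iteration", "l_seg", "l_b", "l_adv_e", "l_adv_d", "l_cls_e", "l_cls_d")


@dataclass(frozen=True)
class TrainConfig:
    mode: str = "dd_uda"
    boundary_enabled: bool = True
    weights: LossWeights = field(default_factory=LossWeights)
    lr_generator: float = 1e-5
    lr_discriminators: float = 1e-6
    batch_size: int = 8
    epochs: int = 50
    seed: int = 0
    image_size: int = 64
    base_channels: int = 64
    activation: str = "relu"
    norm: str = "batch"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.lr_generator <= 0 or self.lr_discriminators <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.image_size % 16:
            raise ValueError("image_size must be divisible by 16")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class LossRecord:
    iteration: int
    l_seg: float = 0.0
    l_b: float = 0.0
    l_adv_e: float = 0.0
    l_adv_d: float = 0.0
    l_cls_e: float = 0.0
    l_cls_d: float = 0.0

    def row(self):
        return [self.iteration] + [repr(getattr(self, c)) for c in LOG_COLUMNS[1:]]


def _to_batch(arr) -> Tensor:
    a = np.asarray(arr, dtype=np.float32)
    if a.ndim == 3:
        a = a[:, None]
    return Tensor(a)


class Trainer:
    """Holds the networks, optimisers and the five update steps."""

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        gcfg = GeneratorConfig(
            base_channels=cfg.base_channels, activation=cfg.activation, norm=cfg.norm
        )
        self.generator = Generator(gcfg, rng, with_boundary_decoder=cfg.boundary_enabled)
        self.disc_e: Optional[Discriminator] = None
        self.disc_d: Optional[Discriminator] = None
        if cfg.mode == "dd_uda":
            self.disc_e = Discriminator(
                DiscriminatorConfig(in_channels=cfg.base_channels * 16, norm=cfg.norm), rng
            )
        if cfg.mode in ("uda_output", "dd_uda"):
            self.disc_d = Discriminator(DiscriminatorConfig(in_channels=1, norm=cfg.norm), rng)

        gen_params = self.generator.parameters()
        self.opt_gen = Adam(gen_params, lr=cfg.lr_generator)
        self.opt_de = Adam(self.disc_e.parameters(), lr=cfg.lr_discriminators) if self.disc_e else None
        self.opt_dd = Adam(self.disc_d.parameters(), lr=cfg.lr_discriminators) if self.disc_d else None

        self._enc_dec1 = self.generator.encoder_parameters() + self.generator.decoder1_parameters()
        self._enc_dec2 = self.generator.encoder_parameters() + self.generator.decoder2_parameters()
        self._f_s = self._h_s = None
        self.iteration = 0
        self.history: list[LossRecord] = []

    # -- individual steps (exposed so gradient routing can be verified) ----

    def _zero_all(self):
        self.generator.zero_grad()
        if self.disc_e:
            self.disc_e.zero_grad()
        if self.disc_d:
            self.disc_d.zero_grad()

    def step1_segmentation(self, src_images, src_masks) -> float:
        out = self.generator(_to_batch(src_images), with_boundary=False)
        # cache detached source outputs for the discriminator steps (4-5)
        self._f_s, self._h_s = out.feature_map.detach(), out.heat_map.detach()
        loss = segmentation_loss(out.heat_map, _to_batch(src_masks))
        self._zero_all()
        loss.backward()
        self.opt_gen.step(self._enc_dec1)
        return float(loss.data)

    def step2_boundary(self, src_images, src_boundaries) -> float:
        out = self.generator(_to_batch(src_images), with_boundary=True)
        bmap = sobel_tensor(out.boundary_logits)
        loss = boundary_loss(bmap, _to_batch(src_boundaries))
        self._zero_all()
        loss.backward()
        self.opt_gen.step(self._enc_dec2)
        return float(loss.data)

    def step3_adversarial(self, tgt_images) -> tuple[float, float, Tensor, Tensor]:
        """Flip labels on target score maps, update encoder + decoder-1.

        Returns the two unweighted adversarial losses plus the detached
        target feature and heat maps (reused by the classification steps).
        """
        out = self.generator(_to_batch(tgt_images), with_boundary=False)
        w = self.cfg.weights
        l_adv_e = l_adv_d = 0.0
        total = None
        if self.disc_e is not None:
            adv_e = adversarial_loss(self.disc_e.scores(out.feature_map))
            l_adv_e = float(adv_e.data)
            total = adv_e * w.lambda_adv_e
        if self.disc_d is not None:
            adv_d = adversarial_loss(self.disc_d.scores(out.heat_map))
            l_adv_d = float(adv_d.data)
            term = adv_d * w.lambda_adv_d
            total = term if total is None else total + term
        if total is not None:
            self._zero_all()
            total.backward()
            # Plain scaled gradient step: Adam's per-parameter normalisation
            # would erase the calibrated lambda_adv scale of this small
            # adversarial correction and bleed its noise into the moment
            # estimates of the supervised steps.
            for p in self._enc_dec1:
                if p.grad is not None:
                    p.data = p.data - self.cfg.lr_generator * p.grad.astype(p.data.dtype, copy=False)
        return l_adv_e, l_adv_d, out.feature_map.detach(), out.heat_map.detach()

    def step4_classify_features(self, f_source: Tensor, f_target: Tensor) -> float:
        """Update De only; inputs must already be detached from the generator."""
        loss = classification_loss(self.disc_e.scores(f_source), self.disc_e.scores(f_target))
        self._zero_all()
        loss.backward()
        self.opt_de.step()
        return float(loss.data)

    def step5_classify_heatmaps(self, h_source: Tensor, h_target: Tensor) -> float:
        """Update Dd only; inputs must already be detached from the generator."""
        loss = classification_loss(self.disc_d.scores(h_source), self.disc_d.scores(h_target))
        self._zero_all()
        loss.backward()
        self.opt_dd.step()
        return float(loss.data)

    def source_outputs_detached(self, src_images=None) -> tuple[Tensor, Tensor]:
        """Detached source feature/heat maps for steps 4-5.

        Reuses the forward pass of step 1 when available (the usual case
        inside ``train_iteration``); otherwise runs a fresh forward.
        """
        if src_images is None:
            if self._f_s is None:
                raise ValueError("no cached source outputs; pass src_images")
            return self._f_s, self._h_s
        out = self.generator(_to_batch(src_images), with_boundary=False)
        return out.feature_map.detach(), out.heat_map.detach()

    # -- one full iteration ------------------------------------------------

    def train_iteration(self, source_batch, target_batch=None) -> LossRecord:
        src_images, src_masks, src_boundaries = source_batch
        cfg = self.cfg
        if cfg.mode != "supervised" and target_batch is None:
            raise ValueError(f"mode {cfg.mode!r} requires a target batch")
        rec = LossRecord(iteration=self.iteration)
        rec.l_seg = self.step1_segmentation(src_images, src_masks)
        if cfg.boundary_enabled:
            rec.l_b = self.step2_boundary(src_images, src_boundaries)
        if cfg.mode != "supervised":
            rec.l_adv_e, rec.l_adv_d, f_t, h_t = self.step3_adversarial(target_batch)
            f_s, h_s = self.source_outputs_detached()
            if self.disc_e is not None:
                rec.l_cls_e = self.step4_classify_features(f_s, f_t)
            if self.disc_d is not None:
                rec.l_cls_d = self.step5_classify_heatmaps(h_s, h_t)
        self.iteration += 1
        self.history.append(rec)
        return rec


def recalibrate_batchnorm(generator, images: np.ndarray, batch_size: int = 8) -> None:
    """Recompute batch-norm running statistics over ``images`` deterministically.

    During short trainings the momentum-based running estimates lag the
    evolving weights and wobble between the batch statistics of whichever
    domain passed through last; re-estimating them as the equal-weight
    average over the given images makes eval-mode behaviour reproducible.
    Pass the training images the model legitimately saw (source only for a
    supervised model; source + target for the adaptation modes).
    """
    from .autograd import BatchNorm2d

    def walk(m):
        yield m
        for c in m._children():
            yield from walk(c)

    bns = [m for m in walk(generator) if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    for bn in bns:
        bn.running_mean[:] = 0.0
        bn.running_var[:] = 1.0
    was_training = generator.training
    generator.train(True)
    try:
        for k, start in enumerate(range(0, len(images), batch_size)):
            for bn in bns:
                bn.momentum = 1.0 / (k + 1)  # running equal-weight average
            generator(_to_batch(images[start : start + batch_size]), with_boundary=False)
    finally:
        for bn in bns:
            bn.momentum = 0.1
        generator.train(was_training)


def pair_batches(source_dataset, target_dataset, batch_size: int, seed: int, epoch: int = 0):
    """Yield paired (source, target) index batches for one epoch.

    One epoch is ``ceil(max(|S|, |T|) / batch_size)`` steps; each dataset is
    shuffled independently and the shorter one wraps around (reshuffled on
    each pass) so every sample of both domains is visited.
    """
    n_s, n_t = len(source_dataset), len(target_dataset)
    if n_s == 0 or n_t == 0:
        raise ValueError("both datasets must be non-empty")
    steps = -(-max(n_s, n_t) // batch_size)
    need = steps * batch_size
    rng = np.random.default_rng(np.random.SeedSequence((seed, epoch)))

    def stream(n):
        idx = []
        while len(idx) < need:
            idx.extend(rng.permutation(n).tolist())
        return idx[:need]

    s_idx, t_idx = stream(n_s), stream(n_t)
    for k in range(steps):
        sl = slice(k * batch_size, (k + 1) * batch_size)
        yield s_idx[sl], t_idx[sl]


def train(
    cfg: TrainConfig,
    source_data: dict,
    target_data: Optional[dict] = None,
    log_path=None,
    checkpoint_path=None,
    val_data: Optional[dict] = None,
) -> tuple[Trainer, list[LossRecord]]:
    """Train for ``cfg.epochs`` epochs; deterministic given ``cfg.seed``.

    ``source_data`` needs ``images``, ``masks``, ``boundaries`` arrays;
    ``target_data`` needs ``images`` only (any held-out masks are for
    evaluation elsewhere and are ignored here). When ``val_data`` (a
    labelled source-domain split with ``images`` and ``masks``) is given,
    the dice coefficient on it is tracked after every epoch and the weights
    of the best epoch are restored at the end.
    """
    if source_data is None or len(source_data.get("images", ())) == 0:
        raise ValueError("source dataset is empty")
    if cfg.mode != "supervised":
        if target_data is None or len(target_data.get("images", ())) == 0:
            raise ValueError("adaptation modes require target images")
    trainer = Trainer(cfg)
    src_imgs = source_data["images"]
    src_masks = source_data["masks"]
    src_bounds = source_data["boundaries"]
    tgt_imgs = target_data["images"] if target_data is not None else src_imgs[:1]

    writer = None
    fh = None
    if log_path is not None:
        fh = open(log_path, "w", newline="")
        writer = csv.writer(fh)
        writer.writerow(LOG_COLUMNS)
    best_dc, best_state = -1.0, None
    try:
        for epoch in range(cfg.epochs):
            for s_idx, t_idx in pair_batches(src_imgs, tgt_imgs, cfg.batch_size, cfg.seed, epoch):
                rec = trainer.train_iteration(
                    (src_imgs[s_idx], src_masks[s_idx], src_bounds[s_idx]),
                    tgt_imgs[t_idx] if cfg.mode != "supervised" else None,
                )
                if writer is not None:
                    writer.writerow(rec.row())
            if val_data is not None:
                from .evaluation import evaluate_dataset

                dc = evaluate_dataset(
                    trainer.generator, zip(val_data["images"], val_data["masks"])
                ).dc
                if dc > best_dc:
                    best_dc = dc
                    best_state = [p.data.copy() for p in trainer.generator.parameters()] + [
                        b.copy() for b in trainer.generator.buffers()
                    ]
    finally:
        if fh is not None:
            fh.close()
    if best_state is not None:
        params = trainer.generator.parameters()
        for p, saved in zip(params, best_state):
            p.data = saved
        for b, saved in zip(trainer.generator.buffers(), best_state[len(params):]):
            b[...] = saved
    if checkpoint_path is not None:
        save_checkpoint(
            checkpoint_path,
            trainer.generator,
            disc_e=trainer.disc_e,
            disc_d=trainer.disc_d,
            seed=cfg.seed,
            extra={"mode": cfg.mode, "epochs": cfg.epochs},
        )
    return trainer, trainer.history
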