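# Methods

## Problem and model

`ddseg` implements adversarial unsupervised domain adaptation (UDA) for 2D
liver segmentation from CT slices. The setting: a *source* domain provides
slices `u_S` with binary liver masks `v_S` (and Sobel-derived boundary labels
`z_S`); a *target* domain — a different contrast-enhancement phase or imaging
centre — provides slices `u_T` only. The goal is a segmenter that works on
the target domain without target annotations.

The segmentation network ("generator") is a U-Net-style encoder–decoder:

- **Encoder** `G_enc`: five blocks of two 3×3 convolutions (stride 1,
  padding 1, each followed by normalisation and activation), channels
  doubling from `base_channels` (b, 2b, 4b, 8b, 16b), with 2×2 max pooling
  after the first four blocks. Its bottleneck output is the feature map
  `f = G_enc(u)` at 1/16 spatial resolution.
- **Decoder-1** `G_dec1`: four stages of 2×2 stride-2 transposed convolution,
  concatenation with the matching encoder skip, and two 3×3 convolutions;
  a final 1×1 convolution plus sigmoid yields the per-pixel liver
  probability heat map `h ∈ [0,1]^{W×H}`.
- **Decoder-2** `G_dec2`: structurally identical (no weight sharing); its
  sigmoid output is passed through a Sobel filter to form the boundary map
  `b = Sobel(G_dec2(G_enc(u)))`. Decoder-2 exists only to shape the shared
  encoder during training; inference uses encoder + decoder-1 alone.

Two fully convolutional domain discriminators judge whether an activation
came from source or target: `D_e` on bottleneck features `f`, `D_d` on heat
maps `h`. Both use five 4×4 stride-2 convolutions with channels
{64, 128, 256, 512, 1}, batch normalisation on the middle three layers,
leaky-ReLU (slope 0.2) after all but the last, and a sigmoid on the final
map. Each stage halves the spatial size; the implementation clamps the
spatial floor at 1×1 by adding extra zero padding when a dimension drops
below 2, so the same network handles 64×64 heat maps (→ 2×2 score map) and
4×4 bottleneck features (→ 1×1) alike. Scores are clamped to
[1e-7, 1 − 1e-7] before any logarithm.

## Losses

With α = 1 for source and α = 0 for target:

- **Segmentation** `L_seg`: soft dice per image,
  `1 − (2 Σ h·v + ε) / (Σ h + Σ v + ε)` with ε = 1e-6, averaged over the
  batch. Probabilities are used directly (no thresholding); ε guards
  empty-liver slices.
- **Boundary** `L_b`: mean squared error between the boundary map `b` and
  the Sobel label `z` of the ground-truth mask. Labels are kept continuous
  in [0,1] (the loss is a regression; thresholding would discard edge
  strength).
- **Adversarial** `L_adv_e`, `L_adv_d`: computed on *target* score maps only,
  with domain labels flipped — mean over score-map locations of
  `−log D(·)`. Minimising this pushes target outputs to look source-like.
- **Classification** `L_cls_e`, `L_cls_d`: the discriminators' own
  cross-entropy with true labels, `mean(−log D(source)) +
  mean(−log(1 − D(target)))`; these update only the discriminators.

The generator objective is
`L_seg + λ_b·L_b + λ_adv_e·L_adv_e + λ_adv_d·L_adv_d` with defaults
λ_b = 0.2, λ_adv_e = 0.0005, λ_adv_d = 0.003. The classification terms are
bookkept alongside but never minimised by the generator — a generator that
minimised the discriminators' classification loss would invert the
adversarial game.

## Training procedure

Each iteration consumes one source batch and one target batch and runs five
steps in order:

1. `L_seg` on source heat maps → update encoder + decoder-1 (Adam);
2. `L_b` on source boundary maps → update encoder + decoder-2 (Adam);
3. weighted adversarial losses on target score maps → update encoder +
   decoder-1 (plain gradient step, see below);
4. `L_cls_e` on detached source/target features → update `D_e` only (Adam);
5. `L_cls_d` on detached source/target heat maps → update `D_d` only (Adam).

Ablation modes degrade this: `supervised` runs steps 1–2 and builds no
discriminators; `uda_output` runs 1, 2, the output half of 3, and 5;
`boundary_enabled=False` drops decoder-2 and step 2.

**Why step 3 is a plain gradient step.** Steps keep their own
backward/update (the routing above is part of the contract), and Adam's
update is scale-invariant: it normalises each parameter's gradient by its
running magnitude, so a loss scaled by a small λ produces the *same-sized*
step as an unscaled loss, and the adversarial gradient noise bleeds into
the moment estimates used by the supervised steps. In desk-scale runs this
collapsed target IoU. The λ weights only retain their calibrated meaning if
the adversarial update is taken as `θ ← θ − lr·∇(λ_e L_adv_e + λ_d L_adv_d)`
without moment normalisation; that is what step 3 does. Adam (β = 0.9/0.999,
no weight decay, no schedule) drives steps 1, 2, 4, 5.

Other conventions: discriminator inputs in steps 4–5 are detached from the
generator graph (they must update only the discriminators); steps 4–5 reuse
the detached source outputs of step 1's forward pass, so every mode performs
the same number of source forwards; one epoch is
`ceil(max(|S|,|T|)/batch)` steps with independent per-epoch shuffles and
wrap-around on the smaller set; conv weights are initialised N(0, 0.02²)
from a seeded generator; batch norm runs in training mode throughout (a
group-norm variant is available for batch-size-1 work). Defaults follow the
full-scale recipe: generator lr 1e-5, discriminators 1e-6, batch 8.

## Preprocessing

CT slices are clamped to the liver window, applied literally as lower/upper
bounds −20 and 200 HU, then min–max normalised per slice over the clamped
values (a constant slice maps to zeros). Per-slice rather than per-volume
normalisation is used; the two differ only in global brightness scaling and
per-slice matches the 2D training granularity.

Boundary labels are the Sobel gradient magnitude of the binary mask:
`sqrt(Gx² + Gy²)` with the standard 3×3 kernels, reflect-padded borders, and
division by the largest magnitude any binary 3×3 patch can produce
(2√5 ≈ 4.4721, found by enumerating all 512 patches). Since the response is
linear in each pixel this bound also holds for any [0,1]-valued input, so
boundary labels and boundary maps live on the same [0,1] scale as the
sigmoid outputs they are compared with. The differentiable Sobel used inside
the network matches this exactly; its gradient at zero magnitude is taken as
0 (subgradient choice).

## Evaluation

Predictions binarise the heat map at a threshold (default 0.5, strict `>`).
Metrics are the usual pixel-count overlap scores — DC, IoU, sensitivity
(TRP), precision (PPV) — with both-empty pairs scored 1 for DC/IoU and
undefined ratios (empty ground truth for TRP, empty prediction for PPV)
returned as `None` and excluded from aggregation. Aggregation is the
arithmetic per-slice mean.

## Synthetic two-domain phantoms

The phantom generator renders 1–2 radially perturbed ellipses (smooth
blobs) per 64×64 slice: foreground intensity 0.65 ± 0.05, background
0.30 ± 0.05, border softened by a σ = 1 px Gaussian, additive noise
σ = 0.03. The mask is the exact pre-blur support. The target domain draws
*fresh* phantoms from the same geometric family (unpaired domains — shifted
copies of the source images would trivialise adaptation) and remaps
intensities: `x → clip(0.5 + 0.5·(x^1.4 − 0.5) + noise)` followed by a
σ = 0.7 px blur, emulating a lower-contrast, slightly blurred acquisition
(poor-contrast phase / different centre). All randomness descends from one
seed through per-image substreams.

What this captures: a covariate shift in intensity distribution with shared
segmentation geometry, enough for every training signal (dice, boundary,
both adversarial paths) to be exercised and for the adaptation ordering to
be measurable. What it does not capture: anatomical shape realism, tumours,
3D context, scanner artefacts, or label noise — passing the synthetic
experiment shows the machinery behaves as designed, not that the method
reaches any particular accuracy on real CT.

## Desk-scale experiment

The end-to-end check trains all three modes on 48 source + 48 target
training slices (120 iterations: 6 steps/epoch × 20 epochs at batch 8) with
`base_channels=8`, evaluating on 48 held-out slices per domain. These sizes
are the package's chosen desk scale: small enough to train in minutes on
one CPU, large enough that runs converge stably (shorter runs left models
undertrained with high seed-to-seed variance). At this scale the paper-scale
learning rates (1e-5) cannot move a freshly initialised network, so the
experiment uses 2e-3 / 2e-4 — the same 10:1 generator:discriminator ratio.

After training, each run's batch-norm running statistics are re-estimated
deterministically (`recalibrate_batchnorm`) over the training images the
mode legitimately saw — source only for `supervised`, source + unlabelled
target for the adaptation modes — because momentum-based estimates from a
120-iteration run lag the final weights and wobble between domain batch
statistics, adding pure measurement noise to eval-mode metrics.

The experiment checks the qualitative adaptation ordering (no adaptation <
output-level UDA ≤ dual-discriminator UDA on mean target IoU, over three
fixed seeds). Two caveats the desk scale imposes, measured rather than
assumed: individual training runs have a heavy-tailed target-IoU
distribution (occasionally a run emerges confident on source but diffuse —
uniformly near-0.5 — on target, in any mode), and the λ-weighted
adversarial updates move the generator by only ~1e-3 in cumulative
parameter distance over 120 iterations, so at this scale the adversarial
corrections are second-order compared to run-to-run trajectory variance.
The ordering assertion therefore probes whether the adaptation signal rises
above that variance under the default phantom shift.

## Known limitations

- The compute engine is NumPy on CPU; full-scale (512×512, base 64) training
  is out of reach — the package targets method-level correctness and
  desk-scale experiments.
- Batch-norm statistics are a live part of the adaptation behaviour;
  batch-size-1 inference should use the stored running statistics (eval
  mode), as `predict_mask` does.
- The discriminator architecture's 1×1 spatial floor means very small
  inputs (e.g. 4×4 bottlenecks) yield single-location score maps; the
  feature-level adversarial signal is correspondingly coarse at desk scale.
- Aggregated TRP/PPV are sensitive to empty-mask conventions; slices with
  undefined ratios are dropped from those means, which can differ from other
  tools' pooled-pixel aggregation.
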