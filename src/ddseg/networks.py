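"""Boundary-enhanced segmentation generator and domain discriminators.

The generator is a U-Net-style encoder with five convolution blocks
(channels doubling from ``base_channels``; 2x2 max-pooling after the first
four blocks) feeding two structurally identical decoders: decoder-1 produces
the per-pixel liver probability heat map h, decoder-2 produces the map whose
Sobel gradient magnitude is the boundary map b. Only the encoder and
decoder-1 are needed at inference.

Both domain discriminators share one architecture: five 4x4 stride-2
convolutions with channels {64, 128, 256, 512, 1}, batch norm on the middle
three layers, leaky-ReLU (slope 0.2) after all but the last, and a sigmoid
squashing of the final 1-channel map into per-location probabilities of
"source". They are fully convolutional and size-agnostic: each stage halves
the spatial extent, clamped at 1x1 (small inputs such as the encoder
bottleneck get extra zero padding so the map never vanishes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .autograd import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    GroupNorm2d,
    Module,
    Tensor,
    concat,
    conv2d,
    max_pool2d,
)
from .preprocessing import SOBEL_BINARY_MAX, SOBEL_KX, SOBEL_KY

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "GeneratorOutputs",
    "DomainScoreMap",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "forward_generator",
    "forward_discriminator",
    "sobel_tensor",
    "save_checkpoint",
    "load_checkpoint",
]

SCORE_EPS = 1e-7  # discriminator probabilities are clamped to [eps, 1-eps]

DISCRIMINATOR_CHANNELS = (64, 128, 256, 512, 1)


@dataclass(frozen=True)
class GeneratorConfig:
    in_channels: int = 1
    base_channels: int = 64
    depth: int = 5
    activation: str = "relu"  # "relu" | "leaky_relu"
    norm: str = "batch"  # "batch" | "group" (batch-size-1 fallback) | "none"

    def __post_init__(self):
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.depth != 5:
            raise ValueError("the generator encoder has exactly five blocks")
        if self.activation not in ("relu", "leaky_relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.norm not in ("batch", "group", "none"):
            raise ValueError(f"unknown norm {self.norm!r}")


@dataclass(frozen=True)
class DiscriminatorConfig:
    in_channels: int = 1  # 1 for the heat-map discriminator Dd; base*16 for De
    leaky_slope: float = 0.2
    norm: str = "batch"

    def __post_init__(self):
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")


@dataclass
class GeneratorOutputs:
    """f: encoder bottleneck; h: decoder-1 heat map; boundary_logits: decoder-2 output."""

    feature_map: Tensor
    heat_map: Tensor
    boundary_logits: Optional[Tensor] = None

    def numpy(self) -> "GeneratorOutputs":
        return GeneratorOutputs(
            feature_map=self.feature_map.data if isinstance(self.feature_map, Tensor) else self.feature_map,
            heat_map=self.heat_map.data if isinstance(self.heat_map, Tensor) else self.heat_map,
            boundary_logits=(
                self.boundary_logits.data
                if isinstance(self.boundary_logits, Tensor)
                else self.boundary_logits
            ),
        )


@dataclass(frozen=True)
class DomainScoreMap:
    """Per-location probability of 'source' from a discriminator."""

    scores: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores)
        if s.size and (s.min() <= 0.0 or s.max() >= 1.0):
            raise ValueError("domain scores must lie strictly in (0, 1)")
        object.__setattr__(self, "scores", s)


def _norm_layer(kind: str, channels: int):
    if kind == "batch":
        return BatchNorm2d(channels)
    if kind == "group":
        return GroupNorm2d(channels)
    return None


class _ConvBlock(Module):
    """[3x3 conv -> norm -> activation] x 2, stride 1, padding 1."""

    def __init__(self, in_ch, out_ch, cfg: GeneratorConfig, rng):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=1, pad=1, rng=rng)
        self.norm1 = _norm_layer(cfg.norm, out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, stride=1, pad=1, rng=rng)
        self.norm2 = _norm_layer(cfg.norm, out_ch)
        self._leaky = cfg.activation == "leaky_relu"

    def _act(self, x):
        return x.leaky_relu(0.2) if self._leaky else x.relu()

    def __call__(self, x):
        x = self.conv1(x)
        if self.norm1 is not None:
            x = self.norm1(x)
        x = self._act(x)
        x = self.conv2(x)
        if self.norm2 is not None:
            x = self.norm2(x)
        return self._act(x)


class _Encoder(Module):
    def __init__(self, cfg: GeneratorConfig, rng):
        super().__init__()
        chans = [cfg.base_channels * 2**i for i in range(cfg.depth)]
        ins = [cfg.in_channels] + chans[:-1]
        self.blocks = [_ConvBlock(i, o, cfg, rng) for i, o in zip(ins, chans)]
        self.channels = chans

    def __call__(self, x):
        skips = []
        for k, block in enumerate(self.blocks):
            x = block(x)
            if k < len(self.blocks) - 1:
                skips.append(x)
                x = max_pool2d(x)
        return x, skips  # bottleneck f, skip activations of blocks 1-4


class _Decoder(Module):
    """Four upsampling stages with skip concatenation, then 1x1 conv + sigmoid."""

    def __init__(self, cfg: GeneratorConfig, rng):
        super().__init__()
        chans = [cfg.base_channels * 2**i for i in range(cfg.depth)]  # b..16b
        self.ups = []
        self.blocks = []
        for i in range(cfg.depth - 1):
            hi = chans[-1 - i]  # 16b, 8b, 4b, 2b
            lo = chans[-2 - i]  # 8b, 4b, 2b, b
            self.ups.append(ConvTranspose2d(hi, lo, 2, 2, rng=rng))
            self.blocks.append(_ConvBlock(2 * lo, lo, cfg, rng))
        self.head = Conv2d(chans[0], 1, 1, stride=1, pad=0, rng=rng)

    def __call__(self, f, skips):
        x = f
        for up, block, skip in zip(self.ups, self.blocks, reversed(skips)):
            x = up(x)
            x = concat([x, skip], axis=1)
            x = block(x)
        return self.head(x).sigmoid()


class Generator(Module):
    """One shared encoder, decoder-1 (segmentation) and optional decoder-2 (boundary)."""

    def __init__(self, cfg: GeneratorConfig, rng, with_boundary_decoder: bool = True):
        super().__init__()
        self.config = cfg
        self.encoder = _Encoder(cfg, rng)
        self.decoder1 = _Decoder(cfg, rng)
        self.decoder2 = _Decoder(cfg, rng) if with_boundary_decoder else None

    @property
    def bottleneck_channels(self) -> int:
        return self.config.base_channels * 16

    def encoder_parameters(self):
        return self.encoder.parameters()

    def decoder1_parameters(self):
        return self.decoder1.parameters()

    def decoder2_parameters(self):
        return self.decoder2.parameters() if self.decoder2 is not None else []

    def __call__(self, x: Tensor, with_boundary: bool = True) -> GeneratorOutputs:
        h, w = x.data.shape[-2:]
        if h % 16 or w % 16 or h < 16 or w < 16:
            raise ValueError(f"input spatial size {h}x{w} must be >= 16 and divisible by 16")
        f, skips = self.encoder(x)
        heat = self.decoder1(f, skips)
        blogits = None
        if with_boundary and self.decoder2 is not None:
            blogits = self.decoder2(f, skips)
        return GeneratorOutputs(feature_map=f, heat_map=heat, boundary_logits=blogits)


class Discriminator(Module):
    def __init__(self, cfg: DiscriminatorConfig, rng):
        super().__init__()
        self.config = cfg
        ins = [cfg.in_channels] + list(DISCRIMINATOR_CHANNELS[:-1])
        self.layers = [Conv2d(i, o, 4, rng=rng) for i, o in zip(ins, DISCRIMINATOR_CHANNELS)]
        self.norms = [None] + [_norm_layer(cfg.norm, c) for c in DISCRIMINATOR_CHANNELS[1:-1]] + [None]
        self.slope = cfg.leaky_slope

    def logits(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.config.in_channels:
            raise ValueError(
                f"discriminator expects {self.config.in_channels} channels, got {x.data.shape[1]}"
            )
        if min(x.data.shape[-2:]) < 1:
            raise ValueError("discriminator input must have spatial size >= 1")
        for k, layer in enumerate(self.layers):
            # extra padding keeps 1x1 maps alive through the stride-2 stage
            pad = 2 if min(x.data.shape[-2:]) < 2 else 1
            x = conv2d(x, layer.weight, layer.bias, stride=2, pad=pad)
            if self.norms[k] is not None:
                x = self.norms[k](x)
            if k < len(self.layers) - 1:
                x = x.leaky_relu(self.slope)
        return x

    def scores(self, x: Tensor) -> Tensor:
        return self.logits(x).sigmoid().clip(SCORE_EPS, 1.0 - SCORE_EPS)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def build_generator(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    with_boundary_decoder: bool = True,
) -> Generator:
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    return Generator(config, rng, with_boundary_decoder=with_boundary_decoder)


def build_discriminator(config: DiscriminatorConfig | None = None, seed: int = 0) -> Discriminator:
    config = config or DiscriminatorConfig()
    rng = np.random.default_rng(seed)
    return Discriminator(config, rng)


def _as_batch_tensor(images: np.ndarray | Tensor) -> Tensor:
    if isinstance(images, Tensor):
        return images
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    elif arr.ndim != 4:
        raise ValueError("expected (H,W), (N,H,W) or (N,C,H,W) images")
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError("generator inputs must be normalised to [0, 1]")
    return Tensor(arr)


def forward_generator(gen: Generator, images, with_boundary: bool = True) -> GeneratorOutputs:
    """Run the generator on a batch of normalised images; outputs as arrays."""
    return gen(_as_batch_tensor(images), with_boundary=with_boundary).numpy()


def forward_discriminator(d: Discriminator, x: np.ndarray | Tensor) -> DomainScoreMap:
    if not isinstance(x, Tensor):
        arr = np.asarray(x, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[None]
        x = Tensor(arr)
    return DomainScoreMap(d.scores(x).data)


# ---------------------------------------------------------------------------
# differentiable Sobel (for the boundary map b)
# ---------------------------------------------------------------------------

_SOBEL_WX = Tensor(SOBEL_KX[None, None].astype(np.float32))
_SOBEL_WY = Tensor(SOBEL_KY[None, None].astype(np.float32))


def _reflect_pad1(x: Tensor) -> Tensor:
    data = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="reflect")

    def back(g, x=x):
        if not x.requires_grad:
            return
        g = np.asarray(g)
        dx = g[..., 1:-1, 1:-1].copy()
        dx[..., 1, :] += g[..., 0, 1:-1]
        dx[..., -2, :] += g[..., -1, 1:-1]
        dx[..., :, 1] += g[..., 1:-1, 0]
        dx[..., :, -2] += g[..., 1:-1, -1]
        dx[..., 1, 1] += g[..., 0, 0]
        dx[..., 1, -2] += g[..., 0, -1]
        dx[..., -2, 1] += g[..., -1, 0]
        dx[..., -2, -2] += g[..., -1, -1]
        x._accum(dx)

    from .autograd import _node

    return _node(data, (x,), back)


def _magnitude(gx: Tensor, gy: Tensor) -> Tensor:
    mag = np.hypot(gx.data, gy.data)
    safe = np.where(mag > 0, mag, 1.0)

    def back(g, gx=gx, gy=gy, mag=mag, safe=safe):
        g = np.asarray(g)
        scale = np.where(mag > 0, g / safe, 0.0)
        if gx.requires_grad:
            gx._accum(scale * gx.data)
        if gy.requires_grad:
            gy._accum(scale * gy.data)

    from .autograd import _node

    return _node(mag, (gx, gy), back)


def sobel_tensor(x: Tensor) -> Tensor:
    """Differentiable normalised Sobel magnitude of a (N,1,H,W) tensor.

    Matches ``preprocessing.sobel_magnitude`` (reflect borders, magnitude
    scaled by the maximum binary-patch response); the gradient at exactly
    zero magnitude is taken as 0 (subgradient choice).
    """
    xp = _reflect_pad1(x)
    gx = conv2d(xp, _SOBEL_WX, None, stride=1, pad=0)
    gy = conv2d(xp, _SOBEL_WY, None, stride=1, pad=0)
    return _magnitude(gx, gy) * (1.0 / SOBEL_BINARY_MAX)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def _state_arrays(module: Module) -> list[np.ndarray]:
    return [p.data for p in module.parameters()] + [b for b in module.buffers()]


def save_checkpoint(path, generator: Generator, disc_e=None, disc_d=None, seed=None, extra=None):
    """Store generator (and optionally discriminators) weights plus a manifest."""
    arrays = {}
    manifest = {
        "seed": seed,
        "extra": extra or {},
        "generator": {
            "config": vars(generator.config) | {},
            "with_boundary_decoder": generator.decoder2 is not None,
        },
        "contains": ["generator"],
    }
    manifest["generator"]["config"] = dict(generator.config.__dict__)
    for i, a in enumerate(_state_arrays(generator)):
        arrays[f"g_{i}"] = a
    if disc_e is not None:
        manifest["contains"].append("discriminator_e")
        manifest["discriminator_e"] = {"config": dict(disc_e.config.__dict__)}
        for i, a in enumerate(_state_arrays(disc_e)):
            arrays[f"de_{i}"] = a
    if disc_d is not None:
        manifest["contains"].append("discriminator_d")
        manifest["discriminator_d"] = {"config": dict(disc_d.config.__dict__)}
        for i, a in enumerate(_state_arrays(disc_d)):
            arrays[f"dd_{i}"] = a
    arrays["manifest"] = np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _load_into(module: Module, npz, prefix: str):
    params = module.parameters()
    buffers = module.buffers()
    n = len(params)
    for i, p in enumerate(params):
        p.data = npz[f"{prefix}_{i}"]
    for j, b in enumerate(buffers):
        b[...] = npz[f"{prefix}_{n + j}"]


def load_checkpoint(path):
    """Rebuild the networks stored in a checkpoint; returns (gen, de, dd, manifest)."""
    npz = np.load(path)
    manifest = json.loads(bytes(npz["manifest"]).decode())
    gcfg = GeneratorConfig(**manifest["generator"]["config"])
    gen = build_generator(gcfg, with_boundary_decoder=manifest["generator"]["with_boundary_decoder"])
    _load_into(gen, npz, "g")
    de = dd = None
    if "discriminator_e" in manifest["contains"]:
        de = build_discriminator(DiscriminatorConfig(**manifest["discriminator_e"]["config"]))
        _load_into(de, npz, "de")
    if "discriminator_d" in manifest["contains"]:
        dd = build_discriminator(DiscriminatorConfig(**manifest["discriminator_d"]["config"]))
        _load_into(dd, npz, "dd")
    return gen, de, dd, manifest
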