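"""Seeded two-domain phantom data for exercising the adaptation pipeline.

The "source" domain contains smooth random blob organs (radially perturbed
ellipses) on a darker noisy background, with exact masks and Sobel boundary
labels. The "target" domain draws fresh phantoms from the same geometric
family and passes them through a deterministic intensity remapping —
contrast compression, gamma, extra noise and a mild blur — emulating the
appearance shift between contrast-enhancement phases or imaging centres
while leaving the segmentation geometry statistics unchanged. Target masks
are produced only for evaluation and are kept out of the training inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocessing import make_boundary_label

__all__ = [
    "PhantomSpec",
    "DomainShiftSpec",
    "make_phantom",
    "apply_domain_shift",
    "make_domain_datasets",
    "generate_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    image_size: int = 64
    n_blobs_min: int = 1
    n_blobs_max: int = 2
    blob_radius_range: tuple = (0.15, 0.35)  # fraction of image size
    foreground_intensity: tuple = (0.65, 0.05)  # mean, sd (per-image draw)
    background_intensity: tuple = (0.30, 0.05)
    noise_sd: float = 0.03
    smoothness: float = 1.0  # border blur sigma, pixels

    def __post_init__(self):
        if self.image_size % 16:
            raise ValueError("image_size must be divisible by 16")
        if not 0 < self.n_blobs_min <= self.n_blobs_max:
            raise ValueError("need 1 <= n_blobs_min <= n_blobs_max")


@dataclass(frozen=True)
class DomainShiftSpec:
    contrast_scale: float = 0.5  # compresses the range around 0.5 (poor contrast)
    gamma: float = 1.4
    extra_noise_sd: float = 0.02
    blur_sigma: float = 0.7

    def __post_init__(self):
        if not 0.0 < self.contrast_scale <= 1.0:
            raise ValueError("contrast_scale must lie in (0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def _blob_mask(size: int, rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Union of radially perturbed ellipses; returns the exact boolean support."""
    n = int(rng.integers(spec.n_blobs_min, spec.n_blobs_max + 1))
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    mask = np.zeros((size, size), dtype=bool)
    lo, hi = spec.blob_radius_range
    for _ in range(n):
        r0 = rng.uniform(lo, hi) * size
        cy = rng.uniform(0.3 * size, 0.7 * size)
        cx = rng.uniform(0.3 * size, 0.7 * size)
        ecc = rng.uniform(0.7, 1.3)  # axis ratio
        rot = rng.uniform(0, np.pi)
        # low-order radial perturbation keeps the outline smooth
        amps = rng.uniform(0.0, 0.12, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        dy, dx = yy - cy, xx - cx
        ry = dy * np.cos(rot) - dx * np.sin(rot)
        rx = dy * np.sin(rot) + dx * np.cos(rot)
        dist = np.hypot(ry * ecc, rx / ecc)
        theta = np.arctan2(ry, rx)
        r_theta = r0 * (1.0 + sum(a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amps, phases))))
        mask |= dist <= r_theta
    return mask


def make_phantom(spec: PhantomSpec, rng_seed) -> tuple[np.ndarray, np.ndarray]:
    """Render one (image, mask) pair; fully determined by (spec, rng_seed)."""
    rng = np.random.default_rng(rng_seed)
    mask = _blob_mask(spec.image_size, rng, spec)
    fg = spec.foreground_intensity[0] + spec.foreground_intensity[1] * rng.standard_normal()
    bg = spec.background_intensity[0] + spec.background_intensity[1] * rng.standard_normal()
    alpha = mask.astype(np.float64)
    if spec.smoothness > 0:
        alpha = gaussian_filter(alpha, spec.smoothness)
    image = bg + (fg - bg) * alpha
    if spec.noise_sd > 0:
        image = image + spec.noise_sd * rng.standard_normal(image.shape)
    return np.clip(image, 0.0, 1.0), mask.astype(np.uint8)


def apply_domain_shift(image: np.ndarray, shift: DomainShiftSpec, rng_seed) -> np.ndarray:
    """x -> clip(0.5 + s*(x^gamma - 0.5) + noise) then Gaussian blur; geometry unchanged."""
    img = np.asarray(image, dtype=np.float64)
    if img.size and (img.min() < 0 or img.max() > 1):
        raise ValueError("input image must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    out = 0.5 + shift.contrast_scale * (img**shift.gamma - 0.5)
    if shift.extra_noise_sd > 0:
        out = out + shift.extra_noise_sd * rng.standard_normal(out.shape)
    out = np.clip(out, 0.0, 1.0)
    if shift.blur_sigma > 0:
        out = np.clip(gaussian_filter(out, shift.blur_sigma), 0.0, 1.0)
    return out


def make_domain_datasets(
    n_source: int,
    n_target: int,
    spec: PhantomSpec | None = None,
    shift: DomainShiftSpec | None = None,
    seed: int = 0,
) -> tuple[dict, dict]:
    """In-memory two-domain dataset.

    Returns ``(source, target)`` dicts. ``source`` has ``images``, ``masks``
    and ``boundaries``; ``target`` has ``images`` plus ``eval_masks`` which
    exist solely for evaluation and must never be fed to training.
    Target phantoms are fresh draws, not shifted copies of source images.
    """
    if n_source < 1 or n_target < 1:
        raise ValueError("need at least one sample per domain")
    spec = spec or PhantomSpec()
    shift = shift or DomainShiftSpec()
    ss = np.random.SeedSequence(seed)
    src_seeds, tgt_seeds = ss.spawn(2)
    src_children = src_seeds.spawn(n_source)
    tgt_children = tgt_seeds.spawn(2 * n_target)

    src_images, src_masks, src_bounds = [], [], []
    for child in src_children:
        img, msk = make_phantom(spec, child)
        src_images.append(img)
        src_masks.append(msk)
        src_bounds.append(make_boundary_label(msk).pixels)
    tgt_images, tgt_masks = [], []
    for k in range(n_target):
        img, msk = make_phantom(spec, tgt_children[2 * k])
        tgt_images.append(apply_domain_shift(img, shift, tgt_children[2 * k + 1]))
        tgt_masks.append(msk)
    source = {
        "images": np.stack(src_images).astype(np.float32),
        "masks": np.stack(src_masks).astype(np.float32),
        "boundaries": np.stack(src_bounds).astype(np.float32),
    }
    target = {
        "images": np.stack(tgt_images).astype(np.float32),
        "eval_masks": np.stack(tgt_masks).astype(np.float32),
    }
    return source, target


def _write_png16(path: Path, arr: np.ndarray):
    import imageio.v3 as iio

    iio.imwrite(path, np.round(np.clip(arr, 0, 1) * 65535).astype(np.uint16))


def generate_dataset(
    n_source: int,
    n_target: int,
    spec: PhantomSpec | None = None,
    shift: DomainShiftSpec | None = None,
    seed: int = 0,
    out_dir=None,
) -> tuple[dict, dict]:
    """Generate the two-domain dataset, optionally writing the on-disk layout.

    Layout: ``source/images|masks|boundaries`` and ``target/images`` as
    16-bit PNG / float32 arrays; target masks go to ``target/eval_only/masks``
    which training never reads.
    """
    source, target = make_domain_datasets(n_source, n_target, spec, shift, seed)
    if out_dir is not None:
        out = Path(out_dir)
        for sub in ("source/images", "source/masks", "source/boundaries", "target/images", "target/eval_only/masks"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        for i in range(n_source):
            _write_png16(out / "source" / "images" / f"{i:04d}.png", source["images"][i])
            _write_png16(out / "source" / "masks" / f"{i:04d}.png", source["masks"][i])
            np.save(out / "source" / "boundaries" / f"{i:04d}.npy", source["boundaries"][i].astype(np.float32))
        for i in range(n_target):
            _write_png16(out / "target" / "images" / f"{i:04d}.png", target["images"][i])
            _write_png16(out / "target" / "eval_only" / "masks" / f"{i:04d}.png", target["eval_masks"][i])
    return source, target
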