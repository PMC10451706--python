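"""CT slice preprocessing: windowing, normalisation and boundary labels.

CT intensities are clamped to the liver window [-20, 200] HU and min-max
rescaled to [0, 1] per slice. Boundary labels are the Sobel gradient
magnitude of the binary liver mask, normalised so that labels from any
binary (or [0,1]-valued) mask stay in [0, 1] and remain commensurate with
the sigmoid outputs they are regressed against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "CTSlice",
    "NormalizedImage",
    "SegmentationMask",
    "BoundaryLabel",
    "SOBEL_KX",
    "SOBEL_KY",
    "SOBEL_BINARY_MAX",
    "load_volume",
    "window_and_normalize",
    "sobel_magnitude",
    "make_boundary_label",
    "pad_to_multiple",
]

DEFAULT_WINDOW_LOW = -20.0
DEFAULT_WINDOW_HIGH = 200.0

SOBEL_KX = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_KY = SOBEL_KX.T.copy()


def _max_binary_sobel_response() -> float:
    """Largest gradient magnitude any binary 3x3 patch can produce.

    Found once by enumerating all 512 binary patches; used to normalise
    Sobel magnitudes so boundary labels of binary masks lie in [0, 1].
    Because the response is linear in each pixel, the same bound holds for
    any patch with values in [0, 1].
    """
    best = 0.0
    for bits in itertools.product((0.0, 1.0), repeat=9):
        patch = np.array(bits).reshape(3, 3)
        gx = float((SOBEL_KX * patch).sum())
        gy = float((SOBEL_KY * patch).sum())
        best = max(best, float(np.hypot(gx, gy)))
    return best


SOBEL_BINARY_MAX = _max_binary_sobel_response()


@dataclass(frozen=True)
class CTSlice:
    """One axial slice with raw (Hounsfield-like) intensities."""

    pixels: np.ndarray
    index: int = 0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError("CTSlice expects a 2D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("CTSlice contains non-finite intensities")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class NormalizedImage:
    """Single-channel image in [0, 1] — the generator input u."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError("NormalizedImage expects a 2D array")
        if px.size and (px.min() < 0.0 or px.max() > 1.0):
            raise ValueError("NormalizedImage values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class SegmentationMask:
    """Binary liver mask v paired with an image of the same shape."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("SegmentationMask expects a 2D array")
        vals = np.unique(px)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("SegmentationMask must be binary {0, 1}")
        object.__setattr__(self, "pixels", px.astype(np.float64))

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class BoundaryLabel:
    """Sobel-derived edge map z of a mask, values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError("BoundaryLabel expects a 2D array")
        if px.size and (px.min() < -1e-12 or px.max() > 1.0 + 1e-12):
            raise ValueError("BoundaryLabel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))

    @property
    def shape(self):
        return self.pixels.shape


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_volume(path) -> list[CTSlice]:
    """Load a NIfTI volume, a 2D image (PNG) or a NumPy array file as slices.

    Volumes are sliced axially (along the last axis) in ascending index
    order; 2D inputs yield a single-slice list. Raw intensities are kept.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        try:
            data = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
        except Exception as exc:  # pragma: no cover - nibabel error paths
            raise IOError(f"could not read volume {path}: {exc}") from exc
    elif suffixes.endswith(".npy"):
        data = np.load(path).astype(np.float64)
    elif suffixes.endswith(".png"):
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path)).astype(np.float64)
        if data.ndim == 3:  # collapse identical RGB channels of a grayscale PNG
            data = data[..., 0]
    else:
        raise ValueError(f"unsupported volume/image format: {path.name}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path.name} contains non-finite voxels")
    if data.ndim == 2:
        return [CTSlice(data, index=0)]
    if data.ndim == 3:
        return [CTSlice(data[..., k], index=k) for k in range(data.shape[-1])]
    raise ValueError(f"{path.name}: expected a 2D or 3D array, got ndim={data.ndim}")


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------


def window_and_normalize(
    slc: CTSlice | np.ndarray,
    wl: float = DEFAULT_WINDOW_LOW,
    ww_upper: float = DEFAULT_WINDOW_HIGH,
) -> NormalizedImage:
    """Clamp intensities to [wl, ww_upper], then min-max rescale per slice.

    The clamp bounds default to the liver window (-20, 200) HU applied as
    literal lower/upper limits. Rescaling uses the min and max of the
    clamped slice; a constant slice maps to all zeros.
    """
    px = slc.pixels if isinstance(slc, CTSlice) else np.asarray(slc, dtype=np.float64)
    if not np.all(np.isfinite(px)):
        raise ValueError("slice contains non-finite intensities")
    clamped = np.clip(px, wl, ww_upper)
    lo, hi = clamped.min(), clamped.max()
    if hi - lo <= 0.0:
        return NormalizedImage(np.zeros_like(clamped))
    return NormalizedImage((clamped - lo) / (hi - lo))


def pad_to_multiple(image: np.ndarray, multiple: int = 16, value: float = 0.0) -> np.ndarray:
    """Pad on the bottom/right so both spatial dims divide ``multiple``."""
    h, w = image.shape[-2:]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return image
    pad = [(0, 0)] * (image.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(image, pad, constant_values=value)


# ---------------------------------------------------------------------------
# Sobel boundary labels
# ---------------------------------------------------------------------------


def sobel_magnitude(image: np.ndarray) -> np.ndarray:
    """Normalised Sobel gradient magnitude with reflect-padded borders.

    Returns sqrt(Gx^2 + Gy^2) / SOBEL_BINARY_MAX so that any input with
    values in [0, 1] yields output in [0, 1].
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("sobel_magnitude requires a 2D image of at least 3x3")
    padded = np.pad(img, 1, mode="reflect")
    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(padded, (3, 3))
    gx = np.einsum("ijkl,kl->ij", windows, SOBEL_KX)
    gy = np.einsum("ijkl,kl->ij", windows, SOBEL_KY)
    return np.hypot(gx, gy) / SOBEL_BINARY_MAX


def make_boundary_label(mask: SegmentationMask | np.ndarray) -> BoundaryLabel:
    """Boundary label z = normalised Sobel magnitude of the binary mask."""
    if not isinstance(mask, SegmentationMask):
        mask = SegmentationMask(np.asarray(mask))
    return BoundaryLabel(sobel_magnitude(mask.pixels))
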