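"""CT intensity pipeline and paired geometric augmentation.

Intensity: raw-to-HU affine conversion, window/level normalization to [0, 1],
and contrast-limited adaptive histogram equalization. Geometry: a single
affine transform (rotation, shift, shear, zoom) sampled once per call and
applied identically to image and mask; the mask is resampled with
nearest-neighbor so it stays binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, transform

__all__ = ["WindowSpec", "AugmentationSpec", "hu_convert", "apply_window",
           "adaptive_hist_eq", "augment_pair", "apply_affine"]

# defaults: standard abdominal soft-tissue window (configurable)
DEFAULT_WINDOW_CENTER = 50.0
DEFAULT_WINDOW_WIDTH = 400.0


@dataclass(frozen=True)
class WindowSpec:
    center: float = DEFAULT_WINDOW_CENTER
    width: float = DEFAULT_WINDOW_WIDTH

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"window width must be > 0, got {self.width}")


@dataclass(frozen=True)
class AugmentationSpec:
    """Symmetric augmentation ranges; zero ranges make :func:`augment_pair` the identity."""

    rotation_range: float = 15.0          # degrees, sampled in [-r, r]
    shift_range: float = 0.10             # fraction of each dimension, [-s, s]
    shear_range: float = 5.0              # degrees, [-s, s]
    zoom_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self):
        if self.rotation_range < 0 or self.shift_range < 0 or self.shear_range < 0:
            raise ValueError("augmentation ranges must be >= 0")
        lo, hi = self.zoom_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError(f"zoom factors must be positive with min <= max, got {self.zoom_range}")

    @property
    def is_identity(self) -> bool:
        return (self.rotation_range == 0 and self.shift_range == 0
                and self.shear_range == 0 and self.zoom_range == (1.0, 1.0))


def hu_convert(raw: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Affine map from stored scanner units to Hounsfield units."""
    if slope == 0:
        raise ValueError("rescale slope must be nonzero")
    return np.asarray(raw, dtype=np.float64) * slope + intercept


def apply_window(hu: np.ndarray, w: WindowSpec | None = None) -> np.ndarray:
    """Map [center - width/2, center + width/2] linearly onto [0, 1], clipping outside."""
    w = w or WindowSpec()
    lo = w.center - w.width / 2.0
    return np.clip((np.asarray(hu, dtype=np.float64) - lo) / w.width, 0.0, 1.0)


def adaptive_hist_eq(img: np.ndarray, tiles: tuple[int, int] = (8, 8),
                     clip_limit: float = 0.01) -> np.ndarray:
    """CLAHE on a [0, 1] image; output stays in [0, 1]."""
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image must be normalized to [0, 1]")
    if np.ptp(img) == 0:
        return img.copy()  # constant image: nothing to equalize
    kernel = (max(1, img.shape[0] // tiles[0]), max(1, img.shape[1] // tiles[1]))
    out = exposure.equalize_adapthist(img, kernel_size=kernel, clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0)


def apply_affine(img: np.ndarray, mask: np.ndarray,
                 rotation_deg: float = 0.0,
                 shift: tuple[float, float] = (0.0, 0.0),
                 shear_deg: float = 0.0,
                 zoom: float = 1.0,
                 fill_value: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Apply one deterministic affine map, about the image center, to both arrays.

    ``shift`` is (row, col) in pixels. The mask is warped with order-0
    interpolation so its values remain {0, 1}; the image with order 1.
    """
    if img.shape != mask.shape:
        raise ValueError(f"image {img.shape} and mask {mask.shape} differ in shape")
    h, w = img.shape
    center = np.array([w / 2.0 - 0.5, h / 2.0 - 0.5])  # (x, y)

    tf = (
        transform.AffineTransform(translation=-center)
        + transform.AffineTransform(
            rotation=np.deg2rad(rotation_deg),
            shear=np.deg2rad(shear_deg),
            scale=(zoom, zoom),
        )
        + transform.AffineTransform(translation=center)
        + transform.AffineTransform(translation=(shift[1], shift[0]))
    )
    out_img = transform.warp(img.astype(np.float64), tf.inverse, order=1,
                             mode="constant", cval=fill_value, preserve_range=True)
    out_mask = transform.warp(mask.astype(np.float64), tf.inverse, order=0,
                              mode="constant", cval=0.0, preserve_range=True)
    return out_img, (out_mask > 0.5).astype(mask.dtype)


def augment_pair(img: np.ndarray, mask: np.ndarray, a: AugmentationSpec,
                 rng: np.random.Generator | None = None,
                 fill_value: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Sample one transform from ``a`` and apply it to image and mask alike."""
    if img.shape != mask.shape:
        raise ValueError(f"image {img.shape} and mask {mask.shape} differ in shape")
    if a.is_identity:
        return img.copy(), mask.copy()
    rng = rng if rng is not None else np.random.default_rng(a.seed)
    h, w = img.shape
    rotation = rng.uniform(-a.rotation_range, a.rotation_range)
    shift = (rng.uniform(-a.shift_range, a.shift_range) * h,
             rng.uniform(-a.shift_range, a.shift_range) * w)
    shear = rng.uniform(-a.shear_range, a.shear_range)
    zoom = rng.uniform(*a.zoom_range)
    return apply_affine(img, mask, rotation_deg=rotation, shift=shift,
                        shear_deg=shear, zoom=zoom, fill_value=fill_value)
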