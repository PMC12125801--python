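"""Seeded synthetic CT-like slice/mask generator.

Produces 2-D Hounsfield-valued images containing one small, irregular,
low-contrast target surrounded by gray-level-similar neighbor blobs on a
noisy background — the regime every downstream module is exercised on.

The target boundary is a perturbed ellipse: the unit radius is modulated by
a truncated Fourier series (first four harmonics) whose total amplitude is
the ``irregularity`` parameter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["PhantomSpec", "PhantomPair", "generate_phantom", "generate_dataset",
           "split_sizes", "save_pair", "load_pair"]

_N_HARMONICS = 4
_NEIGHBOR_HU_JITTER = 10.0  # neighbors stay within +/- 10 HU of their configured mean


class PhantomSpecError(ValueError):
    """A PhantomSpec field violates its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic slice/mask pair."""

    height: int = 64
    width: int = 64
    background_hu: float = 40.0
    target_mean_hu: float = 90.0
    neighbor_mean_hu: float = 95.0
    target_axes: tuple[float, float] = (10.0, 7.0)
    irregularity: float = 0.3
    noise_sd: float = 10.0
    n_neighbors: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.height < 32:
            raise PhantomSpecError(f"height must be >= 32, got {self.height}")
        if self.width < 32:
            raise PhantomSpecError(f"width must be >= 32, got {self.width}")
        a, b = self.target_axes
        if a < 0 or b < 0:
            raise PhantomSpecError(f"target_axes must be non-negative, got {self.target_axes}")
        # leave room for the irregular perturbation (radius grows by <= irregularity)
        max_r = max(a, b) * (1.0 + self.irregularity)
        if 2 * max_r >= min(self.height, self.width):
            raise PhantomSpecError(
                f"target_axes {self.target_axes} do not fit strictly inside "
                f"a {self.height}x{self.width} frame"
            )
        if not 0.0 <= self.irregularity <= 1.0:
            raise PhantomSpecError(f"irregularity must be in [0,1], got {self.irregularity}")
        if self.noise_sd < 0:
            raise PhantomSpecError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_neighbors < 0:
            raise PhantomSpecError(f"n_neighbors must be >= 0, got {self.n_neighbors}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["target_axes"] = list(d["target_axes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["target_axes"] = tuple(d["target_axes"])
        return cls(**d)


@dataclass
class PhantomPair:
    image: np.ndarray  # (H, W) float HU
    mask: np.ndarray   # (H, W) uint8 {0, 1}
    spec: PhantomSpec

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} differ in shape"
            )


def _blob_mask(height: int, width: int, center: tuple[float, float],
               axes: tuple[float, float], angle: float,
               fourier: np.ndarray | None) -> np.ndarray:
    """Boolean mask of a (possibly perturbed) rotated ellipse.

    A pixel (y, x) is inside when its elliptical radius rho satisfies
    rho <= 1 + sum_k [a_k cos(k theta) + b_k sin(k theta)].
    """
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    dy = yy - center[0]
    dx = xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    a, b = axes
    if a <= 0 or b <= 0:
        return np.zeros((height, width), dtype=bool)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    boundary = np.ones((height, width), dtype=np.float64)
    if fourier is not None:
        theta = np.arctan2(v / b, u / a)
        for k in range(1, _N_HARMONICS + 1):
            boundary += fourier[2 * (k - 1)] * np.cos(k * theta)
            boundary += fourier[2 * (k - 1) + 1] * np.sin(k * theta)
    return rho <= boundary


def _fourier_coefficients(rng: np.random.Generator, amplitude: float) -> np.ndarray | None:
    """Random harmonic coefficients with total L1 norm == amplitude."""
    if amplitude == 0.0:
        return None
    raw = rng.normal(size=2 * _N_HARMONICS)
    l1 = np.abs(raw).sum()
    if l1 == 0:
        return None
    return raw * (amplitude / l1)


def generate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Render one seeded slice/mask pair from its spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # target near the frame center, mildly jittered
    max_r = max(spec.target_axes) * (1.0 + spec.irregularity)
    jitter = min(h, w) * 0.05
    cy = h / 2.0 + rng.uniform(-jitter, jitter)
    cx = w / 2.0 + rng.uniform(-jitter, jitter)
    angle = rng.uniform(0, np.pi)
    fourier = _fourier_coefficients(rng, spec.irregularity)
    mask = _blob_mask(h, w, (cy, cx), spec.target_axes, angle, fourier)

    image = np.full((h, w), spec.background_hu, dtype=np.float64)

    # neighbor blobs: disjoint from the target, gray levels close to its own
    placed = 0
    attempts = 0
    forbidden = _dilate(mask, 2)
    while placed < spec.n_neighbors and attempts < 200 * max(spec.n_neighbors, 1):
        attempts += 1
        na = rng.uniform(3.0, max(4.0, 0.8 * max(spec.target_axes)))
        nb = rng.uniform(3.0, max(4.0, 0.8 * max(spec.target_axes)))
        ncy = rng.uniform(na + 1, h - na - 1)
        ncx = rng.uniform(nb + 1, w - nb - 1)
        nangle = rng.uniform(0, np.pi)
        blob = _blob_mask(h, w, (ncy, ncx), (na, nb), nangle, None)
        if not blob.any() or (blob & forbidden).any():
            continue
        hu = spec.neighbor_mean_hu + rng.uniform(-_NEIGHBOR_HU_JITTER, _NEIGHBOR_HU_JITTER)
        image[blob] = hu
        forbidden |= _dilate(blob, 2)
        placed += 1

    image[mask] = spec.target_mean_hu
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=(h, w))

    return PhantomPair(image=image, mask=mask.astype(np.uint8), spec=spec)


def _dilate(mask: np.ndarray, it: int) -> np.ndarray:
    from scipy.ndimage import binary_dilation

    return binary_dilation(mask, iterations=it)


# ---------------------------------------------------------------------------
# dataset generation and splitting
# ---------------------------------------------------------------------------

def split_sizes(n: int, ratio: tuple[int, int, int] = (7, 1, 7)) -> tuple[int, int, int]:
    """Train/val/test sizes for ``n`` cases at the given ratio.

    The validation share is rounded up (a validation set must never be
    starved), the training share rounded down, and the test set takes the
    remainder; every split must end up non-empty.
    """
    if n < 3:
        raise ValueError(f"need at least 3 cases to populate three splits, got {n}")
    total = sum(ratio)
    n_train = int(np.floor(n * ratio[0] / total))
    n_val = int(np.ceil(n * ratio[1] / total))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n={n} too small for ratio {ratio}: sizes {(n_train, n_val, n_test)}")
    return n_train, n_val, n_test


_JITTERABLE = {"background_hu", "target_mean_hu", "neighbor_mean_hu",
               "irregularity", "noise_sd"}


def generate_dataset(
    n: int,
    base_spec: PhantomSpec | None = None,
    jitter: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    ratio: tuple[int, int, int] = (7, 1, 7),
) -> tuple[list[PhantomPair], list[str]]:
    """Generate ``n`` phantoms with per-case jitter and a train/val/test split.

    Returns (pairs, labels) where labels[i] in {"train", "val", "test"}.
    The split is per-case, assigned by a seeded shuffle.
    """
    base_spec = base_spec or PhantomSpec()
    jitter = jitter or {}
    for key in jitter:
        if key == "target_axes":
            continue
        if key not in _JITTERABLE:
            raise ValueError(f"cannot jitter field {key!r}")
    n_train, n_val, n_test = split_sizes(n, ratio)

    rng = np.random.default_rng(seed)
    pairs: list[PhantomPair] = []
    for i in range(n):
        overrides: dict = {"seed": int(rng.integers(0, 2**31 - 1))}
        for key, (lo, hi) in jitter.items():
            if key == "target_axes":
                overrides[key] = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
            else:
                overrides[key] = float(rng.uniform(lo, hi))
                if key == "irregularity":
                    overrides[key] = float(np.clip(overrides[key], 0.0, 1.0))
                if key == "noise_sd":
                    overrides[key] = max(overrides[key], 0.0)
        spec = dataclasses.replace(base_spec, **overrides)
        pairs.append(generate_phantom(spec))

    labels = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    order = rng.permutation(n)
    assigned = [""] * n
    for pos, idx in enumerate(order):
        assigned[idx] = labels[pos]
    return pairs, assigned


# ---------------------------------------------------------------------------
# disk I/O: paired 16-bit PNG image + 8-bit PNG mask + JSON sidecar, or NIfTI
# ---------------------------------------------------------------------------

_PNG_OFFSET = 1024.0  # stored = HU + 1024, clipped to uint16


def save_pair(pair: PhantomPair, out_dir: str | Path, stem: str, fmt: str = "png") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        import imageio.v3 as iio

        stored = np.clip(np.rint(pair.image + _PNG_OFFSET), 0, 65535).astype(np.uint16)
        iio.imwrite(out_dir / f"{stem}_image.png", stored)
        iio.imwrite(out_dir / f"{stem}_mask.png", (pair.mask * 255).astype(np.uint8))
    elif fmt == "nifti":
        import nibabel as nib

        nib.save(nib.Nifti1Image(pair.image.astype(np.float32), np.eye(4)),
                 out_dir / f"{stem}_image.nii.gz")
        nib.save(nib.Nifti1Image(pair.mask.astype(np.uint8), np.eye(4)),
                 out_dir / f"{stem}_mask.nii.gz")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    with open(out_dir / f"{stem}_spec.json", "w") as fh:
        json.dump(pair.spec.to_dict(), fh, indent=2)


def load_pair(out_dir: str | Path, stem: str, fmt: str = "png") -> PhantomPair:
    out_dir = Path(out_dir)
    with open(out_dir / f"{stem}_spec.json") as fh:
        spec = PhantomSpec.from_dict(json.load(fh))
    if fmt == "png":
        import imageio.v3 as iio

        stored = iio.imread(out_dir / f"{stem}_image.png").astype(np.float64)
        image = stored - _PNG_OFFSET
        mask = (iio.imread(out_dir / f"{stem}_mask.png") > 127).astype(np.uint8)
    elif fmt == "nifti":
        import nibabel as nib

        image = np.asarray(nib.load(out_dir / f"{stem}_image.nii.gz").dataobj, dtype=np.float64)
        mask = (np.asarray(nib.load(out_dir / f"{stem}_mask.nii.gz").dataobj) > 0).astype(np.uint8)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return PhantomPair(image=image, mask=mask, spec=spec)
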