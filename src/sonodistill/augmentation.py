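"""Stochastic training-time image transformations.

The pipeline mirrors the acquisition variability of fetal ultrasound:
horizontal/vertical flips (fetal position, operator mirroring), gamma
correction (gain settings), zoom and small rotations (probe placement and
display settings).  Images are normalised to [0, 1] *before* augmentation —
gamma correction on un-normalised intensities is ill-posed — and the
pipeline preserves that range (clamping after resampling).

All randomness comes from an owned ``numpy.random.Generator``, so a fixed
seed makes the full pipeline a pure function.  Augmentation is applied to
the training split only; validation and test images get normalisation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "AugmentationConfig",
    "gamma_correct",
    "random_flip",
    "zoom",
    "rotate",
    "augment",
]


@dataclass(frozen=True)
class AugmentationConfig:
    """Transform probabilities and ranges (defaults as used for training)."""

    p_flip_h: float = 0.5
    p_flip_v: float = 0.5
    gamma_range: tuple[float, float] = (0.3, 1.7)
    zoom_range: tuple[float, float] = (0.8, 1.2)
    rotation_range_deg: tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.gamma_range, self.zoom_range, self.rotation_range_deg):
            if lo > hi:
                raise ValueError("range bounds must be ordered")
        if not (0 <= self.p_flip_h <= 1 and 0 <= self.p_flip_v <= 1):
            raise ValueError("flip probabilities must lie in [0, 1]")

    @staticmethod
    def identity() -> "AugmentationConfig":
        """A configuration under which ``augment`` is the identity map."""
        return AugmentationConfig(
            p_flip_h=0.0,
            p_flip_v=0.0,
            gamma_range=(1.0, 1.0),
            zoom_range=(1.0, 1.0),
            rotation_range_deg=(0.0, 0.0),
        )


def _check_unit_range(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if image.size and (image.min() < 0.0 or image.max() > 1.0):
        raise ValueError("pixel values must lie in [0, 1]; normalise first")
    return image


def gamma_correct(image: np.ndarray, gamma: float) -> np.ndarray:
    """Pixel-wise power law p -> p**gamma; [0,1] maps onto itself."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return _check_unit_range(image) ** gamma


def random_flip(
    image: np.ndarray, axis: int, p: float = 0.5, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Mirror along ``axis`` (0 = vertical flip, 1 = horizontal) with
    probability ``p``; the deterministic flip is an involution."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    rng = rng if rng is not None else np.random.default_rng()
    if p >= 1.0 or (p > 0.0 and rng.random() < p):
        return np.flip(image, axis=axis).copy()
    return image


def zoom(image: np.ndarray, factor: float) -> np.ndarray:
    """Rescale the content about the centre, keeping the canvas size.

    factor > 1 zooms in (crop after upsampling); factor < 1 zooms out
    (pad with the border value after downsampling).  Allowed range
    [0.8, 1.2].
    """
    image = np.asarray(image, dtype=float)
    if not 0.8 <= factor <= 1.2:
        raise ValueError("zoom factor outside the configured [0.8, 1.2] range")
    if factor == 1.0:
        return image.copy()
    h, w = image.shape
    scaled = ndimage.zoom(image, factor, order=1, mode="nearest", grid_mode=False)
    sh, sw = scaled.shape
    if sh >= h and sw >= w:  # zoom in: central crop
        top, left = (sh - h) // 2, (sw - w) // 2
        return scaled[top : top + h, left : left + w]
    # zoom out: centre on an edge-padded canvas
    ph, pw = (h - sh) // 2, (w - sw) // 2
    return np.pad(scaled, ((ph, h - sh - ph), (pw, w - sw - pw)), mode="edge")


def rotate(image: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotate about the centre with bilinear resampling, border-filled."""
    image = np.asarray(image, dtype=float)
    if not -10.0 <= theta_deg <= 10.0:
        raise ValueError("rotation angle outside the configured [-10, 10] degree range")
    if theta_deg == 0.0:
        return image.copy()
    return ndimage.rotate(image, theta_deg, reshape=False, order=1, mode="nearest")


def normalize(image: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]; a constant image maps to all zeros."""
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def augment(
    image: np.ndarray,
    config: AugmentationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply the full stochastic pipeline to a [0,1] grayscale image.

    Order: horizontal flip, vertical flip, gamma, zoom, rotation; the
    output is clamped back to [0, 1] after resampling.
    """
    config = config if config is not None else AugmentationConfig()
    rng = rng if rng is not None else np.random.default_rng()
    out = _check_unit_range(image)
    out = random_flip(out, axis=1, p=config.p_flip_h, rng=rng)
    out = random_flip(out, axis=0, p=config.p_flip_v, rng=rng)
    g_lo, g_hi = config.gamma_range
    out = gamma_correct(out, float(rng.uniform(g_lo, g_hi)) if g_hi > g_lo else g_lo)
    z_lo, z_hi = config.zoom_range
    out = zoom(out, float(rng.uniform(z_lo, z_hi)) if z_hi > z_lo else z_lo)
    r_lo, r_hi = config.rotation_range_deg
    out = rotate(out, float(rng.uniform(r_lo, r_hi)) if r_hi > r_lo else r_lo)
    return np.clip(out, 0.0, 1.0)
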