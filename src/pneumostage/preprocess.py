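"""Radiograph preprocessing: histogram equalization, downsampling, augmentation.

Chest radiographs have poor contrast and a wide dynamic range; global
histogram equalization redistributes gray levels so the cumulative
distribution becomes approximately linear, which sharpens the contrast
between lung fields, opacities and surrounding tissue.  Full-resolution
films are then downsampled (area-weighted) to the classifier's working
resolution.

Three augmentation regimes are available for training crops:

* ``none`` — identity.
* ``mild`` — rotation of 5–10° magnitude (random sign), zoom to
  110–120% with center crop back to the original frame, random
  horizontal flip.
* ``heavy`` — mild plus random vertical flip and additive Gaussian
  intensity noise.

Geometric transforms can be applied jointly to an image and its binary
mask (nearest-neighbour interpolation for the mask) so crops and labels
stay aligned.  Exposed rotation corners are filled with the image
minimum so they cannot imitate bright opacities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

__all__ = ["equalize_histogram", "downsample", "AugmentationPolicy", "augment", "hflip", "vflip"]

log = logging.getLogger(__name__)


def _levels(img: np.ndarray) -> int:
    if img.dtype == np.uint8:
        return 256
    if img.dtype == np.uint16:
        return 65536
    raise TypeError(f"expected uint8/uint16 or float in [0,1], got dtype {img.dtype}")


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Global histogram equalization over the image's declared gray range.

    Integer images (uint8/uint16) are mapped through the standard
    cumulative-distribution transform over their full bit depth; float
    images in [0,1] are quantized to 256 levels, equalized, and returned
    as float.  The mapping is monotone non-decreasing; a constant image
    is returned unchanged.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("cannot equalize an empty image")
    as_float = np.issubdtype(img.dtype, np.floating)
    if as_float:
        if img.min() < 0 or img.max() > 1:
            raise ValueError("float image must be normalized to [0,1]")
        work = np.round(img * 255).astype(np.uint8)
    else:
        work = img
    n_levels = _levels(work)
    hist = np.bincount(work.ravel(), minlength=n_levels)
    cdf = np.cumsum(hist)
    nz = np.flatnonzero(hist)
    cdf_min = cdf[nz[0]]
    total = work.size
    if total == cdf_min:  # single gray level
        out = work.copy()
    else:
        lut = np.round((cdf - cdf_min) / (total - cdf_min) * (n_levels - 1)).astype(work.dtype)
        out = lut[work]
    if as_float:
        return (out / 255.0).astype(img.dtype)
    return out


def downsample(img: np.ndarray, target: int) -> np.ndarray:
    """Resize a square-ish image to ``target``×``target`` with anti-aliasing.

    Area-weighted (Gaussian-prefiltered bilinear) interpolation; values
    and dtype are preserved.  A target larger than the input is allowed
    but logged, since it is upsampling.
    """
    img = np.asarray(img)
    if target < 1:
        raise ValueError(f"target size must be >= 1, got {target}")
    if img.shape == (target, target):
        return img.copy()
    if target > max(img.shape):
        log.warning("downsample called with target %d > input %s (upsampling)", target, img.shape)
    out = sktransform.resize(img.astype(np.float64), (target, target),
                             anti_aliasing=min(img.shape) > target, preserve_range=True)
    if np.issubdtype(img.dtype, np.integer):
        return np.round(out).astype(img.dtype)
    return out.astype(img.dtype)


@dataclass(frozen=True)
class AugmentationPolicy:
    """Sampling ranges for one augmentation draw; see the regime presets."""

    regime: str = "none"
    rotation_degrees: tuple[float, float] = (0.0, 0.0)
    zoom_percent: tuple[float, float] = (100.0, 100.0)
    hflip: bool = False
    vflip: bool = False
    gaussian_noise_sd: float = 0.0
    seed: int = 0

    @classmethod
    def none(cls, seed: int = 0) -> "AugmentationPolicy":
        return cls(seed=seed)

    @classmethod
    def mild(cls, seed: int = 0) -> "AugmentationPolicy":
        return cls(regime="mild", rotation_degrees=(5.0, 10.0), zoom_percent=(110.0, 120.0),
                   hflip=True, vflip=False, gaussian_noise_sd=0.0, seed=seed)

    @classmethod
    def heavy(cls, seed: int = 0, noise_sd: float = 0.15) -> "AugmentationPolicy":
        return cls(regime="heavy", rotation_degrees=(5.0, 10.0), zoom_percent=(110.0, 120.0),
                   hflip=True, vflip=True, gaussian_noise_sd=noise_sd, seed=seed)

    def validate(self) -> None:
        if self.regime not in ("none", "mild", "heavy"):
            raise ValueError(f"regime must be none/mild/heavy, got {self.regime!r}")
        lo, hi = self.rotation_degrees
        if lo > hi or lo < 0:
            raise ValueError("rotation_degrees must be a non-negative (lo, hi) magnitude range")
        zlo, zhi = self.zoom_percent
        if zlo > zhi or zlo <= 0:
            raise ValueError("zoom_percent must be a positive (lo, hi) range")
        if self.gaussian_noise_sd < 0:
            raise ValueError("gaussian_noise_sd must be >= 0")


def hflip(img: np.ndarray) -> np.ndarray:
    """Horizontal mirror (an involution)."""
    return img[:, ::-1].copy()


def vflip(img: np.ndarray) -> np.ndarray:
    return img[::-1, :].copy()


def _zoom_center_crop(img: np.ndarray, factor: float, order: int, cval: float) -> np.ndarray:
    h, w = img.shape
    scaled = sktransform.rescale(img.astype(np.float64), factor, order=order,
                                 cval=cval, preserve_range=True, anti_aliasing=False)
    sh, sw = scaled.shape
    if sh >= h:
        r0, c0 = (sh - h) // 2, (sw - w) // 2
        return scaled[r0:r0 + h, c0:c0 + w]
    pad_r, pad_c = h - sh, w - sw  # zoom < 100%: pad back to frame
    return np.pad(scaled, ((pad_r // 2, pad_r - pad_r // 2), (pad_c // 2, pad_c - pad_c // 2)),
                  constant_values=cval)


def sample_transform(policy: AugmentationPolicy, rng: np.random.Generator) -> dict:
    """Draw one concrete transform (angle, zoom, flips, noise) from the policy."""
    if policy.regime == "none":
        return {"angle": 0.0, "zoom": 1.0, "hflip": False, "vflip": False, "noise_sd": 0.0}
    magnitude = rng.uniform(*policy.rotation_degrees)
    angle = magnitude * (1 if rng.random() < 0.5 else -1)
    zoom = rng.uniform(*policy.zoom_percent) / 100.0
    return {"angle": float(angle), "zoom": float(zoom),
            "hflip": bool(policy.hflip and rng.random() < 0.5),
            "vflip": bool(policy.vflip and rng.random() < 0.5),
            "noise_sd": float(policy.gaussian_noise_sd)}


def apply_transform(img: np.ndarray, t: dict, is_mask: bool = False,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply a sampled transform; masks use nearest-neighbour and no noise."""
    order = 0 if is_mask else 1
    was_bool = img.dtype == bool
    out = img.astype(np.float64)
    cval = 0.0 if is_mask else float(out.min())
    if t["angle"] != 0.0:
        out = sktransform.rotate(out, t["angle"], order=order, cval=cval, preserve_range=True)
    if t["zoom"] != 1.0:
        out = _zoom_center_crop(out, t["zoom"], order, cval)
    if t["hflip"]:
        out = hflip(out)
    if t["vflip"]:
        out = vflip(out)
    if not is_mask and t["noise_sd"] > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        out = np.clip(out + rng.normal(0, t["noise_sd"], out.shape), 0.0, 1.0)
    if was_bool:
        return out > 0.5
    return out.astype(np.float32) if np.issubdtype(img.dtype, np.floating) else np.round(out).astype(img.dtype)


def augment(img: np.ndarray, policy: AugmentationPolicy,
            mask: np.ndarray | None = None):
    """Apply one random augmentation draw; same geometry for image and mask.

    Returns the augmented image, or an ``(image, mask)`` pair when a
    mask is supplied.  ``regime="none"`` is the identity.
    """
    policy.validate()
    if policy.regime == "none":
        return (img.copy(), mask.copy()) if mask is not None else img.copy()
    rng = np.random.default_rng(policy.seed)
    t = sample_transform(policy, rng)
    out = apply_transform(img, t, is_mask=False, rng=rng)
    if mask is not None:
        return out, apply_transform(mask, t, is_mask=True)
    return out
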