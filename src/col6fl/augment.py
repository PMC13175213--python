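"""Training-set augmentation and shared resize/normalize preprocessing.

All partitions are bilinearly resized to 256 x 256 and scaled to [0, 1].
The training partition is additionally expanded with 45-degree-family
rotations, a horizontal flip, and HSV value-channel brightness scaling
(factors 1.25 and 1.5 by default); evaluation partitions are never
augmented, which the partition tag on each image enforces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _skresize

from .simulate import LabeledImage

__all__ = [
    "AugmentationConfig",
    "resize_normalize",
    "rotate",
    "hflip",
    "hsv_brightness",
    "augment_training_set",
]

_ALLOWED_ANGLES = set(range(45, 360, 45))


@dataclass(frozen=True)
class AugmentationConfig:
    rotation_angles: tuple[int, ...] = (45,)
    apply_hflip: bool = True
    brightness_factors: tuple[float, ...] = (1.25, 1.5)
    target_size: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        for a in self.rotation_angles:
            if a not in _ALLOWED_ANGLES:
                raise ValueError(
                    f"rotation angle {a} not a multiple of 45 in [45, 315]"
                )
        for f in self.brightness_factors:
            if f <= 0:
                raise ValueError(f"brightness factor must be > 0, got {f}")

    @property
    def variants_per_image(self) -> int:
        return (
            1
            + len(self.rotation_angles)
            + int(self.apply_hflip)
            + len(self.brightness_factors)
        )


def resize_normalize(image: np.ndarray, target_size=(256, 256)) -> np.ndarray:
    """Bilinear resize to ``target_size`` and scale intensities to [0, 1].

    8-bit input is divided by 255; floating input already in [0, 1] is left
    on its scale (an already-sized [0,1] image is returned unchanged);
    other floating input is divided by its maximum.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("image must be at least 2 x 2")

    if img.dtype == np.uint8:
        scale = 255.0
    else:
        m = float(img.max())
        scale = m if m > 1.0 else 1.0
    img = img.astype(float)

    if img.shape[:2] != tuple(target_size):
        img = _skresize(
            img,
            (*target_size, 3),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    if scale != 1.0:
        img = img / scale
    return np.clip(img, 0.0, 1.0)


def rotate(image: np.ndarray, angle_deg: int) -> np.ndarray:
    """Rotate about the image centre by a multiple of 45 degrees.

    Right-angle multiples are exact index permutations.  Odd multiples of
    45 use bilinear rotation with mirror-reflected out-of-frame sampling,
    so no corner is filled with a flat colour that would let a classifier
    spot augmented frames.
    """
    img = np.asarray(image, dtype=float)
    angle = int(angle_deg) % 360
    if angle % 45 != 0:
        raise ValueError(f"angle must be a multiple of 45 degrees, got {angle_deg}")
    if angle == 0:
        return img.copy()
    if angle % 90 == 0:
        return np.ascontiguousarray(np.rot90(img, k=angle // 90, axes=(0, 1)))
    out = ndimage.rotate(
        img, angle, axes=(1, 0), reshape=False, order=1, mode="mirror"
    )
    return np.clip(out, img.min(), img.max())


def hflip(image: np.ndarray) -> np.ndarray:
    """Mirror the image left-right (columns reversed)."""
    img = np.asarray(image)
    return np.ascontiguousarray(img[:, ::-1])


def hsv_brightness(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale the HSV value channel by ``factor`` (clipped to [0, 1]).

    Equivalent to RGB -> HSV, V *= factor, clip V, HSV -> RGB, computed in
    closed form: for fixed hue and saturation every RGB channel is linear
    in V (= max channel), so the round trip is a per-pixel rescaling of
    RGB by min(factor, 1/V).  Hue and saturation are preserved exactly.
    """
    if factor <= 0:
        raise ValueError(f"brightness factor must be > 0, got {factor}")
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {img.shape}")
    v = img.max(axis=2)
    with np.errstate(divide="ignore"):
        scale = np.minimum(factor, np.where(v > 0, 1.0 / np.maximum(v, 1e-300), factor))
    return np.clip(img * scale[..., None], 0.0, 1.0)


def augment_training_set(
    images: list[LabeledImage], cfg: AugmentationConfig | None = None
) -> list[LabeledImage]:
    """Expand a preprocessed training partition with the configured variants.

    Per input image, emits the original plus one variant per rotation
    angle, one horizontal flip if enabled, and one per brightness factor.
    Labels and patient/site metadata are copied verbatim.  Raises if any
    image is tagged as an evaluation partition.
    """
    cfg = cfg or AugmentationConfig()
    out: list[LabeledImage] = []
    for im in images:
        if im.partition in ("test", "val", "validation"):
            raise ValueError(
                f"augmentation must not be applied to the {im.partition!r} "
                f"partition (patient {im.patient_id})"
            )
        if im.pixels.shape[:2] != tuple(cfg.target_size):
            raise ValueError(
                f"image of patient {im.patient_id} is {im.pixels.shape[:2]}, "
                f"expected {cfg.target_size}; run resize_normalize first"
            )
        out.append(im)
        for a in cfg.rotation_angles:
            out.append(replace(im, pixels=rotate(im.pixels, a)))
        if cfg.apply_hflip:
            out.append(replace(im, pixels=hflip(im.pixels)))
        for f in cfg.brightness_factors:
            out.append(replace(im, pixels=hsv_brightness(im.pixels, f)))
    return out
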