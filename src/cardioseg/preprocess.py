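"""Intensity normalization and label-consistent slice augmentation.

Normalization clips CT intensities to the [0, 2048] HU window and
divides by 2048, so soft tissue and contrast-filled blood land in
(0, 1) and air/bone saturate the ends.  Augmentation is deliberately
conservative — horizontal flip, up-to-5% in-plane translation and
95–105% isotropic scaling — geometric transforms that do not alter
clinically meaningful shape or intensity features.  Images are
interpolated linearly, labels (and any prior-mask channels) by nearest
neighbour, with one shared transform per draw so image and label stay
aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imageio import Volume

__all__ = ["HU_CEILING", "AugmentSpec", "normalize_hu", "augment_pair", "augment_case"]

HU_CEILING = 2048.0


def normalize_hu(vol: Volume) -> Volume:
    """Clip to [0, 2048] HU then scale to [0, 1].

    Raises if the volume is already normalized (guards against the
    silent double division that would crush contrast).
    """
    if vol.intensity_kind != "HU":
        raise ValueError(
            f"normalize_hu expects HU intensities, got {vol.intensity_kind!r} "
            "(volume appears to be normalized already)"
        )
    data = np.clip(vol.data.astype(np.float32), 0.0, HU_CEILING) / HU_CEILING
    return vol.with_data(data, intensity_kind="normalized")


@dataclass(frozen=True)
class AugmentSpec:
    """Parameters of the train-time geometric augmentation."""

    p_hflip: float = 0.5
    max_translate_frac: float = 0.05
    scale_range: tuple[float, float] = (0.95, 1.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_hflip <= 1.0:
            raise ValueError(f"p_hflip must be in [0, 1], got {self.p_hflip}")
        if not 0.0 <= self.max_translate_frac < 0.5:
            raise ValueError(
                f"max_translate_frac must be in [0, 0.5), got {self.max_translate_frac}"
            )
        lo, hi = self.scale_range
        if not 0.0 < lo <= hi:
            raise ValueError(f"scale_range must satisfy 0 < low <= high, got {self.scale_range}")


def _draw_transform(shape: tuple[int, int], spec: AugmentSpec, seed: int):
    rng = np.random.default_rng(seed)
    flip = rng.random() < spec.p_hflip
    lo, hi = spec.scale_range
    scale = float(rng.uniform(lo, hi))
    h, w = shape
    ty = float(rng.uniform(-spec.max_translate_frac, spec.max_translate_frac)) * h
    tx = float(rng.uniform(-spec.max_translate_frac, spec.max_translate_frac)) * w
    return flip, scale, (ty, tx)


def _apply(plane: np.ndarray, flip: bool, scale: float, shift: tuple[float, float], order: int):
    out = plane[:, ::-1] if flip else plane
    if scale == 1.0 and shift == (0.0, 0.0):
        return np.ascontiguousarray(out)
    h, w = out.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    # output coord y maps to input coord (y - center - shift)/scale + center
    matrix = np.eye(2) / scale
    offset = center - matrix @ (center + np.asarray(shift))
    return ndimage.affine_transform(
        out, matrix, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=(order > 1),
    )


def augment_pair(
    image_slice: np.ndarray,
    label_slice: np.ndarray,
    spec: AugmentSpec,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random flip/translate/scale draw to an image slice and
    its label slice with matched geometry.

    Deterministic for a fixed ``seed``.  Out-of-frame regions are filled
    with 0 for both image and label (the clipped intensity floor and the
    background code respectively).
    """
    image_slice = np.asarray(image_slice)
    label_slice = np.asarray(label_slice)
    if image_slice.shape != label_slice.shape:
        raise ValueError(
            f"image and label shapes differ: {image_slice.shape} vs {label_slice.shape}"
        )
    flip, scale, shift = _draw_transform(image_slice.shape, spec, seed)
    img = _apply(image_slice.astype(np.float32), flip, scale, shift, order=1)
    lab = _apply(label_slice, flip, scale, shift, order=0)
    return img, lab.astype(label_slice.dtype)


def augment_case(
    image_slice: np.ndarray,
    label_slice: np.ndarray,
    mask_channels: np.ndarray | None,
    spec: AugmentSpec,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Like :func:`augment_pair` but also transforms a stack of binary
    mask channels (anatomical priors) with the same draw, using nearest
    interpolation so the masks stay binary."""
    img, lab = augment_pair(image_slice, label_slice, spec, seed)
    if mask_channels is None:
        return img, lab, None
    flip, scale, shift = _draw_transform(image_slice.shape, spec, seed)
    out = np.stack(
        [_apply(ch, flip, scale, shift, order=0) for ch in np.asarray(mask_channels)]
    )
    return img, lab, out.astype(mask_channels.dtype)
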