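"""Dice, surface-distance (SD) and hybrid segmentation losses.

The training objective combines a region-overlap term with a boundary
term:

    loss = dice + alpha * sd

* **Dice loss** — one minus the class-averaged soft Dice overlap
  ``k * sum(P*G) / (sum(P^2) + sum(G^2))``.  In the standard form the
  numerator carries the factor ``k = 2`` and a perfect prediction
  scores 0; a literal variant with ``k = 1`` (``dice_as_printed``)
  is kept for fidelity testing — both have identical minimizers.
* **SD loss** — a Brier-type squared error in which each voxel is
  weighted by its normalized Euclidean distance to the gold-standard
  surface raised to the power ``gamma``; errors far from the true
  boundary are penalized most, which sharpens boundary placement
  where Dice is insensitive.

Every loss also has a closed-form gradient with respect to the
predicted probabilities (the ``*_grad`` functions), which is what the
network trainer consumes.

Array convention: probability maps and one-hot gold labels carry the
class channel on axis 0, i.e. shape ``(C, *spatial)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "LossConfig",
    "DistanceMap",
    "one_hot",
    "dice_loss",
    "dice_loss_grad",
    "distance_map",
    "distance_map_stack",
    "sd_loss",
    "sd_loss_grad",
    "hybrid_loss",
    "hybrid_loss_grad",
]


@dataclass(frozen=True)
class LossConfig:
    """Weights and variants of the hybrid loss.

    ``alpha`` scales the SD term (default 1: both terms contribute at
    comparable magnitude once distances are max-normalized to [0, 1]).
    ``gamma`` is the exponent on the normalized distance.
    """

    alpha: float = 1.0
    gamma: float = 1.0
    dice_as_printed: bool = False
    include_background: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.gamma < 0:
            raise ValueError("alpha and gamma must be >= 0")


@dataclass
class DistanceMap:
    """Per-class normalized distances to the gold-standard surface.

    ``data`` is non-negative, zero exactly on boundary voxels of the
    gold region, and bounded by 1 under max normalization.
    ``degenerate`` marks the class-absent case where distances are
    undefined and a uniform map of ones is substituted.
    """

    data: np.ndarray
    normalization: str = "max"
    degenerate: bool = False


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Encode an integer label array as (n_classes, *spatial) one-hot."""
    labels = np.asarray(labels)
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = labels == c
    return out


def _check_probs(pred: np.ndarray, gold: np.ndarray) -> None:
    if pred.shape != gold.shape:
        raise ValueError(f"pred/gold shape mismatch: {pred.shape} vs {gold.shape}")
    sums = pred.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-3):
        raise ValueError(
            "pred is not a probability map (per-voxel channel sums deviate "
            f"from 1 by up to {np.abs(sums - 1).max():.3g})"
        )


def _channel_slice(cfg: LossConfig, n_channels: int) -> range:
    return range(0, n_channels) if cfg.include_background else range(1, n_channels)


def _dice_terms(pred, gold, cfg):
    k = 1.0 if cfg.dice_as_printed else 2.0
    chans = _channel_slice(cfg, pred.shape[0])
    terms = []
    for c in chans:
        p, g = pred[c], gold[c]
        num = float((p * g).sum())
        den = float((p * p).sum() + (g * g).sum())
        terms.append((c, num, den, k))
    return terms


def dice_loss(pred: np.ndarray, gold: np.ndarray, cfg: LossConfig = LossConfig()) -> float:
    """Class-averaged soft Dice loss (0 at pred == gold in standard mode)."""
    pred = np.asarray(pred, dtype=np.float64)
    gold = np.asarray(gold, dtype=np.float64)
    _check_probs(pred, gold)
    terms = _dice_terms(pred, gold, cfg)
    total = 0.0
    for _, num, den, k in terms:
        # den == 0 only if the class is empty in gold and predicted
        # identically zero: perfect agreement on absence.
        total += (k / 2.0) if den == 0 else k * num / den
    return 1.0 - total / len(terms)


def dice_loss_grad(pred: np.ndarray, gold: np.ndarray, cfg: LossConfig = LossConfig()) -> np.ndarray:
    """Gradient of :func:`dice_loss` w.r.t. ``pred`` (same shape)."""
    pred = np.asarray(pred, dtype=np.float64)
    gold = np.asarray(gold, dtype=np.float64)
    grad = np.zeros_like(pred)
    terms = _dice_terms(pred, gold, cfg)
    n = len(terms)
    for c, num, den, k in terms:
        if den == 0:
            continue
        grad[c] = -(k * (gold[c] * den - 2.0 * pred[c] * num) / (den * den)) / n
    return grad


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Voxels of ``mask`` facing a non-mask voxel (face connectivity)."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def distance_map(
    gold: np.ndarray,
    class_code: int,
    spacing,
    normalization: str = "max",
) -> DistanceMap:
    """Unsigned distance (mm) of every voxel to the gold surface of one class.

    The surface is the set of boundary voxels of the class region; the
    map is zero there and grows with Euclidean distance computed under
    the physical ``spacing``.  Under ``normalization="max"`` the map is
    divided by its maximum so values lie in [0, 1].  If the class is
    absent the distances are undefined: a uniform map of ones is
    returned with ``degenerate=True`` and a warning.
    """
    gold = np.asarray(gold)
    mask = gold == class_code
    if not mask.any():
        warnings.warn(
            f"class {class_code} absent from gold labels; distance map is "
            "undefined, substituting uniform 1s",
            RuntimeWarning,
            stacklevel=2,
        )
        return DistanceMap(np.ones(gold.shape, dtype=np.float64), normalization, True)
    boundary = _boundary(mask)
    dist = ndimage.distance_transform_edt(~boundary, sampling=spacing)
    if normalization == "max":
        m = dist.max()
        if m > 0:
            dist = dist / m
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return DistanceMap(dist, normalization, False)


def distance_map_stack(labels: np.ndarray, n_classes: int, spacing) -> np.ndarray:
    """Distance maps for classes 0..n_classes-1 stacked on axis 0.

    Class 0 (background) is treated like any other channel; absent
    classes get the degenerate uniform-1 map without a warning storm.
    """
    out = np.empty((n_classes,) + labels.shape, dtype=np.float32)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for c in range(n_classes):
            out[c] = distance_map(labels, c, spacing).data
    return out


def _sd_weights(dmaps: np.ndarray, gamma: float) -> np.ndarray:
    return dmaps if gamma == 1.0 else np.power(dmaps, gamma)


def sd_loss(
    pred: np.ndarray,
    gold: np.ndarray,
    dmaps: np.ndarray,
    cfg: LossConfig = LossConfig(),
) -> float:
    """Distance-weighted squared error, averaged over voxels and classes."""
    pred = np.asarray(pred, dtype=np.float64)
    gold = np.asarray(gold, dtype=np.float64)
    if pred.shape != gold.shape:
        raise ValueError(f"pred/gold shape mismatch: {pred.shape} vs {gold.shape}")
    if dmaps is None or np.asarray(dmaps).shape != pred.shape:
        raise ValueError(
            "dmaps must provide one distance map per included class "
            f"(expected shape {pred.shape})"
        )
    dmaps = np.asarray(dmaps, dtype=np.float64)
    chans = _channel_slice(cfg, pred.shape[0])
    v = pred[0].size
    w = _sd_weights(dmaps, cfg.gamma)
    total = 0.0
    for c in chans:
        total += float((((pred[c] - gold[c]) ** 2) * w[c]).sum()) / v
    return total / len(chans)


def sd_loss_grad(
    pred: np.ndarray,
    gold: np.ndarray,
    dmaps: np.ndarray,
    cfg: LossConfig = LossConfig(),
) -> np.ndarray:
    pred = np.asarray(pred, dtype=np.float64)
    gold = np.asarray(gold, dtype=np.float64)
    dmaps = np.asarray(dmaps, dtype=np.float64)
    chans = _channel_slice(cfg, pred.shape[0])
    v = pred[0].size
    w = _sd_weights(dmaps, cfg.gamma)
    grad = np.zeros_like(pred)
    n = len(chans)
    for c in chans:
        grad[c] = 2.0 * (pred[c] - gold[c]) * w[c] / (v * n)
    return grad


def hybrid_loss(
    pred: np.ndarray,
    gold: np.ndarray,
    dmaps: np.ndarray,
    cfg: LossConfig = LossConfig(),
) -> float:
    """``dice_loss + alpha * sd_loss``."""
    value = dice_loss(pred, gold, cfg)
    if cfg.alpha > 0:
        value += cfg.alpha * sd_loss(pred, gold, dmaps, cfg)
    return value


def hybrid_loss_grad(
    pred: np.ndarray,
    gold: np.ndarray,
    dmaps: np.ndarray,
    cfg: LossConfig = LossConfig(),
) -> tuple[float, np.ndarray]:
    """Hybrid loss value and its gradient w.r.t. ``pred`` in one pass."""
    value = dice_loss(pred, gold, cfg)
    grad = dice_loss_grad(pred, gold, cfg)
    if cfg.alpha > 0:
        value += cfg.alpha * sd_loss(pred, gold, dmaps, cfg)
        grad += cfg.alpha * sd_loss_grad(pred, gold, dmaps, cfg)
    return value, grad
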