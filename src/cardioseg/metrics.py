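"""3D evaluation metrics: DSC, HD95, Recall, Precision.

All metrics are computed per case, per structure, on the full 3D
volume.  Surface distances are physical (mm, via the voxel spacing).

* ``dsc``: 2|G∩P| / (|G|+|P|); 1 when both masks are empty (perfect
  agreement on absence), 0 when exactly one is empty — so a structure
  the model fails to predict at all scores 0, never NaN.
* ``hd95``: symmetric percentile Hausdorff distance between the two
  boundary point sets.  ``percentile=100`` recovers the classic
  max–min Hausdorff distance; the default 95th percentile discards
  the most extreme 5% of boundary mismatches.  Undefined (raises)
  when either mask is empty; :func:`evaluate_case` converts that into
  a flagged NaN cell, never a silent 0.
* ``recall`` / ``precision``: |G∩P|/|G| and |G∩P|/|P|; NaN when the
  denominator mask is empty.

The fast path computes boundary distances with a Euclidean distance
transform; :func:`hd_bruteforce` is an exhaustive all-pairs oracle
kept for verification on small masks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

from .imageio import LabelMap
from .registry import REGISTRY

__all__ = [
    "dsc",
    "recall",
    "precision",
    "hd95",
    "hd_bruteforce",
    "surface_voxels",
    "evaluate_case",
    "aggregate_reports",
]


def _binarize(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def _check_shapes(gold, pred):
    if gold.shape != pred.shape:
        raise ValueError(f"gold/pred shape mismatch: {gold.shape} vs {pred.shape}")


def dsc(gold: np.ndarray, pred: np.ndarray) -> float:
    """Dice similarity coefficient 2|G∩P| / (|G|+|P|)."""
    gold, pred = _binarize(gold), _binarize(pred)
    _check_shapes(gold, pred)
    ng, np_ = int(gold.sum()), int(pred.sum())
    if ng == 0 and np_ == 0:
        return 1.0
    return 2.0 * int((gold & pred).sum()) / (ng + np_)


def recall(gold: np.ndarray, pred: np.ndarray) -> float:
    """Sensitivity |G∩P|/|G|; NaN when gold is empty."""
    gold, pred = _binarize(gold), _binarize(pred)
    _check_shapes(gold, pred)
    ng = int(gold.sum())
    if ng == 0:
        return float("nan")
    return int((gold & pred).sum()) / ng


def precision(gold: np.ndarray, pred: np.ndarray) -> float:
    """Positive predictive value |G∩P|/|P|; NaN when pred is empty."""
    gold, pred = _binarize(gold), _binarize(pred)
    _check_shapes(gold, pred)
    np_ = int(pred.sum())
    if np_ == 0:
        return float("nan")
    return int((gold & pred).sum()) / np_


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: mask voxels with a face-adjacent non-mask voxel
    (6-connectivity in 3D); the array border counts as outside."""
    mask = _binarize(mask)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def _directed_percentile(
    from_boundary: np.ndarray, to_boundary: np.ndarray, spacing, percentile: float
) -> float:
    """Percentile of distances from each boundary voxel of one mask to
    the nearest boundary voxel of the other, via a distance transform."""
    dist_to = ndimage.distance_transform_edt(~to_boundary, sampling=spacing)
    return float(np.percentile(dist_to[from_boundary], percentile))


def hd95(
    gold: np.ndarray,
    pred: np.ndarray,
    spacing,
    percentile: float = 95.0,
) -> float:
    """Symmetric percentile Hausdorff distance between mask boundaries, in mm."""
    gold, pred = _binarize(gold), _binarize(pred)
    _check_shapes(gold, pred)
    if not gold.any() or not pred.any():
        raise ValueError(
            "Hausdorff distance is undefined for an empty mask "
            f"(|G|={int(gold.sum())}, |P|={int(pred.sum())})"
        )
    bg, bp = surface_voxels(gold), surface_voxels(pred)
    h_gp = _directed_percentile(bg, bp, spacing, percentile)
    h_pg = _directed_percentile(bp, bg, spacing, percentile)
    return max(h_gp, h_pg)


def hd_bruteforce(
    gold: np.ndarray,
    pred: np.ndarray,
    spacing,
    percentile: float = 95.0,
) -> float:
    """Exhaustive all-pairs percentile Hausdorff distance (oracle path).

    O(n*m) in boundary points; use on small masks only.
    """
    gold, pred = _binarize(gold), _binarize(pred)
    _check_shapes(gold, pred)
    if not gold.any() or not pred.any():
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    sp = np.asarray(spacing, dtype=np.float64)
    pg = np.argwhere(surface_voxels(gold)) * sp
    pp = np.argwhere(surface_voxels(pred)) * sp
    d = cdist(pg, pp)
    h_gp = float(np.percentile(d.min(axis=1), percentile))
    h_pg = float(np.percentile(d.min(axis=0), percentile))
    return max(h_gp, h_pg)


def evaluate_case(
    gold: LabelMap | np.ndarray,
    pred: LabelMap | np.ndarray,
    spacing=None,
    percentile: float = 95.0,
) -> pd.DataFrame:
    """All four metrics for each of the ten substructures of one case.

    Returns a DataFrame with one row per structure and columns
    ``structure, code, dsc, recall, precision, hd95_mm``; cells whose
    metric is undefined (empty mask) hold NaN.
    """
    if isinstance(gold, LabelMap):
        spacing = spacing or gold.spacing
        gold = gold.data
    if isinstance(pred, LabelMap):
        spacing = spacing or pred.spacing
        pred = pred.data
    if spacing is None:
        raise ValueError("spacing is required when passing bare arrays")
    _check_shapes(gold, pred)
    rows = []
    for s in REGISTRY:
        g = gold == s.code
        p = pred == s.code
        try:
            hd = hd95(g, p, spacing, percentile)
        except ValueError:
            hd = float("nan")
        rows.append(
            {
                "structure": s.acronym,
                "code": s.code,
                "size_class": s.size_class,
                "dsc": dsc(g, p),
                "recall": recall(g, p),
                "precision": precision(g, p),
                "hd95_mm": hd,
            }
        )
    return pd.DataFrame(rows)


def aggregate_reports(reports: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean ± sd over cases, per structure, for each metric."""
    if not reports:
        raise ValueError("no reports to aggregate")
    allcases = pd.concat(reports, keys=range(len(reports)), names=["case"])
    metrics = ["dsc", "recall", "precision", "hd95_mm"]
    agg = allcases.groupby(["code", "structure", "size_class"])[metrics].agg(
        ["mean", "std"]
    )
    agg.columns = [f"{m}_{stat}" for m, stat in agg.columns]
    return agg.reset_index().sort_values("code").reset_index(drop=True)
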