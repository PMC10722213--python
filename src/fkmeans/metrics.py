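"""Segmentation overlap and surface-distance metrics, plus rater agreement.

Overlap metrics (Dice, precision, recall) are voxel-count based.  Surface
distances are computed between boundary voxels — foreground voxels with at
least one face-adjacent background voxel — in physical units (mm):

* ASSD: mean of the pooled directed surface distances (both directions)
* MSSD / HD: maximum of the pooled distances (the Hausdorff distance)
* HD95: 95th percentile of the pooled distances, robust to small outliers

ICC is the two-way random-effects, absolute-agreement, single-measure
intraclass correlation ICC(2,1), from the classical mean-squares
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, ValidationError


@dataclass
class SegmentationReport:
    dice: float
    precision: float
    recall: float
    assd: float
    mssd: float
    hd: float
    hd95: float
    n_pred: int
    n_truth: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("precision", "recall", "dice", "assd", "mssd", "hd", "hd95",
                 "n_pred", "n_truth")}


def _as_bool(mask) -> np.ndarray:
    data = mask.data if hasattr(mask, "data") else mask
    return np.asarray(data) > 0


def _check_same_grid(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")


def dice(pred, truth) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); two empty masks give 1.0."""
    a, b = _as_bool(pred), _as_bool(truth)
    _check_same_grid(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def precision_recall(pred, truth) -> tuple[float, float]:
    """(TP/(TP+FP), TP/(TP+FN)); an empty prediction has precision 0."""
    a, b = _as_bool(pred), _as_bool(truth)
    _check_same_grid(a, b)
    tp = int((a & b).sum())
    n_pred = int(a.sum())
    n_truth = int(b.sum())
    precision = tp / n_pred if n_pred else 0.0
    recall = tp / n_truth if n_truth else 0.0
    return precision, recall


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one face-adjacent background voxel."""
    mask = _as_bool(mask)
    if not mask.any():
        return np.zeros_like(mask)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def surface_distances(pred, truth, spacing=(1.0, 1.0, 1.0)
                      ) -> tuple[float, float, float, float]:
    """(ASSD, MSSD, HD, HD95) between mask boundaries, in physical units.

    Distances from every boundary voxel of each mask to the nearest boundary
    voxel of the other mask are pooled over both directions; ASSD is their
    mean, MSSD and HD their maximum, HD95 the 95th percentile.
    """
    a, b = _as_bool(pred), _as_bool(truth)
    _check_same_grid(a, b)
    if not a.any() or not b.any():
        raise DegenerateInputError("surface distances need two nonempty masks")
    sp = np.asarray(spacing, dtype=np.float64)
    pa = np.argwhere(boundary_voxels(a)) * sp
    pb = np.argwhere(boundary_voxels(b)) * sp
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    pooled = np.concatenate([d_ab, d_ba])
    hd = float(pooled.max())
    return float(pooled.mean()), hd, hd, float(np.percentile(pooled, 95))


def evaluate_masks(pred, truth, spacing=(1.0, 1.0, 1.0)) -> SegmentationReport:
    """Full per-case report (the columns of a segmentation results table)."""
    a, b = _as_bool(pred), _as_bool(truth)
    p, r = precision_recall(a, b)
    d = dice(a, b)
    if a.any() and b.any():
        assd, mssd, hd, hd95 = surface_distances(a, b, spacing)
    else:
        assd = mssd = hd = hd95 = float("nan")
    return SegmentationReport(dice=d, precision=p, recall=r, assd=assd,
                              mssd=mssd, hd=hd, hd95=hd95,
                              n_pred=int(a.sum()), n_truth=int(b.sum()))


def icc(ratings_a, ratings_b) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings_a`` and ``ratings_b`` are the two raters' values over the same
    cases (length >= 3).
    """
    x = np.asarray(ratings_a, dtype=np.float64)
    y = np.asarray(ratings_b, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("ratings must be two equal-length 1D sequences")
    n = len(x)
    if n < 3:
        raise ValidationError("ICC needs at least 3 cases")
    data = np.column_stack([x, y])  # n cases x k raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)      # between-cases
    msc = ss_cols / (k - 1)      # between-raters
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise DegenerateInputError("zero variance: ICC undefined")
    return float((msr - mse) / denom)
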