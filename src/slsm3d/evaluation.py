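"""Segmentation evaluation: confusion counts and the CCR/SP/FAR triple.

Accuracy of a 3D segmentation against a standard (ground-truth) tumor
mask is summarized by per-voxel confusion counts and three percentages:

    CCR = 100·(TPN + TNN)/N        correct classification rate
    SP  = 100·TNN/(TNN + FPN)      specificity
    FAR = 100·FPN/Nn               false alarm rate

with N the lattice size (the 3D ROI), Np/Nn the voxels inside/outside
the standard tumor.  Also here: the expert-contour intersection used to
build a standard mask from several delineations, rectangular ROI
cropping, and a Dice coefficient offered as an extra.

``CLINICAL_CASE_COUNTS`` carries the confusion counts of five
segmentation algorithms on three clinical breast-MRI cases; it is the
worked example of the metric definitions and the regression fixture for
the rounding conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence, Tuple

import numpy as np

from .io import BinaryMask, ScalarVolume

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion",
    "metrics",
    "intersect_masks",
    "build_roi",
    "dice",
    "round_half_up",
    "CLINICAL_CASE_COUNTS",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 → 0.01), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel confusion counts of a segmentation against a standard mask.

    tpn/fpn/tnn/fnn are the true/false positive/negative voxel numbers;
    n_pos/n_neg the standard-mask inside/outside sizes; total the lattice
    size.  Counts produced by :func:`confusion` always satisfy
    tpn + fnn = n_pos, tnn + fpn = n_neg, and n_pos + n_neg = total;
    externally reported tallies sometimes do not, so the identities are
    checked by :meth:`is_consistent` rather than enforced.
    """

    tpn: int
    fpn: int
    tnn: int
    fnn: int
    n_pos: int
    n_neg: int
    total: int

    def __post_init__(self):
        for name in ("tpn", "fpn", "tnn", "fnn", "n_pos", "n_neg", "total"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")

    def is_consistent(self) -> bool:
        return (
            self.tpn + self.fnn == self.n_pos
            and self.tnn + self.fpn == self.n_neg
            and self.n_pos + self.n_neg == self.total
        )


@dataclass(frozen=True)
class MetricSet:
    """CCR / SP / FAR in percent (full precision)."""

    ccr: float
    sp: float
    far: float

    def __post_init__(self):
        for name in ("ccr", "sp", "far"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")

    def rounded(self, ndigits: int = 2) -> "MetricSet":
        """Half-up rounding for report tables."""
        return MetricSet(
            round_half_up(self.ccr, ndigits),
            round_half_up(self.sp, ndigits),
            round_half_up(self.far, ndigits),
        )


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Per-voxel confusion counts over the full (ROI-cropped) lattice."""
    if pred.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}"
        )
    p = pred.data.astype(bool)
    t = truth.data.astype(bool)
    tpn = int((p & t).sum())
    fpn = int((p & ~t).sum())
    tnn = int((~p & ~t).sum())
    fnn = int((~p & t).sum())
    n_pos = int(t.sum())
    total = t.size
    return ConfusionCounts(tpn, fpn, tnn, fnn, n_pos, total - n_pos, total)


def metrics(c: ConfusionCounts) -> MetricSet:
    """CCR, SP, FAR (percent) from confusion counts."""
    if c.total <= 0:
        raise ValueError("CCR undefined: total voxel count N is zero")
    if c.tnn + c.fpn <= 0:
        raise ValueError("SP undefined: TNN + FPN is zero")
    if c.n_neg <= 0:
        raise ValueError("FAR undefined: Nn is zero")
    return MetricSet(
        ccr=100.0 * (c.tpn + c.tnn) / c.total,
        sp=100.0 * c.tnn / (c.tnn + c.fpn),
        far=100.0 * c.fpn / c.n_neg,
    )


def intersect_masks(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Voxelwise AND of expert delineations → the standard contour mask."""
    if len(masks) < 2:
        raise ValueError("need at least two masks to intersect")
    shape = masks[0].shape
    out = np.ones(shape, dtype=bool)
    for m in masks:
        if m.shape != shape:
            raise ValueError("all masks must share a shape")
        out &= m.data.astype(bool)
    return BinaryMask(out.astype(np.uint8), masks[0].spacing, masks[0].origin)


def build_roi(
    vol: ScalarVolume,
    rect: Tuple[int, int, int, int],
    slices: Tuple[int, int],
) -> ScalarVolume:
    """Crop the axis-aligned 3D ROI box [x0,x1)×[y0,y1)×[z0,z1).

    The rectangle is delineated on one 2D slice and extended across the
    slice range; the origin metadata is shifted so world coordinates are
    preserved.
    """
    x0, y0, x1, y1 = rect
    z0, z1 = slices
    nx, ny, nz = vol.shape
    if not (0 <= x0 < x1 <= nx and 0 <= y0 < y1 <= ny and 0 <= z0 < z1 <= nz):
        raise ValueError(
            f"ROI box ({x0},{y0},{x1},{y1})×({z0},{z1}) invalid for shape {vol.shape}"
        )
    sub = vol.data[x0:x1, y0:y1, z0:z1].copy()
    dx, dy, dz = vol.spacing
    ox, oy, oz = vol.origin
    origin = (ox + x0 * dx, oy + y0 * dy, oz + z0 * dz)
    return ScalarVolume(sub, vol.spacing, origin)


def dice(pred: BinaryMask, truth: BinaryMask) -> float:
    """Dice overlap coefficient 2|P∩T|/(|P|+|T|); extra, not a headline metric."""
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    p = pred.data.astype(bool)
    t = truth.data.astype(bool)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / denom


# Confusion counts (TPN, FPN, TNN, FNN, Np, Nn, N) of five algorithms on
# three clinical breast-MRI cases, all evaluated inside a fixed 3D ROI.
# Note the case-2 ACM row reuses the case-1 Np/Nn in its TPN..FNN tallies
# (is_consistent() is False there); the derived metrics nevertheless
# follow the formulas exactly as printed here.
CLINICAL_CASE_COUNTS = {
    ("case1", "ACM"): ConfusionCounts(6768, 44035, 113364, 571, 7339, 157399, 164738),
    ("case1", "LSM"): ConfusionCounts(6695, 15600, 141799, 644, 7339, 157399, 164738),
    ("case1", "SLSM"): ConfusionCounts(5004, 3074, 154325, 2335, 7339, 157399, 164738),
    ("case1", "3D-LSM"): ConfusionCounts(6926, 11959, 145440, 413, 7339, 157399, 164738),
    ("case1", "3D-SLSM"): ConfusionCounts(6006, 518, 156881, 1333, 7339, 157399, 164738),
    ("case2", "ACM"): ConfusionCounts(5648, 64123, 93276, 1691, 2784, 161954, 164738),
    ("case2", "LSM"): ConfusionCounts(2601, 4461, 157493, 183, 2784, 161954, 164738),
    ("case2", "SLSM"): ConfusionCounts(2122, 2156, 159798, 662, 2784, 161954, 164738),
    ("case2", "3D-LSM"): ConfusionCounts(2530, 2421, 159533, 254, 2784, 161954, 164738),
    ("case2", "3D-SLSM"): ConfusionCounts(2173, 253, 161701, 611, 2784, 161954, 164738),
    ("case3", "ACM"): ConfusionCounts(57877, 102006, 718123, 454, 58331, 820129, 878460),
    ("case3", "LSM"): ConfusionCounts(55432, 60356, 759773, 2899, 58331, 820129, 878460),
    ("case3", "SLSM"): ConfusionCounts(37814, 18512, 801617, 20517, 58331, 820129, 878460),
    ("case3", "3D-LSM"): ConfusionCounts(48647, 37622, 782507, 9684, 58331, 820129, 878460),
    ("case3", "3D-SLSM"): ConfusionCounts(35338, 11217, 808912, 22993, 58331, 820129, 878460),
}
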