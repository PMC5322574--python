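"""Segmentation evaluation: volumetric overlap, surface distance, and ROC.

Given ground-truth kidney voxels G and segmented voxels S the suite reports

* ``DC  = 100 * 2|G n S| / (|G| + |S|)`` — Dice coefficient, percent;
* ``PVD = 100 * (|G| - |S|) / |G|`` — signed percentage volume difference
  (the absolute value is reported alongside, since cohort summaries are
  conventionally nonnegative);
* ``BHD95`` — the bidirectional 95th-percentile Hausdorff distance between
  the two kidney surfaces, in physical mm (anisotropic spacing respected);
* ROC/AUC over a voxel-wise probability map.

Surfaces are KT voxels with at least one 6-connected face neighbor that is
OT or outside the volume; distances are between surface-voxel centers.
Percentiles use the nearest-rank convention on the sorted directed-distance
list, so percentile 1.0 is the classical Hausdorff maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.metrics import roc_curve

from .core import LabelMap, ProbabilityMap, require_compatible
from .errors import RenalsegError


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel counts of the four confusion subsets of a G/S pair."""

    c_tp: int
    c_fp: int
    c_fn: int
    c_tn: int

    @property
    def n_truth(self) -> int:
        return self.c_tp + self.c_fn

    @property
    def n_seg(self) -> int:
        return self.c_tp + self.c_fp

    @property
    def total(self) -> int:
        return self.c_tp + self.c_fp + self.c_fn + self.c_tn


@dataclass
class EvalReport:
    """All metrics for one (ground truth, segmentation) pair."""

    dc: float
    pvd: float
    abs_pvd: float
    bhd95: float
    auc: Optional[float] = None
    roc_points: Optional[list[tuple[float, float]]] = None

    def to_dict(self) -> dict:
        d = {
            "dc": self.dc,
            "pvd": self.pvd,
            "abs_pvd": self.abs_pvd,
            "bhd95_mm": self.bhd95,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def confusion(truth: LabelMap, seg: LabelMap) -> ConfusionCounts:
    require_compatible(truth.grid, seg.grid, "confusion counting")
    g = truth.kt_mask
    s = seg.kt_mask
    tp = int(np.count_nonzero(g & s))
    fp = int(np.count_nonzero(~g & s))
    fn = int(np.count_nonzero(g & ~s))
    tn = int(np.count_nonzero(~g & ~s))
    return ConfusionCounts(tp, fp, fn, tn)


def dice(c: ConfusionCounts) -> float:
    """Dice coefficient in percent; undefined when both sets are empty."""
    denom = 2 * c.c_tp + c.c_fp + c.c_fn
    if denom == 0:
        raise RenalsegError("Dice undefined: both ground truth and segmentation are empty")
    return 100.0 * 2 * c.c_tp / denom


def pvd(c: ConfusionCounts) -> float:
    """Signed percentage volume difference 100*(|G|-|S|)/|G|."""
    if c.n_truth == 0:
        raise RenalsegError("PVD undefined: ground truth contains no kidney voxels")
    return 100.0 * (c.n_truth - c.n_seg) / c.n_truth


def surface_voxels(m: LabelMap) -> np.ndarray:
    """(N, 3) voxel coordinates of the KT boundary (6-connectivity faces).

    A KT voxel is boundary if any face neighbor is OT or lies outside the
    volume; erosion with zero border value implements both cases at once.
    """
    kt = m.kt_mask
    if not kt.any():
        raise RenalsegError("surface undefined: no KT voxels")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(kt, structure=structure, border_value=0)
    return np.argwhere(kt & ~interior)


def directed_hd(
    from_set: np.ndarray,
    to_set: np.ndarray,
    spacing: tuple[float, float, float],
    percentile: float = 1.0,
) -> float:
    """Directed Hausdorff statistic in mm at a nearest-rank percentile.

    For each point of ``from_set`` the Cartesian mm distance to its nearest
    point of ``to_set`` is computed; the given percentile (1.0 = classical
    max) of the sorted distances is returned.
    """
    from_set = np.atleast_2d(np.asarray(from_set, dtype=float))
    to_set = np.atleast_2d(np.asarray(to_set, dtype=float))
    if from_set.size == 0 or to_set.size == 0:
        raise RenalsegError("directed Hausdorff undefined for an empty point set")
    if not (0 < percentile <= 1.0):
        raise ValueError("percentile must lie in (0, 1]")
    sp = np.asarray(spacing, dtype=float)
    d, _ = cKDTree(to_set * sp).query(from_set * sp, k=1)
    d = np.sort(np.atleast_1d(d))
    k = int(np.ceil(percentile * d.size))  # nearest-rank
    return float(d[k - 1])


def bhd95(truth: LabelMap, seg: LabelMap, percentile: float = 0.95) -> float:
    """Symmetric (bidirectional) percentile Hausdorff distance in mm."""
    require_compatible(truth.grid, seg.grid, "Hausdorff distance")
    g = surface_voxels(truth)
    s = surface_voxels(seg)
    sp = truth.grid.spacing
    return max(directed_hd(g, s, sp, percentile), directed_hd(s, g, sp, percentile))


def roc_auc(truth: LabelMap, prob: ProbabilityMap) -> tuple[list[tuple[float, float]], float]:
    """ROC points (fpr, tpr) and trapezoidal AUC of a probability map."""
    require_compatible(truth.grid, prob.grid, "ROC computation")
    y = truth.kt_mask.ravel(order="F")
    s = prob.p_kt.ravel(order="F")
    if y.all() or not y.any():
        raise RenalsegError("ROC undefined: ground truth contains a single class")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def evaluate_pair(
    truth: LabelMap, seg: LabelMap, prob: Optional[ProbabilityMap] = None
) -> EvalReport:
    """Full report for one segmentation against its ground truth."""
    c = confusion(truth, seg)
    report = EvalReport(
        dc=dice(c),
        pvd=pvd(c),
        abs_pvd=abs(pvd(c)),
        bhd95=bhd95(truth, seg),
    )
    if prob is not None:
        report.roc_points, report.auc = roc_auc(truth, prob)
    return report
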