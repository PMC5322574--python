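"""Voxel feature assembly, random-forest classification, and postprocessing.

Each voxel is described by 9 features: three channels (first-order CT
appearance, adaptive shape prior P_s, MGRF spatial probability P_G), each
summarized by its local value, the mean over the 26-neighbor cube, and the
mean over the 8 in-plane neighbors (center excluded in both means; border
voxels average over the neighbors that exist). Appearance features are
min-max normalized per volume so no channel dominates; shape and spatial
channels are already probabilities.

Classification uses a bagged random forest (default 400 trees) with random
feature subsetting at each split; the output probability is the fraction of
trees voting KT, and the label rule is ``probability >= 0.5 -> KT``. Noisy
labels are smoothed by a 3D median (voxel-majority) filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .core import (
    LABEL_KT,
    LABEL_OT,
    IntensityVolume,
    LabelMap,
    ProbabilityMap,
    VoxelGrid,
    require_compatible,
)
from .errors import EstimationError

logger = logging.getLogger("renalseg")

FEATURE_COLUMNS = (
    "app_local",
    "app_cube26",
    "app_plane8",
    "shape_local",
    "shape_cube26",
    "shape_plane8",
    "spatial_local",
    "spatial_cube26",
    "spatial_plane8",
)
APPEARANCE_COLUMNS = (0, 1, 2)


@dataclass
class FeatureTable:
    """(n_voxels, 9) feature matrix in lexicographic (z, y, x) row order."""

    data: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[1] != len(FEATURE_COLUMNS):
            raise ValueError(f"feature table must have {len(FEATURE_COLUMNS)} columns")
        if self.data.shape[0] != self.grid.n_voxels:
            raise ValueError("one row per voxel required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("features must be finite")


@dataclass
class ForestModel:
    """A trained random forest plus the metadata needed for reproducibility."""

    estimator: RandomForestClassifier
    n_trees: int
    seed: int


@dataclass
class ClassifierOutput:
    probability: ProbabilityMap
    labels: LabelMap


def _ravel(volume_array: np.ndarray) -> np.ndarray:
    # Fortran order scans x fastest, z slowest == lexicographic (z, y, x)
    return np.asarray(volume_array).ravel(order="F")


def _unravel(flat: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    return np.asarray(flat).reshape(grid.dims, order="F")


def neighborhood_mean(arr: np.ndarray, kernel_shape: tuple[int, int, int]) -> np.ndarray:
    """Mean over the window's neighbors of each voxel, center excluded.

    Windows are clipped at the volume border, so border voxels average over
    the neighbors that actually exist.
    """
    arr = np.asarray(arr, dtype=np.float64)
    kernel = np.ones(kernel_shape)
    total = ndimage.correlate(arr, kernel, mode="constant", cval=0.0)
    count = ndimage.correlate(np.ones_like(arr), kernel, mode="constant", cval=0.0)
    return (total - arr) / (count - 1.0)


def _channel_features(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    local = _ravel(arr)
    cube26 = _ravel(neighborhood_mean(arr, (3, 3, 3)))
    plane8 = _ravel(neighborhood_mean(arr, (3, 3, 1)))
    return local, cube26, plane8


def extract_features(
    volume: IntensityVolume, prior: ProbabilityMap, spatial: ProbabilityMap
) -> FeatureTable:
    """Assemble the 9-column voxel descriptor from the three channels."""
    require_compatible(volume.grid, prior.grid, "feature extraction")
    require_compatible(volume.grid, spatial.grid, "feature extraction")
    cols: list[np.ndarray] = []
    for arr in (np.asarray(volume.values, dtype=float), prior.p_kt, spatial.p_kt):
        cols.extend(_channel_features(arr))
    return FeatureTable(data=np.column_stack(cols), grid=volume.grid)


def normalize_appearance(table: FeatureTable) -> FeatureTable:
    """Min-max rescale the appearance columns to [0, 1], per volume.

    A constant column carries no information and maps to zeros (warned).
    """
    data = table.data.copy()
    for c in APPEARANCE_COLUMNS:
        col = data[:, c]
        lo, hi = col.min(), col.max()
        if hi > lo:
            data[:, c] = (col - lo) / (hi - lo)
        else:
            warnings.warn(
                f"appearance column {FEATURE_COLUMNS[c]!r} is constant; mapped to zeros",
                stacklevel=2,
            )
            data[:, c] = 0.0
    return FeatureTable(data=data, grid=table.grid)


def _stratified_rows(
    labels_flat: np.ndarray,
    appearance: np.ndarray,
    cap_per_class: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Row indices keeping at most cap_per_class voxels of each class.

    The background draw is split between uniform sampling and hard
    negatives — background voxels whose appearance falls inside the kidney
    intensity range — so rare confusable structures (adjacent organs with
    kidney-like intensity) stay represented in a heavily subsampled
    training set.
    """
    kt_rows = np.flatnonzero(labels_flat == LABEL_KT)
    if kt_rows.size > cap_per_class:
        kt_rows = rng.choice(kt_rows, size=cap_per_class, replace=False)
    ot_rows = np.flatnonzero(labels_flat == LABEL_OT)
    if ot_rows.size > cap_per_class:
        lo, hi = appearance[kt_rows].min(), appearance[kt_rows].max()
        hard = ot_rows[(appearance[ot_rows] >= lo) & (appearance[ot_rows] <= hi)]
        n_hard = min(hard.size, cap_per_class // 2)
        n_uniform = cap_per_class - n_hard
        picked = [rng.choice(ot_rows, size=n_uniform, replace=False)]
        if n_hard:
            picked.append(rng.choice(hard, size=n_hard, replace=False))
        ot_rows = np.unique(np.concatenate(picked))
    return np.sort(np.concatenate([kt_rows, ot_rows]))


def train_rf(
    tables: list[FeatureTable],
    truths: list[LabelMap],
    n_trees: int = 400,
    seed: int = 0,
    max_voxels_per_class_per_volume: int | None = None,
) -> ForestModel:
    """Train the bagged forest on (feature table, truth) pairs.

    ``max_voxels_per_class_per_volume`` optionally subsamples each volume's
    rows stratified by class (seeded), to keep training tractable on large
    cohorts; None trains on every voxel.
    """
    if len(tables) != len(truths):
        raise ValueError("one truth per feature table required")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for table, truth in zip(tables, truths):
        require_compatible(table.grid, truth.grid, "RF training")
        y = _ravel(truth.labels)
        if max_voxels_per_class_per_volume is not None:
            rows = _stratified_rows(
                y, table.data[:, 0], max_voxels_per_class_per_volume, rng
            )
            xs.append(table.data[rows])
            ys.append(y[rows])
        else:
            xs.append(table.data)
            ys.append(y)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if np.unique(y).size < 2:
        raise EstimationError("RF training requires both KT and OT voxels in the truth")
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=3,  # sqrt(9) random features per split
        random_state=int(seed) % (2**32),
        n_jobs=1,
    )
    est.fit(x, y)
    logger.info("trained RF: %d trees on %d voxels", n_trees, x.shape[0])
    return ForestModel(estimator=est, n_trees=n_trees, seed=seed)


def predict(model: ForestModel, table: FeatureTable, grid: VoxelGrid) -> ClassifierOutput:
    """Per-voxel KT vote fraction and the thresholded (>= 0.5 -> KT) labels.

    Trees are grown to (near-)pure leaves, so the forest's averaged leaf
    posteriors coincide with the fraction of tree votes for KT.
    """
    require_compatible(table.grid, grid, "prediction")
    proba = model.estimator.predict_proba(table.data)
    kt_col = list(model.estimator.classes_).index(LABEL_KT)
    p_flat = proba[:, kt_col]
    labels_flat = np.where(p_flat >= 0.5, LABEL_KT, LABEL_OT).astype(np.uint8)
    return ClassifierOutput(
        probability=ProbabilityMap(grid=grid, p_kt=_unravel(p_flat, grid)),
        labels=LabelMap(grid=grid, labels=_unravel(labels_flat, grid)),
    )


def postprocess_median(labels: LabelMap, radius: int = 1) -> LabelMap:
    """3D median (binary majority) filter over the (2r+1)^3 cube.

    Windows are clipped at the border; an exact tie goes to OT.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    kt = (labels.labels == LABEL_KT).astype(np.float64)
    size = 2 * radius + 1
    kernel = np.ones((size, size, size))
    votes = ndimage.correlate(kt, kernel, mode="constant", cval=0.0)
    count = ndimage.correlate(np.ones_like(kt), kernel, mode="constant", cval=0.0)
    out = np.where(votes > count / 2.0, LABEL_KT, LABEL_OT).astype(np.uint8)
    return LabelMap(grid=labels.grid, labels=out)
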