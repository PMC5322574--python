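"""Domain containers and NIfTI I/O for 3D CT-like volumes and label maps.

All voxel data live on a 3D arithmetic lattice indexed ``(x, y, z)`` with
0-based indices; arrays are stored with shape ``(X, Y, Z)``. Physical
position of a voxel center is ``origin + index * spacing`` (mm). Labels use
the two-class renal convention: 0 = OT (other/background tissue),
1 = KT (kidney tissue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .errors import FormatError, GridCompatibilityError, LabelDomainError

logger = logging.getLogger("renalseg")

#: integer codes of the two tissue classes on disk and in arrays
LABEL_OT = 0
LABEL_KT = 1

#: relative tolerance under which two spacings count as equal
SPACING_RTOL = 1e-6


class Phase(str, Enum):
    """Contrast-enhancement phase of a dynamic CT acquisition."""

    NONCONTRAST = "noncontrast"
    POSTCONTRAST = "postcontrast"
    LATE = "late"


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of the sampling lattice: dims (X, Y, Z), spacing and origin in mm."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def physical_extent(self) -> tuple[float, float, float]:
        """Edge-to-edge physical size of the lattice in mm."""
        return tuple(d * s for d, s in zip(self.dims, self.spacing))


def validate_compatible(a: VoxelGrid, b: VoxelGrid) -> bool:
    """True iff two grids share dims and spacing within relative tolerance.

    Compatibility is what every multi-volume operation in the package
    requires; origins may differ (co-alignment is the registration module's
    job), only the lattice itself must match.
    """
    if tuple(a.dims) != tuple(b.dims):
        return False
    sa = np.asarray(a.spacing)
    sb = np.asarray(b.spacing)
    return bool(np.all(np.abs(sa - sb) <= SPACING_RTOL * np.maximum(np.abs(sa), np.abs(sb))))


def require_compatible(a: VoxelGrid, b: VoxelGrid, what: str = "volumes") -> None:
    if not validate_compatible(a, b):
        raise GridCompatibilityError(
            f"incompatible grids for {what}: dims {a.dims} vs {b.dims}, "
            f"spacing {a.spacing} vs {b.spacing}"
        )


@dataclass
class IntensityVolume:
    """A 3D grayscale (Hounsfield-like) volume on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != tuple(self.grid.dims):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity values must be finite")


@dataclass
class LabelMap:
    """Per-voxel labels in {OT, KT} on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != tuple(self.grid.dims):
            raise ValueError(
                f"labels shape {self.labels.shape} does not match grid dims {self.grid.dims}"
            )
        uniq = np.unique(self.labels)
        if not np.all(np.isin(uniq, (LABEL_OT, LABEL_KT))):
            raise LabelDomainError(f"label values outside {{0, 1}}: {uniq}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def kt_mask(self) -> np.ndarray:
        return self.labels == LABEL_KT


@dataclass
class ProbabilityMap:
    """Per-voxel probability of the KT label; P(OT) is implicitly 1 - p_kt."""

    grid: VoxelGrid
    p_kt: np.ndarray

    def __post_init__(self) -> None:
        self.p_kt = np.asarray(self.p_kt, dtype=np.float64)
        if self.p_kt.shape != tuple(self.grid.dims):
            raise ValueError(
                f"p_kt shape {self.p_kt.shape} does not match grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.p_kt)):
            raise ValueError("probabilities must be finite")
        if self.p_kt.min() < 0 or self.p_kt.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SubjectRecord:
    """One scan of one subject at one contrast phase, with optional truth."""

    subject_id: str
    phase: Phase
    volume: IntensityVolume
    truth: Optional[LabelMap] = None

    def __post_init__(self) -> None:
        self.phase = Phase(self.phase)
        if self.truth is not None:
            require_compatible(self.volume.grid, self.truth.grid, "volume/truth pair")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _affine_from_grid(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_image(img: nib.Nifti1Image, path: Path) -> VoxelGrid:
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got {img.ndim}D shape {img.shape}")
    try:
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # pragma: no cover - corrupt headers are rare
        raise FormatError(f"{path}: unreadable header field 'pixdim' ({exc})") from exc
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path}: invalid voxel spacing (pixdim) {zooms}")
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return VoxelGrid(dims=tuple(int(d) for d in img.shape), spacing=tuple(map(float, zooms)), origin=origin)


def read_volume(path) -> IntensityVolume:
    """Read a 3D NIfTI grayscale volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    grid = _grid_from_image(img, path)
    values = np.asanyarray(img.dataobj)
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: volume contains non-finite values")
    return IntensityVolume(grid=grid, values=np.asarray(values))


def write_volume(volume: IntensityVolume, path) -> Path:
    """Write an :class:`IntensityVolume` as NIfTI; round-trips geometry and values."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.values), _affine_from_grid(volume.grid))
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, str(path))
    return path


def read_labelmap(path) -> LabelMap:
    """Read a NIfTI label map; stored values must be exactly 0 (OT) or 1 (KT)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    grid = _grid_from_image(img, path)
    values = np.asanyarray(img.dataobj)
    uniq = np.unique(values)
    if not np.all(np.isin(uniq, (0, 1))):
        raise LabelDomainError(f"{path}: stored label values {uniq} outside {{0, 1}}")
    return LabelMap(grid=grid, labels=values.astype(np.uint8))


def write_labelmap(labelmap: LabelMap, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(labelmap.labels.astype(np.uint8), _affine_from_grid(labelmap.grid))
    img.header.set_zooms(labelmap.grid.spacing)
    nib.save(img, str(path))
    return path
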