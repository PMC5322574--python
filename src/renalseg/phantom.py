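"""Seeded synthetic dynamic-CT kidney phantoms with ground-truth labels.

The generator emulates the data regime the segmentation framework targets:
per subject, three 3D scans at different contrast phases (noncontrast,
postcontrast, late) sharing one anatomy, on an anisotropic lattice
(default 0.64 x 0.64 x 0.9 mm). The kidney is a bean shape — an ellipsoid
with a spherical hilum notch — containing brighter/darker medullary lobes;
scans carry a smooth multiplicative bias field (intensity inhomogeneity),
additive Gaussian noise (low contrast), and optional distractor organs with
intensities near the kidney's (adjacent-organ confusion). Subjects differ
by a smooth random deformation plus a small affine jitter of the canonical
anatomy, which gives the registration stage real work.

Everything is a pure function of ``(spec, seeds)``: identical inputs yield
bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .core import IntensityVolume, LabelMap, Phase, SubjectRecord, VoxelGrid
from .errors import PhantomSpecError

#: default per-phase (background, medulla, cortex) class means, HU-like.
#: noncontrast: weak kidney/background separation; postcontrast: strong
#: cortical enhancement with cortex >> medulla; late: intermediate, medulla
#: partially enhanced.
DEFAULT_CLASS_MEANS: dict[Phase, tuple[float, float, float]] = {
    Phase.NONCONTRAST: (40.0, 55.0, 65.0),
    Phase.POSTCONTRAST: (45.0, 110.0, 190.0),
    Phase.LATE: (45.0, 120.0, 140.0),
}

_REGION_BG, _REGION_CORTEX, _REGION_MEDULLA, _REGION_DISTRACTOR = 0, 1, 2, 3


def phase_contrast_profile(phase: Phase) -> tuple[float, float, float]:
    """Default (background, medulla, cortex) intensity means for a phase."""
    return DEFAULT_CLASS_MEANS[Phase(phase)]


@dataclass(frozen=True)
class PhantomSpec:
    """All knobs of the synthetic cohort; defaults define moderate difficulty."""

    dims: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.64, 0.64, 0.9)
    kidney_half_axes: tuple[float, float, float] = (11.0, 8.0, 17.0)  # mm
    concavity_depth: float = 0.3  # hilum notch radius as a fraction of 2a
    class_means: Mapping[Phase, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEANS)
    )
    noise_sd: float = 8.0
    bias_amplitude: float = 0.15
    distractor_count: int = 2
    deformation_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.concavity_depth <= 0.5):
            raise PhantomSpecError("concavity_depth must lie in [0, 0.5]")
        if self.noise_sd < 0 or self.bias_amplitude < 0 or self.deformation_mm < 0:
            raise PhantomSpecError("noise, bias and deformation magnitudes must be >= 0")
        if self.distractor_count < 0:
            raise PhantomSpecError("distractor_count must be >= 0")
        grid = self.grid
        half_extent = np.asarray(grid.physical_extent()) / 2.0
        margin = 2.0 * np.asarray(self.spacing)
        if np.any(np.asarray(self.kidney_half_axes) + margin >= half_extent):
            raise PhantomSpecError(
                f"kidney half-axes {self.kidney_half_axes} mm do not fit inside the "
                f"grid extent {grid.physical_extent()} mm with a 2-voxel margin"
            )
        for ph in Phase:
            means = self.class_means[ph]
            if len(means) != 3 or not np.all(np.isfinite(means)):
                raise PhantomSpecError(f"invalid class means for phase {ph.value}")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(dims=self.dims, spacing=self.spacing)


@dataclass
class PhantomSubject:
    """Three contrast-phase scans of one synthetic subject, one shared truth."""

    subject_id: str
    records: dict[Phase, SubjectRecord]

    def __post_init__(self) -> None:
        if set(self.records) != set(Phase):
            raise ValueError("a phantom subject needs all three contrast phases")

    @property
    def truth(self) -> LabelMap:
        return self.records[Phase.POSTCONTRAST].truth


def _centered_coords(grid: VoxelGrid) -> np.ndarray:
    """Physical mm coordinates relative to the grid center, shape (3, X, Y, Z)."""
    axes = [
        (np.arange(d) - (d - 1) / 2.0) * s for d, s in zip(grid.dims, grid.spacing)
    ]
    return np.stack(np.meshgrid(*axes, indexing="ij"))


def _smooth_displacement(
    rng: np.random.Generator, dims: tuple[int, int, int], magnitude_mm: float
) -> np.ndarray:
    """Random smooth (B-spline-style) mm displacement field, shape (3, X, Y, Z)."""
    coarse = rng.normal(0.0, magnitude_mm / 2.0, size=(3, 5, 5, 5))
    if magnitude_mm == 0.0:
        return np.zeros((3,) + tuple(dims))
    zoom = [1.0] + [d / 5.0 for d in dims]
    return ndimage.zoom(coarse, zoom, order=3, mode="nearest")


def _jitter_affine(rng: np.random.Generator, deformation_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Small random rotation+scale matrix and mm translation, scaled with
    the inter-subject deformation magnitude (zero magnitude -> identity)."""
    scale_of = deformation_mm / 3.0
    angles = rng.normal(0.0, np.deg2rad(3.0) * scale_of, size=3)
    scales = 1.0 + rng.normal(0.0, 0.03 * scale_of, size=3)
    translation = rng.normal(0.0, deformation_mm / 2.0, size=3) if deformation_mm else np.zeros(3)
    cx, sx = np.cos(angles[0]), np.sin(angles[0])
    cy, sy = np.cos(angles[1]), np.sin(angles[1])
    cz, sz = np.cos(angles[2]), np.sin(angles[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rx @ ry @ rz @ np.diag(scales), translation


def _ellipsoid(q: np.ndarray, center: np.ndarray, half_axes: np.ndarray) -> np.ndarray:
    d = (q - center.reshape(3, 1, 1, 1)) / half_axes.reshape(3, 1, 1, 1)
    return (d**2).sum(axis=0) <= 1.0


def _region_map(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-voxel anatomical region id after subject-specific warping."""
    grid = spec.grid
    coords = _centered_coords(grid)
    mat, trans = _jitter_affine(rng, spec.deformation_mm)
    disp = _smooth_displacement(rng, grid.dims, spec.deformation_mm)
    # evaluate canonical shapes at warped coordinates (inverse-warp rendering)
    q = np.einsum("ij,jxyz->ixyz", mat, coords) + trans.reshape(3, 1, 1, 1) + disp

    a, b, c = spec.kidney_half_axes
    axes = np.asarray(spec.kidney_half_axes)
    kidney = _ellipsoid(q, np.zeros(3), axes)
    if spec.concavity_depth > 0:
        notch_r = spec.concavity_depth * 2.0 * a
        notch_center = np.array([a, 0.0, 0.0])
        d = q - notch_center.reshape(3, 1, 1, 1)
        kidney &= (d**2).sum(axis=0) > notch_r**2

    medulla = np.zeros_like(kidney)
    lobe_axes = np.array([0.40 * a, 0.40 * b, 0.22 * c])
    for zc in (-0.45 * c, 0.0, 0.45 * c):
        medulla |= _ellipsoid(q, np.array([-0.15 * a, 0.0, zc]), lobe_axes)
    medulla &= kidney

    region = np.zeros(grid.dims, dtype=np.uint8)
    region[kidney] = _REGION_CORTEX
    region[medulla] = _REGION_MEDULLA

    half_extent = np.asarray(grid.physical_extent()) / 2.0
    dist_axes = np.array([5.0, 5.0, 7.0])
    for _ in range(spec.distractor_count):
        signs = rng.choice((-1.0, 1.0), size=3)
        frac = rng.uniform(0.55, 0.75, size=3)
        center = signs * frac * np.maximum(half_extent - dist_axes, 0.0)
        blob = _ellipsoid(coords, center, dist_axes)
        region[blob & (region == _REGION_BG)] = _REGION_DISTRACTOR

    if not (region == _REGION_CORTEX).any():
        raise PhantomSpecError("warped kidney left the grid; reduce deformation or axes")
    return region


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * B(u), max |B| = 1."""
    grid = spec.grid
    u = []
    for axis, d in enumerate(grid.dims):
        shape = [1, 1, 1]
        shape[axis] = d
        u.append(np.linspace(-1.0, 1.0, d).reshape(shape))
    terms = [u[0], u[1], u[2], u[0] * u[1], u[0] * u[2], u[1] * u[2], u[0] ** 2, u[1] ** 2, u[2] ** 2]
    coefs = rng.normal(0.0, 1.0, size=len(terms))
    b = sum(c * t for c, t in zip(coefs, terms))
    b = np.broadcast_to(b, grid.dims).astype(float)
    peak = np.abs(b).max()
    if peak > 0:
        b = b / peak
    return 1.0 + spec.bias_amplitude * b


def _render_phase(
    spec: PhantomSpec, region: np.ndarray, phase: Phase, rng: np.random.Generator
) -> np.ndarray:
    bg, medulla, cortex = spec.class_means[phase]
    distractor = 0.95 * cortex  # adjacent organ with near-kidney intensity
    means = np.array([bg, cortex, medulla, distractor])
    img = means[region]
    bias = _bias_field(spec, rng)
    noise = rng.normal(0.0, 1.0, size=region.shape)
    return img * bias + spec.noise_sd * noise


def generate_subject(spec: PhantomSpec, subject_seed: int) -> PhantomSubject:
    """One synthetic subject: warped anatomy rendered at the three phases."""
    rng = np.random.default_rng([int(spec.seed), int(subject_seed)])
    region = _region_map(spec, rng)
    truth = LabelMap(
        grid=spec.grid,
        labels=np.isin(region, (_REGION_CORTEX, _REGION_MEDULLA)).astype(np.uint8),
    )
    records: dict[Phase, SubjectRecord] = {}
    for phase in Phase:  # fixed enum order keeps draws deterministic
        values = _render_phase(spec, region, phase, rng)
        records[phase] = SubjectRecord(
            subject_id=f"s{subject_seed}",
            phase=phase,
            volume=IntensityVolume(grid=spec.grid, values=values),
            truth=truth,
        )
    return PhantomSubject(subject_id=f"s{subject_seed}", records=records)


def generate_cohort(
    spec: PhantomSpec, n_subjects: int, master_seed: int
) -> list[PhantomSubject]:
    """A reproducible multi-subject cohort (3 scans per subject)."""
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects (leave-one-out folds)")
    seeds = np.random.SeedSequence(master_seed).generate_state(n_subjects)
    subjects = []
    for i, s in enumerate(seeds):
        subject = generate_subject(spec, int(s))
        subject.subject_id = f"sub{i:02d}"
        for rec in subject.records.values():
            rec.subject_id = subject.subject_id
        subjects.append(subject)
    return subjects
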