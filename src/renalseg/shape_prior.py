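"""Atlas ranking by normalized cross correlation and the adaptive shape prior.

The shape prior is appearance-conditioned: at each test voxel p, every
selected co-aligned atlas image i contributes the atlas voxels rho inside a
search cube C_p around p whose intensity matches the test voxel within a
fixed signal range tau, ``|g_{i:rho} - g_{t:p}| <= tau``. The prior
probability of kidney at p is the fraction of those matched voxels whose
atlas label is KT:

    ``P_s:p(KT) = (1 / v_p) * sum_i sum_{rho in v_{i:p}} delta(KT - m_{i:rho})``

with ``v_p`` the total matched count pooled over the selected atlases.
When no atlas voxel matches at the initial cube size the cube grows
progressively (keeping the prior as local as possible); if nothing matches
even at the maximum size the prior falls back to the uninformative 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    LABEL_KT,
    IntensityVolume,
    LabelMap,
    Phase,
    ProbabilityMap,
    VoxelGrid,
    require_compatible,
)
from .errors import CohortSizeError, ConstantVolumeError

logger = logging.getLogger("renalseg")


@dataclass
class AtlasEntry:
    """One co-aligned grayscale scan with its co-aligned label map."""

    subject_id: str
    phase: Phase
    volume: IntensityVolume
    labelmap: LabelMap

    def __post_init__(self) -> None:
        self.phase = Phase(self.phase)
        require_compatible(self.volume.grid, self.labelmap.grid, "atlas entry")

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.phase.value)


@dataclass
class AtlasDatabase:
    """Co-aligned training scans sharing one grid (the atlas space)."""

    entries: list[AtlasEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("atlas database must contain at least one entry")
        ref = self.entries[0].volume.grid
        for e in self.entries[1:]:
            require_compatible(ref, e.volume.grid, "atlas database")

    @property
    def grid(self) -> VoxelGrid:
        return self.entries[0].volume.grid

    def without_subject(self, subject_id: str) -> "AtlasDatabase":
        kept = [e for e in self.entries if e.subject_id != subject_id]
        if not kept:
            raise CohortSizeError(f"excluding subject {subject_id!r} empties the atlas")
        return AtlasDatabase(entries=kept)

    def without_entry(self, subject_id: str, phase: Phase) -> "AtlasDatabase":
        phase = Phase(phase)
        kept = [e for e in self.entries if e.key != (subject_id, phase.value)]
        if not kept:
            raise CohortSizeError("excluding that entry empties the atlas")
        return AtlasDatabase(entries=kept)


@dataclass(frozen=True)
class ShapePriorParams:
    """Tunables of the adaptive prior: signal range tau and cube growth bounds."""

    tau: float = 50.0
    initial_half_width: int = 1
    max_half_width: int = 5

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if not (1 <= self.initial_half_width <= self.max_half_width):
            raise ValueError("need 1 <= initial_half_width <= max_half_width")


def ncc(a: IntensityVolume, b: IntensityVolume) -> float:
    """Pearson-type normalized cross correlation over all voxels, in [-1, 1]."""
    require_compatible(a.grid, b.grid, "NCC")
    x = np.asarray(a.values, dtype=float).ravel()
    y = np.asarray(b.values, dtype=float).ravel()
    x = x - x.mean()
    y = y - y.mean()
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ConstantVolumeError("NCC undefined for a constant volume")
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


def select_top(
    test: IntensityVolume,
    db: AtlasDatabase,
    n: int,
    exclude_subject: str | None = None,
) -> list[AtlasEntry]:
    """The n atlas entries most NCC-similar to the test volume, descending.

    All entries of ``exclude_subject`` are removed first (leave-one-subject-out
    hygiene). Ties break deterministically by (subject_id, phase).
    """
    candidates = [
        e for e in db.entries if exclude_subject is None or e.subject_id != exclude_subject
    ]
    if len(candidates) < n:
        raise CohortSizeError(
            f"requested top {n} atlas scans but only {len(candidates)} candidates remain"
        )
    scored = [(-ncc(test, e.volume), e.subject_id, e.phase.value, e) for e in candidates]
    scored.sort(key=lambda t: t[:3])
    top = [t[3] for t in scored[:n]]
    logger.info(
        "atlas selection: top %d of %d candidates, best NCC %.4f",
        n,
        len(candidates),
        -scored[0][0],
    )
    return top


def _cube_offsets(half_width: int) -> list[tuple[int, int, int]]:
    """All offsets with Chebyshev norm <= half_width (cube, center included)."""
    r = range(-half_width, half_width + 1)
    return [(dx, dy, dz) for dx in r for dy in r for dz in r]


def _shell_offsets(half_width: int) -> list[tuple[int, int, int]]:
    """Offsets with Chebyshev norm exactly half_width (a cube shell)."""
    return [o for o in _cube_offsets(half_width) if max(abs(c) for c in o) == half_width]


def _accumulate_offset(
    g_test: np.ndarray,
    g_stack: np.ndarray,
    kt_stack: np.ndarray,
    offset: tuple[int, int, int],
    tau: np.float32,
    tot: np.ndarray,
    kt: np.ndarray,
) -> None:
    """Add one search-cube offset's matched/KT counts into the accumulators.

    A voxel p gathers atlas voxel p + offset in every stacked atlas image;
    out-of-volume positions never match (the cube is clipped to the lattice).
    """
    dims = g_test.shape
    src = []
    dst = []
    for axis in range(3):
        o = offset[axis]
        lo_dst, hi_dst = max(0, -o), dims[axis] - max(0, o)
        if hi_dst <= lo_dst:
            return
        src.append(slice(lo_dst + o, hi_dst + o))
        dst.append(slice(lo_dst, hi_dst))
    src, dst = tuple(src), tuple(dst)
    match = np.abs(g_stack[(slice(None),) + src] - g_test[dst]) <= tau
    tot[dst] += match.sum(axis=0, dtype=np.int32)
    kt[dst] += (match & kt_stack[(slice(None),) + src]).sum(axis=0, dtype=np.int32)


def compute_shape_prior(
    test: IntensityVolume,
    selected: list[AtlasEntry],
    params: ShapePriorParams = ShapePriorParams(),
) -> ProbabilityMap:
    """Adaptive appearance-conditioned shape prior P_s(KT) over the lattice.

    Implements the matched-voxel counting described in the module docstring.
    The initial cube is evaluated for all voxels at once; the (typically
    few) voxels with no match grow their cube individually up to the maximum
    half-width before the 0.5 fallback applies. All selected entries
    contribute with equal weight.
    """
    if not selected:
        raise ValueError("at least one selected atlas entry is required")
    for e in selected:
        require_compatible(test.grid, e.volume.grid, "shape prior")
    g_test = np.asarray(test.values, dtype=np.float32)
    g_stack = np.stack([np.asarray(e.volume.values, dtype=np.float32) for e in selected])
    kt_stack = np.stack([e.labelmap.labels == LABEL_KT for e in selected])
    tau = np.float32(params.tau)

    dims = tuple(test.grid.dims)
    tot = np.zeros(dims, dtype=np.int32)
    kt = np.zeros(dims, dtype=np.int32)
    for off in _cube_offsets(params.initial_half_width):
        _accumulate_offset(g_test, g_stack, kt_stack, off, tau, tot, kt)

    p = np.full(dims, 0.5)
    matched = tot > 0
    p[matched] = kt[matched] / tot[matched]

    unresolved = np.argwhere(~matched)
    n_fallback = 0
    for x, y, z in unresolved:
        value = None
        for hw in range(params.initial_half_width + 1, params.max_half_width + 1):
            cube = tuple(
                slice(max(0, c - hw), min(d, c + hw + 1))
                for c, d in zip((x, y, z), dims)
            )
            m = np.abs(g_stack[(slice(None),) + cube] - g_test[x, y, z]) <= tau
            v_p = int(m.sum())
            if v_p > 0:
                value = int((m & kt_stack[(slice(None),) + cube]).sum()) / v_p
                break
        if value is None:
            n_fallback += 1
            value = 0.5
        p[x, y, z] = value

    if n_fallback:
        logger.info("shape prior: %d voxels fell back to P=0.5 (no matches)", n_fallback)
    return ProbabilityMap(grid=test.grid, p_kt=p)
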