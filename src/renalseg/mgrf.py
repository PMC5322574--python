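"""Higher-order Markov-Gibbs spatial model with analytic Potts potentials.

Label interactions on the 3D lattice are modeled by a Potts-type
Markov-Gibbs random field whose clique system extends the traditional
pairwise families with triple and quad families, all built from
18-connectivity steps (6 face + 12 edge neighbors):

* pairwise — one family per unique 18-neighborhood direction (9 families);
* triple   — collinear ``{p - d, p, p + d}`` per direction (9 families);
* quad     — unit 2x2 squares in each axis-aligned plane (3 families).

Each family ``a`` of order ``n`` carries one scalar potential ``V_a``
contributing ``+V_a`` to a configuration's energy when all clique labels
coincide and ``-V_a`` otherwise. For the two-label case (K = 2) the
analytic maximum-likelihood estimate of the pairwise Potts potential,

    ``V_a = K^2/(K - 1) * (f_eq(a) - K^(1 - n))``,

centers the empirical all-equal clique rate ``f_eq`` at its expectation
under independent uniform labels and is applied uniformly to all three
orders. Potentials are estimated per volume from an initial shape-and-
intensity labeling (self-calibration), and a single sweep of Gibbs
conditional probabilities turns that labeling into the per-voxel spatial
feature ``P_G(KT)``. Cliques extending beyond the lattice are skipped
(free boundary) in both estimation and the conditionals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .core import (
    LABEL_KT,
    LABEL_OT,
    IntensityVolume,
    LabelMap,
    ProbabilityMap,
    require_compatible,
)
from .errors import EstimationError
from .shape_prior import AtlasDatabase

#: number of labels in L = {KT, OT}
K_LABELS = 2

#: the 9 unique directions of the 18-connectivity neighborhood
#: (3 axis-aligned + 6 edge diagonals; each direction covers itself and
#: its negation, 9 * 2 = 18 neighbors)
DIRECTIONS_18: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
)


@dataclass(frozen=True)
class CliqueFamily:
    """All lattice translations of one fixed voxel-offset pattern."""

    name: str
    order: int
    offsets: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.order not in (2, 3, 4):
            raise ValueError("clique order must be 2, 3 or 4")
        if len(set(self.offsets)) != self.order:
            raise ValueError("offsets must contain exactly `order` distinct elements")


@dataclass
class PottsModel:
    """One scalar potential per clique family (the +V/-V equal/unequal form)."""

    families: list[CliqueFamily]
    potentials: np.ndarray  # shape (len(families),)

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        if self.potentials.shape != (len(self.families),):
            raise ValueError("one potential per family required")
        if not np.all(np.isfinite(self.potentials)):
            raise ValueError("potentials must be finite")

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(v) for f, v in zip(self.families, self.potentials)}


@dataclass
class IntensityClassModel:
    """Per-label Gaussian intensity model (mean, sd) for KT and OT."""

    mean_kt: float
    sd_kt: float
    mean_ot: float
    sd_ot: float

    def __post_init__(self) -> None:
        if self.sd_kt <= 0 or self.sd_ot <= 0:
            raise ValueError("standard deviations must be positive")


def build_families() -> list[CliqueFamily]:
    """The 21 clique families: 9 pairwise, 9 collinear triple, 3 planar quad."""
    families: list[CliqueFamily] = []
    for d in DIRECTIONS_18:
        families.append(CliqueFamily(name=f"pair{d}", order=2, offsets=((0, 0, 0), d)))
    for d in DIRECTIONS_18:
        neg = tuple(-c for c in d)
        families.append(CliqueFamily(name=f"triple{d}", order=3, offsets=(neg, (0, 0, 0), d)))
    plane_axes = (("xy", (1, 0, 0), (0, 1, 0)), ("xz", (1, 0, 0), (0, 0, 1)), ("yz", (0, 1, 0), (0, 0, 1)))
    for name, e1, e2 in plane_axes:
        both = tuple(a + b for a, b in zip(e1, e2))
        families.append(CliqueFamily(name=f"quad_{name}", order=4, offsets=((0, 0, 0), e1, e2, both)))
    return families


def estimate_intensity_model(atlas: AtlasDatabase, sd_floor: float = 1e-3) -> IntensityClassModel:
    """Pooled per-label intensity mean/sd over all atlas voxels.

    Degenerate (constant) classes get their sd clamped to ``sd_floor``.
    """
    kt_vals: list[np.ndarray] = []
    ot_vals: list[np.ndarray] = []
    for entry in atlas.entries:
        mask = entry.labelmap.kt_mask
        kt_vals.append(np.asarray(entry.volume.values)[mask])
        ot_vals.append(np.asarray(entry.volume.values)[~mask])
    kt = np.concatenate(kt_vals) if kt_vals else np.empty(0)
    ot = np.concatenate(ot_vals) if ot_vals else np.empty(0)
    if kt.size == 0 or ot.size == 0:
        raise EstimationError("both labels must be present in the atlas to fit intensities")
    return IntensityClassModel(
        mean_kt=float(kt.mean()),
        sd_kt=max(float(kt.std()), sd_floor),
        mean_ot=float(ot.mean()),
        sd_ot=max(float(ot.std()), sd_floor),
    )


def _log_gaussian(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return -0.5 * ((values - mean) / sd) ** 2 - np.log(sd)


def initial_labeling(
    volume: IntensityVolume, prior: ProbabilityMap, model: IntensityClassModel
) -> LabelMap:
    """Voxel-wise MAP labeling from shape prior x Gaussian intensity likelihood.

    ``m0_p = argmax_l P_s:p(l) * N(g_p; mu_l, sd_l)``; ties go to OT.
    """
    require_compatible(volume.grid, prior.grid, "initial labeling")
    g = np.asarray(volume.values, dtype=float)
    p_kt = prior.p_kt
    with np.errstate(divide="ignore"):
        score_kt = np.log(p_kt) + _log_gaussian(g, model.mean_kt, model.sd_kt)
        score_ot = np.log(1.0 - p_kt) + _log_gaussian(g, model.mean_ot, model.sd_ot)
    labels = np.where(score_kt > score_ot, LABEL_KT, LABEL_OT).astype(np.uint8)
    return LabelMap(grid=volume.grid, labels=labels)


def _clique_windows(dims: tuple[int, int, int], offsets) -> list[tuple[slice, slice, slice]] | None:
    """Per-offset slices selecting each member over all in-volume translates.

    Returns None when no clique translate fits inside the volume.
    """
    offs = np.asarray(offsets)
    lo = offs.min(axis=0)
    hi = offs.max(axis=0)
    starts = np.maximum(0, -lo)
    stops = np.asarray(dims) - np.maximum(0, hi)
    if np.any(stops <= starts):
        return None
    return [
        tuple(slice(int(starts[a] + o[a]), int(stops[a] + o[a])) for a in range(3))
        for o in offs
    ]


def equality_rate(m: LabelMap, family: CliqueFamily) -> float:
    """Fraction of fully-inside clique translates whose labels all coincide."""
    windows = _clique_windows(m.grid.dims, family.offsets)
    if windows is None:
        raise EstimationError(
            f"volume {m.grid.dims} cannot contain a single {family.name} clique"
        )
    lab = m.labels
    first = lab[windows[0]]
    equal = np.ones(first.shape, dtype=bool)
    for w in windows[1:]:
        equal &= lab[w] == first
    return float(equal.mean())


def estimate_potentials(m: LabelMap, families: list[CliqueFamily] | None = None) -> PottsModel:
    """Analytic Potts potential per family from the empirical equality rate.

    ``V_a = K^2/(K-1) * (f_eq - K^(1-n))`` with K = 2: a constant map gives
    V = 2 for pairwise families, independent fair labels give V ~ 0.
    """
    if families is None:
        families = build_families()
    k = K_LABELS
    scale = k * k / (k - 1)
    pots = np.array(
        [scale * (equality_rate(m, f) - k ** (1 - f.order)) for f in families]
    )
    return PottsModel(families=families, potentials=pots)


def gibbs_probability(m: LabelMap, model: PottsModel) -> ProbabilityMap:
    """One sweep of Gibbs conditionals: P_G:p(KT) given the neighbors under m.

    For each voxel p and candidate label l the energy sums +/-V_a over every
    clique containing p (all other members keeping their labels under m):
    +V_a when all clique labels would coincide, -V_a otherwise. The
    conditional is the two-label softmax of the energies.
    """
    dims = m.grid.dims
    lab = m.labels
    e_kt = np.zeros(dims, dtype=float)
    e_ot = np.zeros(dims, dtype=float)
    for fam, v in zip(model.families, model.potentials):
        offs = [np.asarray(o) for o in fam.offsets]
        # role j: voxel p occupies member j; other members sit at offsets o_k - o_j
        for j in range(fam.order):
            rel = [offs[k] - offs[j] for k in range(fam.order) if k != j]
            windows = _clique_windows(dims, [(0, 0, 0)] + [tuple(r) for r in rel])
            if windows is None:
                continue
            center_w = windows[0]
            others_kt = np.ones(lab[center_w].shape, dtype=bool)
            others_ot = np.ones_like(others_kt)
            for w in windows[1:]:
                others_kt &= lab[w] == LABEL_KT
                others_ot &= lab[w] == LABEL_OT
            # all-equal indicator maps to +V, else -V: V * (2*ind - 1)
            e_kt[center_w] += v * (2.0 * others_kt - 1.0)
            e_ot[center_w] += v * (2.0 * others_ot - 1.0)
    return ProbabilityMap(grid=m.grid, p_kt=expit(e_kt - e_ot))


def spatial_probability(
    volume: IntensityVolume,
    prior: ProbabilityMap,
    intensity_model: IntensityClassModel,
    families: list[CliqueFamily] | None = None,
) -> tuple[ProbabilityMap, PottsModel, LabelMap]:
    """Full spatial-feature stage: initial labeling -> potentials -> P_G."""
    m0 = initial_labeling(volume, prior, intensity_model)
    potts = estimate_potentials(m0, families)
    return gibbs_probability(m0, potts), potts, m0
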