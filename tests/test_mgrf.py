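"""Higher-order Potts model: clique families, analytic potentials, Gibbs sweep."""

import itertools

import numpy as np
import pytest

from renalseg import (
    AtlasDatabase,
    AtlasEntry,
    IntensityVolume,
    LabelMap,
    Phase,
    ProbabilityMap,
    VoxelGrid,
    build_families,
    equality_rate,
    estimate_intensity_model,
    estimate_potentials,
    gibbs_probability,
    initial_labeling,
)
from renalseg.errors import EstimationError
from renalseg.mgrf import DIRECTIONS_18, IntensityClassModel, PottsModel


def make_map(labels, spacing=(1.0, 1.0, 1.0)):
    labels = np.asarray(labels, dtype=np.uint8)
    return LabelMap(grid=VoxelGrid(dims=labels.shape, spacing=spacing), labels=labels)


def checkerboard(dims):
    return np.indices(dims).sum(axis=0) % 2


def gibbs_brute_force(m, model):
    """Per-voxel enumeration of every clique containing p, both hypotheses."""
    dims = m.grid.dims
    lab = m.labels.astype(int)
    out = np.zeros(dims)
    for x, y, z in itertools.product(*[range(d) for d in dims]):
        energy = {0: 0.0, 1: 0.0}
        for fam, v in zip(model.families, model.potentials):
            offs = fam.offsets
            for role in range(fam.order):
                members = [
                    (x + o[0] - offs[role][0], y + o[1] - offs[role][1], z + o[2] - offs[role][2])
                    for o in offs
                ]
                if any(
                    not (0 <= px < dims[0] and 0 <= py < dims[1] and 0 <= pz < dims[2])
                    for px, py, pz in members
                ):
                    continue
                others = [lab[q] for q in members if q != (x, y, z)]
                for candidate in (0, 1):
                    all_equal = all(o == candidate for o in others)
                    energy[candidate] += v if all_equal else -v
        out[x, y, z] = np.exp(energy[1]) / (np.exp(energy[1]) + np.exp(energy[0]))
    return out


class TestFamilies:
    def test_family_counts(self):
        fams = build_families()
        assert sum(f.order == 2 for f in fams) == 9
        assert sum(f.order == 3 for f in fams) == 9
        assert sum(f.order == 4 for f in fams) == 3

    def test_pairwise_covers_18_neighborhood(self):
        signed = {d for d in DIRECTIONS_18} | {tuple(-c for c in d) for d in DIRECTIONS_18}
        assert len(signed) == 18
        assert all(max(abs(c) for c in d) == 1 for d in signed)

    def test_triple_steps_are_18_connectivity(self):
        for fam in build_families():
            if fam.order != 3:
                continue
            steps = [
                tuple(b - a for a, b in zip(fam.offsets[i], fam.offsets[i + 1]))
                for i in range(2)
            ]
            for s in steps:
                assert max(abs(c) for c in s) == 1 and sum(abs(c) for c in s) <= 2

    def test_quads_have_four_members(self):
        assert all(len(f.offsets) == 4 for f in build_families() if f.order == 4)


class TestEqualityRate:
    def test_constant_map_is_one_for_every_family(self):
        m = make_map(np.ones((6, 6, 6)))
        assert all(equality_rate(m, f) == 1.0 for f in build_families())

    def test_checkerboard_axis_pairwise_is_zero(self):
        m = make_map(checkerboard((8, 8, 8)))
        axis_pair = build_families()[0]  # direction (1, 0, 0)
        assert equality_rate(m, axis_pair) == 0.0

    def test_iid_fair_labels_match_closed_form(self):
        rng = np.random.default_rng(0)
        m = make_map(rng.random((32, 32, 32)) < 0.5)
        for fam in build_families():
            assert equality_rate(m, fam) == pytest.approx(2.0 ** (1 - fam.order), abs=0.02)

    def test_brute_force_count_on_checkerboard(self):
        """Exhaustive clique enumeration on an 8^3 checkerboard."""
        dims = (8, 8, 8)
        m = make_map(checkerboard(dims))
        fam = build_families()[0]  # pair, direction (1, 0, 0)
        equal = total = 0
        for x, y, z in itertools.product(range(7), range(8), range(8)):
            total += 1
            equal += int(m.labels[x, y, z] == m.labels[x + 1, y, z])
        assert equality_rate(m, fam) == equal / total == 0.0


class TestPotentials:
    def test_constant_map_pairwise_potential_is_two(self):
        model = estimate_potentials(make_map(np.ones((6, 6, 6))))
        pairwise = [v for f, v in zip(model.families, model.potentials) if f.order == 2]
        assert all(v == pytest.approx(2.0) for v in pairwise)

    def test_checkerboard_axis_pairwise_potential_is_minus_two(self):
        model = estimate_potentials(make_map(checkerboard((8, 8, 8))))
        assert model.potentials[0] == pytest.approx(-2.0)

    def test_iid_fair_labels_give_near_zero_potentials(self):
        rng = np.random.default_rng(1)
        model = estimate_potentials(make_map(rng.random((32, 32, 32)) < 0.5))
        assert np.abs(model.potentials).max() < 0.05

    def test_label_flip_invariance(self):
        rng = np.random.default_rng(2)
        labels = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
        a = estimate_potentials(make_map(labels))
        b = estimate_potentials(make_map(1 - labels))
        assert np.allclose(a.potentials, b.potentials)


class TestGibbsProbability:
    def test_zero_potentials_give_half_everywhere(self):
        m = make_map(np.ones((5, 5, 5)))
        model = PottsModel(families=build_families(), potentials=np.zeros(21))
        pg = gibbs_probability(m, model)
        assert np.all(pg.p_kt == 0.5)

    def test_constant_kt_interior_supports_kt(self):
        m = make_map(np.ones((7, 7, 7)))
        model = estimate_potentials(m)
        pg = gibbs_probability(m, model)
        assert pg.p_kt[3, 3, 3] > 0.5

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        m = make_map(rng.random((5, 5, 5)) < 0.4)
        model = estimate_potentials(make_map(rng.random((8, 8, 8)) < 0.4))
        fast = gibbs_probability(m, model)
        slow = gibbs_brute_force(m, model)
        assert np.allclose(fast.p_kt, slow, atol=1e-12)

    def test_normalization(self):
        rng = np.random.default_rng(4)
        m = make_map(rng.random((6, 6, 6)) < 0.5)
        pg = gibbs_probability(m, estimate_potentials(m))
        assert np.all((pg.p_kt >= 0) & (pg.p_kt <= 1))

    def test_label_flip_antisymmetry(self):
        """P_G(assigned label) is invariant under relabeling KT <-> OT."""
        rng = np.random.default_rng(5)
        labels = (rng.random((6, 6, 6)) < 0.4).astype(np.uint8)
        m = make_map(labels)
        m_flip = make_map(1 - labels)
        pg = gibbs_probability(m, estimate_potentials(m))
        pg_flip = gibbs_probability(m_flip, estimate_potentials(m_flip))
        p_assigned = np.where(labels == 1, pg.p_kt, 1 - pg.p_kt)
        p_assigned_flip = np.where(1 - labels == 1, pg_flip.p_kt, 1 - pg_flip.p_kt)
        assert np.allclose(p_assigned, p_assigned_flip)


class TestIntensityModelAndInitialLabeling:
    def entry_from(self, values, labels):
        v = IntensityVolume(grid=VoxelGrid(dims=values.shape, spacing=(1, 1, 1)), values=values)
        m = LabelMap(grid=v.grid, labels=labels.astype(np.uint8))
        return AtlasEntry(subject_id="a", phase=Phase.LATE, volume=v, labelmap=m)

    def test_recovers_known_class_means(self):
        rng = np.random.default_rng(6)
        labels = rng.random((10, 10, 10)) < 0.5
        values = np.where(labels, rng.normal(100, 5, labels.shape), rng.normal(20, 5, labels.shape))
        model = estimate_intensity_model(AtlasDatabase(entries=[self.entry_from(values, labels)]))
        assert model.mean_kt == pytest.approx(100, abs=1.5)
        assert model.mean_ot == pytest.approx(20, abs=1.5)

    def test_degenerate_class_sd_clamped(self):
        labels = np.zeros((4, 4, 4), bool)
        labels[:2] = True
        values = np.where(labels, 100.0, 20.0)
        model = estimate_intensity_model(AtlasDatabase(entries=[self.entry_from(values, labels)]))
        assert model.sd_kt > 0 and model.sd_ot > 0

    def test_missing_class_raises(self):
        values = np.random.default_rng(7).random((4, 4, 4))
        with pytest.raises(EstimationError):
            estimate_intensity_model(
                AtlasDatabase(entries=[self.entry_from(values, np.zeros((4, 4, 4), bool))])
            )

    def test_certain_prior_overrides_intensity(self):
        grid = VoxelGrid(dims=(3, 3, 3), spacing=(1, 1, 1))
        vol = IntensityVolume(grid=grid, values=np.full((3, 3, 3), 20.0))  # OT-like signal
        prior = ProbabilityMap(grid=grid, p_kt=np.ones((3, 3, 3)))
        model = IntensityClassModel(mean_kt=100, sd_kt=5, mean_ot=20, sd_ot=5)
        m = initial_labeling(vol, prior, model)
        assert np.all(m.labels == 1)

    def test_uninformative_prior_reduces_to_intensity_rule(self):
        grid = VoxelGrid(dims=(4, 4, 4), spacing=(1, 1, 1))
        rng = np.random.default_rng(8)
        values = np.where(rng.random((4, 4, 4)) < 0.5, 100.0, 20.0)
        vol = IntensityVolume(grid=grid, values=values)
        prior = ProbabilityMap(grid=grid, p_kt=np.full((4, 4, 4), 0.5))
        model = IntensityClassModel(mean_kt=100, sd_kt=5, mean_ot=20, sd_ot=5)
        m = initial_labeling(vol, prior, model)
        assert np.array_equal(m.labels == 1, values == 100.0)
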