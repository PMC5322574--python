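"""Metric suite checked against independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from renalseg import (
    ConfusionCounts,
    LabelMap,
    ProbabilityMap,
    VoxelGrid,
    bhd95,
    confusion,
    dice,
    directed_hd,
    pvd,
    roc_auc,
    surface_voxels,
)
from renalseg.errors import RenalsegError


def make_map(labels, spacing=(1.0, 1.0, 1.0)):
    labels = np.asarray(labels, dtype=np.uint8)
    return LabelMap(grid=VoxelGrid(dims=labels.shape, spacing=spacing), labels=labels)


def brute_confusion(g, s):
    """Exhaustive voxel loop."""
    tp = fp = fn = tn = 0
    for idx in itertools.product(*[range(d) for d in g.shape]):
        if g[idx] and s[idx]:
            tp += 1
        elif s[idx]:
            fp += 1
        elif g[idx]:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_directed_hd(a_pts, b_pts, spacing, percentile):
    """O(|A||B|) scan + nearest-rank percentile."""
    sp = np.asarray(spacing)
    dists = sorted(
        min(np.linalg.norm((np.asarray(a) - np.asarray(b)) * sp) for b in b_pts)
        for a in a_pts
    )
    k = int(np.ceil(percentile * len(dists)))
    return dists[k - 1]


def mann_whitney_auc(y, s):
    """Normalized U statistic: P(score_pos > score_neg) + 0.5 P(equal)."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionDicePvd:
    def test_counts_match_brute_force_on_random_maps(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            g = rng.random((4, 4, 4)) > 0.6
            s = rng.random((4, 4, 4)) > 0.6
            c = confusion(make_map(g), make_map(s))
            assert (c.c_tp, c.c_fp, c.c_fn, c.c_tn) == brute_confusion(g, s)

    def test_perfect_and_disjoint(self):
        g = np.zeros((4, 4, 4), bool)
        g[1:3, 1:3, 1:3] = True
        c = confusion(make_map(g), make_map(g))
        assert c.c_fp == c.c_fn == 0 and dice(c) == 100.0
        s = ~g
        c2 = confusion(make_map(g), make_map(s))
        assert c2.c_tp == 0 and dice(c2) == 0.0

    def test_all_background_segmentation(self):
        g = np.zeros((4, 4, 4), bool)
        g[:2, :2, :2] = True
        c = confusion(make_map(g), make_map(np.zeros((4, 4, 4), bool)))
        assert c.c_fn == 8 and c.c_tp == 0

    @pytest.mark.parametrize(
        "counts, expected_dc", [((40, 10, 10, 0), 80.0), ((1, 0, 0, 0), 100.0)]
    )
    def test_dice_closed_form(self, counts, expected_dc):
        assert dice(ConfusionCounts(*counts)) == expected_dc

    @pytest.mark.parametrize(
        "tp, fp, fn, expected",
        [(90, 0, 10, 10.0), (100, 10, 0, -10.0), (50, 50, 50, 0.0)],
    )
    def test_pvd_signed(self, tp, fp, fn, expected):
        assert pvd(ConfusionCounts(tp, fp, fn, 0)) == expected

    def test_empty_sets_raise(self):
        with pytest.raises(RenalsegError):
            dice(ConfusionCounts(0, 0, 0, 64))
        with pytest.raises(RenalsegError):
            pvd(ConfusionCounts(0, 5, 0, 59))

    def test_agrees_with_set_formula_on_random_maps(self):
        rng = np.random.default_rng(7)
        g = rng.random((5, 5, 5)) > 0.5
        s = rng.random((5, 5, 5)) > 0.5
        c = confusion(make_map(g), make_map(s))
        assert dice(c) == pytest.approx(100 * 2 * (g & s).sum() / (g.sum() + s.sum()))
        assert pvd(c) == pytest.approx(100 * (g.sum() - s.sum()) / g.sum())


label_arrays = hnp.arrays(np.uint8, (4, 4, 4), elements=st.integers(0, 1))


class TestMetricProperties:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(g=label_arrays, s=label_arrays)
    def test_confusion_partitions_the_lattice(self, g, s):
        c = confusion(make_map(g), make_map(s))
        assert c.total == 64
        assert c.n_truth == int((g == 1).sum())
        assert c.n_seg == int((s == 1).sum())

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(g=label_arrays, s=label_arrays)
    def test_dice_symmetric_and_bounded(self, g, s):
        if not (g.any() or s.any()):
            return
        a = dice(confusion(make_map(g), make_map(s)))
        b = dice(confusion(make_map(s), make_map(g)))
        assert a == b and 0.0 <= a <= 100.0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(g=label_arrays, s=label_arrays)
    def test_bhd_symmetric_nonnegative(self, g, s):
        if not (g.any() and s.any()):
            return
        d = bhd95(make_map(g), make_map(s))
        assert d >= 0.0 and d == bhd95(make_map(s), make_map(g))


class TestSurfaceAndHausdorff:
    def test_single_voxel_is_its_own_surface(self):
        g = np.zeros((5, 5, 5), bool)
        g[2, 2, 2] = True
        assert surface_voxels(make_map(g)).tolist() == [[2, 2, 2]]

    def test_solid_block_surface_is_shell(self):
        g = np.zeros((5, 5, 5), bool)
        g[1:4, 1:4, 1:4] = True
        surf = {tuple(p) for p in surface_voxels(make_map(g))}
        assert len(surf) == 26 and (2, 2, 2) not in surf

    def test_volume_border_counts_as_surface(self):
        g = np.ones((3, 3, 3), bool)
        assert len(surface_voxels(make_map(g))) == 26  # all but the center

    def test_known_distance(self):
        assert directed_hd(np.array([[0, 0, 0]]), np.array([[3, 4, 0]]), (1, 1, 1)) == 5.0

    def test_spacing_scales_distances(self):
        d = directed_hd(np.array([[0, 0, 0]]), np.array([[0, 0, 2]]), (0.64, 0.64, 0.9))
        assert d == pytest.approx(1.8)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 6, size=(20, 3))
        b = rng.integers(0, 6, size=(15, 3))
        for q in (0.5, 0.95, 1.0):
            assert directed_hd(a, b, (0.64, 0.64, 0.9), q) == pytest.approx(
                brute_directed_hd(a, b, (0.64, 0.64, 0.9), q)
            )

    def test_percentile_monotone_and_max_is_classical(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 8, size=(25, 3))
        b = rng.integers(0, 8, size=(25, 3))
        ds = [directed_hd(a, b, (1, 1, 1), q) for q in (0.5, 0.75, 0.95, 1.0)]
        assert ds == sorted(ds)
        assert ds[-1] == brute_directed_hd(a, b, (1, 1, 1), 1.0)

    def test_bhd95_symmetric_and_zero_on_identity(self):
        rng = np.random.default_rng(6)
        g = make_map(rng.random((6, 6, 6)) > 0.6)
        s = make_map(rng.random((6, 6, 6)) > 0.6)
        assert bhd95(g, s) == bhd95(s, g)
        assert bhd95(g, g) == 0.0

    def test_single_voxel_sets_at_known_distance(self):
        g = np.zeros((8, 8, 8), bool)
        s = np.zeros((8, 8, 8), bool)
        g[1, 1, 1] = True
        s[6, 1, 1] = True
        assert bhd95(make_map(g), make_map(s)) == 5.0

    def test_empty_set_raises(self):
        g = np.zeros((4, 4, 4), bool)
        g[0, 0, 0] = True
        with pytest.raises(RenalsegError):
            bhd95(make_map(g), make_map(np.zeros((4, 4, 4), bool)))


class TestRocAuc:
    def make_prob(self, p):
        p = np.asarray(p, dtype=float)
        return ProbabilityMap(grid=VoxelGrid(dims=p.shape, spacing=(1, 1, 1)), p_kt=p)

    def test_perfect_separation(self):
        y = np.zeros((2, 2, 2), bool)
        y[0] = True
        p = np.where(y, 0.9, 0.1)
        _, auc = roc_auc(make_map(y), self.make_prob(p))
        assert auc == 1.0

    def test_constant_scores_give_chance(self):
        y = np.zeros((2, 2, 2), bool)
        y[0, 0, 0] = True
        _, auc = roc_auc(make_map(y), self.make_prob(np.full((2, 2, 2), 0.5)))
        assert auc == pytest.approx(0.5)

    def test_matches_mann_whitney_u(self):
        rng = np.random.default_rng(8)
        y = rng.random(20) > 0.5
        s = np.round(rng.random(20), 1)  # ties on purpose
        ymap = make_map(y.reshape(20, 1, 1))
        pmap = self.make_prob(s.reshape(20, 1, 1))
        _, auc = roc_auc(ymap, pmap)
        assert auc == pytest.approx(mann_whitney_auc(y.astype(int), s))

    def test_single_class_truth_raises(self):
        y = np.ones((2, 2, 2), bool)
        with pytest.raises(RenalsegError):
            roc_auc(make_map(y), self.make_prob(np.full((2, 2, 2), 0.5)))
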