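"""Seed correlation maps, group statistics, overlap and graph metrics."""

import math

import numpy as np
import pytest

import lesionsynth as ls
from lesionsynth.connectivity import (
    ConstantSeedError,
    TooFewSubjectsError,
    GroupTMap,
    SeedMap,
)
from scipy import stats

from oracles import exhaustive_centrality, one_sample_t, pearson_r


def volume_from_series(series_by_voxel, shape):
    """Build a tiny 4-D volume from {(i,j,k): 1-D series}."""
    t = len(next(iter(series_by_voxel.values())))
    vol = np.zeros((*shape, t))
    for idx, series in series_by_voxel.items():
        vol[idx] = series
    return vol


class TestSeedRmap:
    def test_single_voxel_seed_self_correlation(self):
        rng = np.random.default_rng(0)
        vol = rng.standard_normal((3, 3, 3, 50))
        seed = np.zeros((3, 3, 3), dtype=bool)
        seed[1, 1, 1] = True
        r = ls.seed_rmap(vol, seed, np.ones((3, 3, 3), bool))
        assert r[1, 1, 1] == pytest.approx(1.0)

    def test_exact_negative_series_gives_minus_one(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(60)
        vol = volume_from_series({(0, 0, 0): s, (1, 0, 0): -s}, (2, 1, 1))
        seed = np.zeros((2, 1, 1), dtype=bool)
        seed[0, 0, 0] = True
        r = ls.seed_rmap(vol, seed, np.ones((2, 1, 1), bool))
        assert r[1, 0, 0] == pytest.approx(-1.0)

    def test_recovers_population_correlation(self):
        rng = np.random.default_rng(2)
        t = 2000
        z = rng.standard_normal(t)
        x = 0.6 * z + math.sqrt(1 - 0.36) * rng.standard_normal(t)
        vol = volume_from_series({(0, 0, 0): z, (1, 0, 0): x}, (2, 1, 1))
        seed = np.zeros((2, 1, 1), dtype=bool)
        seed[0, 0, 0] = True
        r = ls.seed_rmap(vol, seed, np.ones((2, 1, 1), bool))
        assert abs(r[1, 0, 0] - 0.6) < 0.05

    def test_zero_variance_voxel_flagged_undefined(self):
        rng = np.random.default_rng(3)
        vol = volume_from_series({(0, 0, 0): rng.standard_normal(30),
                                  (1, 0, 0): np.zeros(30)}, (2, 1, 1))
        seed = np.zeros((2, 1, 1), dtype=bool)
        seed[0, 0, 0] = True
        r = ls.seed_rmap(vol, seed, np.ones((2, 1, 1), bool))
        assert np.isnan(r[1, 0, 0])

    def test_constant_seed_is_error(self):
        vol = np.zeros((2, 1, 1, 30))
        seed = np.zeros((2, 1, 1), dtype=bool)
        seed[0, 0, 0] = True
        with pytest.raises(ConstantSeedError):
            ls.seed_rmap(vol, seed, np.ones((2, 1, 1), bool))

    def test_matches_per_voxel_oracle(self, small_sample, small_atlas):
        roi = small_atlas.rois[0]
        mask = ls.roi_mask(small_atlas, roi)
        subject = small_sample.subjects[0]
        r = ls.seed_rmap(subject, mask, small_sample.brain_mask)
        seed_series = subject[mask.data].mean(axis=0)
        rng = np.random.default_rng(5)
        voxels = np.argwhere(small_sample.brain_mask)
        for idx in voxels[rng.choice(len(voxels), 50, replace=False)]:
            want = pearson_r(list(seed_series), list(subject[tuple(idx)]))
            assert r[tuple(idx)] == pytest.approx(want, abs=1e-6)


class TestGroupMaps:
    def test_identical_subjects_average_to_themselves(self, small_atlas):
        rng = np.random.default_rng(6)
        subject = rng.standard_normal((16, 16, 16, 40)).astype(np.float32)
        sample = ls.NormativeSample([subject, subject.copy()], small_atlas.affine,
                                    np.ones((16, 16, 16), bool))
        sm = ls.group_rmap(sample, small_atlas.rois[0], small_atlas)
        np.testing.assert_allclose(sm.group_map, sm.subject_maps[0], atol=1e-6)

    def test_opposite_r_average_to_zero(self):
        maps = [np.full((2, 2, 2), 0.5), np.full((2, 2, 2), -0.5)]
        z = np.arctanh(np.stack(maps))
        assert np.tanh(z.mean(axis=0)) == pytest.approx(0.0)
        # and through the public API
        rng = np.random.default_rng(7)
        s = rng.standard_normal(40)
        sub1 = volume_from_series({(0, 0, 0): s, (1, 0, 0): s}, (2, 1, 1))
        sub2 = volume_from_series({(0, 0, 0): s, (1, 0, 0): -s}, (2, 1, 1))
        sample = ls.NormativeSample([sub1, sub2], np.eye(4), np.ones((2, 1, 1), bool))
        seed = np.zeros((2, 1, 1), dtype=bool)
        seed[0, 0, 0] = True
        sm = ls.group_rmap(sample, seed)
        assert sm.group_map[1, 0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_group_tmap_hand_computation(self):
        # subject z-values {0.1, 0.2, 0.3}: t = 0.2 / (0.1/sqrt(3)) = 2*sqrt(3)
        maps = [np.full((1, 1, 1), np.tanh(z)) for z in (0.1, 0.2, 0.3)]
        tm = ls.group_tmap(SeedMap(None, maps, np.tanh(np.full((1, 1, 1), 0.2))))
        assert tm.t_volume[0, 0, 0] == pytest.approx(3.4641016, abs=1e-5)
        assert tm.df == 2

    def test_zero_z_everywhere_is_undefined(self):
        maps = [np.zeros((1, 1, 1))] * 3
        tm = ls.group_tmap(SeedMap(None, maps, np.zeros((1, 1, 1))))
        assert np.isnan(tm.t_volume[0, 0, 0])

    def test_constant_nonzero_z_is_undefined_not_infinite(self):
        maps = [np.full((1, 1, 1), 0.4)] * 4
        tm = ls.group_tmap(SeedMap(None, maps, np.full((1, 1, 1), 0.4)))
        assert np.isnan(tm.t_volume[0, 0, 0])

    def test_fewer_than_three_subjects_rejected(self):
        maps = [np.zeros((1, 1, 1))] * 2
        with pytest.raises(TooFewSubjectsError):
            ls.group_tmap(SeedMap(None, maps, np.zeros((1, 1, 1))))

    def test_group_t_matches_per_voxel_oracle(self, small_sample, small_atlas):
        sm = ls.group_rmap(small_sample, small_atlas.rois[1], small_atlas)
        tm = ls.group_tmap(sm)
        z_stack = [np.arctanh(np.clip(m, -1 + 1e-7, 1 - 1e-7)) for m in sm.subject_maps]
        rng = np.random.default_rng(8)
        voxels = np.argwhere(small_sample.brain_mask)
        for idx in voxels[rng.choice(len(voxels), 60, replace=False)]:
            zs = [float(z[tuple(idx)]) for z in z_stack]
            want = one_sample_t(zs)
            got = tm.t_volume[tuple(idx)]
            if math.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-5)


class TestBonferroni:
    def _tmap(self, t_values, n_subjects=20):
        t = np.asarray(t_values, dtype=float)
        return GroupTMap(None, t, n_subjects - 1, n_subjects)

    def test_p_exactly_at_threshold_is_not_significant(self):
        tm = self._tmap([[[2.5]]])
        mask = np.ones((1, 1, 1), bool)
        p0 = float(stats.t.sf(2.5, tm.df))
        assert not ls.bonferroni_mask(tm, mask, alpha=p0).any()
        assert ls.bonferroni_mask(tm, mask, alpha=p0 * 1.001).any()

    def test_single_extreme_voxel_in_100_voxel_toy(self):
        t = np.zeros((10, 10, 1))
        t[3, 4, 0] = 10.0
        tm = self._tmap(t)
        sig = ls.bonferroni_mask(tm, np.ones((10, 10, 1), bool), alpha=0.05)
        # oracle: p(10, df=19) << 0.05/100, p(0) = 0.5 >> 0.05/100
        assert stats.t.sf(10.0, 19) < 0.05 / 100 < stats.t.sf(0.0, 19)
        assert sig.sum() == 1 and sig[3, 4, 0]

    def test_alpha_zero_is_empty(self):
        tm = self._tmap(np.full((4, 4, 1), 8.0))
        assert not ls.bonferroni_mask(tm, np.ones((4, 4, 1), bool), alpha=0.0).any()

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(9)
        tm = self._tmap(rng.standard_normal((6, 6, 6)) * 4)
        mask = np.ones((6, 6, 6), bool)
        prev = np.zeros((6, 6, 6), bool)
        for alpha in (0.001, 0.01, 0.05, 0.2, 1.0):
            cur = ls.bonferroni_mask(tm, mask, alpha=alpha)
            assert (prev <= cur).all()
            prev = cur

    def test_undefined_voxels_never_significant_and_shrink_v(self):
        t = np.full((2, 2, 1), 10.0)
        t[0, 0, 0] = np.nan
        tm = self._tmap(t)
        sig = ls.bonferroni_mask(tm, np.ones((2, 2, 1), bool), alpha=0.05)
        assert not sig[0, 0, 0] and sig.sum() == 3


class TestExternalNetwork:
    def test_tau_is_ceil_of_fraction(self, small_sample, small_atlas):
        ov = ls.external_network(small_sample, small_atlas, small_atlas.rois[:3], fraction=0.5)
        assert ov.tau == 2
        ov5 = ls.external_network(small_sample, small_atlas, small_atlas.rois[:3], fraction=1.0)
        assert ov5.tau == 3

    def test_single_roi_threshold_equals_its_mask(self, small_sample, small_atlas):
        roi = small_atlas.rois[0]
        ov = ls.external_network(small_sample, small_atlas, [roi], fraction=0.5)
        tm = ls.group_tmap(ls.group_rmap(small_sample, roi, small_atlas))
        want = ls.bonferroni_mask(tm, small_sample.brain_mask, alpha=0.05)
        assert np.array_equal(ov.threshold_volume, want)

    def test_counts_equal_brute_force_mask_intersection(self, small_sample, small_atlas):
        rois = small_atlas.rois
        ov = ls.external_network(small_sample, small_atlas, rois, alpha=0.05, fraction=0.5)
        masks = [
            ls.bonferroni_mask(ls.group_tmap(ls.group_rmap(small_sample, r, small_atlas)),
                               small_sample.brain_mask, alpha=0.05)
            for r in rois
        ]
        counts = sum(m.astype(int) for m in masks)
        assert np.array_equal(ov.count_volume, counts)
        assert np.array_equal(ov.threshold_volume, counts >= ov.tau)

    def test_count_volume_permutation_invariant(self, small_sample, small_atlas):
        rois = small_atlas.rois
        a = ls.external_network(small_sample, small_atlas, rois, fraction=0.5)
        b = ls.external_network(small_sample, small_atlas, list(reversed(rois)), fraction=0.5)
        assert np.array_equal(a.count_volume, b.count_volume)

    def test_threshold_monotone_decreasing_in_fraction(self, small_sample, small_atlas):
        rois = small_atlas.rois
        prev = None
        for fraction in (0.25, 0.5, 0.75, 1.0):
            ov = ls.external_network(small_sample, small_atlas, rois, fraction=fraction)
            if prev is not None:
                assert (ov.threshold_volume <= prev).all()
            prev = ov.threshold_volume


class TestCentrality:
    def test_path_topology_middle_node_is_most_between(self):
        # a-b and b-c strongly similar, a-c weakly: shortest a-c route runs
        # through b (0.2 + 0.2 < 0.9), so b carries all the betweenness
        nodes = ["a", "b", "c"]
        sim = np.array([[1.0, 0.8, 0.1], [0.8, 1.0, 0.8], [0.1, 0.8, 1.0]])
        _, bet, clo, disconnected = ls.centrality_from_similarity(nodes, sim)
        assert not disconnected
        assert bet["b"] == max(bet.values()) and bet["b"] > 0
        assert clo["b"] == max(clo.values())

    def test_uniform_similarity_gives_flat_centrality(self):
        nodes = list("abcd")
        sim = np.full((4, 4), 0.5)
        np.fill_diagonal(sim, 1.0)
        _, bet, clo, _ = ls.centrality_from_similarity(nodes, sim)
        assert all(b == 0.0 for b in bet.values())
        assert len({round(v, 12) for v in clo.values()}) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        sim = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                sim[i, j] = sim[j, i] = rng.uniform(0.05, 0.95)
        np.fill_diagonal(sim, 1.0)
        nodes = list(range(n))
        _, bet, clo, disconnected = ls.centrality_from_similarity(nodes, sim)
        assert not disconnected
        lengths = {
            frozenset({i, j}): 1.0 - sim[i, j]
            for i in range(n) for j in range(i + 1, n)
        }
        want_bet, want_clo = exhaustive_centrality(nodes, lengths)
        for u in nodes:
            assert bet[u] == pytest.approx(want_bet[u], abs=1e-9)
            assert clo[u] == pytest.approx(want_clo[u], abs=1e-9)

    def test_disconnected_graph_flagged_with_harmonic_closeness(self):
        nodes = list("abcd")
        sim = np.zeros((4, 4))
        np.fill_diagonal(sim, 1.0)
        sim[0, 1] = sim[1, 0] = 0.9
        sim[2, 3] = sim[3, 2] = 0.9
        with pytest.warns(UserWarning, match="disconnected"):
            _, _, clo, disconnected = ls.centrality_from_similarity(nodes, sim)
        assert disconnected
        assert all(np.isfinite(v) for v in clo.values())


class TestInternalNetwork:
    def test_requires_three_rois(self, small_sample, small_atlas):
        with pytest.raises(ValueError, match=">= 3"):
            ls.internal_network(small_sample, small_atlas, small_atlas.rois[:2])

    def test_similarity_symmetric_unit_diagonal(self, small_sample, small_atlas):
        net = ls.internal_network(small_sample, small_atlas, small_atlas.rois)
        np.testing.assert_allclose(net.similarity, net.similarity.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(net.similarity), 1.0)

    def test_recovers_planted_modules(self):
        atlas = ls.make_synthetic_atlas((20, 20, 20), 6, 2, seed=21)
        spec = ls.NetworkSpec(n_subjects=6, n_timepoints=200, seed=21)
        sample = ls.make_normative_sample(atlas, spec)
        net = ls.internal_network(sample, atlas, atlas.rois, cut_k=2)
        planted = sample.module_of_roi
        got = net.cluster_assignment
        # same partition up to label renaming
        pairs = {(planted[r], got[r]) for r in atlas.rois}
        assert len(pairs) == 2
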