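"""fROI candidate rule, peak growth, parameter extraction."""

import numpy as np
import pytest
from scipy import stats

import froikit as fk
from froikit.froi import (FroiConfig, define_froi, extract_parameters,
                          extract_parameters_from_voxels, find_candidates,
                          select_froi)
from froikit.hypothesis_space import HypothesisSpace
from froikit.volumes import BinaryMask, ScalarVolume
from conftest import flood_fill_components


def _space(grid, indices, name="R"):
    mask = BinaryMask.from_indices(grid, indices)
    anchor = tuple(grid.voxel_to_world(mask.members[0]))
    return HypothesisSpace(name=name, mask=mask, source_half=1,
                           seed_point_mm=anchor)


def _full_space(grid, name="R"):
    return _space(grid, np.indices(grid.dims).reshape(3, -1).T, name)


def candidate_oracle(tmap, space, config):
    """Independent reimplementation: threshold, BFS clusters within the
    masked map, keep clusters of size >= min_other_voxels + 1."""
    cutoff = stats.t.isf(config.candidate_p, tmap.df)
    field = (tmap.values > cutoff) & space.mask.data
    comps = flood_fill_components(field, config.connectivity)
    out = set()
    for comp in comps:
        if len(comp) >= config.min_other_voxels + 1:
            out |= comp
    return out


def selection_oracle(candidates, tmap, config):
    """Independent peak growth: global peak (lowest linear index on
    ties), distance filter, then BFS from the peak over the kept set."""
    candidates = {tuple(c) for c in candidates}
    if not candidates:
        return set()
    grid = tmap.grid
    best = None
    for c in sorted(candidates,
                    key=lambda v: np.ravel_multi_index(v, grid.dims)):
        if best is None or tmap.values[c] > tmap.values[best]:
            best = c
    peak_mm = grid.voxel_to_world(best)
    kept = {c for c in candidates
            if np.linalg.norm(grid.voxel_to_world(c) - peak_mm)
            <= config.radius_mm}
    data = np.zeros(grid.dims, dtype=bool)
    for c in kept:
        data[c] = True
    comps = flood_fill_components(data, config.connectivity)
    return set(next(c for c in comps if best in c))


class TestFindCandidates:
    def test_twelve_voxel_cluster_all_candidates(self, small_grid):
        values = np.zeros(small_grid.dims)
        voxels = [(5, 5, z) for z in range(4)] + [(5, 6, z) for z in range(4)] \
            + [(6, 5, z) for z in range(4)]
        for v in voxels:
            values[v] = 6.0
        tmap = ScalarVolume(small_grid, values, df=100)
        got = find_candidates(tmap, _full_space(small_grid))
        assert {tuple(v) for v in got} == set(voxels)

    def test_isolated_voxel_not_a_candidate(self, small_grid):
        values = np.zeros(small_grid.dims)
        values[8, 8, 8] = 10.0
        tmap = ScalarVolume(small_grid, values, df=100)
        assert find_candidates(tmap, _full_space(small_grid)).shape[0] == 0

    def test_missing_df_rejected(self, small_grid):
        tmap = ScalarVolume(small_grid, np.zeros(small_grid.dims))
        with pytest.raises(ValueError, match="df"):
            find_candidates(tmap, _full_space(small_grid))

    def test_matches_brute_force_oracle_on_random_maps(self, small_grid):
        rng = np.random.default_rng(21)
        config = FroiConfig(min_other_voxels=3)
        g = fk.mni_grid((8, 8, 8), 4.0)
        for _ in range(50):
            tmap = ScalarVolume(g, rng.normal(1.5, 1.5, g.dims), df=40)
            mask_idx = np.argwhere(rng.random(g.dims) < 0.7)
            space = _space(g, mask_idx)
            got = {tuple(v) for v in find_candidates(tmap, space, config)}
            assert got == candidate_oracle(tmap, space, config)


class TestSelectFroi:
    def test_chain_beyond_radius_excluded(self):
        g = fk.mni_grid((16, 4, 4), 4.0)
        values = np.zeros(g.dims)
        chain = [(x, 1, 1) for x in range(6)]  # 0..20 mm from peak
        for v in chain:
            values[v] = 5.0
        values[0, 1, 1] = 9.0  # peak at one end
        tmap = ScalarVolume(g, values, df=100)
        res = select_froi(np.array(chain), tmap,
                          FroiConfig(radius_mm=9.0))
        got_x = sorted(v[0] for v in res.voxels)
        assert got_x == [0, 1, 2]  # 0, 4, 8 mm kept; 12+ mm dropped

    def test_growth_from_global_peak_only(self, small_grid):
        values = np.zeros(small_grid.dims)
        a = [(2, 2, 2), (2, 2, 3)]
        b = [(12, 12, 12), (12, 12, 13)]
        for v in a:
            values[v] = 4.0
        for v in b:
            values[v] = 7.0
        tmap = ScalarVolume(small_grid, values, df=100)
        res = select_froi(np.array(a + b), tmap)
        assert {tuple(v) for v in res.voxels} == set(b)

    def test_empty_candidates_is_not_found(self, small_grid):
        tmap = ScalarVolume(small_grid, np.zeros(small_grid.dims), df=100)
        res = select_froi(np.empty((0, 3)), tmap, region="R")
        assert not res.found and res.size == 0
        assert np.isnan(res.mean_t) and np.all(np.isnan(res.com_mm))

    def test_peak_tie_broken_by_lowest_linear_index(self, small_grid):
        values = np.zeros(small_grid.dims)
        values[2, 2, 2] = 5.0
        values[12, 12, 12] = 5.0
        tmap = ScalarVolume(small_grid, values, df=100)
        res = select_froi(np.array([(2, 2, 2), (12, 12, 12)]), tmap)
        assert {tuple(v) for v in res.voxels} == {(2, 2, 2)}

    def test_matches_brute_force_selection_oracle(self):
        rng = np.random.default_rng(31)
        g = fk.mni_grid((8, 8, 8), 4.0)
        config = FroiConfig(min_other_voxels=2)
        for _ in range(50):
            tmap = ScalarVolume(g, rng.normal(1.5, 1.5, g.dims), df=40)
            space = _full_space(g)
            cands = find_candidates(tmap, space, config)
            res = select_froi(cands, tmap, config)
            oracle = selection_oracle(cands, tmap, config)
            assert {tuple(v) for v in res.voxels} == oracle


class TestExtractParameters:
    def test_single_voxel(self):
        g = fk.mni_grid((16, 16, 16), 4.0)
        vox = g.world_to_voxel((4.0, -8.0, 12.0))
        values = np.zeros(g.dims)
        values[tuple(vox)] = 5.0
        tmap = ScalarVolume(g, values, df=100)
        res = extract_parameters_from_voxels(np.array([vox]), tmap, "R")
        assert res.size == 1 and res.mean_t == 5.0
        assert np.allclose(res.com_mm, (4.0, -8.0, 12.0))

    def test_weighted_center_of_mass(self):
        g = fk.mni_grid((8, 4, 4), 4.0)
        v1 = g.world_to_voxel((0, 0, 0))
        v2 = g.world_to_voxel((4, 0, 0))
        values = np.zeros(g.dims)
        values[tuple(v1)] = 2.0
        values[tuple(v2)] = 6.0
        tmap = ScalarVolume(g, values, df=100)
        res = extract_parameters_from_voxels(np.array([v1, v2]), tmap)
        assert res.com_mm[0] == pytest.approx(3.0)  # (0*2 + 4*6)/8
        assert res.mean_t == pytest.approx(4.0)

    def test_three_voxel_hand_computed_centroid(self):
        g = fk.mni_grid((8, 8, 4), 4.0)
        pts = [((0, 0, 0), 1.0), ((4, 0, 0), 2.0), ((0, 4, 0), 5.0)]
        values = np.zeros(g.dims)
        voxels = []
        for mm, t in pts:
            vox = g.world_to_voxel(mm)
            values[tuple(vox)] = t
            voxels.append(vox)
        tmap = ScalarVolume(g, values, df=100)
        res = extract_parameters_from_voxels(np.array(voxels), tmap)
        # x: (0*1 + 4*2 + 0*5)/8 = 1; y: (0 + 0 + 4*5)/8 = 2.5
        assert res.com_mm[0] == pytest.approx(1.0)
        assert res.com_mm[1] == pytest.approx(2.5)

    def test_not_found_gives_missing_not_zero(self, small_grid):
        tmap = ScalarVolume(small_grid, np.zeros(small_grid.dims), df=100)
        res = select_froi(np.empty((0, 3)), tmap, region="R")
        size, mean_t, com, found = extract_parameters(res, tmap)
        assert not found and np.isnan(mean_t) and np.isnan(size)
        assert np.all(np.isnan(com))


class TestFroiInvariants:
    def _random_case(self, rng):
        g = fk.mni_grid((8, 8, 8), 4.0)
        tmap = ScalarVolume(g, rng.normal(1.5, 1.5, g.dims), df=40)
        space = _space(g, np.argwhere(rng.random(g.dims) < 0.8))
        return tmap, space

    def test_roi_nested_in_candidates_nested_in_space(self):
        rng = np.random.default_rng(41)
        config = FroiConfig(min_other_voxels=2)
        for _ in range(20):
            tmap, space = self._random_case(rng)
            cands = {tuple(v) for v in find_candidates(tmap, space, config)}
            res = select_froi(np.array(sorted(cands)).reshape(-1, 3),
                              tmap, config)
            roi = {tuple(v) for v in res.voxels}
            members = {tuple(v) for v in space.mask.members}
            assert roi <= cands <= members

    def test_radius_monotonicity(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            tmap, space = self._random_case(rng)
            sizes = []
            for radius in (4.0, 9.0, 16.0):
                config = FroiConfig(min_other_voxels=2, radius_mm=radius)
                res = define_froi(tmap, space, config)
                sizes.append(res.size)
            assert sizes == sorted(sizes)

    def test_candidate_p_monotonicity(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            tmap, space = self._random_case(rng)
            counts = []
            for p in (0.05, 0.01, 0.001):
                config = FroiConfig(candidate_p=p, min_other_voxels=2)
                counts.append(find_candidates(tmap, space, config).shape[0])
            assert counts == sorted(counts, reverse=True)

    def test_found_roi_values_exceed_cutoff(self, small_grid, origin_space):
        cohort = fk.generate_cohort(fk.CohortConfig(n_nt=10, n_asd=0),
                                    seed=3)
        blob = [fk.BlobSpec("R", (0, 0, 0))]
        cutoff = stats.t.isf(0.001, 100)
        for _, even, _, _ in fk.simulate_cohort_maps(
                cohort, blob, fk.NoiseSpec(sd=1.0), small_grid, seed=4):
            res = define_froi(even, origin_space)
            if res.found:
                assert np.all(even.values[tuple(res.voxels.T)] > cutoff)
                assert res.mean_t > cutoff
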