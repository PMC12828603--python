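"""ROI selection: filters, top-fraction, density clustering, splits."""

import numpy as np
import pytest

from ncreann.containers import VoxelSourceMap
from ncreann.roi import (NOISE, ROISet, assemble_rois, cluster_voxels,
                         filter_voxels, select_rois, select_top_fraction,
                         split_temporal)
from ncreann.synthetic import PlantedCluster, VoxelMapSpec, simulate_voxel_map


def _map(coords, power=None, brain=None, wm=None, cereb=None, labels=None,
         spacing=5.0):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return VoxelSourceMap(
        coords=coords,
        power=np.ones(n) if power is None else np.asarray(power, float),
        grid_spacing=spacing,
        brain_mask=np.ones(n, bool) if brain is None else np.asarray(brain, bool),
        wm_mask=np.zeros(n, bool) if wm is None else np.asarray(wm, bool),
        cerebellum_mask=np.zeros(n, bool) if cereb is None else np.asarray(cereb, bool),
        label_id=np.zeros(n, int) if labels is None else np.asarray(labels, int),
    )


def _grid(n, spacing=5.0):
    ax = np.arange(n) * spacing
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


class TestFilter:
    def test_hand_counted_toy_map(self):
        # 10 voxels: 2 in cerebellum, 1 in white matter -> 7 survive
        coords = [(i * 5.0, 0.0, 0.0) for i in range(10)]
        cereb = [i in (0, 1) for i in range(10)]
        wm = [i == 5 for i in range(10)]
        vmap = _map(coords, wm=wm, cereb=cereb)
        assert filter_voxels(vmap).sum() == 7

    def test_voxel_outside_brain_excluded(self):
        vmap = _map([(0, 0, 0), (5, 0, 0)], brain=[True, False])
        assert list(filter_voxels(vmap)) == [True, False]

    def test_all_masks_permissive_is_identity(self):
        vmap = _map(_grid(3))
        assert filter_voxels(vmap).all()


class TestTopFraction:
    def test_three_percent_of_100_is_3(self, rng):
        coords = [(i * 5.0, 0.0, 0.0) for i in range(100)]
        vmap = _map(coords, power=rng.random(100))
        assert select_top_fraction(vmap, 0.03).size == 3

    def test_ceiling_selects_at_least_one(self):
        vmap = _map([(0, 0, 0), (5, 0, 0)])
        assert select_top_fraction(vmap, 0.03).size == 1

    def test_equal_powers_tie_break_lexicographic(self):
        coords = [(5, 0, 0), (0, 5, 0), (0, 0, 5), (0, 0, 0)]
        vmap = _map(coords)
        sel = select_top_fraction(vmap, 0.5)
        assert [tuple(vmap.coords[i]) for i in sel] == [(0, 0, 0), (0, 0, 5)]

    def test_planted_high_power_selected_before_background(self, rng):
        coords = _grid(5)
        power = rng.uniform(0, 1, coords.shape[0])
        hot = [3, 17, 44]
        power[hot] += 10.0
        vmap = _map(coords, power=power)
        sel = select_top_fraction(vmap, 3 / coords.shape[0])
        assert set(sel) == set(hot)

    def test_invalid_fraction_or_empty_map_rejected(self):
        vmap = _map([(0, 0, 0)], brain=[False])
        with pytest.raises(ValueError, match="fraction"):
            select_top_fraction(_map([(0, 0, 0)]), 0.0)
        with pytest.raises(ValueError, match="no voxels"):
            select_top_fraction(vmap, 0.5)


def _brute_force_n_clusters(coords, eps, min_samples):
    """Transitive closure of the eps-neighborhood graph over core points."""
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    neighbors = d <= eps
    core = neighbors.sum(axis=1) >= min_samples  # includes self
    reach = neighbors & core[None, :] & core[:, None]
    labels = -np.ones(n, int)
    current = 0
    for i in range(n):
        if not core[i] or labels[i] >= 0:
            continue
        stack = [i]
        while stack:
            j = stack.pop()
            if labels[j] >= 0:
                continue
            labels[j] = current
            stack.extend(np.flatnonzero(reach[j] & (labels < 0)).tolist())
        current += 1
    return current


class TestClustering:
    def test_two_distant_blobs_give_two_clusters(self):
        blob1 = _grid(2) + 0.0
        blob2 = _grid(2) + 200.0
        vmap = _map(np.vstack([blob1, blob2]))
        ids = cluster_voxels(vmap, np.arange(16))
        assert len(set(ids) - {NOISE}) == 2

    def test_single_voxel_is_noise(self):
        vmap = _map([(0.0, 0.0, 0.0)])
        assert list(cluster_voxels(vmap, np.array([0]))) == [NOISE]

    def test_chain_at_09_eps_matches_reachability_oracle(self):
        eps = 10.0  # 2 * spacing
        coords = [(i * 0.9 * eps, 0.0, 0.0) for i in range(8)]
        vmap = _map(coords)
        ids = cluster_voxels(vmap, np.arange(8))
        assert len(set(ids) - {NOISE}) == 1
        assert _brute_force_n_clusters(coords, eps, 3) == 1

    def test_random_configurations_match_oracle_count(self, rng):
        for _ in range(5):
            coords = rng.integers(0, 8, (30, 3)) * 5.0
            coords = np.unique(coords, axis=0)
            vmap = _map(coords)
            ids = cluster_voxels(vmap, np.arange(coords.shape[0]))
            assert (len(set(ids) - {NOISE})
                    == _brute_force_n_clusters(coords, 10.0, 3))


class TestTemporalSplit:
    def test_one_mm_anterior_goes_atl_boundary_goes_ptl(self):
        vmap = _map([(50, -20.0, 0), (50, -21.0, 0)])
        parts = split_temporal(vmap, np.array([0, 1]), reference_y=-21.0)
        assert list(parts["ATL"]) == [0] and list(parts["PTL"]) == [1]

    def test_all_anterior_leaves_ptl_empty(self):
        vmap = _map([(50, 0.0, 0), (50, 5.0, 0)])
        parts = split_temporal(vmap, np.array([0, 1]), reference_y=-21.0)
        assert parts["PTL"].size == 0 and parts["ATL"].size == 2

    def test_mixed_set_matches_per_voxel_sign_check(self, rng):
        ys = rng.uniform(-60, 30, 6)
        coords = [(50.0, y, 0.0) for y in ys]
        vmap = _map(coords)
        parts = split_temporal(vmap, np.arange(6), reference_y=-21.0)
        for i, y in enumerate(ys):
            assert (i in parts["ATL"]) == (y > -21.0)


class TestAssemble:
    def test_insula_label_maps_to_ic_and_subcortical_dropped(self):
        coords = [(40.0 + 5 * i, 0.0, 0.0) for i in range(4)]
        labels = [3, 3, 9, 0]  # insula, insula, subcortical, unlabelled
        vmap = _map(coords, labels=labels)
        rois = assemble_rois(vmap, np.arange(4), np.zeros(4, int))
        assert set(rois.names()) == {"IC"}
        assert list(rois.rois["IC"]) == [0, 1]

    def test_empty_recipe_gives_empty_roiset(self):
        vmap = _map([(0.0, 0.0, 0.0)], labels=[3])
        rois = assemble_rois(vmap, np.array([0]), np.array([0]), recipe={})
        assert len(rois) == 0

    def test_recipe_with_unknown_label_rejected(self):
        vmap = _map([(0.0, 0.0, 0.0)], labels=[3])
        with pytest.raises(ValueError, match="unknown atlas label"):
            assemble_rois(vmap, np.array([0]), np.array([0]),
                          recipe={999: "IC"})

    def test_noise_voxels_discarded(self):
        vmap = _map([(0.0, 0.0, 0.0), (5.0, 0.0, 0.0)], labels=[3, 3])
        rois = assemble_rois(vmap, np.arange(2), np.array([0, NOISE]))
        assert list(rois.rois["IC"]) == [0]

    def test_overlapping_rois_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            ROISet(rois={"A": np.array([0, 1]), "B": np.array([1])})


class TestFullStage:
    def _planted_map(self, seed=0):
        return simulate_voxel_map(VoxelMapSpec(
            grid_spacing=5.0, extent=40.0, brain_radii=(38.0, 38.0, 38.0),
            planted_clusters=[
                PlantedCluster((20.0, 20.0, 5.0), 9.0, 3.0, label_id=3),
                PlantedCluster((0.0, -25.0, -5.0), 8.0, 3.0, label_id=1),
            ], background_sd=0.15, seed=seed))

    def test_stage_order_filter_before_top_fraction_matters(self):
        # hottest voxels sit in the cerebellum; the pipeline must never
        # select them, which a top-fraction-first ordering would
        vmap = simulate_voxel_map(VoxelMapSpec(
            planted_clusters=[
                PlantedCluster((40.0, 20.0, 5.0), 9.0, 3.0, label_id=3)],
            background_sd=0.15, seed=0))
        cereb = vmap.cerebellum_mask
        assert cereb.sum() > 0
        vmap.power[cereb] += 50.0
        valid = filter_voxels(vmap)
        sel = select_top_fraction(vmap, 0.03, valid=valid)
        assert not np.any(cereb[sel])
        naive = np.argsort(-vmap.power)[:sel.size]
        assert np.any(cereb[naive])

    def test_planted_clusters_far_apart_recovered_exactly(self):
        for seed in (0, 1, 2):
            vmap = self._planted_map(seed)
            valid = filter_voxels(vmap)
            sel = select_top_fraction(vmap, 0.03, valid=valid)
            ids = cluster_voxels(vmap, sel)
            assert len(set(ids) - {NOISE}) == 2

    def test_deterministic_given_map(self):
        vmap = self._planted_map()
        a = select_rois(vmap)
        b = select_rois(vmap)
        assert a.names() == b.names()
        for name in a.names():
            assert np.array_equal(a.rois[name], b.rois[name])
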