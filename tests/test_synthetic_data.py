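"""Toy-brain generator: geometry invariants, determinism, planted structure."""

import numpy as np
import pytest
from scipy import ndimage

from disconnectomics import synthetic_data as sd
from disconnectomics.grids import voxel_to_world


class TestMakeToyBrain:
    def test_region_ids_and_hemisphere_assignment(self, toy_brain):
        assert list(toy_brain.region_ids) == list(range(1, 9))
        left_ids = toy_brain.region_table.query("hemisphere == 'left'")["region_id"]
        for rid in left_ids:
            labels = np.unique(toy_brain.hemisphere_labels[toy_brain.parcellation == rid])
            assert labels.tolist() == [1]

    def test_deterministic_construction(self):
        a = sd.make_toy_brain((16, 16, 16), 4, seed=1)
        b = sd.make_toy_brain((16, 16, 16), 4, seed=1)
        assert np.array_equal(a.parcellation, b.parcellation)
        assert np.array_equal(a.brain_mask, b.brain_mask)
        assert np.array_equal(a.wm_mask, b.wm_mask)

    def test_every_region_nonempty_and_inside_brain(self, small_brain):
        # exhaustive voxel scan of the emitted volumes
        for rid in small_brain.region_ids:
            assert (small_brain.parcellation == rid).sum() > 0
        assert not np.any((small_brain.parcellation > 0) & ~small_brain.brain_mask)
        small_brain.validate()

    def test_hemisphere_split_at_midsagittal_plane(self, toy_brain):
        idx = np.argwhere(toy_brain.brain_mask)
        world_x = voxel_to_world(idx, toy_brain.affine)[:, 0]
        codes = toy_brain.hemisphere_labels[tuple(idx.T)]
        assert np.all((world_x <= 0) == (codes == 1))

    @pytest.mark.parametrize("shape", [(4, 16, 16), (16, 7, 16), (8, 8, 7)])
    def test_degenerate_grid_rejected(self, shape):
        with pytest.raises(ValueError, match=">= 8"):
            sd.make_toy_brain(shape, 2, seed=0)


class TestMakeToyTractograms:
    def test_zero_jitter_gives_identical_polylines(self, toy_brain):
        tgs = sd.make_toy_tractograms(toy_brain, [(1, 5)], 1, 3, 0.0, seed=0)
        assert len(tgs) == 1 and len(tgs[0]) == 3
        for s in tgs[0].streamlines[1:]:
            np.testing.assert_array_equal(s, tgs[0].streamlines[0])

    def test_streamline_counting(self, toy_brain):
        tgs = sd.make_toy_tractograms(toy_brain, [(1, 5), (2, 6)], 4, 2, 1.0, seed=0)
        assert len(tgs) == 4
        assert all(len(t) == 4 for t in tgs)

    def test_jittered_endpoints_stay_in_their_regions(self, toy_brain):
        # point-in-region check per emitted endpoint
        pairs = [(1, 3), (5, 7)]
        tgs = sd.make_toy_tractograms(toy_brain, pairs, 2, 10, 0.5, seed=9)
        from disconnectomics.grids import world_to_voxel

        for tg in tgs:
            for i, s in enumerate(tg.streamlines):
                a, b = pairs[i // 10]
                for point, rid in ((s[0], a), (s[-1], b)):
                    v = np.floor(world_to_voxel(point, toy_brain.affine)[0] + 0.5).astype(int)
                    assert toy_brain.parcellation[tuple(v)] == rid

    def test_unknown_region_and_negative_jitter_rejected(self, toy_brain):
        with pytest.raises(KeyError):
            sd.make_toy_tractograms(toy_brain, [(1, 99)], 1, 1, 0.0, seed=0)
        with pytest.raises(ValueError):
            sd.make_toy_tractograms(toy_brain, [(1, 5)], 1, 1, -0.1, seed=0)


class TestPlantLesionCohort:
    def test_uniform_cohort_connected_single_hemisphere_sized(self, toy_brain):
        cohort = sd.plant_lesion_cohort(toy_brain, None, 50, "uniform", (5, 40), seed=11)
        assert len(cohort) == 50
        for les in cohort:
            assert 5 <= les.size_vox <= 40
            _, n_comp = ndimage.label(les.volume)
            assert n_comp == 1
            les.validate(toy_brain.brain_mask, toy_brain.hemisphere_labels)

    def test_zero_dispersion_pins_all_centres(self, toy_brain, planted):
        one_seed = sd.PlantedStructure(
            n_patterns=1,
            pattern_region_profiles=planted["structure"].pattern_region_profiles[:1],
            pattern_lesion_seeds=planted["structure"].pattern_lesion_seeds[:1],
            term_mixing=np.ones((2, 1)),
        )
        cohort = sd.plant_lesion_cohort(
            toy_brain, one_seed, 8, "clustered", (5, 5), seed=4, dispersion_mm=0.0
        )
        seeds = {tuple(np.argwhere(les.volume)[0]) for les in cohort}
        # all blobs grow from the same centre voxel
        centre_hits = [
            les.volume[tuple(np.round(
                np.argwhere(cohort[0].volume).mean(0)).astype(int))]
            for les in cohort
        ]
        assert len({les.hemisphere for les in cohort}) == 1
        assert all(centre_hits)
        del seeds

    def test_same_seed_reproduces_masks_exactly(self, toy_brain, planted):
        a = sd.plant_lesion_cohort(toy_brain, planted["structure"], 10, "clustered", (5, 20), seed=6)
        b = sd.plant_lesion_cohort(toy_brain, planted["structure"], 10, "clustered", (5, 20), seed=6)
        for la, lb in zip(a, b):
            assert np.array_equal(la.volume, lb.volume)

    def test_infeasible_size_range_rejected(self, toy_brain):
        hemi_vol = int(toy_brain.hemisphere_mask("left").sum())
        with pytest.raises(ValueError, match="infeasible"):
            sd.plant_lesion_cohort(toy_brain, None, 2, "uniform", (hemi_vol + 10, hemi_vol + 20))

    def test_clustered_centres_tighter_than_uniform(self, toy_brain, planted):
        # mean nearest-neighbour centre distance, >= 20 replicates
        def mean_nn(cohort):
            centres = np.array([np.argwhere(l.volume).mean(0) for l in cohort])
            d = np.linalg.norm(centres[:, None] - centres[None], axis=-1)
            np.fill_diagonal(d, np.inf)
            return d.min(axis=1).mean()

        wins = 0
        for rep in range(20):
            clus = sd.plant_lesion_cohort(
                toy_brain, planted["structure"], 25, "clustered", (5, 20), seed=500 + rep
            )
            unif = sd.plant_lesion_cohort(
                toy_brain, None, 25, "uniform", (5, 20), seed=900 + rep
            )
            wins += mean_nn(clus) < mean_nn(unif)
        assert wins == 20


class TestMakeToyTermMaps:
    def test_identity_mixing_no_noise_reproduces_profiles(self, toy_brain, planted):
        profiles = planted["structure"].pattern_region_profiles
        st = sd.PlantedStructure(
            n_patterns=4,
            pattern_region_profiles=profiles,
            pattern_lesion_seeds=planted["structure"].pattern_lesion_seeds,
            term_mixing=np.eye(4),
            noise_sd=0.0,
        )
        tm = sd.make_toy_term_maps(st, toy_brain.n_regions, seed=0)
        np.testing.assert_allclose(tm.values, profiles)

    def test_half_half_mixing_gives_exact_average(self, toy_brain, planted):
        profiles = planted["structure"].pattern_region_profiles[:2]
        st = sd.PlantedStructure(
            n_patterns=2,
            pattern_region_profiles=profiles,
            pattern_lesion_seeds=planted["structure"].pattern_lesion_seeds[:2],
            term_mixing=np.array([[0.5, 0.5]]),
            noise_sd=0.0,
        )
        tm = sd.make_toy_term_maps(st, toy_brain.n_regions, seed=0)
        np.testing.assert_allclose(tm.values[0], profiles.mean(axis=0))

    def test_noisy_maps_reproducible_and_faithful(self, toy_brain, planted):
        st = planted["structure"]
        a = sd.make_toy_term_maps(st, toy_brain.n_regions, seed=5)
        b = sd.make_toy_term_maps(st, toy_brain.n_regions, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        # direct recomputation from the planted profiles
        clean = st.term_mixing @ st.pattern_region_profiles
        dominant = st.term_mixing.argmax(axis=1)
        for t in range(a.values.shape[0]):
            r = np.corrcoef(a.values[t], st.pattern_region_profiles[dominant[t]])[0, 1]
            assert r > 0.9
        assert np.abs(a.values - clean).max() < 5 * st.noise_sd * 4

    def test_dimension_mismatch_rejected(self, planted):
        with pytest.raises(ValueError):
            sd.make_toy_term_maps(planted["structure"], 5, seed=0)
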