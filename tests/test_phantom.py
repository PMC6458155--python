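"""Phantom generators: determinism, ground-truth consistency, layouts."""

import numpy as np
import pytest

from trichrome import phantom
from trichrome.chromatic import ChromaticShiftModel
from trichrome.core import InvalidParameterError
from trichrome.unmixing import MixingModel


class TestProjectionPhantom:
    def test_zero_overlap_populations_are_pixel_disjoint(self, small_projection_phantom):
        _, truth = small_projection_phantom
        assert truth.multi_population_fraction() == 0.0

    def test_same_seed_is_bit_identical(self):
        kwargs = dict(shape=(300, 300), n_per_population=(5, 5, 5), seed=42, block_px=30)
        img_a, gt_a = phantom.generate_projection_phantom(**kwargs)
        img_b, gt_b = phantom.generate_projection_phantom(**kwargs)
        np.testing.assert_array_equal(img_a.data, img_b.data)
        np.testing.assert_array_equal(gt_a.axon_membership, gt_b.axon_membership)

    def test_overlap_fraction_controls_multi_population_pixels(
        self, overlap_projection_phantom
    ):
        _, truth = overlap_projection_phantom
        assert truth.multi_population_fraction() == pytest.approx(0.3, abs=0.1)

    def test_superpixel_composition_matches_brute_force(self, small_projection_phantom):
        _, truth = small_projection_phantom
        b = truth.superpixel_block_px
        mem = truth.axon_membership
        for pop in range(3):
            for gy in range(mem.shape[1] // b):
                for gx in range(mem.shape[2] // b):
                    block = mem[pop, gy * b : (gy + 1) * b, gx * b : (gx + 1) * b]
                    assert truth.true_superpixel_composition[pop, gy, gx] == pytest.approx(
                        block.mean()
                    )

    def test_image_renders_exactly_its_membership(self, small_projection_phantom):
        image, truth = small_projection_phantom
        np.testing.assert_array_equal(image.data > 0, truth.axon_membership)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"shape": (0, 300)},
            {"shape": (301, 300)},  # not divisible by the block
            {"n_per_population": (0, 5, 5)},
            {"overlap_fraction": -0.1},
        ],
    )
    def test_invalid_parameters_raise(self, kwargs):
        base = dict(shape=(300, 300), n_per_population=(5, 5, 5), seed=0, block_px=30)
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            phantom.generate_projection_phantom(**base)


class TestTerritoryPhantom:
    def test_single_territory_fills_the_volume(self):
        _, truth = phantom.generate_territory_phantom(
            shape=(10, 12, 12), n_territories=1, n_colors=2, seed=0
        )
        assert set(np.unique(truth.territory_label_volume)) == {0}

    def test_nearest_seed_partition_matches_brute_force(self):
        _, truth = phantom.generate_territory_phantom(
            shape=(20, 20, 20), n_territories=6, n_colors=3, seed=3
        )
        seeds = truth.extras["seed_points"]
        coords = np.stack(
            np.meshgrid(*[np.arange(20) + 0.5] * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        dists = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=-1)
        expected = dists.argmin(axis=1).reshape(20, 20, 20)
        np.testing.assert_array_equal(truth.territory_label_volume, expected)

    def test_mean_contacts_per_territory_near_request(self):
        _, truth = phantom.generate_territory_phantom(
            shape=(30, 40, 40), n_territories=40, n_colors=4,
            somata_per_territory=12, seed=5,
        )
        counts = np.bincount(truth.contacted_soma_labels, minlength=40)
        # Poisson(12) mean over 40 territories: s.e. ~ sqrt(12/40) ~ 0.55
        assert counts.mean() == pytest.approx(12, abs=3 * 0.6)

    def test_every_soma_lies_inside_its_territory(self):
        img, truth = phantom.generate_territory_phantom(
            shape=(16, 20, 20), n_territories=5, n_colors=3,
            somata_per_territory=4, seed=9, voxel_size_um=(1.0, 1.0, 1.0),
        )
        for pos, label in zip(truth.soma_positions_um, truth.contacted_soma_labels):
            voxel = tuple((pos - 0.5).astype(int))
            assert truth.territory_label_volume[voxel] == label

    def test_too_many_territories_raise(self):
        with pytest.raises(InvalidParameterError):
            phantom.generate_territory_phantom(
                shape=(4, 4, 4), n_territories=100, n_colors=2, seed=0
            )

    def test_adjacency_is_symmetric_and_nonempty(self):
        _, truth = phantom.generate_territory_phantom(
            shape=(16, 16, 16), n_territories=8, n_colors=3, seed=1
        )
        pairs = phantom.territory_adjacency(truth.territory_label_volume)
        assert pairs and all(a < b for a, b in pairs)


class TestMixingAndNoise:
    def test_identity_model_zero_noise_is_identity(self, small_projection_phantom):
        image, _ = small_projection_phantom
        out = phantom.apply_mixing_and_noise(image, MixingModel(), gain=0.0)
        np.testing.assert_array_equal(out.data, image.data)

    def test_pure_red_pixel_follows_the_mixing_equations(self):
        px = np.zeros((3, 1, 1))
        px[0] = 1.0
        model = MixingModel(a_RG=0.2, a_RB=0.1)
        out = phantom.apply_mixing_and_noise(px, model, gain=0.0)
        np.testing.assert_allclose(out.data.ravel(), [1.0, 0.2, 0.1])

    def test_zero_image_stays_zero_under_any_model(self):
        model = MixingModel(a_GR=0.3, a_BG=0.2, a_RB=0.15)
        out = phantom.apply_mixing_and_noise(np.zeros((3, 8, 8)), model, gain=0.0)
        assert not out.data.any()

    def test_noise_is_seeded_and_non_negative(self):
        img = np.full((3, 32, 32), 4.0)
        a = phantom.apply_mixing_and_noise(img, MixingModel(), gain=50.0,
                                           read_noise_sd=0.5, seed=5)
        b = phantom.apply_mixing_and_noise(img, MixingModel(), gain=50.0,
                                           read_noise_sd=0.5, seed=5)
        np.testing.assert_array_equal(a.data, b.data)
        assert (a.data >= 0).all() and a.data.std() > 0


class TestBeadField:
    def test_zero_model_zero_noise_gives_zero_shifts(self):
        beads = phantom.generate_bead_field(50, 400.0, ChromaticShiftModel(), seed=0)
        assert (beads[["dx", "dy", "dz"]].to_numpy() == 0).all()

    def test_fixed_seed_reproduces_the_table(self):
        model = ChromaticShiftModel(lateral=[[1e-3, 0, 0.05], [0, 2e-3, 0]])
        a = phantom.generate_bead_field(100, 400.0, model, 0.05, seed=8)
        b = phantom.generate_bead_field(100, 400.0, model, 0.05, seed=8)
        assert a.equals(b)


class TestTileAndVignette:
    def test_layout_570_image_gives_2x2_grid_at_270_pitch(self):
        img = np.zeros((3, 570, 570))
        tiles_, truth = phantom.tile_and_vignette(img, 300, overlap_fraction=0.1)
        assert truth.extras["grid_shape"] == (2, 2)
        assert truth.extras["pitch_px"] == 270
        assert truth.true_tile_offsets == [(0, 0), (0, 270), (270, 0), (270, 270)]

    def test_last_tile_is_clamped_flush_with_the_edge(self):
        img = np.zeros((3, 540, 540))
        _, truth = phantom.tile_and_vignette(img, 300, overlap_fraction=0.1)
        assert truth.extras["grid_shape"] == (2, 2)
        assert truth.true_tile_offsets[-1] == (240, 240)

    def test_flat_profile_tiles_are_exact_crops(self, small_projection_phantom):
        image, _ = small_projection_phantom
        tiles_, truth = phantom.tile_and_vignette(image, 200, 0.2, profile_sigma_px=None)
        for t in tiles_:
            y, x = t.nominal_offset_px
            np.testing.assert_array_equal(
                t.pixels, image.data[:, y : y + 200, x : x + 200]
            )

    def test_reassembly_after_profile_division_recovers_the_image(
        self, small_projection_phantom
    ):
        from trichrome import tiles as tiles_mod

        image, _ = small_projection_phantom
        tile_list, truth = phantom.tile_and_vignette(image, 200, 0.2, profile_sigma_px=100)
        profile = tiles_mod.IlluminationProfile(truth.illumination_profile)
        corrected = [tiles_mod.flatfield_correct(t, profile) for t in tile_list]
        mosaic = tiles_mod.assemble_mosaic(corrected, truth.true_tile_offsets, "feather")
        np.testing.assert_allclose(mosaic, image.data, atol=1e-6)

    def test_profile_maximum_is_one(self):
        _, truth = phantom.tile_and_vignette(np.ones((3, 300, 300)), 150, 0.1,
                                             profile_sigma_px=60)
        assert truth.illumination_profile.max() == pytest.approx(1.0, abs=1e-12)

    def test_oversized_tile_raises(self):
        with pytest.raises(InvalidParameterError):
            phantom.tile_and_vignette(np.zeros((3, 100, 100)), 200, 0.1)


class TestAuxiliaryPhantoms:
    def test_interface_phantom_reports_its_own_geometry(self):
        pair, truth = phantom.generate_interface_phantom(
            tilt_deg=25.0, noise_sd_um=0.0, seed=2, rigid_motion=False
        )
        assert truth["tilt_deg"] == 25.0
        np.testing.assert_allclose(pair.points, truth["clean_points"])

    def test_color_combination_modes_are_separated(self):
        samples, truth = phantom.generate_color_combinations(20, 50, 0.02, seed=3)
        assert samples.shape == (1000, 3)
        np.testing.assert_allclose(samples.sum(axis=1), 1.0, atol=1e-12)
        assert truth["min_separation"] > 10 * truth["noise_sd"]
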