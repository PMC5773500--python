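"""Simulator ground-truth tests: determinism, photon budget, barrier physics."""

import numpy as np
import pytest

from carpetfcs.simcarpet import (
    BarrierSpec,
    PlacementError,
    SimulationConfig,
    SpeciesSpec,
    expected_mean_intensity,
    simulate_carpet,
    simulate_cotransport_stack,
    simulate_sphere_field,
    simulate_trajectories,
)


def _single_species_config(**overrides):
    defaults = dict(
        species=[SpeciesSpec(D_um2_per_s=2.0, brightness_cpsm=5.0, n_particles=200,
                             channel_weights=(0.0, 1.0))],
        n_pixels=64, n_lines=2000, seed=5,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestCarpetSimulation:
    def test_identical_config_and_seed_bit_identical(self):
        a = simulate_carpet(_single_species_config())
        b = simulate_carpet(_single_species_config())
        np.testing.assert_array_equal(a.data, b.data)

    def test_different_seed_differs(self):
        a = simulate_carpet(_single_species_config())
        b = simulate_carpet(_single_species_config(seed=6))
        assert (a.data != b.data).any()

    def test_no_emitters_no_background_all_zero(self):
        carpet = simulate_carpet(SimulationConfig(species=[], n_pixels=32,
                                                  n_lines=100, seed=1))
        assert carpet.data.sum() == 0

    def test_static_source_gives_constant_gaussian_profile(self):
        # one immobile particle on the pixel-50 center, expectation mode:
        # every line identical, column profile is the PSF
        px_um = 0.041
        cfg = SimulationConfig(
            species=[SpeciesSpec(D_um2_per_s=1.0, brightness_cpsm=10.0, n_particles=1,
                                 channel_weights=(1.0, 0.0), mobile_fraction=0.0,
                                 initial_positions_um=(((50 + 0.5) * px_um, 0.0),))],
            n_pixels=96, n_lines=50, seed=2,
        )
        carpet = simulate_carpet(cfg, expectation=True)
        lines = carpet.data[:, :, 0]
        np.testing.assert_allclose(lines - lines[0][None, :], 0.0, atol=1e-12)
        profile = lines[0]
        cols = np.arange(96)
        w_px = cfg.psf_waist_nm / cfg.pixel_size_nm
        expected = 10.0 * np.exp(-2.0 * (cols - 50.0) ** 2 / w_px**2)
        mask = expected > 1e-6
        np.testing.assert_allclose(profile[mask], expected[mask], rtol=1e-6)
        assert int(np.argmax(profile)) == 50

    def test_photon_conservation_in_expectation(self):
        cfg = _single_species_config(n_lines=12000, background_rate=0.3, seed=8)
        carpet = simulate_carpet(cfg)
        expected = expected_mean_intensity(cfg)[1]
        block_means = carpet.data[:, :, 1].reshape(20, -1).mean(axis=1)
        observed = block_means.mean()
        sem = block_means.std(ddof=1) / np.sqrt(len(block_means))
        assert abs(observed - expected) < 3 * sem + 1e-9

    def test_drift_free_displacement_moments(self):
        cfg = SimulationConfig(
            species=[SpeciesSpec(D_um2_per_s=2.0, brightness_cpsm=1.0,
                                 n_particles=1500, channel_weights=(1.0, 0.0))],
            n_pixels=64, n_lines=400, seed=3,
        )
        trajs = simulate_trajectories(cfg)
        xs = trajs[0]["xs"]
        Lx = cfg.field_length_um
        steps = np.diff(xs, axis=0)
        steps -= Lx * np.round(steps / Lx)  # unwrap periodic jumps
        disp = steps.sum(axis=0)
        T = (cfg.n_lines - 1) * cfg.line_period_s
        var_expected = 2 * cfg.species[0].D_um2_per_s * T
        se_mean = np.sqrt(var_expected / disp.size)
        assert abs(disp.mean()) < 4 * se_mean
        rel_tol = 4 * np.sqrt(2.0 / (disp.size - 1))
        assert abs(disp.var(ddof=1) / var_expected - 1) < rel_tol

    def test_impermeable_barrier_preserves_sides(self):
        cfg = _single_species_config(
            n_lines=3000,
            barrier=BarrierSpec(position_px=32, crossing_probability=0.0))
        trajs = simulate_trajectories(cfg)
        xb = 32 * cfg.pixel_size_nm * 1e-3
        sides = np.sign(trajs[0]["xs"] - xb)
        assert (sides == sides[0]).all()

    def test_thick_barrier_excludes_slab_and_preserves_sides(self):
        cfg = _single_species_config(
            n_lines=3000,
            barrier=BarrierSpec(position_px=32, crossing_probability=0.0,
                                thickness_um=0.4))
        trajs = simulate_trajectories(cfg)
        xb = 32 * cfg.pixel_size_nm * 1e-3
        xs = trajs[0]["xs"]
        assert (np.abs(xs - xb) >= 0.2 - 1e-12).all()
        sides = np.sign(xs - xb)
        assert (sides == sides[0]).all()

    def test_thick_barrier_transmission_jumps_the_slab(self):
        cfg = _single_species_config(
            n_lines=3000,
            barrier=BarrierSpec(position_px=32, crossing_probability=0.5,
                                thickness_um=0.4))
        trajs = simulate_trajectories(cfg)
        xb = 32 * cfg.pixel_size_nm * 1e-3
        xs = trajs[0]["xs"]
        assert (np.abs(xs - xb) >= 0.2 - 1e-12).all()
        assert (np.sign(xs - xb) != np.sign(xs[0] - xb)).any()

    def test_permeable_barrier_allows_crossings(self):
        cfg = _single_species_config(
            n_lines=3000,
            barrier=BarrierSpec(position_px=32, crossing_probability=0.5))
        trajs = simulate_trajectories(cfg)
        xb = 32 * cfg.pixel_size_nm * 1e-3
        sides = np.sign(trajs[0]["xs"] - xb)
        assert (sides != sides[0]).any()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="n_pixels and n_lines"):
            SimulationConfig(n_pixels=0)
        with pytest.raises(ValueError, match="crossing_probability"):
            BarrierSpec(position_px=10, crossing_probability=1.5)
        with pytest.raises(ValueError, match="summing to 1"):
            SpeciesSpec(D_um2_per_s=1, brightness_cpsm=1, n_particles=1,
                        channel_weights=(0.7, 0.7))
        with pytest.raises(ValueError, match="exceeds field_length_um"):
            SimulationConfig(n_pixels=64, pixel_size_nm=41, field_length_um=1.0)


class TestCotransportStack:
    def test_full_cotransport_channels_proportional(self):
        cfg = SimulationConfig(
            species=[SpeciesSpec(D_um2_per_s=3.0, brightness_cpsm=6.0, n_particles=40,
                                 channel_weights=(0.5, 0.5))],
            n_pixels=32, pixel_size_nm=200.0, seed=4)
        stack = simulate_cotransport_stack(cfg, n_frames=30, cotransport_fraction=1.0,
                                           expectation=True)
        np.testing.assert_allclose(stack.data[..., 0], stack.data[..., 1], rtol=1e-12)

    def test_zero_cotransport_channels_independent_particles(self):
        cfg = SimulationConfig(
            species=[SpeciesSpec(D_um2_per_s=3.0, brightness_cpsm=6.0, n_particles=40,
                                 channel_weights=(0.5, 0.5))],
            n_pixels=32, pixel_size_nm=200.0, seed=4)
        stack = simulate_cotransport_stack(cfg, n_frames=30, cotransport_fraction=0.0,
                                           expectation=True)
        a, b = stack.data[..., 0], stack.data[..., 1]
        assert not np.allclose(a, b)
        assert a.sum() > 0 and b.sum() > 0

    def test_fraction_bounds_validated(self):
        cfg = SimulationConfig(
            species=[SpeciesSpec(D_um2_per_s=1, brightness_cpsm=1, n_particles=2)],
            n_pixels=16, seed=0)
        with pytest.raises(ValueError, match="cotransport_fraction"):
            simulate_cotransport_stack(cfg, n_frames=10, cotransport_fraction=1.5)


class TestSphereField:
    def test_empty_field(self):
        field = simulate_sphere_field(0, 4.0, shape=(8, 16, 16), seed=0)
        assert field.stack.data.sum() == 0
        assert len(field.truth) == 0

    def test_truth_volume_matches_analytic_sphere(self):
        field = simulate_sphere_field(1, 4.0, shape=(24, 32, 32),
                                      voxel_size_nm=(55, 55, 55), seed=1)
        analytic = 4.0 / 3.0 * np.pi * 4.0**3
        assert abs(field.truth.loc[0, "volume_vox"] - analytic) / analytic < 0.1

    def test_spheres_do_not_overlap(self):
        field = simulate_sphere_field(6, 3.0, shape=(24, 48, 48),
                                      voxel_size_nm=(55, 55, 55), seed=2)
        c = field.truth[["center_z_um", "center_y_um", "center_x_um"]].to_numpy()
        r = field.truth["radius_um"].to_numpy()
        for i in range(len(c)):
            for j in range(i + 1, len(c)):
                assert np.linalg.norm(c[i] - c[j]) > r[i] + r[j]

    def test_impossible_placement_raises(self):
        with pytest.raises(PlacementError):
            simulate_sphere_field(30, 6.0, shape=(16, 20, 20),
                                  voxel_size_nm=(55, 55, 55), seed=3,
                                  max_tries_per_sphere=50)

    def test_nucleus_distances_signed(self):
        nuc = {"center_vox": (12, 24, 24), "semiaxes_vox": (8, 16, 16)}
        field = simulate_sphere_field(4, 2.5, shape=(24, 48, 48),
                                      voxel_size_nm=(55, 55, 55),
                                      nucleus_mask_spec=nuc, seed=4)
        # placement keeps spheres outside the nucleus: distances positive
        assert (field.truth["distance_to_ne_um"] > 0).all()
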