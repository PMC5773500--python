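"""Image pCF maps: identities, nulls, overlays and NE profiles."""

import numpy as np
import pytest

from carpetfcs.carpet_io import ImageStack
from carpetfcs.corrspec import correlate_series, make_lag_grid
from carpetfcs.pcfimage import (
    cross_pcf_map,
    overlay_pcf_maps,
    pcf_image_map,
    profile_across_ne,
)
from carpetfcs.simcarpet import SimulationConfig, SpeciesSpec, simulate_cotransport_stack


def _stack(data, frame_period_ms=10.0):
    return ImageStack(data=np.asarray(data), pixel_size_nm=200.0,
                      frame_period_ms=frame_period_ms)


def _correlated_half_stack(rng, n_frames=128, size=24):
    """Left half shares a slowly varying signal; right half is constant-rate."""
    t = np.arange(n_frames)
    drive = 4.0 + 2.0 * np.sin(2 * np.pi * t / 40.0)
    data = np.zeros((n_frames, size, size, 1))
    data[:, :, : size // 2, 0] = rng.poisson(drive[:, None, None],
                                             (n_frames, size, size // 2))
    data[:, :, size // 2:, 0] = rng.poisson(4.0, (n_frames, size, size - size // 2))
    return _stack(data)


class TestPcfImageMap:
    def test_temporally_constant_stack_zero_amplitude(self):
        data = np.full((128, 16, 16, 1), 5.0)
        amp = pcf_image_map(_stack(data), d_px=2)
        np.testing.assert_allclose(amp.masked[amp.valid], 0.0, atol=1e-10)

    def test_confined_signal_localized(self, rng):
        stack = _correlated_half_stack(rng)
        amp = pcf_image_map(stack, d_px=2, integral_mode="mean")
        left = np.nanmean(amp.masked[:, 2:8])
        right = np.nanmean(amp.masked[:, 16:22])
        assert left > 5 * abs(right)

    def test_d_zero_matches_column_acf_integral(self, rng):
        data = rng.poisson(5.0, (128, 6, 6, 1)).astype(float)
        stack = _stack(data)
        amp = pcf_image_map(stack, d_px=0, integral_mode="sum")
        lags = make_lag_grid(128, min_lag=1, max_lag=16)
        for y in range(6):
            for x in range(6):
                series = data[:, y, x, 0]
                vals, _ = correlate_series(series, series, lags)
                assert amp.values[y, x] == pytest.approx(vals.sum(), abs=1e-10)

    def test_short_stack_rejected(self, rng):
        data = rng.poisson(5.0, (32, 8, 8, 1))
        with pytest.raises(ValueError, match="64 frames"):
            pcf_image_map(_stack(data), d_px=2)

    def test_offset_larger_than_frame_rejected(self, rng):
        data = rng.poisson(5.0, (128, 8, 8, 1))
        with pytest.raises(ValueError, match="outside"):
            pcf_image_map(_stack(data), d_px=8)

    def test_frame_shuffle_destroys_amplitude(self, rng):
        stack = _correlated_half_stack(rng)
        amp = pcf_image_map(stack, d_px=2, integral_mode="mean")
        shuffled = _stack(stack.data[rng.permutation(stack.n_frames)])
        null = pcf_image_map(shuffled, d_px=2, integral_mode="mean")
        left = np.nanmean(amp.masked[:, 2:8])
        left_null = np.nanmean(null.masked[:, 2:8])
        assert left > 5 * abs(left_null)


class TestCrossPcf:
    def test_duplicated_channels_equal_single_channel_map(self, rng):
        one = rng.poisson(5.0, (128, 12, 12, 1)).astype(np.int32)
        dup = np.concatenate([one, one], axis=3)
        single = pcf_image_map(_stack(one), d_px=3)
        cross = cross_pcf_map(_stack(dup), d_px=3)
        np.testing.assert_allclose(cross.masked, single.masked, atol=1e-12)

    def test_single_channel_stack_rejected(self, rng):
        data = rng.poisson(5.0, (128, 8, 8, 1))
        with pytest.raises(ValueError, match="two-channel"):
            cross_pcf_map(_stack(data), d_px=2)

    def test_cotransport_raises_cross_amplitude(self):
        cfg = SimulationConfig(
            species=[SpeciesSpec(D_um2_per_s=3.5, brightness_cpsm=8.0,
                                 n_particles=100, channel_weights=(0.5, 0.5))],
            n_pixels=48, pixel_size_nm=200.0, psf_waist_nm=300.0,
            seed=91, background_rate=0.1)
        co = simulate_cotransport_stack(cfg, 192, 1.0, frame_period_ms=10.0)
        ind = simulate_cotransport_stack(cfg, 192, 0.0, frame_period_ms=10.0)
        m_co = np.nanmean(cross_pcf_map(co, d_px=4,
                                        direction_mode="radial_mean").masked)
        m_ind = np.nanmean(cross_pcf_map(ind, d_px=4,
                                         direction_mode="radial_mean").masked)
        assert m_co > m_ind + 0.1


class TestOverlay:
    def test_identical_maps_score_one(self, rng):
        data = rng.poisson(5.0, (128, 10, 10, 1)).astype(float)
        m = pcf_image_map(_stack(data), d_px=2)
        _, score = overlay_pcf_maps(m, m)
        assert score == 1.0

    def test_disjoint_supports_score_zero(self, rng):
        base = rng.poisson(5.0, (128, 10, 10, 1)).astype(float)
        m1 = pcf_image_map(_stack(base), d_px=2)
        m2 = pcf_image_map(_stack(base), d_px=2)
        m1.values = np.zeros_like(m1.values)
        m1.values[:5] = 1.0
        m2.values = np.zeros_like(m2.values)
        m2.values[6:] = 1.0
        m1.valid = np.ones_like(m1.valid)
        m2.valid = np.ones_like(m2.valid)
        _, score = overlay_pcf_maps(m1, m2)
        assert score == 0.0

    def test_cotransport_orders_overlay_scores(self):
        def score(fraction, seed):
            cfg = SimulationConfig(
                species=[SpeciesSpec(D_um2_per_s=3.5, brightness_cpsm=8.0,
                                     n_particles=100, channel_weights=(0.5, 0.5))],
                n_pixels=48, pixel_size_nm=200.0, psf_waist_nm=300.0,
                seed=seed, background_rate=0.1)
            st = simulate_cotransport_stack(cfg, 160, fraction, frame_period_ms=10.0)
            a = pcf_image_map(st, d_px=4, channel_pair=(0, 0))
            b = pcf_image_map(st, d_px=4, channel_pair=(1, 1))
            return overlay_pcf_maps(a, b)[1]

        co = np.median([score(1.0, s) for s in range(1, 6)])
        ind = np.median([score(0.0, s) for s in range(1, 6)])
        assert co > ind

    def test_shape_mismatch_rejected(self, rng):
        a = pcf_image_map(_stack(rng.poisson(5.0, (128, 8, 8, 1))), d_px=2)
        b = pcf_image_map(_stack(rng.poisson(5.0, (128, 10, 10, 1))), d_px=2)
        with pytest.raises(ValueError, match="shapes differ"):
            overlay_pcf_maps(a, b)


class TestProfileAcrossNe:
    def _uniform_maps(self, value=2.0, shape=(20, 30)):
        from carpetfcs.pcfimage import PcfAmplitudeMap

        values = np.full(shape, value)
        m = PcfAmplitudeMap(values=values, d_px=4, direction_mode="max",
                            tau_window_s=(0.01, 0.1), channel_pair=(0, 0),
                            valid=np.ones(shape, bool))
        return m

    def test_uniform_map_flat_unit_profile(self):
        m = self._uniform_maps()
        prof = profile_across_ne(m, m, ne_line=15.0, band_width_px=2)
        np.testing.assert_allclose(prof["profile_a"], 1.0)
        np.testing.assert_allclose(prof["profile_b"], 1.0)

    def test_profiles_normalized_to_unit_max(self, rng):
        from carpetfcs.pcfimage import PcfAmplitudeMap

        shape = (16, 40)
        a = PcfAmplitudeMap(values=rng.uniform(0.5, 3.0, shape), d_px=4,
                            direction_mode="max", tau_window_s=(0.01, 0.1),
                            channel_pair=(0, 0), valid=np.ones(shape, bool))
        b = PcfAmplitudeMap(values=rng.uniform(0.5, 3.0, shape), d_px=4,
                            direction_mode="max", tau_window_s=(0.01, 0.1),
                            channel_pair=(0, 1), valid=np.ones(shape, bool))
        prof = profile_across_ne(a, b, ne_line=20.0, band_width_px=3)
        assert prof["profile_a"].max() == pytest.approx(1.0)
        assert prof["profile_b"].max() == pytest.approx(1.0)

    def test_signed_distance_layout(self):
        from carpetfcs.pcfimage import PcfAmplitudeMap

        shape = (8, 30)
        values = np.tile(np.arange(30, dtype=float), (8, 1))
        m = PcfAmplitudeMap(values=values, d_px=4, direction_mode="max",
                            tau_window_s=(0.01, 0.1), channel_pair=(0, 0),
                            valid=np.ones(shape, bool))
        prof = profile_across_ne(m, m, ne_line=15.0, band_width_px=1)
        assert prof["distance_px"].min() < 0 < prof["distance_px"].max()
        # ramp increases with column -> profile increases with distance
        assert prof["profile_a"].iloc[-1] > prof["profile_a"].iloc[0]
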