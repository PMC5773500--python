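"""Number & brightness: moment formulas, scheme behaviour, peaks, histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carpetfcs.carpet_io import LineScanCarpet
from carpetfcs.numbright import (
    NBSegmentationScheme,
    brightness_vs_distance,
    detect_rare_peaks,
    joint_speed_partition,
    nb_aggregate,
    nb_compute,
)
from carpetfcs.fcsfit import FcsFitResult
from carpetfcs.simcarpet import SimulationConfig, SpeciesSpec, simulate_carpet
from carpetfcs.zones import assign_zones
from tests.conftest import poisson_carpet


def _carpet(data):
    return LineScanCarpet(data=np.asarray(data, float)[..., None],
                          pixel_size_nm=41.0, line_period_ms=1.5, dwell_time_us=2.0)


def _fit(column, d, valid=True):
    cls = "invalid" if not valid else ("fast" if d > 2 else "slow")
    return FcsFitResult(column=column, G0=0.1, tau_D_s=1e-3, D_um2_s=d,
                        chi2=1.0, dof=5, valid=valid, speed_class=cls)


class TestMoments:
    def test_direct_formula_substitution(self):
        # mean 10, variance 5  ->  N = 20, B = 0.5
        a = np.sqrt(5.0)
        col = np.tile([10 - a, 10 + a], 50)
        nb = nb_compute(_carpet(col[:, None]),
                        NBSegmentationScheme(mode="fast", block_lines=100))
        row = nb.iloc[0]
        assert row["mean_k"] == pytest.approx(10.0)
        assert row["var_k"] == pytest.approx(5.0, rel=0.02)
        assert row["N_apparent"] == pytest.approx(20.0, rel=0.03)
        assert row["B_apparent"] == pytest.approx(0.5, rel=0.03)

    def test_pure_shot_noise_brightness_unity(self, rng):
        carpet = poisson_carpet(20000, 16, 4.0, seed=31)
        nb = nb_compute(carpet, NBSegmentationScheme(mode="fast", block_lines=20000))
        assert nb["B_apparent"].mean() == pytest.approx(1.0, abs=0.03)
        assert (nb["N_apparent"] / nb["mean_k"]).mean() == pytest.approx(1.0, abs=0.03)

    def test_zero_variance_flagged(self):
        col = np.full((200, 1), 7.0)
        nb = nb_compute(_carpet(col), NBSegmentationScheme(mode="fast", block_lines=200))
        row = nb.iloc[0]
        assert not row["defined"]
        assert np.isnan(row["N_apparent"])
        assert row["B_apparent"] == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.5, max_value=50.0))
    def test_count_scaling_moves_brightness_not_number(self, c):
        r = np.random.default_rng(7)
        data = r.poisson(5.0, (400, 3)).astype(float) + 1.0
        base = nb_compute(_carpet(data), NBSegmentationScheme("fast", block_lines=400))
        scaled = nb_compute(_carpet(data * c), NBSegmentationScheme("fast", block_lines=400))
        np.testing.assert_allclose(scaled["N_apparent"], base["N_apparent"], rtol=1e-9)
        np.testing.assert_allclose(scaled["B_apparent"], base["B_apparent"] * c, rtol=1e-9)

    def test_sem_shrinks_with_more_segments(self, rng):
        carpet = poisson_carpet(40000, 4, 6.0, seed=32)
        few = nb_compute(carpet, NBSegmentationScheme("fast", block_lines=1000,
                                                      n_segments=10))
        many = nb_compute(carpet, NBSegmentationScheme("fast", block_lines=1000,
                                                       n_segments=40))
        sem_few = nb_aggregate(few)["sem_N"].mean()
        sem_many = nb_aggregate(many)["sem_N"].mean()
        # 4x the segments -> SEM halves, within statistical slack
        assert sem_many / sem_few == pytest.approx(0.5, abs=0.25)


@pytest.fixture(scope="module")
def fast_species_carpet():
    cfg = SimulationConfig(
        species=[SpeciesSpec(D_um2_per_s=11.0, brightness_cpsm=8.0,
                             n_particles=200, channel_weights=(0.0, 1.0))],
        n_pixels=96, n_lines=15000, seed=61, background_rate=0.05)
    return simulate_carpet(cfg)


@pytest.fixture(scope="module")
def aggregate_carpet():
    # near-immobile bright endosome-like structures: fluctuation period
    # far beyond one fast-scheme segment but inside the full record
    cfg = SimulationConfig(
        species=[SpeciesSpec(D_um2_per_s=0.004, brightness_cpsm=50.0,
                             n_particles=40, channel_weights=(0.0, 1.0))],
        n_pixels=96, n_lines=15000, seed=62, background_rate=0.5)
    return simulate_carpet(cfg)


class TestSchemes:
    def test_slow_scheme_suppresses_fast_species(self, fast_species_carpet):
        b_fast = nb_compute(fast_species_carpet,
                            NBSegmentationScheme("fast", block_lines=300),
                            channel=1)["B_apparent"].mean()
        b_slow = nb_compute(fast_species_carpet,
                            NBSegmentationScheme("slow", average_window=100),
                            channel=1)["B_apparent"].mean()
        assert b_slow < b_fast

    def test_slow_scheme_exposes_slow_aggregates(self, aggregate_carpet):
        b_fast = nb_compute(aggregate_carpet,
                            NBSegmentationScheme("fast", block_lines=300),
                            channel=1)["B_apparent"].mean()
        b_slow = nb_compute(aggregate_carpet,
                            NBSegmentationScheme("slow", average_window=100),
                            channel=1)["B_apparent"].mean()
        assert b_slow > b_fast

    def test_scheme_overrun_rejected(self, rng):
        carpet = poisson_carpet(150, 4, 3.0, seed=33)
        with pytest.raises(ValueError, match="need >= 2|lines per segment"):
            nb_compute(carpet, NBSegmentationScheme("slow", average_window=100))


class TestJointPartition:
    def test_matching_scheme_selected_and_invalid_excluded(self, rng):
        carpet = poisson_carpet(2000, 6, 5.0, seed=34)
        nb_fast = nb_compute(carpet, NBSegmentationScheme("fast", block_lines=500))
        nb_slow = nb_compute(carpet, NBSegmentationScheme("slow", average_window=10))
        fits = [_fit(0, 5.0), _fit(1, 0.5), _fit(2, 9.0), _fit(3, 1.0),
                _fit(4, 3.0, valid=False), _fit(5, 0.2)]
        joint = joint_speed_partition(nb_fast, nb_slow, fits)
        assert set(joint["column"]) == {0, 1, 2, 3, 5}
        assert (joint.loc[joint["speed_class"] == "fast", "column"].tolist() == [0, 2])

    def test_all_fast_leaves_no_slow_rows(self, rng):
        carpet = poisson_carpet(2000, 3, 5.0, seed=35)
        nb_fast = nb_compute(carpet, NBSegmentationScheme("fast", block_lines=500))
        nb_slow = nb_compute(carpet, NBSegmentationScheme("slow", average_window=10))
        joint = joint_speed_partition(nb_fast, nb_slow,
                                      [_fit(i, 8.0) for i in range(3)])
        assert (joint["speed_class"] == "fast").all()

    def test_column_mismatch_raises(self, rng):
        carpet = poisson_carpet(2000, 3, 5.0, seed=36)
        nb_fast = nb_compute(carpet, NBSegmentationScheme("fast", block_lines=500))
        nb_slow = nb_compute(carpet, NBSegmentationScheme("slow", average_window=10))
        with pytest.raises(ValueError, match="missing"):
            joint_speed_partition(nb_fast, nb_slow, [_fit(99, 5.0)])

    def test_brighter_species_shows_higher_brightness(self):
        rng = np.random.default_rng(8)
        Lx, Ly = 96 * 0.041, 12.0
        bright = tuple((float(x), float(y)) for x, y in
                       zip(rng.uniform(0, Lx / 2, 80), rng.uniform(0, Ly, 80)))
        dim = tuple((float(x), float(y)) for x, y in
                    zip(rng.uniform(Lx / 2, Lx, 80), rng.uniform(0, Ly, 80)))
        cfg = SimulationConfig(
            species=[SpeciesSpec(D_um2_per_s=3.0, brightness_cpsm=25.0,
                                 n_particles=80, channel_weights=(0.0, 1.0),
                                 initial_positions_um=bright),
                     SpeciesSpec(D_um2_per_s=3.0, brightness_cpsm=5.0,
                                 n_particles=80, channel_weights=(0.0, 1.0),
                                 initial_positions_um=dim)],
            n_pixels=96, n_lines=6000, seed=63, background_rate=0.05,
            barrier=None)
        from carpetfcs.simcarpet import BarrierSpec
        cfg.barrier = BarrierSpec(position_px=48, crossing_probability=0.0)
        carpet = simulate_carpet(cfg)
        nb = nb_compute(carpet, NBSegmentationScheme("fast", block_lines=300),
                        channel=1)
        agg = nb_aggregate(nb)
        left = agg[agg["column"] < 40]["mean_B"].mean()
        right = agg[agg["column"] >= 56]["mean_B"].mean()
        assert left > right


class TestBrightnessVsDistance:
    def _nb_frame(self, columns, b_values):
        return nb_compute(
            _carpet(np.tile(np.asarray(b_values) * 0 + 5.0, (100, 1))),
            NBSegmentationScheme("fast", block_lines=100),
        ).assign(column=columns, B_apparent=b_values, defined=True)

    def test_uniform_brightness_flat_histogram(self):
        cols = np.arange(20)
        nb = self._nb_frame(cols, np.full(20, 1.3))
        zm = assign_zones(10, 3, "left", 20)
        hist = brightness_vs_distance(nb, zm, pixel_size_nm=41.0, bin_width_um=0.2)
        np.testing.assert_allclose(hist["mean_B"], 1.3, rtol=1e-9)

    def test_peak_lands_in_planted_bin(self):
        cols = np.arange(60)
        b = np.full(60, 1.0)
        zm = assign_zones(40, 3, "left", 60)
        # plant high B one micron on the cytoplasmic side: column 40 - 24 px
        b[14:19] = 5.0
        nb = self._nb_frame(cols, b)
        hist = brightness_vs_distance(nb, zm, pixel_size_nm=41.0, bin_width_um=0.25)
        peak = hist.loc[hist["mean_B"].idxmax()]
        assert peak["bin_center_um"] == pytest.approx(-1.0, abs=0.25)

    def test_bin_width_change_preserves_peak_location(self):
        cols = np.arange(60)
        b = np.full(60, 1.0)
        b[14:19] = 5.0
        zm = assign_zones(40, 3, "left", 60)
        nb = self._nb_frame(cols, b)
        for width in (0.2, 0.4):
            hist = brightness_vs_distance(nb, zm, pixel_size_nm=41.0,
                                          bin_width_um=width)
            peak = hist.loc[hist["mean_B"].idxmax()]
            assert abs(peak["bin_center_um"] - (-1.0)) <= width

    def test_empty_input_empty_histogram(self):
        nb = self._nb_frame(np.arange(5), np.ones(5)).assign(defined=False)
        zm = assign_zones(2, 1, "left", 5)
        hist = brightness_vs_distance(nb, zm, pixel_size_nm=41.0)
        assert hist.empty


class TestDetectRarePeaks:
    def test_monotone_input_no_peaks(self):
        assert detect_rare_peaks(np.arange(100.0), min_prominence=1.0).empty

    def test_single_spike_found_at_position(self):
        s = np.zeros(200)
        s[77] = 10.0
        peaks = detect_rare_peaks(s, min_prominence=5.0)
        assert peaks["position"].tolist() == [77]
        assert peaks["height"].iloc[0] == pytest.approx(10.0)

    def test_planted_transits_recovered_without_false_positives(self, rng):
        t = np.arange(3000)
        s = rng.normal(10.0, 0.3, 3000)
        for pos in (400, 1500, 2600):
            s += 6.0 * np.exp(-0.5 * ((t - pos) / 8.0) ** 2)
        peaks = detect_rare_peaks(s, min_prominence=3.0, min_separation=50)
        assert len(peaks) == 3
        assert sorted(abs(p - q) < 10 for p, q in
                      zip(sorted(peaks["position"]), (400, 1500, 2600))) == [True] * 3
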