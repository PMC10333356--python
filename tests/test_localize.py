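import numpy as np
import pytest

from pamloc.geometry import Bearing, HydrophoneArray, bearing_to_unit_vector
from pamloc.localize import (
    AlignmentConvergenceError,
    LocalizationError,
    TDOASet,
    bearing_error,
    bearing_grid_search,
    elevation_error,
    estimate_alignment_offset,
    estimate_tdoas,
    predicted_tdoas,
)
from pamloc.simulate import MultichannelAudio

SR = 48_000.0
C = 1500.0


def audio_from(channels):
    return MultichannelAudio(channels=np.asarray(channels, float),
                             sample_rate=SR)


class TestEstimateTdoas:
    def test_identical_channels_zero_delay(self, chirp48k):
        x = np.concatenate([np.zeros(500), chirp48k.samples, np.zeros(500)])
        t = estimate_tdoas(audio_from([x, x]), ref_channel=0)
        assert t.delays[0] == pytest.approx(0.0, abs=0.1 / SR)

    def test_constructed_integer_shift(self, chirp48k):
        x = np.concatenate([np.zeros(500), chirp48k.samples, np.zeros(500)])
        y = np.roll(x, 13)
        t = estimate_tdoas(audio_from([x, y]), ref_channel=0)
        assert t.delays[0] == pytest.approx(13 / SR, abs=0.1 / SR)

    def test_reference_swap_negates_delay(self, chirp48k):
        x = np.concatenate([np.zeros(500), chirp48k.samples, np.zeros(500)])
        y = np.roll(x, 9)
        fwd = estimate_tdoas(audio_from([x, y]), ref_channel=0)
        rev = estimate_tdoas(audio_from([x, y]), ref_channel=1)
        assert fwd.delays[0] == pytest.approx(-rev.delays[0], abs=0.1 / SR)

    def test_phat_weighting_recovers_same_shift(self, chirp48k):
        x = np.concatenate([np.zeros(500), chirp48k.samples, np.zeros(500)])
        y = np.roll(x, 13)
        t = estimate_tdoas(audio_from([x, y]), ref_channel=0,
                           weighting="phat")
        assert t.delays[0] == pytest.approx(13 / SR, abs=0.2 / SR)

    def test_feasible_lag_clamp_uses_array_baselines(self, chirp48k,
                                                     long_arr):
        x = np.concatenate([np.zeros(500), chirp48k.samples, np.zeros(500)])
        channels = [np.roll(x, k) for k in range(long_arr.n_hydrophones)]
        t = estimate_tdoas(audio_from(channels), ref_channel=0,
                           array=long_arr)
        baselines = long_arr.baselines(0)
        for ch, delay in zip(t.channels, t.delays):
            assert abs(delay) <= baselines[ch] / C + 1.5 / SR

    def test_span_shorter_than_lag_window_rejected(self, long_arr):
        audio = audio_from(np.zeros((8, 100)))
        with pytest.raises(LocalizationError):
            estimate_tdoas(audio, span=(0.0, 100 / SR), array=long_arr)

    def test_single_channel_rejected(self):
        with pytest.raises(LocalizationError):
            estimate_tdoas(audio_from(np.zeros((1, 1000))))


class TestPredictedTdoas:
    def test_broadside_pair_zero_delay(self):
        arr = HydrophoneArray("pair", [[0, -1.5, 0], [0, 1.5, 0]])
        t = predicted_tdoas(arr, Bearing(90.0, 0.0), C, ref_channel=0)
        assert t.delays[0] == pytest.approx(0.0, abs=1e-15)

    def test_endfire_pair_full_delay(self):
        arr = HydrophoneArray("pair", [[0, -1.5, 0], [0, 1.5, 0]])
        t = predicted_tdoas(arr, Bearing(0.0, 0.0), C, ref_channel=0)
        # source ahead: channel 1 (forward) receives first, reference later
        assert abs(t.delays[0]) == pytest.approx(3.0 / C)

    def test_starboard_wave_hits_streamer_rows_together(self, long_arr):
        # at 90 deg the four cross-streamer pairs see identical delays
        t = predicted_tdoas(long_arr, Bearing(90.0, 0.0), C, ref_channel=0)
        delays = dict(zip(t.channels, t.delays))
        cross = [delays[4], delays[5], delays[6], delays[7]]
        np.testing.assert_allclose(cross, cross[0], atol=1e-15)
        # same-streamer partners are simultaneous
        np.testing.assert_allclose([delays[1], delays[2], delays[3]], 0.0,
                                   atol=1e-15)

    def test_sign_convention_matches_measurement(self):
        # a source at +90 deg reaches the starboard (+x) hydrophone first,
        # so its delay w.r.t. the port reference is negative
        arr = HydrophoneArray("pair", [[-2.0, 0, 0], [2.0, 0, 0]])
        t = predicted_tdoas(arr, Bearing(90.0, 0.0), C, ref_channel=0)
        assert t.delays[0] < 0


class TestBearingGridSearch:
    def test_exact_predicted_delays_recovered(self, long_arr):
        truth = Bearing(90.0, 0.0)
        measured = predicted_tdoas(long_arr, truth, C, ref_channel=0)
        est = bearing_grid_search(measured, long_arr, C)
        assert est.bearing.azimuth == pytest.approx(90.0, abs=1e-6)
        assert est.residual == pytest.approx(0.0, abs=1e-18)

    def test_matches_brute_force_scan(self, long_arr):
        """Grid minimum equals an independent exhaustive cost scan on 100
        random bearings."""
        rng = np.random.default_rng(42)
        res = 5.0
        azs = np.arange(-180.0, 180.0, res)
        els = np.arange(-90.0, 90.0 + res / 2, res)
        # oracle delay table, one predicted_tdoas call per grid point,
        # scanned azimuth-major / elevation-ascending
        grid = [(az, el) for az in azs for el in els]
        table = np.array([
            predicted_tdoas(long_arr, Bearing(az, el), C, ref_channel=0).delays
            for az, el in grid
        ])
        for _ in range(100):
            truth = Bearing(rng.uniform(-180, 180), rng.uniform(-90, 90))
            measured = predicted_tdoas(long_arr, truth, C, ref_channel=0)
            est = bearing_grid_search(measured, long_arr, C, resolution=res,
                                      refine=False, pairing="ref")
            costs = ((measured.delays[None, :] - table) ** 2).sum(axis=1)
            best_az, best_el = grid[int(np.argmin(costs))]
            assert est.bearing.azimuth == pytest.approx(best_az)
            assert est.bearing.elevation == pytest.approx(best_el)

    def test_refinement_improves_off_grid_bearing(self, long_arr):
        truth = Bearing(37.4, 0.0)
        measured = predicted_tdoas(long_arr, truth, C, ref_channel=0)
        coarse = bearing_grid_search(measured, long_arr, C, refine=False)
        fine = bearing_grid_search(measured, long_arr, C, refine=True)
        assert bearing_error(fine.bearing, truth) <= bearing_error(
            coarse.bearing, truth)
        assert bearing_error(fine.bearing, truth) < 0.2

    def test_planar_array_ties_resolve_downward(self, long_arr):
        measured = predicted_tdoas(long_arr, Bearing(45.0, -20.0), C,
                                   ref_channel=0)
        est = bearing_grid_search(measured, long_arr, C)
        assert est.bearing.elevation <= 0.0

    def test_empty_tdoa_set_rejected(self, long_arr):
        empty = TDOASet(ref_channel=0, channels=(), delays=np.array([]))
        with pytest.raises(LocalizationError):
            bearing_grid_search(empty, long_arr, C)


class TestBearingError:
    @pytest.mark.parametrize("a,b,expected", [
        (179.0, -179.0, 2.0),
        (0.0, 0.0, 0.0),
        (0.0, 90.0, 90.0),
        (-170.0, 170.0, 20.0),
    ])
    def test_wrapped_absolute_difference(self, a, b, expected):
        assert bearing_error(Bearing(a), Bearing(b)) == pytest.approx(expected)

    def test_elevation_reported_separately(self):
        assert elevation_error(Bearing(0, 10), Bearing(0, -5)) == 15.0


class TestAlignmentOffset:
    def test_identical_lists_converge_to_zero(self):
        ref = np.linspace(0, 350, 36)
        assert abs(estimate_alignment_offset(ref, ref)) < 0.01

    def test_recovers_constant_offset(self):
        ref = np.linspace(0, 350, 36)
        measured = (ref + 12.3) % 360
        offset = estimate_alignment_offset(measured, ref)
        assert offset == pytest.approx(12.3, abs=0.01)

    def test_recovers_offset_under_gaussian_noise(self):
        rng = np.random.default_rng(7)
        ref = rng.uniform(0, 360, size=500)
        measured = (ref + 12.3 + rng.normal(0, 5.0, size=500)) % 360
        offset = estimate_alignment_offset(measured, ref)
        assert offset == pytest.approx(12.3, abs=1.0)

    def test_nonconvergence_carries_last_iterate(self):
        # one iteration is not enough to verify a 170-degree offset
        ref = np.zeros(4)
        measured = np.full(4, 170.0)
        with pytest.raises(AlignmentConvergenceError) as excinfo:
            estimate_alignment_offset(measured, ref, tolerance=1e-9,
                                      max_iter=1)
        assert excinfo.value.last_offset == pytest.approx(170.0)

    def test_mismatched_lists_rejected(self):
        with pytest.raises(LocalizationError):
            estimate_alignment_offset(np.array([1.0]), np.array([]))
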