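"""Forward model, frequency filtering and delay-and-sum reconstruction."""

import numpy as np
import pytest
from scipy import fft

import paformat as pf
from paformat.simulate import Pulse, _grid_from_fov


def _single_detector_device(position, fov_half=30e-3):
    det = pf.DetectionElement(position=np.asarray(position, dtype=float),
                              orientation=np.array([0.0, 1.0, 0.0]))
    return pf.DeviceMetadata(
        field_of_view=np.array([-fov_half, fov_half, -fov_half, fov_half,
                                0.0, 0.0]),
        detectors=[det])


class TestForwardModel:
    def test_pulse_centre_lands_at_the_time_of_flight_sample(self):
        # distance 15 mm, c = 1500 m/s, fs = 40 MHz -> sample 400
        device = _single_detector_device([0.0, 15e-3, 0.0])
        sources = pf.PointSourceSet(positions=[[0.0, 0.0, 0.0]],
                                    pulse=Pulse(shape="gaussian"))
        data = pf.simulate_time_series(device, sources, speed_of_sound=1500.0,
                                       sampling_rate=40e6, n_samples=600)
        trace = data.tensor.values[0, :, 0, 0]
        assert int(np.argmax(trace)) == round(15e-3 / 1500.0 * 40e6) == 400

    def test_zero_sources_give_an_all_zero_tensor(self):
        device = _single_detector_device([0.0, 10e-3, 0.0])
        data = pf.simulate_time_series(
            device, pf.PointSourceSet(positions=np.empty((0, 3))),
            n_samples=128)
        assert not np.any(data.tensor.values)

    def test_amplitude_follows_the_inverse_distance_law(self):
        # distances chosen as whole sample multiples so the bipolar pulse's
        # extrema are sampled exactly and the ratio is exact
        c, fs = 1500.0, 40e6
        r = 200 * c / fs
        device = pf.DeviceMetadata(
            field_of_view=np.array([-0.05, 0.05, -0.05, 0.05, 0, 0]),
            detectors=[
                pf.DetectionElement(position=np.array([0.0, r, 0.0]),
                                    orientation=np.array([0.0, -1.0, 0.0])),
                pf.DetectionElement(position=np.array([0.0, 2 * r, 0.0]),
                                    orientation=np.array([0.0, -1.0, 0.0]))])
        pulse = Pulse(width=2 / fs)  # sigma = 2 samples
        sources = pf.PointSourceSet(positions=[[0.0, 0.0, 0.0]], pulse=pulse)
        data = pf.simulate_time_series(device, sources, speed_of_sound=c,
                                       sampling_rate=fs, n_samples=600)
        peak_near = np.abs(data.tensor.values[0, :, 0, 0]).max()
        peak_far = np.abs(data.tensor.values[1, :, 0, 0]).max()
        assert peak_near / peak_far == pytest.approx(2.0, rel=1e-2)

    def test_doubling_amplitudes_doubles_every_sample_exactly(self):
        device, sources = pf.demo_setup("arc180")
        base = pf.simulate_time_series(device, sources, n_samples=1200)
        doubled = pf.simulate_time_series(
            device,
            pf.PointSourceSet(positions=sources.positions, amplitudes=2.0,
                              pulse=sources.pulse),
            n_samples=1200)
        np.testing.assert_array_equal(doubled.tensor.values,
                                      2.0 * base.tensor.values)

    def test_fixed_seed_is_bit_reproducible(self):
        device, sources = pf.demo_setup("linear")
        first = pf.simulate_time_series(device, sources, n_samples=1200,
                                        noise_sd=0.1, seed=9)
        second = pf.simulate_time_series(device, sources, n_samples=1200,
                                         noise_sd=0.1, seed=9)
        assert first.equals(second)

    def test_insufficient_samples_error_cites_the_minimum(self):
        device = _single_detector_device([0.0, 30e-3, 0.0])
        sources = pf.PointSourceSet(positions=[[0.0, -20e-3, 0.0]])
        required = int(np.ceil((50e-3 / 1500.0 + 3 * 50e-9) * 40e6)) + 1
        with pytest.raises(ValueError) as err:
            pf.simulate_time_series(device, sources, n_samples=100)
        assert str(required) in str(err.value)

    def test_source_outside_fov_warns_but_simulates(self):
        device = _single_detector_device([0.0, 10e-3, 0.0], fov_half=5e-3)
        sources = pf.PointSourceSet(positions=[[0.0, -8e-3, 0.0]])
        with pytest.warns(UserWarning, match="field of view"):
            data = pf.simulate_time_series(device, sources, n_samples=1024)
        assert np.any(data.tensor.values)

    def test_simulated_dataset_is_complete_and_consistent(self):
        device, sources = pf.demo_setup("arc360")
        data = pf.simulate_time_series(device, sources, n_samples=1200,
                                       noise_sd=0.02, seed=0)
        report = pf.quality_check(data)
        assert report.overall_pass, report.failures()


class TestFrequencyFilter:
    @staticmethod
    def _impulse_data(filter_edges, n=4096, fs=40e6):
        data = pf.PAData(tensor=np.zeros((1, n)))
        data.tensor.values[0, n // 8, 0, 0] = 1.0
        data.acquisition["ad_sampling_rate"] = fs
        data.acquisition["frequency_domain_filter"] = np.asarray(filter_edges,
                                                                 dtype=float)
        return data

    @staticmethod
    def _response_db(data, frequency, fs=40e6):
        trace = data.tensor.values[0, :, 0, 0]
        spectrum = np.abs(fft.rfft(trace))
        freqs = fft.rfftfreq(trace.size, 1 / fs)
        return 20 * np.log10(spectrum[np.argmin(np.abs(freqs - frequency))])

    def test_lowpass_is_3db_down_at_the_stated_edge(self):
        data = self._impulse_data([-1.0, 5e6])
        out = pf.apply_frequency_filter(data)
        assert self._response_db(out, 5e6) == pytest.approx(-3.0, abs=0.5)
        assert self._response_db(out, 15e6) < -30

    def test_highpass_is_3db_down_and_kills_dc(self):
        data = self._impulse_data([1e6, -1.0])
        out = pf.apply_frequency_filter(data)
        assert self._response_db(out, 1e6) == pytest.approx(-3.0, abs=0.5)
        trace = out.tensor.values[0, :, 0, 0]
        assert abs(trace.sum()) < 1e-9  # DC fully attenuated

    def test_bandpass_hits_both_edges(self):
        data = self._impulse_data([1e6, 8e6])
        out = pf.apply_frequency_filter(data)
        assert self._response_db(out, 1e6) == pytest.approx(-3.0, abs=0.5)
        assert self._response_db(out, 8e6) == pytest.approx(-3.0, abs=0.5)

    def test_unset_sentinels_are_the_identity(self):
        data = self._impulse_data([-1.0, -1.0])
        out = pf.apply_frequency_filter(data)
        np.testing.assert_array_equal(out.tensor.values, data.tensor.values)
        assert out is not data  # new object, input untouched

    def test_edges_at_or_above_nyquist_are_rejected(self):
        with pytest.raises(ValueError):
            pf.apply_frequency_filter(self._impulse_data([-1.0, 20e6]))

    def test_missing_filter_tag_is_an_error(self):
        data = pf.PAData(tensor=np.zeros((1, 64)))
        data.acquisition["ad_sampling_rate"] = 40e6
        with pytest.raises(KeyError):
            pf.apply_frequency_filter(data)


class TestBackProjection:
    def test_point_source_recovered_by_full_ring(self):
        device = pf.build_arc_array(128, 20e-3, 2 * np.pi)
        truth = np.array([4e-3, -3e-3, 0.0])
        data = pf.simulate_time_series(
            device, pf.PointSourceSet(positions=[truth]), n_samples=1024)
        image, grid = pf.backproject(data, 0.25e-3)
        peak = pf.peak_location(image, grid)
        assert np.linalg.norm(peak - truth) <= 0.25e-3

    def test_linear_array_recovers_the_lateral_coordinate(self):
        device = pf.build_linear_array(128, 0.3e-3)
        truth = np.array([5e-3, 20e-3, 0.0])
        data = pf.simulate_time_series(
            device, pf.PointSourceSet(positions=[truth]), n_samples=1200)
        image, grid = pf.backproject(data, 0.25e-3)
        peak = pf.peak_location(image, grid)
        assert abs(peak[0] - truth[0]) <= 0.25e-3  # lateral within one cell

    def test_all_zero_tensor_maps_to_all_zero_image(self):
        device = pf.build_arc_array(16, 20e-3, 2 * np.pi)
        data = pf.simulate_time_series(
            device, pf.PointSourceSet(positions=np.empty((0, 3))),
            n_samples=512)
        image, _ = pf.backproject(data, 1e-3)
        assert not np.any(image)

    def test_gains_are_compensated(self):
        device = pf.build_arc_array(32, 20e-3, 2 * np.pi)
        truth = np.array([2e-3, 1e-3, 0.0])
        data = pf.simulate_time_series(
            device, pf.PointSourceSet(positions=[truth]), n_samples=1024)
        plain, grid = pf.backproject(data, 0.5e-3)
        data.acquisition["overall_gain"] = 4.0
        data.tensor.values[:] *= 4.0
        compensated, _ = pf.backproject(data, 0.5e-3)
        np.testing.assert_allclose(compensated, plain, rtol=1e-9)

    def test_heterogeneous_speed_of_sound_is_unsupported(self):
        device = pf.build_arc_array(16, 20e-3, 2 * np.pi)
        data = pf.simulate_time_series(
            device, pf.PointSourceSet(positions=[[0.0, 0.0, 0.0]]),
            n_samples=1024)
        data.acquisition["speed_of_sound"] = np.full((3, 3, 3), 1500.0)
        with pytest.raises(ValueError, match="heterogeneous"):
            pf.backproject(data, 1e-3)

    def test_incomplete_dataset_is_rejected(self, padata_factory):
        data = padata_factory()
        del data.acquisition["field_of_view"]
        with pytest.raises(ValueError, match="field_of_view"):
            pf.backproject(data, 1e-3)


class TestPeakLocation:
    def _grid(self):
        return _grid_from_fov(np.array([0, 4e-3, 0, 3e-3, 0, 0]), 1e-3)

    def test_delta_image_maps_to_its_cell_centre(self):
        grid = self._grid()
        image = np.zeros(grid.shape)
        image[2, 1, 0] = 1.0
        np.testing.assert_allclose(pf.peak_location(image, grid),
                                   [2e-3, 1e-3, 0.0])

    def test_ties_break_to_the_lowest_flat_index(self):
        grid = self._grid()
        image = np.zeros(grid.shape)
        image[1, 2, 0] = image[3, 1, 0] = 5.0
        np.testing.assert_allclose(pf.peak_location(image, grid),
                                   [1e-3, 2e-3, 0.0])

    def test_matches_brute_force_scan_on_random_images(self, rng):
        grid = self._grid()
        for _ in range(20):
            image = rng.normal(size=grid.shape)
            best = max(image.ravel())  # exhaustive scan, first occurrence
            index = next(i for i in np.ndindex(image.shape)
                         if image[i] == best)
            np.testing.assert_allclose(pf.peak_location(image, grid),
                                       grid.coordinate(index))

    def test_constant_image_has_no_peak(self):
        grid = self._grid()
        with pytest.raises(ValueError):
            pf.peak_location(np.ones(grid.shape), grid)
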