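"""Device factories: geometric oracles and consistency of the digital twins."""

import numpy as np
import pytest

import paformat as pf
from paformat.qualitycontrol import check_consistency


def _orientation_norms(device):
    return [np.linalg.norm(np.asarray(d.orientation)) for d in
            device.detectors + device.illuminators
            if d.orientation is not None]


class TestLinearArray:
    def test_lateral_extent_matches_pitch_arithmetic(self):
        device = pf.build_linear_array(128, 0.3e-3)
        positions = device.detector_positions()
        extent = positions[:, 0].max() - positions[:, 0].min()
        assert extent == pytest.approx((128 - 1) * 0.3e-3, abs=1e-12)
        assert positions[:, 0].mean() == pytest.approx(0.0, abs=1e-12)

    def test_single_element_sits_at_lateral_centre(self):
        device = pf.build_linear_array(1, 0.3e-3)
        np.testing.assert_allclose(device.detector_positions()[0],
                                   [0.0, 0.0, 0.0], atol=1e-15)

    def test_orientations_are_axial_unit_vectors(self):
        device = pf.build_linear_array(16, 0.2e-3)
        for det in device.detectors:
            np.testing.assert_allclose(det.orientation, [0.0, 1.0, 0.0])
        assert all(n == pytest.approx(1.0) for n in _orientation_norms(device))

    def test_elevation_axis_is_collapsed(self):
        fov = pf.build_linear_array(64, 0.3e-3).field_of_view
        assert fov[4] == fov[5] == 0.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            pf.build_linear_array(8, 0.0)
        with pytest.raises(ValueError):
            pf.build_linear_array(0, 0.3e-3)


class TestArcArray:
    def test_all_elements_sit_on_the_circle(self):
        centre = np.array([1e-3, -2e-3, 0.0])
        device = pf.build_arc_array(256, 40e-3, 2 * np.pi, center=centre)
        radii = np.linalg.norm(device.detector_positions() - centre, axis=1)
        np.testing.assert_allclose(radii, 40e-3, atol=1e-12)

    def test_half_circle_gaps_are_uniform(self):
        device = pf.build_arc_array(3, 10e-3, np.pi)
        positions = device.detector_positions()
        angles = np.unwrap(np.arctan2(positions[:, 1], positions[:, 0]))
        gaps = np.diff(angles)
        np.testing.assert_allclose(np.abs(gaps), np.pi / 2, atol=1e-12)

    def test_full_circle_minimum_distance_is_the_chord(self):
        n, radius = 256, 40e-3
        device = pf.build_arc_array(n, radius, 2 * np.pi)
        positions = device.detector_positions()
        diffs = np.linalg.norm(positions[:, None] - positions[None, :], axis=2)
        diffs[np.diag_indices(n)] = np.inf
        assert diffs.min() == pytest.approx(2 * radius * np.sin(np.pi / n),
                                            rel=1e-9)

    def test_full_circle_omits_duplicate_endpoint(self):
        device = pf.build_arc_array(8, 10e-3, 2 * np.pi)
        positions = device.detector_positions()
        assert np.unique(np.round(positions, 12), axis=0).shape[0] == 8

    def test_orientations_point_at_the_centre(self):
        centre = np.array([0.0, 5e-3, 0.0])
        device = pf.build_arc_array(16, 20e-3, np.pi, center=centre)
        for det in device.detectors:
            towards = centre - np.asarray(det.position)
            towards /= np.linalg.norm(towards)
            np.testing.assert_allclose(det.orientation, towards, atol=1e-12)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            pf.build_arc_array(8, -1e-3, np.pi)


class TestRandomArray:
    BOUNDS = [-20e-3, 20e-3, -10e-3, 30e-3, 0.0, 0.0]

    def test_same_seed_reproduces_the_device(self):
        first = pf.build_random_array(32, self.BOUNDS, seed=5)
        second = pf.build_random_array(32, self.BOUNDS, seed=5)
        assert first.equals(second)
        assert not first.equals(pf.build_random_array(32, self.BOUNDS, seed=6))

    def test_positions_stay_inside_bounds(self):
        device = pf.build_random_array(200, self.BOUNDS, seed=1)
        positions = device.detector_positions()
        bounds = np.asarray(self.BOUNDS)
        assert np.all(positions >= bounds[0::2] - 1e-15)
        assert np.all(positions <= bounds[1::2] + 1e-15)

    def test_empirical_mean_approaches_cuboid_centre(self):
        n = 10_000
        device = pf.build_random_array(n, self.BOUNDS, seed=11)
        positions = device.detector_positions()
        bounds = np.asarray(self.BOUNDS)
        centre = (bounds[0::2] + bounds[1::2]) / 2
        extent = bounds[1::2] - bounds[0::2]
        stderr = extent / np.sqrt(12 * n)
        for axis in range(2):  # x3 has zero extent
            assert abs(positions[:, axis].mean() - centre[axis]) \
                < 3 * stderr[axis]

    def test_fully_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            pf.build_random_array(4, [0, 0, 1e-3, 1e-3, 0, 0], seed=0)


class TestSlitIlluminators:
    def test_two_offsets_add_two_slits(self, linear_device):
        device = pf.add_slit_illuminators(linear_device, (-5.8e-3, 5.8e-3),
                                          tilt=np.deg2rad(25))
        assert device.num_illuminators == 2
        assert all(i.geometry_type == "slit" for i in device.illuminators)
        assert linear_device.num_illuminators == 0  # input untouched

    def test_empty_offsets_leave_device_unchanged(self, linear_device):
        device = pf.add_slit_illuminators(linear_device, ())
        assert device.equals(linear_device)

    def test_slit_geometry_roundtrips_through_the_container(self, tmp_path,
                                                            padata_factory):
        data = padata_factory(n_detectors=8)
        data.device = pf.add_slit_illuminators(data.device, (-5.8e-3, 5.8e-3),
                                               tilt=0.3)
        data.acquisition["device_reference_uuid"] = data.device.uuid
        path = tmp_path / "slits.hdf5"
        pf.write_ipasc(data, path)
        back = pf.read_ipasc(path)
        assert back.device.num_illuminators == 2
        assert all(a.equals(b) for a, b in
                   zip(back.device.illuminators, data.device.illuminators))


@pytest.mark.parametrize("factory", [
    lambda: pf.build_linear_array(32, 0.3e-3),
    lambda: pf.build_arc_array(64, 20e-3, np.pi),
    lambda: pf.build_arc_array(64, 20e-3, 2 * np.pi),
    lambda: pf.build_random_array(32, [-2e-2, 2e-2, -2e-2, 2e-2, 0, 0], seed=3),
    lambda: pf.add_slit_illuminators(pf.build_linear_array(32, 3e-4),
                                     (-5e-3, 5e-3), tilt=0.4),
])
def test_every_factory_output_is_internally_consistent(factory):
    data = pf.PAData(device=factory())
    assert all(item.ok for item in check_consistency(data))
    factory().validate()  # strict element validation also passes
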