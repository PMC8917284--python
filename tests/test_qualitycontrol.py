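"""Completeness/consistency auditing, report rendering, visual control."""

import numpy as np
import pytest

import paformat as pf
from paformat.qualitycontrol import check_completeness, check_consistency


def _completeness_map(data):
    return {item.tag: item for item in check_completeness(data)}


def _consistency_map(data):
    return {item.tag: item for item in check_consistency(data)}


class TestCompleteness:
    def test_fully_populated_dataset_passes(self, complete_padata):
        report = pf.quality_check(complete_padata)
        assert report.overall_pass
        assert not report.failures()

    @pytest.mark.parametrize("tag", ["uuid", "compression", "encoding",
                                     "ad_sampling_rate",
                                     "acquisition_wavelengths",
                                     "field_of_view"])
    def test_each_missing_minimal_tag_flips_to_fail(self, tag,
                                                    padata_factory):
        data = padata_factory()
        del data.acquisition[tag]
        report = pf.quality_check(data)
        assert not report.overall_pass
        assert tag in report.failures()
        assert f"[FAIL] {tag}" in report.render()

    def test_missing_tensor_fails_binary_descriptors(self, padata_factory):
        data = padata_factory()
        data.tensor = None
        failures = pf.quality_check(data).failures()
        assert {"data_type", "dimensionality", "sizes"} <= set(failures)

    def test_missing_device_fails_detector_positions(self, padata_factory):
        data = padata_factory()
        data.device = None
        assert "detector_position" in pf.quality_check(data).failures()

    def test_absent_optional_tag_is_informational(self, complete_padata):
        items = _completeness_map(complete_padata)
        assert not items["pulse_energy"].present
        assert not items["pulse_energy"].failing
        assert pf.quality_check(complete_padata).overall_pass


class TestConsistency:
    def test_positive_scalar_speed_of_sound_is_ok(self, complete_padata):
        assert _consistency_map(complete_padata)["speed_of_sound"].ok

    def test_detector_count_mismatch_is_flagged(self, padata_factory):
        data = padata_factory(n_detectors=4)
        data.device = pf.build_linear_array(3, 0.3e-3)
        data.acquisition.set_unchecked("device_reference_uuid",
                                       data.device.uuid)
        item = _consistency_map(data)["tensor_vs_detector_count"]
        assert not item.ok and "3" in item.message and "4" in item.message
        assert not pf.quality_check(data).overall_pass

    def test_wavelength_count_mismatch_is_flagged(self, padata_factory):
        data = padata_factory(n_wavelengths=2)
        data.acquisition["acquisition_wavelengths"] = np.array([700e-9])
        assert not _consistency_map(data)["tensor_vs_wavelength_count"].ok

    def test_misordered_filter_edges_are_flagged(self, padata_factory):
        data = padata_factory()
        data.acquisition.set_unchecked("frequency_domain_filter",
                                       np.array([5e6, 1e6]))
        item = _consistency_map(data)["frequency_domain_filter"]
        assert not item.ok

    def test_device_reference_mismatch_is_flagged(self, padata_factory):
        data = padata_factory()
        data.acquisition.set_unchecked("device_reference_uuid", "feedface")
        assert not _consistency_map(data)["device_reference_uuid_match"].ok

    def test_full_scan_requires_single_measurement_per_image(
            self, padata_factory):
        data = padata_factory()
        data.acquisition.set_unchecked("measurements_per_image", 4)
        item = _consistency_map(data)["full_scan_measurements_per_image"]
        assert not item.ok
        assert not pf.quality_check(data).overall_pass

    def test_gain_length_mismatch_is_flagged(self, padata_factory):
        data = padata_factory(n_detectors=4)
        data.acquisition.set_unchecked("element_dependent_gain", np.ones(3))
        assert not _consistency_map(data)["element_dependent_gain_length"].ok

    def test_optional_violations_are_warnings_not_failures(
            self, padata_factory):
        data = padata_factory()
        data.acquisition.set_unchecked("temperature_control", np.array([-5.0]))
        report = pf.quality_check(data)
        assert "temperature_control" in report.warnings()
        assert report.overall_pass and not report.strict_pass

    def test_strict_construction_never_fails_consistency(self):
        data = pf.PAData(tensor=np.zeros((4, 16)),
                         device=pf.build_linear_array(4, 0.3e-3))
        for tag, value in [
                ("uuid", "ab12"), ("compression", "none"), ("encoding", "raw"),
                ("ad_sampling_rate", 40e6),
                ("acquisition_wavelengths", np.array([800e-9])),
                ("field_of_view", np.asarray(data.device.field_of_view)),
                ("speed_of_sound", 1500.0),
                ("scanning_method", "full_scan"),
                ("measurements_per_image", 1),
                ("device_reference_uuid", data.device.uuid),
                ("overall_gain", 2.0),
                ("element_dependent_gain", np.ones(4)),
                ("time_gain_compensation", np.ones(16))]:
            pf.set_metadatum(data, tag, value)
        assert all(item.ok for item in check_consistency(data))


class TestReport:
    def test_passing_report_contains_overall_pass_marker(self,
                                                         complete_padata,
                                                         tmp_path):
        report = pf.quality_check(complete_padata)
        path = tmp_path / "report.txt"
        pf.write_report(report, path)
        assert "Overall: PASS" in path.read_text()

    def test_single_failure_yields_exactly_one_fail_line(self, padata_factory,
                                                         tmp_path):
        data = padata_factory()
        del data.acquisition["ad_sampling_rate"]
        report = pf.quality_check(data)
        pf.write_report(report, tmp_path / "report.txt")
        text = (tmp_path / "report.txt").read_text()
        fail_lines = [l for l in text.splitlines() if l.startswith("[FAIL]")]
        assert len(fail_lines) == 1 and "ad_sampling_rate" in fail_lines[0]
        assert "Overall: FAIL" in text

    def test_identical_reports_are_byte_identical(self, padata_factory,
                                                  tmp_path):
        first, second = tmp_path / "a.txt", tmp_path / "b.txt"
        pf.write_report(pf.quality_check(padata_factory()), first)
        pf.write_report(pf.quality_check(padata_factory()), second)
        assert first.read_bytes() == second.read_bytes()


class TestVisualControl:
    def test_linear_probe_with_slits_renders(self, tmp_path):
        device = pf.add_slit_illuminators(
            pf.build_linear_array(128, 0.3e-3), (-5.8e-3, 5.8e-3),
            tilt=np.deg2rad(25))
        out = tmp_path / "probe.png"
        pf.visualize_device(device, out)
        assert out.stat().st_size > 0

    def test_circular_tomograph_renders(self, tmp_path):
        device = pf.build_arc_array(256, 40e-3, 2 * np.pi)
        out = tmp_path / "ring.png"
        pf.visualize_device(device, out)
        assert out.stat().st_size > 0

    def test_single_detector_at_origin_renders(self, tmp_path):
        device = pf.DeviceMetadata(detectors=[pf.DetectionElement(
            position=np.zeros(3), orientation=np.array([0.0, 1.0, 0.0]))])
        pf.visualize_device(device, tmp_path / "one.png")
        assert (tmp_path / "one.png").exists()

    def test_empty_device_is_an_error(self, tmp_path):
        with pytest.raises(ValueError):
            pf.visualize_device(pf.DeviceMetadata(), tmp_path / "x.png")
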