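"""Randomised dataset construction for validation of the container format.

:func:`random_padata` draws a structurally valid dataset with random tensor
shape and dtype, a random device, and a random subset of the optional
metadata tags (with lengths kept coherent with the tensor axes).  It is the
workhorse behind the round-trip identity property: whatever subset of the
schema a file exercises, write -> read must reproduce it field by field.
"""

from __future__ import annotations

import numpy as np

from .metadata import (
    AcquisitionMetadata,
    DetectionElement,
    DeviceMetadata,
    IlluminationElement,
    MeasurementDeviceInfo,
    PAData,
    TimeSeriesTensor,
)
from .registry import SCANNING_METHODS

__all__ = ["random_padata"]

_TENSOR_DTYPES = (np.int16, np.int32, np.float32, np.float64)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    vec = rng.normal(size=3)
    return vec / np.linalg.norm(vec)


def _random_device(rng: np.random.Generator, n_detectors: int) -> DeviceMetadata:
    device = DeviceMetadata(
        uuid=rng.bytes(16).hex(),
        field_of_view=np.sort(rng.uniform(-30e-3, 30e-3, 6).reshape(3, 2),
                              axis=1).ravel())
    for _ in range(n_detectors):
        element = DetectionElement(
            position=rng.uniform(-25e-3, 25e-3, 3),
            orientation=_random_unit(rng))
        if rng.random() < 0.5:
            element.geometry_type = "point"
        if rng.random() < 0.5:
            element.frequency_response = np.array([rng.uniform(1e6, 10e6),
                                                   rng.uniform(1e6, 8e6)])
        if rng.random() < 0.3:
            angles = np.linspace(0, np.pi / 2, 5)
            element.angular_response = np.stack([angles, np.cos(angles)])
        device.detectors.append(element)
    for _ in range(int(rng.integers(0, 3))):
        illuminator = IlluminationElement(
            position=rng.uniform(-25e-3, 25e-3, 3),
            orientation=_random_unit(rng),
            geometry_type="slit",
            geometry=rng.uniform(1e-3, 20e-3, 2))
        if rng.random() < 0.5:
            low = rng.uniform(600e-9, 800e-9)
            illuminator.wavelength_range = np.array(
                [low, low + rng.uniform(0, 400e-9), 1e-9])
        if rng.random() < 0.4:
            illuminator.pulse_duration = rng.uniform(1e-9, 20e-9)
        if rng.random() < 0.3:
            wl = np.linspace(680e-9, 950e-9, 4)
            illuminator.laser_energy_profile = np.stack(
                [wl, rng.uniform(1e-3, 30e-3, 4)])
        device.illuminators.append(illuminator)
    return device


def random_padata(rng: np.random.Generator) -> PAData:
    """One random, minimally complete dataset with a random optional-tag
    subset; always passes the completeness gate of the writer."""
    n_det = int(rng.integers(1, 9))
    n_samples = int(rng.integers(4, 65))
    n_wl = int(rng.integers(1, 4))
    n_meas = int(rng.integers(1, 3))
    dtype = _TENSOR_DTYPES[int(rng.integers(len(_TENSOR_DTYPES)))]
    shape = (n_det, n_samples, n_wl, n_meas)
    if np.issubdtype(dtype, np.integer):
        values = rng.integers(-30000, 30000, size=shape).astype(dtype)
    else:
        values = rng.normal(size=shape).astype(dtype)

    device = _random_device(rng, n_det)
    acq = AcquisitionMetadata()
    acq["uuid"] = rng.bytes(16).hex()
    acq["compression"] = "none"
    acq["encoding"] = "raw"
    acq["ad_sampling_rate"] = float(rng.uniform(10e6, 100e6))
    acq["acquisition_wavelengths"] = rng.uniform(650e-9, 1100e-9, n_wl)
    acq["field_of_view"] = np.asarray(device.field_of_view, dtype=float)

    if rng.random() < 0.8:
        acq["device_reference_uuid"] = device.uuid
    if rng.random() < 0.5:
        acq["pulse_energy"] = (float(rng.uniform(1e-3, 50e-3))
                               if rng.random() < 0.5
                               else rng.uniform(1e-3, 50e-3, n_meas))
    if rng.random() < 0.4:
        acq["measurement_timestamps"] = np.sort(rng.uniform(0, 10, n_meas))
    if rng.random() < 0.3:
        acq["measurement_spatial_poses"] = np.concatenate(
            [np.zeros((1, 6)), rng.normal(0, 1e-3, (n_meas - 1, 6))])
    if rng.random() < 0.4:
        acq["time_gain_compensation"] = rng.uniform(0.5, 4.0, n_samples)
    if rng.random() < 0.4:
        acq["overall_gain"] = float(rng.uniform(0.5, 10.0))
    if rng.random() < 0.4:
        acq["element_dependent_gain"] = rng.uniform(0.5, 2.0, n_det)
    if rng.random() < 0.3:
        acq["temperature_control"] = rng.uniform(290.0, 310.0, n_meas)
    if rng.random() < 0.4:
        acq["acoustic_coupling_agent"] = str(
            rng.choice(["water", "ultrasound gel", "heavy water"]))
    if rng.random() < 0.7:
        acq["speed_of_sound"] = (float(rng.uniform(1400, 1600))
                                 if rng.random() < 0.8
                                 else rng.uniform(1400, 1600, (3, 3, 3)))
    if rng.random() < 0.6:
        method = str(rng.choice(SCANNING_METHODS))
        acq["scanning_method"] = method
        acq["measurements_per_image"] = (1 if method == "full_scan"
                                         else int(rng.integers(1, 9)))
    if rng.random() < 0.4:
        choice = rng.random()
        if choice < 1 / 3:
            acq["frequency_domain_filter"] = np.array([-1.0, rng.uniform(1e6, 9e6)])
        elif choice < 2 / 3:
            acq["frequency_domain_filter"] = np.array([rng.uniform(1e4, 1e6), -1.0])
        else:
            low = rng.uniform(1e4, 1e6)
            acq["frequency_domain_filter"] = np.array(
                [low, low + rng.uniform(1e6, 9e6)])
    if rng.random() < 0.3:
        acq["regions_of_interest"] = {
            "lesion_1": np.sort(rng.uniform(-20e-3, 20e-3, 6).reshape(3, 2),
                                axis=1).ravel(),
            "vessel": rng.uniform(-20e-3, 20e-3, (4, 3)),
        }
    if rng.random() < 0.3:
        acq.measurement_devices["pulse_energy"] = MeasurementDeviceInfo(
            device_type="pyroelectric sensor", manufacturer="ACME",
            serial_number=str(int(rng.integers(10000, 99999))),
            calibration_date="2025-06-01T12:00:00")

    custom = {}
    if rng.random() < 0.5:
        custom["lab_notes"] = "phantom A"
    if rng.random() < 0.3:
        custom["operator_id"] = int(rng.integers(1, 100))
    if rng.random() < 0.3:
        custom["prototype_gain_curve"] = rng.uniform(0, 1, 7)
    if rng.random() < 0.2:
        custom["session"] = {"room": "B12", "repeat": int(rng.integers(1, 4))}

    return PAData(tensor=TimeSeriesTensor(values), acquisition=acq,
                  device=device, custom=custom)
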