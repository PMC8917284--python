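"""Conversion adapters: proprietary vendor data -> consensus format.

An adapter supplies three generators — the binary time-series payload, the
acquisition metadata and the device metadata — and may add custom items.
:func:`convert` assembles these into a :class:`PAData`, verifies that the
minimal metadata set is covered (a gap is a hard conversion error) and runs
the quality-control engine, attaching its report to the result; issues on
report-if-present tags are warnings in the report, never fatal.

Adapters are the single unit-normalisation boundary: whatever convention a
vendor file uses (nanometre wavelength lists, millimetre pitches), the
adapter converts to strict SI before anything reaches the core model.

A fully worked reference adapter is included for a simple fixture dialect:
a flat little-endian ``int16`` blob (detector-major, then sample-major, then
wavelength) next to a ``key=value`` text sidecar describing the acquisition.
It stands in for the proprietary formats real vendors ship and doubles as
the template for third-party adapter authors.
"""

from __future__ import annotations

import os
from abc import ABC, abstractmethod
from typing import Any

import numpy as np

from .devices import build_linear_array
from .iohandler import missing_minimal_tags
from .metadata import AcquisitionMetadata, DeviceMetadata, PAData, TimeSeriesTensor
from .qualitycontrol import quality_check
from .registry import MINIMAL_TAGS

__all__ = [
    "Adapter",
    "ConversionError",
    "convert",
    "list_required_generators",
    "required_minimal_tags",
    "VendorFixtureAdapter",
    "write_vendor_fixture",
]

#: Names of the generator operations every adapter must implement.
_GENERATORS = ("binary_data", "acquisition_metadata", "device_metadata")


class ConversionError(ValueError):
    """The adapter output does not cover the minimal metadata set."""


class Adapter(ABC):
    """Contract for vendor-format conversion.

    Subclasses implement the three required generators; the returned
    acquisition and device metadata together must cover every minimal tag.
    """

    @abstractmethod
    def generate_binary_data(self) -> np.ndarray:
        """The raw payload in canonical axis order
        [detectors, time_samples, wavelengths, measurements]."""

    @abstractmethod
    def generate_acquisition_metadata(self) -> AcquisitionMetadata:
        """Container and acquisition tags, in SI units."""

    @abstractmethod
    def generate_device_metadata(self) -> DeviceMetadata:
        """The device digital twin, supplied inline (no external database)."""

    def generate_custom_metadata(self) -> dict[str, Any]:
        """Optional vendor-specific extras for the custom namespace."""
        return {}


def list_required_generators() -> list[str]:
    """The three generator operations an adapter must provide."""
    return list(_GENERATORS)


def required_minimal_tags() -> frozenset[str]:
    """The minimal tag set the generators must jointly cover."""
    return frozenset(MINIMAL_TAGS)


def convert(adapter: Adapter) -> PAData:
    """Run an adapter and return a quality-checked :class:`PAData`.

    Raises :class:`ConversionError` listing the gaps when the adapter output
    misses minimal metadata.  The quality-control report is attached as
    ``result.qc_report``.
    """
    data = PAData(tensor=TimeSeriesTensor(adapter.generate_binary_data()),
                  acquisition=adapter.generate_acquisition_metadata(),
                  device=adapter.generate_device_metadata(),
                  custom=adapter.generate_custom_metadata())
    missing = missing_minimal_tags(data)
    if missing:
        raise ConversionError(
            f"adapter {type(adapter).__name__} did not provide the minimal "
            "metadata: " + ", ".join(missing))
    data.qc_report = quality_check(data)
    return data


# ---------------------------------------------------------------------------
# reference fixture dialect

_SIDE_CAR_KEYS = ("sampling_rate_hz", "wavelengths_nm", "n_detectors",
                  "n_samples", "detector_pitch_mm", "speed_of_sound_m_s")


def _parse_sidecar(path: str) -> dict[str, str]:
    values: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConversionError(
                    f"sidecar line {line!r} is not of the form key=value")
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
    return values


class VendorFixtureAdapter(Adapter):
    """Reference adapter for the fixture dialect (``.bin`` + ``.txt``).

    The blob stores signed little-endian 16-bit integers in C order with
    detectors as the slowest axis, then time samples, then wavelengths.  The
    sidecar carries the acquisition parameters in vendor units (Hz, nm, mm);
    this adapter converts them to SI.
    """

    def __init__(self, sidecar_path: str | os.PathLike):
        self.sidecar_path = os.fspath(sidecar_path)
        self.blob_path = os.path.splitext(self.sidecar_path)[0] + ".bin"
        params = _parse_sidecar(self.sidecar_path)
        missing = [k for k in _SIDE_CAR_KEYS if k not in params]
        if missing:
            raise ConversionError(
                "sidecar is missing required keys: " + ", ".join(missing))
        self.sampling_rate = float(params["sampling_rate_hz"])
        self.wavelengths = np.array(
            [float(v) * 1e-9 for v in params["wavelengths_nm"].split(",")])
        self.n_detectors = int(params["n_detectors"])
        self.n_samples = int(params["n_samples"])
        self.pitch = float(params["detector_pitch_mm"]) * 1e-3
        self.speed_of_sound = float(params["speed_of_sound_m_s"])
        self._device: DeviceMetadata | None = None

    def generate_binary_data(self) -> np.ndarray:
        n_values = self.n_detectors * self.n_samples * self.wavelengths.size
        blob = np.fromfile(self.blob_path, dtype="<i2")
        if blob.size != n_values:
            raise ConversionError(
                f"blob holds {blob.size} int16 values but the sidecar "
                f"declares {n_values} "
                f"({self.n_detectors} detectors x {self.n_samples} samples x "
                f"{self.wavelengths.size} wavelengths)")
        return blob.reshape(self.n_detectors, self.n_samples,
                            self.wavelengths.size)

    def generate_device_metadata(self) -> DeviceMetadata:
        if self._device is None:
            self._device = build_linear_array(self.n_detectors, self.pitch)
        return self._device

    def generate_acquisition_metadata(self) -> AcquisitionMetadata:
        from .metadata import new_hex_uuid

        device = self.generate_device_metadata()
        acquisition = AcquisitionMetadata()
        acquisition["uuid"] = new_hex_uuid()
        acquisition["compression"] = "none"
        acquisition["encoding"] = "raw"
        acquisition["ad_sampling_rate"] = self.sampling_rate
        acquisition["acquisition_wavelengths"] = self.wavelengths
        acquisition["field_of_view"] = np.asarray(device.field_of_view,
                                                  dtype=float)
        acquisition["speed_of_sound"] = self.speed_of_sound
        acquisition["scanning_method"] = "full_scan"
        acquisition["measurements_per_image"] = 1
        acquisition["device_reference_uuid"] = device.uuid
        return acquisition

    def generate_custom_metadata(self) -> dict[str, Any]:
        return {"vendor_dialect": "fixture-v1",
                "vendor_sidecar": os.path.basename(self.sidecar_path)}


def write_vendor_fixture(stem: str | os.PathLike,
                         values: np.ndarray,
                         sampling_rate_hz: float = 40e6,
                         wavelengths_nm=(700.0,),
                         detector_pitch_mm: float = 0.3,
                         speed_of_sound_m_s: float = 1500.0) -> str:
    """Write a fixture-dialect pair (``<stem>.bin`` + ``<stem>.txt``).

    ``values`` must be int16-representable with shape (detectors, samples)
    or (detectors, samples, wavelengths).  Returns the sidecar path.  Used
    to generate test inputs programmatically.
    """
    stem = os.fspath(stem)
    arr = np.asarray(values)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError("fixture payload must be 2-D or 3-D")
    wavelengths_nm = tuple(float(w) for w in wavelengths_nm)
    if arr.shape[2] != len(wavelengths_nm):
        raise ValueError("wavelength axis does not match wavelengths_nm")
    arr.astype("<i2").tofile(stem + ".bin")
    sidecar = stem + ".txt"
    with open(sidecar, "w", encoding="utf-8") as handle:
        handle.write(f"sampling_rate_hz={sampling_rate_hz:g}\n")
        handle.write("wavelengths_nm=" + ",".join(f"{w:g}" for w in wavelengths_nm) + "\n")
        handle.write(f"n_detectors={arr.shape[0]}\n")
        handle.write(f"n_samples={arr.shape[1]}\n")
        handle.write(f"detector_pitch_mm={detector_pitch_mm:g}\n")
        handle.write(f"speed_of_sound_m_s={speed_of_sound_m_s:g}\n")
    return sidecar
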