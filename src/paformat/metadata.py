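"""In-memory containers for photoacoustic raw datasets.

The object model mirrors the container layout: a 4-D raw time-series tensor,
an acquisition-metadata namespace, a device description (the digital twin:
illumination and detection elements with positions, orientations and
response characteristics) and an open ``custom`` namespace for anything the
schema does not cover.

Assignment through :func:`set_metadatum` (or the mapping interface of
:class:`AcquisitionMetadata`) is strict: values are validated against the
registry and a :class:`TypeError` is raised on constraint violation.  The
file reader deliberately bypasses this strictness so that imperfect
third-party files can still be opened and *reported on* by the
quality-control engine.
"""

from __future__ import annotations

import uuid as _uuid
from collections.abc import MutableMapping
from dataclasses import dataclass, field, fields
from datetime import datetime
from typing import Any, Iterator, Mapping

import numpy as np

from .registry import (
    Category,
    MetadatumSpec,
    registry_lookup,
    validate_value,
)

__all__ = [
    "AXIS_NAMES",
    "TimeSeriesTensor",
    "MeasurementDeviceInfo",
    "IlluminationElement",
    "DetectionElement",
    "DeviceMetadata",
    "AcquisitionMetadata",
    "PAData",
    "set_metadatum",
    "new_hex_uuid",
    "values_equal",
]

#: Canonical axis order of the raw payload.
AXIS_NAMES = ("detectors", "time_samples", "wavelengths", "measurements")


def new_hex_uuid() -> str:
    """A random 32-hex-digit identifier (version-4 style)."""
    return _uuid.uuid4().hex


# ---------------------------------------------------------------------------
# generic value equality (used for round-trip comparisons)


def values_equal(a: Any, b: Any) -> bool:
    """Deep equality across the value kinds the format stores.

    Numeric arrays compare element-wise (shape-sensitive), mappings compare
    key-by-key, strings and scalars compare exactly.  NumPy scalars compare
    equal to the equivalent Python scalars.
    """
    if a is None or b is None:
        return a is None and b is None
    if isinstance(a, Mapping) or isinstance(b, Mapping):
        if not (isinstance(a, Mapping) and isinstance(b, Mapping)):
            return False
        if set(a.keys()) != set(b.keys()):
            return False
        return all(values_equal(a[k], b[k]) for k in a)
    if isinstance(a, str) or isinstance(b, str):
        return isinstance(a, str) and isinstance(b, str) and a == b
    arr_a, arr_b = np.asarray(a), np.asarray(b)
    if arr_a.shape != arr_b.shape:
        return False
    return bool(np.array_equal(arr_a, arr_b))


# ---------------------------------------------------------------------------
# tensor


class TimeSeriesTensor:
    """The raw time-series payload, canonicalised to four axes.

    Axis order is ``[detectors, time_samples, wavelengths, measurements]``.
    Lower-dimensional input is expanded with trailing singleton axes, so a
    plain ``(detectors, samples)`` array becomes shape ``(d, s, 1, 1)``.
    The numeric dtype of the input is preserved bit-exactly.
    """

    def __init__(self, values: np.ndarray):
        arr = np.asarray(values)
        if not np.issubdtype(arr.dtype, np.number):
            raise TypeError(f"time-series payload must be numeric, got dtype {arr.dtype}")
        if arr.ndim > 4:
            raise ValueError(
                f"payload has {arr.ndim} axes; at most 4 "
                f"({', '.join(AXIS_NAMES)}) are supported")
        while arr.ndim < 4:
            arr = arr[..., np.newaxis]
        self.values = arr

    @property
    def dtype_descriptor(self) -> str:
        return str(self.values.dtype)

    @property
    def dims(self) -> tuple[str, ...]:
        return AXIS_NAMES

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.values.shape)

    def equals(self, other: "TimeSeriesTensor") -> bool:
        return (self.values.dtype == other.values.dtype
                and self.values.shape == other.values.shape
                and bool(np.array_equal(self.values, other.values)))

    def __repr__(self) -> str:
        return f"TimeSeriesTensor(shape={self.shape}, dtype={self.dtype_descriptor})"


# ---------------------------------------------------------------------------
# elements


@dataclass
class MeasurementDeviceInfo:
    """Auxiliary instrument that measured a metadatum (e.g. a wavemeter)."""

    device_type: str | None = None
    manufacturer: str | None = None
    serial_number: str | None = None
    calibration_date: str | None = None  # ISO-8601

    def __post_init__(self):
        if self.calibration_date is not None:
            try:
                datetime.fromisoformat(self.calibration_date)
            except ValueError:
                raise TypeError(
                    f"calibration_date {self.calibration_date!r} is not an "
                    "ISO-8601 timestamp") from None

    def equals(self, other: "MeasurementDeviceInfo") -> bool:
        return all(
            values_equal(getattr(self, f.name), getattr(other, f.name))
            for f in fields(self))


def _validate_element_field(tag: str, value: Any) -> None:
    if value is None:
        return
    result = validate_value(registry_lookup(tag), value)
    if not result.ok:
        raise TypeError(result.message)


_ILLUMINATOR_TAGS = {
    "position": "illuminator_position",
    "orientation": "illuminator_orientation",
    "geometry_type": "illuminator_geometry_type",
    "geometry": "illuminator_geometry",
    "wavelength_range": "wavelength_range",
    "laser_energy_profile": "laser_energy_profile",
    "laser_stability_profile": "laser_stability_profile",
    "pulse_duration": "pulse_duration",
    "beam_intensity_profile": "beam_intensity_profile",
    "intensity_profile_distance": "intensity_profile_distance",
    "beam_divergence_angle": "beam_divergence_angle",
}

_DETECTOR_TAGS = {
    "position": "detector_position",
    "orientation": "detector_orientation",
    "geometry_type": "detector_geometry_type",
    "geometry": "detector_geometry",
    "frequency_response": "frequency_response",
    "angular_response": "angular_response",
}


@dataclass
class IlluminationElement:
    """One light-delivery element: position, beam direction and source model."""

    position: Any = None
    orientation: Any = None
    geometry_type: str | None = None
    geometry: Any = None
    wavelength_range: Any = None
    laser_energy_profile: Any = None
    laser_stability_profile: Any = None
    pulse_duration: float | None = None
    beam_intensity_profile: Any = None
    intensity_profile_distance: float | None = None
    beam_divergence_angle: float | None = None

    field_tags = _ILLUMINATOR_TAGS

    def validate(self) -> None:
        """Strict constraint check; raises TypeError on first violation."""
        for name, tag in self.field_tags.items():
            _validate_element_field(tag, getattr(self, name))

    def equals(self, other: "IlluminationElement") -> bool:
        return all(
            values_equal(getattr(self, n), getattr(other, n))
            for n in self.field_tags)


@dataclass
class DetectionElement:
    """One transducer element: position, orientation and response model."""

    position: Any = None
    orientation: Any = None
    geometry_type: str | None = None
    geometry: Any = None
    frequency_response: Any = None
    angular_response: Any = None

    field_tags = _DETECTOR_TAGS

    def validate(self) -> None:
        for name, tag in self.field_tags.items():
            _validate_element_field(tag, getattr(self, name))

    def equals(self, other: "DetectionElement") -> bool:
        return all(
            values_equal(getattr(self, n), getattr(other, n))
            for n in self.field_tags)


# ---------------------------------------------------------------------------
# device


class DeviceMetadata:
    """Digital twin of a scanner: identity, field of view, element lists."""

    def __init__(self, uuid: str | None = None,
                 field_of_view: Any = None,
                 illuminators: list[IlluminationElement] | None = None,
                 detectors: list[DetectionElement] | None = None):
        self.uuid = uuid if uuid is not None else new_hex_uuid()
        self.field_of_view = None if field_of_view is None else np.asarray(
            field_of_view, dtype=float)
        self.illuminators: list[IlluminationElement] = list(illuminators or [])
        self.detectors: list[DetectionElement] = list(detectors or [])
        # element counts declared by a file (may disagree with the element
        # lists in broken third-party files; audited by quality control)
        self.declared_num_detectors: int | None = None
        self.declared_num_illuminators: int | None = None

    @property
    def num_illuminators(self) -> int:
        return len(self.illuminators)

    @property
    def num_detectors(self) -> int:
        return len(self.detectors)

    def detector_positions(self) -> np.ndarray:
        """(n_detectors, 3) array of element centroids in metres."""
        return np.asarray([np.asarray(d.position, dtype=float).ravel()
                           for d in self.detectors])

    def validate(self) -> None:
        for element in self.illuminators + self.detectors:
            element.validate()
        if self.field_of_view is not None and np.asarray(self.field_of_view).size != 6:
            raise TypeError("device field_of_view must hold six coordinates")

    def equals(self, other: "DeviceMetadata") -> bool:
        if self.uuid != other.uuid:
            return False
        if not values_equal(self.field_of_view, other.field_of_view):
            return False
        if len(self.illuminators) != len(other.illuminators):
            return False
        if len(self.detectors) != len(other.detectors):
            return False
        return (all(a.equals(b) for a, b in zip(self.illuminators, other.illuminators))
                and all(a.equals(b) for a, b in zip(self.detectors, other.detectors)))

    def __repr__(self) -> str:
        return (f"DeviceMetadata(uuid={self.uuid[:8]}..., "
                f"detectors={self.num_detectors}, "
                f"illuminators={self.num_illuminators})")


# ---------------------------------------------------------------------------
# acquisition metadata


class AcquisitionMetadata(MutableMapping):
    """Tag→value namespace for container and acquisition metadata.

    ``md[tag] = value`` validates against the registry and raises
    :class:`TypeError` when the value breaks the tag's constraint.  Absent
    values are absent keys — never NaN sentinels.  Auxiliary
    measurement-device details for a tag live in :attr:`measurement_devices`.
    """

    #: tags that belong to this namespace
    _OWN_CATEGORIES = (Category.MINIMAL, Category.ACQUISITION)
    #: binary descriptors are derived from the tensor, never stored here
    _TENSOR_DERIVED = frozenset({"data_type", "dimensionality", "sizes"})

    def __init__(self, initial: Mapping[str, Any] | None = None):
        self._values: dict[str, Any] = {}
        self.measurement_devices: dict[str, MeasurementDeviceInfo] = {}
        if initial:
            for key, value in initial.items():
                self[key] = value

    # -- mapping protocol --------------------------------------------------
    def __getitem__(self, tag: str) -> Any:
        return self._values[tag]

    def __setitem__(self, tag: str, value: Any) -> None:
        spec = registry_lookup(tag)
        if spec.category not in self._OWN_CATEGORIES:
            self._reject_foreign(spec)
        if tag in self._TENSOR_DERIVED:
            raise KeyError(
                f"tag {tag!r} is derived from the time-series tensor and "
                "cannot be assigned directly")
        result = validate_value(spec, value)
        if not result.ok:
            raise TypeError(result.message)
        self._values[tag] = value

    @staticmethod
    def _reject_foreign(spec: MetadatumSpec):
        raise KeyError(
            f"tag {spec.tag_name!r} belongs to the device description "
            f"(category {spec.category.value}); set it on DeviceMetadata or "
            "its elements instead")

    def __delitem__(self, tag: str) -> None:
        del self._values[tag]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    # -- lenient path used by the file reader ------------------------------
    def set_unchecked(self, tag: str, value: Any) -> None:
        """Store without validation (load path for imperfect files)."""
        self._values[tag] = value

    def equals(self, other: "AcquisitionMetadata") -> bool:
        if set(self._values) != set(other._values):
            return False
        if not all(values_equal(self._values[k], other._values[k])
                   for k in self._values):
            return False
        if set(self.measurement_devices) != set(other.measurement_devices):
            return False
        return all(self.measurement_devices[k].equals(other.measurement_devices[k])
                   for k in self.measurement_devices)

    def __repr__(self) -> str:
        return f"AcquisitionMetadata({sorted(self._values)})"


# ---------------------------------------------------------------------------
# the complete dataset


class PAData:
    """A complete raw photoacoustic dataset.

    Holds the 4-D time-series tensor, the acquisition metadata, the device
    digital twin and the open custom namespace.  A quality-control report may
    be attached after conversion (:attr:`qc_report`); it is derived data and
    is not serialised.
    """

    def __init__(self, tensor: TimeSeriesTensor | np.ndarray | None = None,
                 acquisition: AcquisitionMetadata | None = None,
                 device: DeviceMetadata | None = None,
                 custom: dict[str, Any] | None = None):
        if tensor is not None and not isinstance(tensor, TimeSeriesTensor):
            tensor = TimeSeriesTensor(tensor)
        self.tensor = tensor
        self.acquisition = acquisition if acquisition is not None else AcquisitionMetadata()
        self.device = device
        self.custom: dict[str, Any] = dict(custom or {})
        self.qc_report = None

    def equals(self, other: "PAData") -> bool:
        """Field-by-field equality; tensor comparison is bit-exact."""
        if (self.tensor is None) != (other.tensor is None):
            return False
        if self.tensor is not None and not self.tensor.equals(other.tensor):
            return False
        if not self.acquisition.equals(other.acquisition):
            return False
        if (self.device is None) != (other.device is None):
            return False
        if self.device is not None and not self.device.equals(other.device):
            return False
        return values_equal(self.custom, other.custom)

    def __repr__(self) -> str:
        shape = None if self.tensor is None else self.tensor.shape
        return (f"PAData(tensor={shape}, acquisition_tags={len(self.acquisition)}, "
                f"device={self.device!r})")


# ---------------------------------------------------------------------------
# registry-driven assignment


def set_metadatum(target: PAData, tag_name: str, value: Any,
                  custom: bool = False) -> PAData:
    """Store a metadatum on ``target`` under its canonical tag.

    Known acquisition-level tags are validated against the registry; a
    constraint violation raises :class:`TypeError` carrying the tag name and
    the constraint text.  With ``custom=True`` the value goes into the open
    custom namespace without any checks.  Element-level tags must be set on
    the device elements themselves.

    Returns ``target`` to allow chaining.
    """
    if custom:
        target.custom[tag_name] = value
        return target
    spec = registry_lookup(tag_name)  # raises UnknownTagError with suggestion
    if spec.category in (Category.MINIMAL, Category.ACQUISITION):
        target.acquisition[tag_name] = value
    elif spec.category is Category.DEVICE:
        if target.device is None:
            target.device = DeviceMetadata()
        if tag_name == "device_uuid":
            result = validate_value(spec, value)
            if not result.ok:
                raise TypeError(result.message)
            target.device.uuid = value
        elif tag_name == "device_field_of_view":
            result = validate_value(spec, value)
            if not result.ok:
                raise TypeError(result.message)
            target.device.field_of_view = np.asarray(value, dtype=float)
        else:
            raise KeyError(
                f"tag {tag_name!r} is derived from the element lists and "
                "cannot be assigned directly")
    else:
        raise KeyError(
            f"tag {tag_name!r} describes a device element; set it on an "
            "IlluminationElement/DetectionElement instead")
    return target
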