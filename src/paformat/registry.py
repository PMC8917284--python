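"""Typed registry of the consensus photoacoustic metadata schema.

Every metadatum defined by the consensus raw-data format is described by a
:class:`MetadatumSpec` that records its necessity, semantic data type, SI
unit, human-readable description and value constraint.  The registry is the
single source of truth for the rest of the package: the in-memory containers
validate assignments against it, the quality-control engine iterates it to
build completeness checklists, and the HDF5 reader/writer uses it to decide
where a value belongs.

Metadata fall into five categories:

``minimal``
    The tags required to reconstruct any image from the raw time series:
    container identity (UUID, compression, encoding), binary-data
    descriptors (data type, dimensionality, axis sizes), A/D sampling rate,
    acquisition wavelengths, detector positions and field of view.
``acquisition``
    Settings at data capture (pulse energy, gains, speed of sound, scanning
    method, frequency-domain filter, ...). Reported if present.
``device`` / ``illumination`` / ``detection``
    The digital twin of the scanner: device-level identity and geometry plus
    per-element descriptions of illuminators and detectors.

All numeric values are strict SI: metres, seconds, hertz, joules, kelvin.
Angles are radians.  Unit conversion from vendor conventions happens in
adapters, never here.
"""

from __future__ import annotations

import difflib
import numbers
from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from typing import Any, Callable, Mapping

import numpy as np

__all__ = [
    "Necessity",
    "Category",
    "Constraint",
    "ValidationResult",
    "MetadatumSpec",
    "UnknownTagError",
    "registry_lookup",
    "validate_value",
    "iter_registry",
    "tags_in_category",
    "REGISTRY",
    "MINIMAL_ITEMS",
    "MINIMAL_TAGS",
    "SCANNING_METHODS",
]


class Necessity(str, Enum):
    """Whether a metadatum is required or only reported when available."""

    MINIMAL = "minimal"
    REPORT_IF_PRESENT = "report_if_present"


class Category(str, Enum):
    """Where in the container a metadatum lives."""

    MINIMAL = "minimal"
    ACQUISITION = "acquisition"
    DEVICE = "device"
    ILLUMINATION = "illumination"
    DETECTION = "detection"


SCANNING_METHODS = ("full_scan", "composite_scan")

#: Sentinel used inside ``frequency_domain_filter`` to mark an absent edge.
FILTER_UNSET = -1.0


@dataclass(frozen=True)
class Constraint:
    """A decidable predicate over candidate values, with prose for reports."""

    text: str
    check: Callable[[Any], bool]

    def __call__(self, value: Any) -> bool:
        return bool(self.check(value))


ALWAYS_OK = Constraint("no constraint", lambda value: True)


@dataclass(frozen=True)
class ValidationResult:
    ok: bool
    message: str = ""

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


@dataclass(frozen=True)
class MetadatumSpec:
    """One registry entry: the machine-readable form of a metadatum's row."""

    tag_name: str
    category: Category
    necessity: Necessity
    dtype: str  # scalar-number | number-array | string | string-enum | coordinate-array | map
    si_unit: str
    description: str
    constraint: Constraint = ALWAYS_OK
    enum_values: tuple[str, ...] = ()
    nested_attributes: tuple["MetadatumSpec", ...] = ()


class UnknownTagError(KeyError):
    """Raised when a tag name is not part of the registry."""

    def __init__(self, tag_name: str, suggestion: str | None = None):
        self.tag_name = tag_name
        self.suggestion = suggestion
        msg = f"unknown metadata tag {tag_name!r}"
        if suggestion:
            msg += f"; did you mean {suggestion!r}?"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return self.args[0]


# ---------------------------------------------------------------------------
# value helpers used by constraints


def _as_array(value: Any) -> np.ndarray:
    return np.asarray(value)


def _is_number(value: Any) -> bool:
    return isinstance(value, numbers.Number) and not isinstance(value, bool) or (
        isinstance(value, np.generic) and np.issubdtype(np.asarray(value).dtype, np.number)
    )


def _is_numeric_array(value: Any) -> bool:
    if isinstance(value, (str, bytes, Mapping)):
        return False
    try:
        arr = np.asarray(value)
    except Exception:
        return False
    return np.issubdtype(arr.dtype, np.number) and not np.issubdtype(arr.dtype, np.bool_)


def _all_strictly_positive(value: Any) -> bool:
    arr = _as_array(value, )
    return arr.size > 0 and bool(np.all(arr > 0))


def _positive_scalar(value: Any) -> bool:
    return float(np.asarray(value)) > 0


def _unit_vector(value: Any, tol: float = 1e-6) -> bool:
    arr = _as_array(value).ravel()
    return arr.size == 3 and abs(float(np.linalg.norm(arr)) - 1.0) <= tol


def _length(value: Any) -> int:
    return int(np.asarray(value).ravel().size)


def _valid_filter(value: Any) -> bool:
    arr = _as_array(value).ravel()
    if arr.size != 2:
        return False
    lower, higher = (float(arr[0]), float(arr[1]))
    for edge in (lower, higher):
        if not (edge == FILTER_UNSET or edge > 0):
            return False
    if lower > 0 and higher > 0 and not lower < higher:
        return False
    return True


def _valid_speed_of_sound(value: Any) -> bool:
    arr = _as_array(value)
    if arr.ndim == 0:
        return float(arr) > 0
    if arr.ndim == 3:
        return bool(np.all(arr > 0))
    return False


def _valid_wavelength_range(value: Any) -> bool:
    arr = _as_array(value).ravel()
    return arr.size == 3 and bool(np.all(arr > 0)) and float(arr[0]) <= float(arr[1])


def _valid_frequency_response(value: Any) -> bool:
    arr = _as_array(value).ravel()
    return arr.size == 2 and bool(np.all(arr > 0))


def _positive_int(value: Any) -> bool:
    scalar = np.asarray(value)
    return scalar.ndim == 0 and float(scalar) >= 1 and float(scalar) == int(scalar)


def _non_negative(value: Any) -> bool:
    return bool(np.all(_as_array(value) >= 0))


def _parses_iso8601(value: Any) -> bool:
    try:
        datetime.fromisoformat(str(value))
        return True
    except ValueError:
        return False


def _coordinate_triplet(value: Any) -> bool:
    return _length(value) == 3


def _six_coordinates(value: Any) -> bool:
    return _length(value) == 6


# ---------------------------------------------------------------------------
# dtype checking


def _check_dtype(spec: MetadatumSpec, value: Any) -> str | None:
    """Return an error message if ``value`` does not match the semantic dtype."""
    kind = spec.dtype
    if kind == "scalar-number":
        if _is_number(value) or (_is_numeric_array(value) and np.asarray(value).ndim == 0):
            return None
        # speed_of_sound-style tags may allow maps; handled by constraint
        if spec.tag_name == "speed_of_sound" and _is_numeric_array(value):
            return None
        if spec.tag_name == "pulse_energy" and _is_numeric_array(value):
            return None
        return f"expected a scalar number, got {type(value).__name__}"
    if kind in ("number-array", "coordinate-array"):
        if _is_numeric_array(value):
            return None
        return f"expected a numeric array, got {type(value).__name__}"
    if kind == "string":
        if isinstance(value, str):
            return None
        return f"expected a string, got {type(value).__name__}"
    if kind == "string-enum":
        if not isinstance(value, str):
            return f"expected a string, got {type(value).__name__}"
        if value not in spec.enum_values:
            return f"{value!r} is not one of {list(spec.enum_values)}"
        return None
    if kind == "map":
        if isinstance(value, Mapping):
            return None
        return f"expected a mapping, got {type(value).__name__}"
    raise ValueError(f"registry defines unknown dtype descriptor {kind!r}")


# ---------------------------------------------------------------------------
# registry construction

_MEASUREMENT_DEVICE_NESTED = (
    MetadatumSpec(
        "measurement_device_type", Category.ACQUISITION, Necessity.REPORT_IF_PRESENT,
        "string", "", "Kind of auxiliary measurement device, e.g. 'pyroelectric sensor' or 'wavemeter'."),
    MetadatumSpec(
        "measurement_device_manufacturer", Category.ACQUISITION, Necessity.REPORT_IF_PRESENT,
        "string", "", "Manufacturer of the auxiliary measurement device."),
    MetadatumSpec(
        "measurement_device_serial_number", Category.ACQUISITION, Necessity.REPORT_IF_PRESENT,
        "string", "", "Serial number of the auxiliary measurement device."),
    MetadatumSpec(
        "measurement_device_calibration_date", Category.ACQUISITION, Necessity.REPORT_IF_PRESENT,
        "string", "", "ISO-8601 timestamp of the last calibration of the measurement device.",
        Constraint("parses as an ISO-8601 timestamp", _parses_iso8601)),
)


def _specs() -> tuple[MetadatumSpec, ...]:
    M, A, D, I, T = (Category.MINIMAL, Category.ACQUISITION, Category.DEVICE,
                     Category.ILLUMINATION, Category.DETECTION)
    MIN, RIP = Necessity.MINIMAL, Necessity.REPORT_IF_PRESENT
    return (
        # --- minimal: container format -----------------------------------
        MetadatumSpec("uuid", M, MIN, "string", "",
                      "Universally unique identifier of the dataset (hexadecimal string)."),
        MetadatumSpec("compression", M, MIN, "string", "",
                      "Type of compression applied to the binary payload ('none' or 'gzip')."),
        MetadatumSpec("encoding", M, MIN, "string", "",
                      "Character/binary encoding of the container ('raw', UTF-8 strings)."),
        # --- minimal: binary data descriptors ----------------------------
        MetadatumSpec("data_type", M, MIN, "string", "",
                      "Numeric dtype descriptor of the raw time-series payload, e.g. 'int16'."),
        MetadatumSpec("dimensionality", M, MIN, "string", "",
                      "Axis names of the payload in storage order: "
                      "detectors, time_samples, wavelengths, measurements."),
        MetadatumSpec("sizes", M, MIN, "number-array", "",
                      "Size of each payload axis.",
                      Constraint("all sizes are positive integers",
                                 lambda v: bool(np.all(_as_array(v) >= 1)))),
        # --- minimal: acquisition-level ----------------------------------
        MetadatumSpec("ad_sampling_rate", M, MIN, "scalar-number", "Hz",
                      "Rate at which the analogue detector signal is sampled for digitisation.",
                      Constraint("strictly positive", _positive_scalar)),
        MetadatumSpec("acquisition_wavelengths", M, MIN, "number-array", "m",
                      "All optical excitation wavelengths used for the acquisition.",
                      Constraint("all wavelengths strictly positive", _all_strictly_positive)),
        MetadatumSpec("field_of_view", M, MIN, "number-array", "m",
                      "Approximate cuboid to reconstruct: "
                      "[x1start, x1end, x2start, x2end, x3start, x3end]. "
                      "A 2-D region sets start == end on the collapsed axis.",
                      Constraint("exactly six coordinates", _six_coordinates)),
        # --- acquisition --------------------------------------------------
        MetadatumSpec("regions_of_interest", A, RIP, "map", "m",
                      "Named regions: each name maps to a six-coordinate cuboid or a "
                      "list of 3-D points outlining the region."),
        MetadatumSpec("device_reference_uuid", A, RIP, "string", "",
                      "UUID of the device description this acquisition refers to."),
        MetadatumSpec("pulse_energy", A, RIP, "scalar-number", "J",
                      "Laser pulse energy used to generate the photoacoustic signal; "
                      "a scalar (possibly pulse-averaged) or one value per measurement.",
                      Constraint("non-negative", _non_negative),
                      nested_attributes=_MEASUREMENT_DEVICE_NESTED),
        MetadatumSpec("measurement_timestamps", A, RIP, "number-array", "s",
                      "Time at which each measurement was recorded (seconds since Unix epoch)."),
        MetadatumSpec("measurement_spatial_poses", A, RIP, "number-array", "m / rad",
                      "Per-measurement pose change relative to the first measurement: "
                      "[dx1, dx2, dx3, rot_x1, rot_x2, rot_x3]."),
        MetadatumSpec("time_gain_compensation", A, RIP, "number-array", "",
                      "Relative per-sample gain factors compensating acoustic attenuation.",
                      Constraint("all factors strictly positive", _all_strictly_positive)),
        MetadatumSpec("overall_gain", A, RIP, "scalar-number", "",
                      "Single amplitude factor applied to the raw time series.",
                      Constraint("strictly positive", _positive_scalar)),
        MetadatumSpec("element_dependent_gain", A, RIP, "number-array", "",
                      "Per-detector gain factors for apodisation or sensitivity correction.",
                      Constraint("all factors strictly positive", _all_strictly_positive)),
        MetadatumSpec("temperature_control", A, RIP, "number-array", "K",
                      "Temperature of the imaged space (medium plus coupling agent) per measurement.",
                      Constraint("all temperatures strictly positive (kelvin)",
                                 _all_strictly_positive),
                      nested_attributes=_MEASUREMENT_DEVICE_NESTED),
        MetadatumSpec("acoustic_coupling_agent", A, RIP, "string", "",
                      "Acoustic coupling agent between device and target, e.g. 'water'."),
        MetadatumSpec("speed_of_sound", A, RIP, "scalar-number", "m/s",
                      "Mean global speed of sound, or a 3-D heterogeneous map in device coordinates.",
                      Constraint("positive scalar or positive 3-D map", _valid_speed_of_sound)),
        MetadatumSpec("scanning_method", A, RIP, "string-enum", "",
                      "Whether one measurement yields an image (full_scan) or several are "
                      "combined (composite_scan).",
                      enum_values=SCANNING_METHODS),
        MetadatumSpec("measurements_per_image", A, RIP, "scalar-number", "",
                      "Number of measurements that constitute one image.",
                      Constraint("positive integer", _positive_int)),
        MetadatumSpec("frequency_domain_filter", A, RIP, "number-array", "Hz",
                      "[lower, higher] -3 dB points of the applied filter; -1 marks an unset "
                      "edge, so [lower, -1] is a high-pass and [-1, higher] a low-pass filter.",
                      Constraint("each edge is -1 or > 0; lower < higher when both set",
                                 _valid_filter)),
        # --- device-level -------------------------------------------------
        MetadatumSpec("device_uuid", D, MIN, "string", "",
                      "Randomly generated hexadecimal identifier of the device.",
                      Constraint("parses as a hexadecimal string",
                                 lambda v: isinstance(v, str) and len(v) > 0
                                 and all(c in "0123456789abcdefABCDEF" for c in v))),
        MetadatumSpec("device_field_of_view", D, RIP, "number-array", "m",
                      "Approximate cuboid detectable by the device, six coordinates.",
                      Constraint("exactly six coordinates", _six_coordinates)),
        MetadatumSpec("num_illuminators", D, RIP, "scalar-number", "",
                      "Number of illumination elements of the device.",
                      Constraint("non-negative integer",
                                 lambda v: float(v) >= 0 and float(v) == int(v))),
        MetadatumSpec("num_detectors", D, MIN, "scalar-number", "",
                      "Number of detection elements of the device.",
                      Constraint("positive integer", _positive_int)),
        # --- illumination elements ---------------------------------------
        MetadatumSpec("illuminator_position", I, RIP, "coordinate-array", "m",
                      "Centroid position of the illuminator, [x1, x2, x3].",
                      Constraint("exactly three coordinates", _coordinate_triplet)),
        MetadatumSpec("illuminator_orientation", I, RIP, "coordinate-array", "",
                      "Direction unit vector of the illuminating beam.",
                      Constraint("unit vector within 1e-6", _unit_vector)),
        MetadatumSpec("illuminator_geometry_type", I, RIP, "string", "",
                      "Shape descriptor of the fibre(-bundle) output, e.g. 'slit'."),
        MetadatumSpec("illuminator_geometry", I, RIP, "number-array", "m",
                      "Numeric geometry payload; interpretation fixed by illuminator_geometry_type."),
        MetadatumSpec("wavelength_range", I, RIP, "number-array", "m",
                      "[minimum wavelength, maximum wavelength, accuracy] the illuminator can emit.",
                      Constraint("three positive entries with min <= max",
                                 _valid_wavelength_range)),
        MetadatumSpec("laser_energy_profile", I, RIP, "number-array", "J",
                      "Two arrays [wavelengths, energies]: pulse energy versus wavelength."),
        MetadatumSpec("laser_stability_profile", I, RIP, "number-array", "J",
                      "Two arrays [wavelengths, standard deviations] of pulse-to-pulse energy."),
        MetadatumSpec("pulse_duration", I, RIP, "scalar-number", "s",
                      "Pulse length between the half-power points of leading and trailing edge.",
                      Constraint("strictly positive", _positive_scalar)),
        MetadatumSpec("beam_intensity_profile", I, RIP, "number-array", "",
                      "Two arrays [positions, intensities]: relative beam intensity across the "
                      "emitting surface at intensity_profile_distance."),
        MetadatumSpec("intensity_profile_distance", I, RIP, "scalar-number", "m",
                      "Distance from the source at which beam_intensity_profile was measured.",
                      Constraint("non-negative", _non_negative)),
        MetadatumSpec("beam_divergence_angle", I, RIP, "scalar-number", "rad",
                      "Opening angle of the beam about the orientation vector.",
                      Constraint("non-negative", _non_negative)),
        # --- detection elements ------------------------------------------
        MetadatumSpec("detector_position", T, MIN, "coordinate-array", "m",
                      "Centroid position of the detection element, [x1, x2, x3].",
                      Constraint("exactly three coordinates", _coordinate_triplet)),
        MetadatumSpec("detector_orientation", T, RIP, "coordinate-array", "",
                      "Direction unit vector of the detection element.",
                      Constraint("unit vector within 1e-6", _unit_vector)),
        MetadatumSpec("detector_geometry_type", T, RIP, "string", "",
                      "Type descriptor of the detector geometry."),
        MetadatumSpec("detector_geometry", T, RIP, "number-array", "m",
                      "Numeric geometry payload; interpretation fixed by detector_geometry_type."),
        MetadatumSpec("frequency_response", T, RIP, "number-array", "Hz",
                      "[center frequency, bandwidth] of the element's response to pressure waves.",
                      Constraint("two strictly positive entries", _valid_frequency_response)),
        MetadatumSpec("angular_response", T, RIP, "number-array", "",
                      "Two arrays [incident angles (rad), responses] of angular sensitivity."),
    )


REGISTRY: dict[str, MetadatumSpec] = {}
for _spec in _specs():
    if _spec.tag_name in REGISTRY:  # pragma: no cover - construction guard
        raise RuntimeError(f"duplicate registry tag {_spec.tag_name!r}")
    REGISTRY[_spec.tag_name] = _spec
del _spec

#: The six documented minimal items mapped onto their registry tags.
#: ``detector_positions`` is housed in the device description (one position
#: per detection element) rather than in the acquisition metadata.
MINIMAL_ITEMS: dict[str, tuple[str, ...]] = {
    "container_format": ("uuid", "compression", "encoding"),
    "binary_data": ("data_type", "dimensionality", "sizes"),
    "ad_sampling_rate": ("ad_sampling_rate",),
    "acquisition_wavelengths": ("acquisition_wavelengths",),
    "detector_positions": ("detector_position",),
    "field_of_view": ("field_of_view",),
}

#: Flat set of tags that must be present for a dataset to be reconstructible.
MINIMAL_TAGS: tuple[str, ...] = tuple(
    tag for tags in MINIMAL_ITEMS.values() for tag in tags
)


def registry_lookup(tag_name: str) -> MetadatumSpec:
    """Return the spec for a known tag.

    Raises :class:`UnknownTagError` (with a nearest-match suggestion) for
    unknown tags.
    """
    try:
        return REGISTRY[tag_name]
    except KeyError:
        matches = difflib.get_close_matches(tag_name, REGISTRY.keys(), n=1)
        raise UnknownTagError(tag_name, matches[0] if matches else None) from None


def iter_registry():
    """Iterate all specs in stable (definition) order."""
    return iter(REGISTRY.values())


def tags_in_category(category: Category | str) -> tuple[str, ...]:
    category = Category(category)
    return tuple(s.tag_name for s in REGISTRY.values() if s.category is category)


def validate_value(spec: MetadatumSpec, value: Any) -> ValidationResult:
    """Check ``value`` against a spec's dtype and constraint.

    Pure and side-effect free: the value is never mutated and repeated calls
    give identical results.
    """
    dtype_error = _check_dtype(spec, value)
    if dtype_error is not None:
        return ValidationResult(False, f"{spec.tag_name}: {dtype_error}")
    try:
        ok = spec.constraint(value)
    except Exception as exc:
        return ValidationResult(
            False, f"{spec.tag_name}: constraint check failed ({exc})")
    if not ok:
        return ValidationResult(
            False,
            f"{spec.tag_name}: violates constraint '{spec.constraint.text}'")
    return ValidationResult(True, f"{spec.tag_name}: ok")
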