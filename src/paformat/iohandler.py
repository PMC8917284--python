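"""Reading and writing of the consensus HDF5 container.

Layout of a written file::

    /binary_time_series_data        4-D dataset [detectors, time_samples,
                                    wavelengths, measurements]; the binary
                                    descriptors (data_type, dimensionality,
                                    sizes) are attributes of the dataset
    /meta_data                      acquisition metadata; scalars and strings
                                    as named attributes, arrays as
                                    sub-datasets
    /meta_data/regions_of_interest  one dataset per named region
    /meta_data/measurement_devices  one group per tag measured by an
                                    auxiliary instrument
    /meta_data_device/general       device uuid, element counts, field of view
    /meta_data_device/illuminators/<i>, /detectors/<i>
                                    zero-padded per-element groups
    /custom                         the open custom namespace, verbatim

The file is self-describing: everything needed to interpret the payload is
inside the container, and strings are UTF-8.  Reading is deliberately
lenient — values are loaded without constraint checks so that imperfect
third-party files can be opened and then audited by the quality-control
engine; strictness lives on the write/assignment path.
"""

from __future__ import annotations

import os
from collections.abc import Mapping
from typing import Any

import h5py
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
from .registry import REGISTRY, Category, MINIMAL_TAGS

__all__ = ["write_ipasc", "read_ipasc", "FormatError", "CompletenessError"]

_PAYLOAD = "binary_time_series_data"
_META = "meta_data"
_DEVICE = "meta_data_device"
_CUSTOM = "custom"
_ROI = "regions_of_interest"
_MEASUREMENT_DEVICES = "measurement_devices"
_ELEMENT_INDEX_WIDTH = 6  # zero-padded decimal group names guarantee ordering


class FormatError(ValueError):
    """The file is not a readable container of this format."""


class CompletenessError(ValueError):
    """Dataset lacks minimal metadata required for writing."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(
            "dataset is missing minimal metadata: " + ", ".join(self.missing)
            + " (pass allow_incomplete=True to write anyway)")


# ---------------------------------------------------------------------------
# generic value storage


def _store(group: h5py.Group, key: str, value: Any) -> None:
    """Scalars and strings become attributes, arrays become datasets,
    mappings become sub-groups (recursively)."""
    if value is None:
        return
    if isinstance(value, str):
        group.attrs[key] = value
        return
    if isinstance(value, Mapping):
        sub = group.create_group(key)
        for sub_key, sub_value in value.items():
            _store(sub, str(sub_key), sub_value)
        return
    arr = np.asarray(value)
    if arr.ndim == 0:
        group.attrs[key] = arr[()]
    else:
        group.create_dataset(key, data=arr)


def _normalise(value: Any) -> Any:
    """Convert h5py-returned values to plain Python/NumPy values."""
    if isinstance(value, bytes):
        return value.decode("utf-8")
    if isinstance(value, np.generic):
        item = value.item()
        return item.decode("utf-8") if isinstance(item, bytes) else item
    if isinstance(value, np.ndarray) and value.dtype.kind in ("S", "O"):
        return np.asarray([_normalise(v) for v in value.ravel()]).reshape(value.shape)
    return value


def _read_group_values(group: h5py.Group) -> dict[str, Any]:
    """All attributes and datasets (and sub-groups, recursively) of a group."""
    out: dict[str, Any] = {}
    for key, value in group.attrs.items():
        out[key] = _normalise(value)
    for key, item in group.items():
        if isinstance(item, h5py.Dataset):
            out[key] = _normalise(item[()])
        else:
            out[key] = _read_group_values(item)
    return out


# ---------------------------------------------------------------------------
# completeness gate (write path)


def missing_minimal_tags(data: PAData) -> list[str]:
    """Minimal tags that are absent from ``data``, in registry order."""
    missing = []
    for tag in MINIMAL_TAGS:
        if tag in ("data_type", "dimensionality", "sizes"):
            present = data.tensor is not None
        elif tag == "detector_position":
            present = (data.device is not None
                       and data.device.num_detectors > 0
                       and all(d.position is not None for d in data.device.detectors))
        else:
            present = tag in data.acquisition
        if not present:
            missing.append(tag)
    return missing


# ---------------------------------------------------------------------------
# writing


def write_ipasc(data: PAData, path: str | os.PathLike, *,
                overwrite: bool = False,
                allow_incomplete: bool = False,
                compress: bool = False) -> None:
    """Serialise ``data`` into a single self-describing HDF5 container.

    Parameters
    ----------
    data
        The dataset to write; must pass the minimal-completeness check
        unless ``allow_incomplete`` is set.
    path
        Output file path (conventionally ``.hdf5``).
    overwrite
        Refuse to replace an existing file unless set.
    compress
        Store the payload gzip-compressed; the container ``compression``
        tag in the file records ``"gzip"`` instead of the in-memory value.
    """
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(
            f"{path} exists; pass overwrite=True to replace it")
    if not allow_incomplete:
        missing = missing_minimal_tags(data)
        if missing:
            raise CompletenessError(missing)

    with h5py.File(path, "w") as handle:
        if data.tensor is not None:
            kwargs = {"compression": "gzip"} if compress else {}
            dset = handle.create_dataset(_PAYLOAD, data=data.tensor.values, **kwargs)
            dset.attrs["data_type"] = data.tensor.dtype_descriptor
            dset.attrs["dimensionality"] = ",".join(data.tensor.dims)
            dset.attrs["sizes"] = np.asarray(data.tensor.shape, dtype=np.int64)

        meta = handle.create_group(_META)
        for tag, value in data.acquisition.items():
            if tag == "compression" and compress:
                value = "gzip"
            _store(meta, tag, value)
        if data.acquisition.measurement_devices:
            mdg = meta.create_group(_MEASUREMENT_DEVICES)
            for tag, info in data.acquisition.measurement_devices.items():
                sub = mdg.create_group(tag)
                _store(sub, "device_type", info.device_type)
                _store(sub, "manufacturer", info.manufacturer)
                _store(sub, "serial_number", info.serial_number)
                _store(sub, "calibration_date", info.calibration_date)

        if data.device is not None:
            device_group = handle.create_group(_DEVICE)
            general = device_group.create_group("general")
            general.attrs["uuid"] = data.device.uuid
            general.attrs["num_illuminators"] = data.device.num_illuminators
            general.attrs["num_detectors"] = data.device.num_detectors
            if data.device.field_of_view is not None:
                general.create_dataset(
                    "field_of_view", data=np.asarray(data.device.field_of_view))
            for kind, elements in (("illuminators", data.device.illuminators),
                                   ("detectors", data.device.detectors)):
                if not elements:
                    continue
                kind_group = device_group.create_group(kind)
                for index, element in enumerate(elements):
                    element_group = kind_group.create_group(
                        f"{index:0{_ELEMENT_INDEX_WIDTH}d}")
                    for name in element.field_tags:
                        _store(element_group, name, getattr(element, name))

        custom = handle.create_group(_CUSTOM)
        for key, value in data.custom.items():
            _store(custom, key, value)


# ---------------------------------------------------------------------------
# reading


def _read_element(group: h5py.Group, cls):
    values = _read_group_values(group)
    element = cls()
    for name in cls.field_tags:
        if name in values:
            setattr(element, name, values[name])
    return element


def read_ipasc(path: str | os.PathLike) -> PAData:
    """Load a container file into a :class:`PAData`.

    All registry tags found in the file are populated; attributes that are
    not part of the schema land in the ``custom`` namespace.  The payload
    dtype is preserved exactly.  No constraint checking happens here — run
    the quality-control engine on the result to audit a file.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if not h5py.is_hdf5(path):
        raise FormatError(f"{path} is not an HDF5 container")

    data = PAData()
    try:
        with h5py.File(path, "r") as handle:
            if _PAYLOAD in handle:
                dset = handle[_PAYLOAD]
                data.tensor = TimeSeriesTensor(dset[()])

            if _META in handle:
                meta = handle[_META]
                values = _read_group_values(meta)
                devices = values.pop(_MEASUREMENT_DEVICES, None)
                for tag, value in values.items():
                    spec = REGISTRY.get(tag)
                    if spec is not None and spec.category in (
                            Category.MINIMAL, Category.ACQUISITION):
                        data.acquisition.set_unchecked(tag, value)
                    else:
                        data.custom[tag] = value
                if devices:
                    for tag, info in devices.items():
                        data.acquisition.measurement_devices[tag] = (
                            MeasurementDeviceInfo(
                                device_type=info.get("device_type"),
                                manufacturer=info.get("manufacturer"),
                                serial_number=info.get("serial_number"),
                                calibration_date=info.get("calibration_date")))

            if _DEVICE in handle:
                device_group = handle[_DEVICE]
                device = DeviceMetadata(uuid="0")
                if "general" in device_group:
                    general = device_group["general"]
                    device.uuid = _normalise(general.attrs.get("uuid", "0"))
                    if "field_of_view" in general:
                        device.field_of_view = np.asarray(general["field_of_view"][()])
                    device.declared_num_detectors = _normalise(
                        general.attrs.get("num_detectors"))
                    device.declared_num_illuminators = _normalise(
                        general.attrs.get("num_illuminators"))
                if "illuminators" in device_group:
                    for name in sorted(device_group["illuminators"]):
                        device.illuminators.append(_read_element(
                            device_group["illuminators"][name], IlluminationElement))
                if "detectors" in device_group:
                    for name in sorted(device_group["detectors"]):
                        device.detectors.append(_read_element(
                            device_group["detectors"][name], DetectionElement))
                data.device = device

            if _CUSTOM in handle:
                data.custom.update(_read_group_values(handle[_CUSTOM]))
    except OSError as exc:
        raise FormatError(f"failed to read {path}: {exc}") from exc
    return data
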