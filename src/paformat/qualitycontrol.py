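"""Completeness and consistency auditing of photoacoustic datasets.

The completeness checker classifies every registry tag as present or absent:
a missing *minimal* tag fails the check, a missing report-if-present tag is
merely informational.  The consistency checker evaluates every *present*
value against its registry constraint and adds cross-field rules that single
tags cannot express — the tensor's detector axis must match the device's
element count, the wavelength axis must match the acquisition wavelengths,
the acquisition must reference the attached device, and a full-scan
acquisition has exactly one measurement per image.

Reports render deterministically in registry order so that two audits of
identical data produce byte-identical text, which makes diffs meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import os
from typing import Any

import numpy as np

from .metadata import DeviceMetadata, PAData
from .registry import (
    REGISTRY,
    Category,
    Necessity,
    registry_lookup,
    validate_value,
)

__all__ = [
    "CompletenessItem",
    "ConsistencyItem",
    "QCReport",
    "check_completeness",
    "check_consistency",
    "quality_check",
    "write_report",
    "visualize_device",
]


@dataclass(frozen=True)
class CompletenessItem:
    tag: str
    necessity: Necessity
    present: bool

    @property
    def failing(self) -> bool:
        return not self.present and self.necessity is Necessity.MINIMAL


@dataclass(frozen=True)
class ConsistencyItem:
    """Outcome of one consistency rule.

    ``severity`` is ``"error"`` for violations that make the dataset
    unreconstructible or internally contradictory (minimal tags, cross-field
    rules) and ``"warning"`` for constraint violations on report-if-present
    tags — imperfect third-party files must remain openable and reportable.
    """

    tag: str
    ok: bool
    message: str = ""
    severity: str = "error"

    @property
    def failing(self) -> bool:
        return not self.ok and self.severity == "error"


@dataclass
class QCReport:
    """Structured quality-control outcome with a human-readable rendering."""

    completeness: list[CompletenessItem] = field(default_factory=list)
    consistency: list[ConsistencyItem] = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        return (not any(item.failing for item in self.completeness)
                and not any(item.failing for item in self.consistency))

    @property
    def strict_pass(self) -> bool:
        """Pass with warnings promoted to failures."""
        return self.overall_pass and all(item.ok for item in self.consistency)

    def failures(self) -> list[str]:
        lines = [item.tag for item in self.completeness if item.failing]
        lines += [item.tag for item in self.consistency if item.failing]
        return lines

    def warnings(self) -> list[str]:
        return [item.tag for item in self.consistency
                if not item.ok and item.severity == "warning"]

    def render(self) -> str:
        lines = ["Quality control report", "=" * 22, "", "Completeness",
                 "-" * 12]
        for item in self.completeness:
            if item.present:
                lines.append(f"[ OK ] {item.tag} ({item.necessity.value})")
            elif item.failing:
                lines.append(f"[FAIL] {item.tag} (minimal): missing")
            else:
                lines.append(
                    f"[ -- ] {item.tag} (report_if_present): absent, informational")
        lines += ["", "Consistency", "-" * 11]
        for item in self.consistency:
            if item.ok:
                lines.append(f"[ OK ] {item.tag}")
            elif item.severity == "warning":
                lines.append(f"[WARN] {item.tag}: {item.message}")
            else:
                lines.append(f"[FAIL] {item.tag}: {item.message}")
        lines += ["", f"Overall: {'PASS' if self.overall_pass else 'FAIL'}", ""]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# completeness


def _element_values(data: PAData, category: Category, name: str) -> list[Any]:
    if data.device is None:
        return []
    elements = (data.device.illuminators if category is Category.ILLUMINATION
                else data.device.detectors)
    return [getattr(e, name) for e in elements]


_ELEMENT_FIELD_BY_TAG: dict[str, str] = {}
for _cls_tags in ({"illuminator_position": "position",
                   "illuminator_orientation": "orientation",
                   "illuminator_geometry_type": "geometry_type",
                   "illuminator_geometry": "geometry"},
                  {"detector_position": "position",
                   "detector_orientation": "orientation",
                   "detector_geometry_type": "geometry_type",
                   "detector_geometry": "geometry"}):
    _ELEMENT_FIELD_BY_TAG.update(_cls_tags)
for _tag in ("wavelength_range", "laser_energy_profile", "laser_stability_profile",
             "pulse_duration", "beam_intensity_profile", "intensity_profile_distance",
             "beam_divergence_angle", "frequency_response", "angular_response"):
    _ELEMENT_FIELD_BY_TAG[_tag] = _tag


def _tag_present(data: PAData, tag: str) -> bool:
    spec = REGISTRY[tag]
    if tag in ("data_type", "dimensionality", "sizes"):
        return data.tensor is not None
    if spec.category in (Category.MINIMAL, Category.ACQUISITION):
        return tag in data.acquisition
    if spec.category is Category.DEVICE:
        if data.device is None:
            return False
        if tag == "device_field_of_view":
            return data.device.field_of_view is not None
        return True  # uuid and element counts always defined on a device
    # element-level: present when at least one element carries the field,
    # except positions, which every element must define
    values = _element_values(data, spec.category, _ELEMENT_FIELD_BY_TAG[tag])
    if tag in ("detector_position", "illuminator_position"):
        return bool(values) and all(v is not None for v in values)
    return any(v is not None for v in values)


def check_completeness(data: PAData) -> list[CompletenessItem]:
    """Classify every registry tag of ``data`` as present or absent."""
    return [CompletenessItem(spec.tag_name, spec.necessity,
                             _tag_present(data, spec.tag_name))
            for spec in REGISTRY.values()]


# ---------------------------------------------------------------------------
# consistency


def _check_elements(data: PAData, items: list[ConsistencyItem]) -> None:
    if data.device is None:
        return
    for kind, elements in (("illuminator", data.device.illuminators),
                           ("detector", data.device.detectors)):
        for index, element in enumerate(elements):
            for name, tag in element.field_tags.items():
                value = getattr(element, name)
                if value is None:
                    continue
                spec = registry_lookup(tag)
                result = validate_value(spec, value)
                severity = ("error" if spec.necessity is Necessity.MINIMAL
                            else "warning")
                items.append(ConsistencyItem(
                    f"{kind}[{index}].{name}", result.ok,
                    "" if result.ok else result.message, severity))


def _cross_field_rules(data: PAData) -> list[ConsistencyItem]:
    items: list[ConsistencyItem] = []
    acq, tensor, device = data.acquisition, data.tensor, data.device

    def rule(tag: str, ok: bool, message: str) -> None:
        items.append(ConsistencyItem(tag, ok, "" if ok else message))

    if tensor is not None and device is not None and device.num_detectors:
        rule("tensor_vs_detector_count",
             tensor.shape[0] == device.num_detectors,
             f"tensor has {tensor.shape[0]} detector rows but the device "
             f"defines {device.num_detectors} detection elements")
    if device is not None:
        for declared, actual, name in (
                (device.declared_num_detectors, device.num_detectors, "detectors"),
                (device.declared_num_illuminators, device.num_illuminators,
                 "illuminators")):
            if declared is not None:
                rule(f"declared_num_{name}", int(declared) == actual,
                     f"file declares {declared} {name} but stores {actual}")
    if tensor is not None and "acquisition_wavelengths" in acq:
        n_wavelengths = int(np.asarray(acq["acquisition_wavelengths"]).ravel().size)
        rule("tensor_vs_wavelength_count",
             tensor.shape[2] == n_wavelengths,
             f"tensor has {tensor.shape[2]} wavelength planes but "
             f"{n_wavelengths} acquisition wavelengths are listed")
    if device is not None and "device_reference_uuid" in acq:
        rule("device_reference_uuid_match",
             acq["device_reference_uuid"] == device.uuid,
             "acquisition references device "
             f"{acq['device_reference_uuid']!r} but the attached device is "
             f"{device.uuid!r}")
    if acq.get("scanning_method") == "full_scan" and "measurements_per_image" in acq:
        rule("full_scan_measurements_per_image",
             int(acq["measurements_per_image"]) == 1,
             "full_scan requires measurements_per_image == 1, got "
             f"{acq['measurements_per_image']}")
    if tensor is not None:
        for tag, axis, axis_name in (("element_dependent_gain", 0, "detector"),
                                     ("time_gain_compensation", 1, "time-sample"),
                                     ("measurement_timestamps", 3, "measurement"),
                                     ("temperature_control", 3, "measurement")):
            if tag in acq:
                length = int(np.asarray(acq[tag]).ravel().size)
                rule(f"{tag}_length", length == tensor.shape[axis],
                     f"{tag} has {length} entries but the tensor has "
                     f"{tensor.shape[axis]} {axis_name}s")
        if "measurement_spatial_poses" in acq:
            poses = np.asarray(acq["measurement_spatial_poses"])
            rows = poses.shape[0] if poses.ndim == 2 else poses.ravel().size // 6
            rule("measurement_spatial_poses_length", rows == tensor.shape[3],
                 f"{rows} poses for {tensor.shape[3]} measurements")
    return items


def check_consistency(data: PAData) -> list[ConsistencyItem]:
    """Evaluate every present tag against its constraint plus cross-field rules."""
    items: list[ConsistencyItem] = []
    for tag, value in data.acquisition.items():
        spec = registry_lookup(tag)
        result = validate_value(spec, value)
        severity = "error" if spec.necessity is Necessity.MINIMAL else "warning"
        items.append(ConsistencyItem(tag, result.ok,
                                     "" if result.ok else result.message,
                                     severity))
    if data.device is not None:
        result = validate_value(registry_lookup("device_uuid"), data.device.uuid)
        items.append(ConsistencyItem("device_uuid", result.ok,
                                     "" if result.ok else result.message))
        if data.device.field_of_view is not None:
            result = validate_value(registry_lookup("device_field_of_view"),
                                    data.device.field_of_view)
            items.append(ConsistencyItem(
                "device_field_of_view", result.ok,
                "" if result.ok else result.message, "warning"))
    _check_elements(data, items)
    items.extend(_cross_field_rules(data))
    return items


def quality_check(data: PAData) -> QCReport:
    """Run completeness and consistency checks and bundle the outcome."""
    return QCReport(completeness=check_completeness(data),
                    consistency=check_consistency(data))


def write_report(report: QCReport, path: str | os.PathLike) -> None:
    """Write the human-readable rendering; identical reports yield
    byte-identical files."""
    with open(os.fspath(path), "w", encoding="utf-8", newline="\n") as handle:
        handle.write(report.render())


# ---------------------------------------------------------------------------
# visual control


def visualize_device(device: DeviceMetadata, out: str | os.PathLike) -> None:
    """Render detector/illuminator positions, orientations and the
    field-of-view cuboid as a static 3-D figure (PNG).

    Axis convention: x1 lateral, x2 axial, x3 elevation, all in metres.
    """
    if device is None or device.num_detectors == 0:
        raise ValueError("cannot visualise a device without detection elements")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt  # noqa: F401

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")

    det = device.detector_positions()
    ax.scatter(det[:, 0], det[:, 1], det[:, 2], c="tab:blue", s=12,
               label=f"detectors (n={device.num_detectors})")
    extent = max(float(np.ptp(det, axis=0).max()), 1e-3)
    arrow = 0.1 * extent

    def _quiver(elements, color):
        starts, dirs = [], []
        for element in elements:
            if element.position is None or element.orientation is None:
                continue
            starts.append(np.asarray(element.position, dtype=float).ravel())
            dirs.append(np.asarray(element.orientation, dtype=float).ravel())
        if starts:
            starts, dirs = np.asarray(starts), np.asarray(dirs)
            ax.quiver(starts[:, 0], starts[:, 1], starts[:, 2],
                      dirs[:, 0], dirs[:, 1], dirs[:, 2],
                      length=arrow, color=color, linewidth=0.7)

    _quiver(device.detectors, "tab:blue")
    if device.illuminators:
        ill = np.asarray([np.asarray(e.position, dtype=float).ravel()
                          for e in device.illuminators
                          if e.position is not None])
        if ill.size:
            ax.scatter(ill[:, 0], ill[:, 1], ill[:, 2], c="tab:orange", s=20,
                       marker="^",
                       label=f"illuminators (n={device.num_illuminators})")
        _quiver(device.illuminators, "tab:orange")

    if device.field_of_view is not None:
        x1s, x1e, x2s, x2e, x3s, x3e = np.asarray(
            device.field_of_view, dtype=float).ravel()
        corners = np.array([[x1, x2, x3] for x1 in (x1s, x1e)
                            for x2 in (x2s, x2e) for x3 in (x3s, x3e)])
        edges = [(0, 1), (0, 2), (0, 4), (1, 3), (1, 5), (2, 3), (2, 6),
                 (3, 7), (4, 5), (4, 6), (5, 7), (6, 7)]
        for a, b in edges:
            ax.plot(*zip(corners[a], corners[b]), c="tab:green", lw=0.8)

    ax.set_xlabel("x1 (lateral) [m]")
    ax.set_ylabel("x2 (axial) [m]")
    ax.set_zlabel("x3 (elevation) [m]")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(os.fspath(out), dpi=120)
    plt.close(fig)
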