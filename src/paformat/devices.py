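"""Programmatic construction of standard device digital twins.

All factories follow the shared coordinate convention: x1 is the lateral
axis of the imaging plane, x2 the axial (depth) axis, x3 the elevation
normal; positions are metres.  Devices that image a 2-D plane encode a
collapsed elevation axis by setting ``x3start == x3end == 0`` in the field
of view.  Every factory is a pure function of its arguments (plus an
explicit seed for the random array) and its output passes the consistency
checker with zero failures.
"""

from __future__ import annotations

import copy
import hashlib

import numpy as np

from .metadata import DetectionElement, DeviceMetadata, IlluminationElement


def _deterministic_uuid(*parts) -> str:
    """Factories are pure functions of their arguments, so the device
    identity is derived from them rather than drawn at random."""
    digest = hashlib.md5("|".join(str(p) for p in parts).encode())
    return digest.hexdigest()

__all__ = [
    "build_linear_array",
    "build_arc_array",
    "build_random_array",
    "add_slit_illuminators",
]


def build_linear_array(n_detectors: int,
                       pitch: float,
                       element_size: tuple[float, float] = (0.24e-3, 5e-3),
                       fov_depth: float = 40e-3) -> DeviceMetadata:
    """A linear (hand-held-probe style) array along x1, looking into +x2.

    Detectors are equally spaced with centre-to-centre distance ``pitch`` and
    centred on x1 = 0, so the centroids span ``(n_detectors - 1) * pitch``
    laterally.  The field of view covers that lateral extent down to
    ``fov_depth`` axially, with the elevation axis collapsed (2-D device).

    Parameters
    ----------
    n_detectors : number of elements (>= 1)
    pitch : element spacing in metres (> 0)
    element_size : (lateral, elevation) extent of one rectangular element, m
    fov_depth : axial imaging depth in metres
    """
    if n_detectors < 1:
        raise ValueError("n_detectors must be >= 1")
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    offsets = (np.arange(n_detectors) - (n_detectors - 1) / 2.0) * pitch
    half_span = abs(offsets[-1]) if n_detectors > 1 else pitch / 2
    detectors = [
        DetectionElement(position=np.array([x1, 0.0, 0.0]),
                         orientation=np.array([0.0, 1.0, 0.0]),
                         geometry_type="rectangular",
                         geometry=np.asarray(element_size, dtype=float))
        for x1 in offsets]
    return DeviceMetadata(
        uuid=_deterministic_uuid("linear", n_detectors, pitch, element_size,
                                 fov_depth),
        field_of_view=np.array([-half_span, half_span, 0.0, fov_depth, 0.0, 0.0]),
        detectors=detectors)


def build_arc_array(n_detectors: int,
                    radius: float,
                    angular_span: float,
                    center: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> DeviceMetadata:
    """Detectors equally spaced on an arc in the x1–x2 (imaging) plane.

    All elements sit at distance ``radius`` from ``center`` and point at it.
    For a full circle (``angular_span == 2*pi``) the duplicate endpoint is
    omitted, giving angular gaps of ``2*pi / n``; shorter arcs are centred on
    the +x2 direction and include both endpoints, with gaps of
    ``angular_span / (n - 1)``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0 < angular_span <= 2 * np.pi + 1e-12:
        raise ValueError("angular_span must lie in (0, 2*pi]")
    center = np.asarray(center, dtype=float)
    if np.isclose(angular_span, 2 * np.pi):
        angles = 2 * np.pi * np.arange(n_detectors) / n_detectors
    elif n_detectors == 1:
        angles = np.array([np.pi / 2])
    else:
        angles = (np.pi / 2 - angular_span / 2
                  + angular_span * np.arange(n_detectors) / (n_detectors - 1))
    detectors = []
    for theta in angles:
        offset = radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        detectors.append(DetectionElement(
            position=center + offset,
            orientation=-offset / radius,
            geometry_type="point"))
    # inscribed square of the detection circle as reconstructable region
    half = radius / np.sqrt(2)
    fov = np.array([center[0] - half, center[0] + half,
                    center[1] - half, center[1] + half, 0.0, 0.0])
    return DeviceMetadata(
        uuid=_deterministic_uuid("arc", n_detectors, radius, angular_span,
                                 tuple(center)),
        field_of_view=fov, detectors=detectors)


def build_random_array(n_detectors: int,
                       bounds,
                       seed: int) -> DeviceMetadata:
    """Detectors placed uniformly at random inside a cuboid.

    ``bounds`` is the six-coordinate cuboid [x1s, x1e, x2s, x2e, x3s, x3e];
    axes with zero extent are allowed (planar or linear supports) but at
    least one axis must have positive extent.  Orientations point at the
    cuboid centre.  The same seed reproduces the identical device.
    """
    bounds = np.asarray(bounds, dtype=float).ravel()
    if bounds.size != 6:
        raise ValueError("bounds must hold six coordinates")
    lows, highs = bounds[0::2], bounds[1::2]
    if np.all(highs - lows == 0):
        raise ValueError("bounds are degenerate: zero extent on every axis")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(lows, highs, size=(n_detectors, 3))
    centre = (lows + highs) / 2.0
    detectors = []
    for pos in positions:
        direction = centre - pos
        norm = np.linalg.norm(direction)
        orientation = direction / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        detectors.append(DetectionElement(position=pos, orientation=orientation,
                                          geometry_type="point"))
    return DeviceMetadata(
        uuid=_deterministic_uuid("random", n_detectors, tuple(bounds), seed),
        field_of_view=bounds.copy(), detectors=detectors)


def add_slit_illuminators(device: DeviceMetadata,
                          offsets,
                          tilt: float = 0.0,
                          slit_size: tuple[float, float] = (25e-3, 1e-3),
                          wavelength_range=(660e-9, 1300e-9, 1e-9)) -> DeviceMetadata:
    """Return a copy of ``device`` with slit illuminators appended.

    Each offset places one slit at that elevation (x3) distance from the
    imaging plane, tilted by ``tilt`` radians back towards the plane, which
    models the bar-shaped fibre-bundle outputs mounted on either side of a
    hand-held linear probe.  An empty offset list returns an unchanged copy.
    """
    device = copy.deepcopy(device)
    for offset in offsets:
        sign = -1.0 if offset > 0 else 1.0
        orientation = np.array([0.0, np.cos(tilt), sign * np.sin(tilt)])
        device.illuminators.append(IlluminationElement(
            position=np.array([0.0, 0.0, float(offset)]),
            orientation=orientation / np.linalg.norm(orientation),
            geometry_type="slit",
            geometry=np.asarray(slit_size, dtype=float),
            wavelength_range=np.asarray(wavelength_range, dtype=float)))
    return device
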