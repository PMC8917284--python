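"""Synthetic forward model and reference delay-and-sum reconstruction.

The forward model is deliberately analytic so that every simulated sample
has a closed-form expectation: each point source emits a short pulse that
reaches detector *d* at the acoustic time of flight ``t = |r_d - r_s| / c``
with amplitude proportional to ``1 / |r_d - r_s|`` (spherical spreading in a
homogeneous, non-attenuating medium).  Contributions from multiple sources
add linearly and optional white Gaussian noise is applied afterwards, so the
noiseless path is bit-reproducible and doubling all source amplitudes
doubles every tensor value exactly.

The default excitation is the first derivative of a Gaussian (a bipolar,
zero-mean pulse, width 50 ns), which resembles the N-shaped signature of a
small absorber; a unipolar Gaussian is available for analyses that need the
trace maximum at the exact arrival sample.  Because the bipolar pulse
crosses zero at its centre, the reconstruction applies a Hilbert envelope to
each trace by default before summation, which places the image maximum at
the source position for either pulse shape.

No acoustic attenuation, detector frequency response or angular sensitivity
is modelled; the point of this stage is to validate the container format
end-to-end (simulate -> write -> audit -> read -> reconstruct) against
analytically known ground truth, not to emulate full wave physics.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .iohandler import missing_minimal_tags
from .metadata import (
    AcquisitionMetadata,
    DeviceMetadata,
    PAData,
    TimeSeriesTensor,
    new_hex_uuid,
)
from .registry import FILTER_UNSET

__all__ = [
    "Pulse",
    "PointSourceSet",
    "ReconstructionGrid",
    "simulate_time_series",
    "apply_frequency_filter",
    "backproject",
    "peak_location",
    "find_peaks",
    "save_reconstruction",
    "demo_setup",
    "DEMO_GEOMETRIES",
]


@dataclass(frozen=True)
class Pulse:
    """Temporal excitation profile.

    ``width`` is the Gaussian sigma in seconds; the bipolar
    gaussian-derivative is normalised to unit peak amplitude (extrema at
    plus/minus one sigma), the unipolar gaussian peaks at the arrival time.
    """

    shape: str = "gaussian-derivative"
    width: float = 50e-9

    def evaluate(self, offsets: np.ndarray) -> np.ndarray:
        u = offsets / self.width
        # compact support at 6 sigma: the tail is < 2e-8 of the peak and
        # cutting it keeps the forward model exactly linear in amplitude
        # (no subnormal tails)
        support = np.abs(u) < 6.0
        u = np.where(support, u, 0.0)
        if self.shape == "gaussian-derivative":
            return np.where(support, -u * np.exp(0.5 - 0.5 * u * u), 0.0)
        if self.shape == "gaussian":
            return np.where(support, np.exp(-0.5 * u * u), 0.0)
        raise ValueError(f"unknown pulse shape {self.shape!r}")


@dataclass
class PointSourceSet:
    """Point absorbers: positions (metres), unitless amplitudes, pulse."""

    positions: np.ndarray
    amplitudes: np.ndarray | float = 1.0
    pulse: Pulse = field(default_factory=Pulse)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size and self.positions.shape[1] != 3:
            raise ValueError("source positions must be 3-D coordinates")
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.ndim == 0:
            amps = np.full(len(self.positions), float(amps))
        self.amplitudes = amps

    def __len__(self) -> int:
        return 0 if self.positions.size == 0 else self.positions.shape[0]


def _sources_in_fov(sources: PointSourceSet, fov: np.ndarray) -> None:
    fov = np.asarray(fov, dtype=float).ravel()
    lows, highs = fov[0::2], fov[1::2]
    tol = 1e-12
    for pos in sources.positions:
        if np.any(pos < lows - tol) or np.any(pos > highs + tol):
            warnings.warn(
                f"source at {pos.tolist()} lies outside the device field of "
                "view; it will still be simulated", stacklevel=3)


def simulate_time_series(device: DeviceMetadata,
                         sources: PointSourceSet,
                         speed_of_sound: float = 1500.0,
                         sampling_rate: float = 40e6,
                         n_samples: int = 1024,
                         noise_sd: float = 0.0,
                         seed: int | None = None,
                         wavelengths=(800e-9,)) -> PAData:
    """Simulate raw time series for ``device`` and package a complete dataset.

    Returns a :class:`PAData` with all minimal metadata filled in and the
    device attached, ready to be written to a container file.

    Raises ``ValueError`` when ``n_samples`` cannot contain the latest
    arrival (the message cites the required minimum).
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if speed_of_sound <= 0:
        raise ValueError("speed_of_sound must be positive")
    detectors = device.detector_positions()
    n_det = detectors.shape[0]
    wavelengths = np.asarray(wavelengths, dtype=float)
    n_wl = wavelengths.size

    if device.field_of_view is not None and len(sources):
        _sources_in_fov(sources, device.field_of_view)

    clean = np.zeros((n_det, n_samples), dtype=float)
    if len(sources):
        # pairwise detector-source distances, (n_det, n_src)
        dist = np.linalg.norm(
            detectors[:, None, :] - sources.positions[None, :, :], axis=2)
        if np.any(dist == 0):
            raise ValueError("a source coincides with a detector position")
        pulse = sources.pulse
        tail = 3.0 * pulse.width
        required = int(np.ceil((dist.max() / speed_of_sound + tail)
                               * sampling_rate)) + 1
        if n_samples < required:
            raise ValueError(
                f"n_samples={n_samples} cannot contain the latest arrival; "
                f"at least {required} samples are required at "
                f"{sampling_rate:g} Hz")
        t = np.arange(n_samples) / sampling_rate
        # offsets (n_det, n_src, n_samples) memory: fine at desk scale
        offsets = t[None, None, :] - (dist / speed_of_sound)[:, :, None]
        waveforms = pulse.evaluate(offsets)
        weights = (sources.amplitudes[None, :] / dist)
        clean = np.einsum("ds,dst->dt", weights, waveforms)

    # a fixed seed makes the whole dataset (including its UUID) reproducible
    rng = np.random.default_rng(seed) if seed is not None else None
    values = np.repeat(clean[:, :, None], n_wl, axis=2)[:, :, :, None]
    if noise_sd > 0:
        noise_rng = rng if rng is not None else np.random.default_rng()
        values = values + noise_rng.normal(0.0, noise_sd, size=values.shape)

    acquisition = AcquisitionMetadata()
    acquisition["uuid"] = rng.bytes(16).hex() if rng is not None else new_hex_uuid()
    acquisition["compression"] = "none"
    acquisition["encoding"] = "raw"
    acquisition["ad_sampling_rate"] = float(sampling_rate)
    acquisition["acquisition_wavelengths"] = wavelengths
    if device.field_of_view is not None:
        acquisition["field_of_view"] = np.asarray(device.field_of_view, dtype=float)
    acquisition["speed_of_sound"] = float(speed_of_sound)
    acquisition["scanning_method"] = "full_scan"
    acquisition["measurements_per_image"] = 1
    acquisition["device_reference_uuid"] = device.uuid

    return PAData(tensor=TimeSeriesTensor(values), acquisition=acquisition,
                  device=device)


# ---------------------------------------------------------------------------
# frequency-domain filtering


def apply_frequency_filter(data: PAData, order: int = 4) -> PAData:
    """Apply the filter declared in ``frequency_domain_filter`` to each trace.

    The tag holds the [lower, higher] -3 dB points in hertz with -1 marking
    an unset edge: ``[lower, -1]`` is a high-pass, ``[-1, higher]`` a
    low-pass, both set a band-pass, and ``[-1, -1]`` is the identity.  A
    Butterworth design is used, whose natural cutoff *is* the -3 dB point.
    Returns a new dataset; the input is never mutated.
    """
    if "frequency_domain_filter" not in data.acquisition:
        raise KeyError("frequency_domain_filter is not set in the acquisition "
                       "metadata")
    if "ad_sampling_rate" not in data.acquisition:
        raise KeyError("ad_sampling_rate is required to design the filter")
    if data.tensor is None:
        raise ValueError("dataset holds no time-series tensor")
    edges = np.asarray(data.acquisition["frequency_domain_filter"],
                       dtype=float).ravel()
    lower, higher = float(edges[0]), float(edges[1])
    fs = float(data.acquisition["ad_sampling_rate"])
    nyquist = fs / 2.0

    filtered = data.tensor.values.astype(float, copy=True)
    if not (lower == FILTER_UNSET and higher == FILTER_UNSET):
        for edge in (lower, higher):
            if edge != FILTER_UNSET and edge >= nyquist:
                raise ValueError(
                    f"filter edge {edge:g} Hz is at or above the Nyquist "
                    f"frequency {nyquist:g} Hz")
        if lower != FILTER_UNSET and higher != FILTER_UNSET:
            sos = _signal.butter(order, [lower, higher], btype="bandpass",
                                 fs=fs, output="sos")
        elif lower != FILTER_UNSET:
            sos = _signal.butter(order, lower, btype="highpass", fs=fs,
                                 output="sos")
        else:
            sos = _signal.butter(order, higher, btype="lowpass", fs=fs,
                                 output="sos")
        filtered = _signal.sosfilt(sos, filtered, axis=1)

    out = PAData(tensor=TimeSeriesTensor(filtered),
                 acquisition=AcquisitionMetadata(),
                 device=data.device,
                 custom=dict(data.custom))
    for tag, value in data.acquisition.items():
        out.acquisition.set_unchecked(tag, value)
    out.acquisition.measurement_devices = dict(
        data.acquisition.measurement_devices)
    return out


# ---------------------------------------------------------------------------
# reconstruction


@dataclass(frozen=True)
class ReconstructionGrid:
    """Regular grid spanning the field of view; axes hold node coordinates."""

    axes: tuple[np.ndarray, np.ndarray, np.ndarray]
    spacing: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(len(axis) for axis in self.axes)

    def points(self) -> np.ndarray:
        """(N, 3) array of all node coordinates, C-order."""
        mesh = np.meshgrid(*self.axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    def coordinate(self, index: tuple[int, int, int]) -> np.ndarray:
        return np.array([self.axes[i][index[i]] for i in range(3)])


def _grid_from_fov(fov: np.ndarray, spacing: float) -> ReconstructionGrid:
    fov = np.asarray(fov, dtype=float).ravel()
    axes = []
    for start, end in zip(fov[0::2], fov[1::2]):
        if end <= start:
            axes.append(np.array([start]))
        else:
            n = int(np.floor((end - start) / spacing + 1e-9)) + 1
            axes.append(start + spacing * np.arange(n))
    return ReconstructionGrid(axes=tuple(axes), spacing=spacing)


def backproject(data: PAData, grid_spacing: float, *,
                envelope: bool = True,
                wavelength_index: int = 0,
                measurement_index: int = 0) -> tuple[np.ndarray, ReconstructionGrid]:
    """Delay-and-sum back projection over the field of view.

    Each grid point accumulates, over all detectors, the trace value at the
    sample nearest the acoustic time of flight from that point (no
    interpolation, which keeps the operation exactly testable).  If present,
    ``overall_gain``, ``element_dependent_gain`` and ``time_gain_compensation``
    are divided out first.  With ``envelope=True`` (default) each trace is
    replaced by its Hilbert envelope before summation so that bipolar pulses
    focus constructively at the source position.

    Only a scalar speed of sound is supported; heterogeneous maps raise.
    Returns ``(image, grid)`` with ``image`` shaped like the grid.
    """
    missing = missing_minimal_tags(data)
    if missing:
        raise ValueError("dataset is not reconstructible; missing minimal "
                         "metadata: " + ", ".join(missing))
    sos_value = np.asarray(data.acquisition["speed_of_sound"]) \
        if "speed_of_sound" in data.acquisition else None
    if sos_value is None:
        raise ValueError("speed_of_sound is required for back projection")
    if sos_value.ndim != 0:
        raise ValueError("heterogeneous speed-of-sound maps are not supported "
                         "by this delay-and-sum implementation")
    c = float(sos_value)
    fs = float(data.acquisition["ad_sampling_rate"])
    fov = np.asarray(data.acquisition["field_of_view"], dtype=float)

    traces = np.asarray(
        data.tensor.values[:, :, wavelength_index, measurement_index],
        dtype=float)
    acq = data.acquisition
    if "overall_gain" in acq:
        traces = traces / float(acq["overall_gain"])
    if "element_dependent_gain" in acq:
        traces = traces / np.asarray(acq["element_dependent_gain"],
                                     dtype=float)[:, None]
    if "time_gain_compensation" in acq:
        traces = traces / np.asarray(acq["time_gain_compensation"],
                                     dtype=float)[None, :]
    if envelope and np.any(traces):
        traces = np.abs(_signal.hilbert(traces, axis=1))

    grid = _grid_from_fov(fov, grid_spacing)
    points = grid.points()
    detectors = data.device.detector_positions()
    n_samples = traces.shape[1]

    # times of flight -> nearest sample, (n_points, n_detectors)
    dist = np.linalg.norm(points[:, None, :] - detectors[None, :, :], axis=2)
    indices = np.rint(dist / c * fs).astype(np.int64)
    valid = indices < n_samples
    indices[~valid] = 0
    gathered = traces[np.arange(detectors.shape[0])[None, :], indices]
    gathered[~valid] = 0.0
    image = gathered.sum(axis=1).reshape(grid.shape)
    return image, grid


def peak_location(image: np.ndarray, grid: ReconstructionGrid) -> np.ndarray:
    """Coordinates (metres) of the maximum-amplitude grid node.

    Ties break to the lowest flat (C-order) index.  A constant image has no
    meaningful peak and raises ``ValueError``.
    """
    image = np.asarray(image)
    if image.max() == image.min():
        raise ValueError("image is constant; no peak to locate")
    index = np.unravel_index(int(np.argmax(image)), image.shape)
    return grid.coordinate(index)


def find_peaks(image: np.ndarray, grid: ReconstructionGrid, n_peaks: int,
               min_distance: float) -> np.ndarray:
    """Greedy extraction of ``n_peaks`` local maxima at least
    ``min_distance`` metres apart (iterative peak-and-suppress)."""
    working = np.asarray(image, dtype=float).copy()
    points = grid.points()
    floor = working.min()
    peaks = []
    for _ in range(n_peaks):
        location = peak_location(working, grid)
        peaks.append(location)
        suppress = np.linalg.norm(points - location, axis=1) <= min_distance
        working.ravel()[suppress] = floor
    return np.asarray(peaks)


def save_reconstruction(image: np.ndarray, grid: ReconstructionGrid,
                        path: str | os.PathLike,
                        png_path: str | os.PathLike | None = None) -> None:
    """Store a reconstructed image with its grid geometry; optional PNG
    preview of the maximum projection along the elevation axis."""
    import h5py

    with h5py.File(os.fspath(path), "w") as handle:
        dset = handle.create_dataset("reconstruction", data=np.asarray(image))
        dset.attrs["grid_spacing"] = grid.spacing
        for i, axis in enumerate(grid.axes):
            handle.create_dataset(f"grid_axis_{i + 1}", data=axis)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        projection = np.asarray(image).max(axis=2).T
        fig, ax = plt.subplots(figsize=(6, 5))
        extent = [grid.axes[0][0], grid.axes[0][-1],
                  grid.axes[1][-1], grid.axes[1][0]]
        ax.imshow(projection, extent=extent, cmap="viridis", aspect="equal")
        ax.set_xlabel("x1 (lateral) [m]")
        ax.set_ylabel("x2 (axial) [m]")
        fig.tight_layout()
        fig.savefig(os.fspath(png_path), dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# desk-scale demonstration setups (simulate -> store -> reconstruct loop)

DEMO_GEOMETRIES = ("linear", "arc180", "arc360", "random")

#: fractional (x1, x2) positions of the three demo sources inside the FOV
_DEMO_SOURCE_FRACTIONS = ((0.30, 0.35), (0.50, 0.65), (0.72, 0.50))


def demo_setup(geometry: str, seed: int = 0):
    """Build one of the four standard demonstration arrays plus three point
    sources placed inside its field of view.

    Geometries: a 128-element linear probe (0.3 mm pitch), 128-element
    semi-circular and 256-element full-circle arrays of 20 mm radius, and a
    64-element random planar array in a 44 mm square.  Returns
    ``(device, sources)``.
    """
    from . import devices as _devices

    if geometry == "linear":
        device = _devices.build_linear_array(128, 0.3e-3)
        device = _devices.add_slit_illuminators(device, (-5.8e-3, 5.8e-3),
                                                tilt=np.deg2rad(25))
    elif geometry == "arc180":
        device = _devices.build_arc_array(128, 20e-3, np.pi)
    elif geometry == "arc360":
        device = _devices.build_arc_array(256, 20e-3, 2 * np.pi)
    elif geometry == "random":
        device = _devices.build_random_array(
            64, [-22e-3, 22e-3, -22e-3, 22e-3, 0.0, 0.0], seed=seed)
    else:
        raise ValueError(f"unknown demo geometry {geometry!r}; "
                         f"choose from {DEMO_GEOMETRIES}")

    # deterministic device identity so repeated runs produce identical files
    import hashlib
    device.uuid = hashlib.md5(f"{geometry}-{seed}".encode()).hexdigest()

    fov = np.asarray(device.field_of_view, dtype=float)
    positions = []
    for f1, f2 in _DEMO_SOURCE_FRACTIONS:
        positions.append([fov[0] + f1 * (fov[1] - fov[0]),
                          fov[2] + f2 * (fov[3] - fov[2]),
                          0.0])
    return device, PointSourceSet(positions=np.asarray(positions))
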