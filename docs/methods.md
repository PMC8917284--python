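# Methods

This note documents the models, conventions and numerical choices behind
`paformat`, and what the synthetic validation loop does and does not show.

## The metadata schema

The registry holds 44 tags in five categories: 9 minimal tags forming the
six documented minimal items (container format = uuid/compression/encoding;
binary descriptors = data_type/dimensionality/sizes; A/D sampling rate;
acquisition wavelengths; detector positions, housed per-element in the
device description; field of view), 14 acquisition tags, 4 device-level
tags, 11 illumination-element tags and 6 detection-element tags. Each tag
carries a semantic dtype (scalar-number, number-array, string, string-enum,
coordinate-array, map), an SI unit string and a decidable constraint
predicate.

Conventions that were genuinely open and fixed here:

- **Tensor axis order** is `[detectors, time_samples, wavelengths,
  measurements]`. Only the descriptors are mandated by the schema; one
  canonical order removes ambiguity for every consumer, and lower-rank
  input is padded with trailing singleton axes.
- **Temperatures in kelvin** (strict SI), despite the clinical °C habit.
- **UUIDs** are random 32-hex-digit strings (version-4 style). Device
  factories instead *derive* the UUID from a hash of their arguments so
  that factory output is a pure function of its inputs (same arguments,
  same digital twin) and fixed-seed pipelines write byte-identical files.
- **`pulse_energy`** accepts a scalar (possibly pulse-averaged) or one
  value per measurement; both readings are in use in practice.
- **Measurement spatial pose** is `[dx1, dx2, dx3, rot_x1, rot_x2, rot_x3]`
  relative to the first measurement, rotations in radians.
- **`speed_of_sound`** is a positive scalar (global mean) or a 3-D map;
  any other rank is rejected.
- **`temperature_control`** is stored as a measured per-measurement series,
  not a setpoint.
- Missing optional values are **absent keys**, never NaN sentinels.
- **Frequency-domain filter**: `[lower, higher]` −3 dB points in Hz with
  −1 marking an unset edge; `[lower, −1]` is a high-pass, `[−1, higher]` a
  low-pass, `[−1, −1]` the identity.

## Strictness model

Assignment (`set_metadatum`, mapping assignment) is strict: dtype or
constraint violations raise `TypeError` immediately, so datasets built
through the API are correct by construction. The file *reader* is lenient:
values load unchecked so that imperfect third-party files can be opened and
audited. The quality-control engine then distinguishes severities:
missing minimal tags and cross-field contradictions (tensor shape vs
detector count, wavelength-axis length, device-reference mismatch,
full-scan ⇒ one measurement per image, gain-curve lengths) are **errors**;
constraint violations on report-if-present tags are **warnings**. A report
passes overall when no errors are present; `strict_pass` (CLI `--strict`)
additionally promotes warnings. This is the only severity model under
which all three requirements — openable broken files, hard completeness
failures, and non-fatal optional-tag issues — hold at once.

## Container layout

One HDF5 file: the payload dataset `binary_time_series_data` (descriptors
as its attributes), `meta_data` for acquisition tags, `meta_data_device`
with a `general` group and zero-padded per-element groups
(`detectors/000000`, ...) to guarantee ordering, and `custom`. Scalars and
strings are stored as named attributes, arrays as datasets (large arrays as
attributes are impractical), mappings as sub-groups. Strings are UTF-8;
timestamps are float seconds since the Unix epoch; calibration dates are
ISO-8601 strings. The payload is uncompressed by default with an opt-in
gzip flag recorded in the `compression` tag. Unknown attributes found in a
file land in the custom namespace rather than being dropped.

## Forward model

Each point source *s* contributes to detector *d* a pulse centred at the
time of flight `t_ds = |r_d − r_s| / c` with amplitude `a_s / |r_d − r_s|`
(spherical spreading in a homogeneous, lossless medium); contributions sum
linearly; optional white Gaussian noise is added last. The default pulse is
the first derivative of a Gaussian (bipolar, zero-mean, σ = 50 ns,
normalised to unit extrema), resembling the N-shaped signature of a small
absorber; a unipolar Gaussian is available when an analysis needs the trace
maximum exactly at the arrival sample. The pulse is truncated at 6σ
(tail < 2·10⁻⁸ of the peak), which keeps the model exactly linear in the
amplitudes in floating point (no subnormal tails). Detector frequency
response, angular response and acoustic attenuation are deliberately not
modelled: the stage exists to validate the container end-to-end against
closed-form expectations, not to replace full-wave simulation.

`n_samples` must cover the latest arrival plus a 3σ pulse tail; the error
message cites the required minimum. Sources outside the device field of
view warn but simulate.

## Filtering

`apply_frequency_filter` realises the declared filter with a 4th-order
Butterworth (`scipy.signal.butter`/`sosfilt`, causal single pass), whose
natural cutoff *is* the −3 dB point — verified in the tests against an FFT
transfer-function oracle to ±0.5 dB. Edges at or above Nyquist are
rejected. Filtering is applied per detector trace and returns a new
dataset.

## Reconstruction

Delay-and-sum: every grid node accumulates, over detectors, the trace value
at the sample nearest `|r − r_d| / c · f_s` (nearest-sample lookup, no
interpolation, for exact testability). Declared `overall_gain`,
`element_dependent_gain` and `time_gain_compensation` are divided out
first. By default each trace is replaced by its Hilbert envelope before
summation: the envelope of the bipolar pulse peaks at the arrival time, so
the image maximum lands on the source for any pulse shape; `envelope=False`
gives the plain coherent sum. The grid spans the acquisition field of view
at the requested spacing (collapsed axes become single-node axes). Only a
scalar speed of sound is supported; heterogeneous maps raise a documented
error. Peak extraction uses flat argmax with lowest-index tie-break;
multi-peak extraction iterates argmax with spherical suppression.

## Demonstration conditions

The four standard geometries are a 128-element linear probe (0.3 mm pitch,
40 mm depth, two slit illuminators at ±5.8 mm elevation tilted 25°), 128-
and 256-element arcs/rings of 20 mm radius, and a 64-element random planar
array in a 44 mm square. Three unit-amplitude point sources sit at fixed
fractional positions of each field of view (≥ 5 mm apart). Simulation uses
c = 1500 m/s, f_s = 40 MHz, 1200 samples, additive noise σ = 0.05
(signal peaks are ~30–50 in these units), and reconstruction uses a
0.25 mm grid. These desk-scale sizes keep the full four-geometry loop
under ten seconds while leaving localisation errors (measured at ~0.3–0.7
cells) clearly resolvable against the 1–2-cell acceptance bands.

## What the synthetic loop does and does not show

Passing the loop demonstrates that the container round-trips every field
bit-exactly, that the QC engine is sensitive to each minimal-tag deletion
and sound on well-formed data, and that the stored metadata suffice to
reconstruct an image — the core promise of the format. It does **not**
demonstrate reconstruction quality on real tissue data: real signals
include bandlimited transducer responses, directivity, attenuation,
heterogeneous sound speed and structured noise, none of which the analytic
forward model emulates.

## Known limitations

- Bimodal (photoacoustic + ultrasound) storage is out of scope.
- No streaming/partial reads; files are read whole.
- No recovery from corrupted HDF5 beyond clean integrity errors.
- Back projection is the only reconstruction; no model-based or k-space
  methods, no fluence correction.
- The visual device control is a static raster image, by design — it is a
  human check, with no automated pass/fail threshold.
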