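# Methods

This note documents the models behind `pamloc`, the defaults and why
they were chosen, the numerical details that matter for accuracy, and
what the synthetic benchmarks do and do not demonstrate about real
recordings.

## Coordinate conventions

Right-handed axes: +y forward (direction of travel), +x starboard,
+z up.  Bearings are (azimuth, elevation) in degrees; azimuth 0° is
forward, clockwise positive viewed from above, wrapped to [−180, 180);
elevation positive up, in [−90, 90].  The unit pointing vector is
`u = (sin θ cos φ, cos θ cos φ, sin φ)`.  Array positions are always
re-centered so their mean is the coordinate origin; source positions are
given as (bearing, horizontal range, depth) relative to that center,
with depth measured straight down (−z).

Streamer arrays are two parallel lines of hydrophones along +y.  The
two shipped geometries have 4 hydrophones per streamer with 2.8 m
("long") or 1.5 m ("short") spacing.  The cross-streamer separation is
8.5 m — the mean of two in-field buoy measurements (8.37 m and 8.60 m)
of an assembled array; exact per-deployment geometries vary, so both
the separation and full custom geometries are configurable through the
YAML array format.

Drift and sinking are rigid rotations: azimuth `a` about +z (clockwise
from above) composed with elevation `e` tilting the forward axis
(negative `e` = sinking), applied so the forward axis maps onto the unit
vector of bearing (a, e).  Pairwise distances are preserved to 1e-9 m.

## Propagation model

Spherical spreading only: received level `RL = SL − 20 log₁₀(d / 1 m)`,
propagation delay `d / c`.  Defaults: sound speed `c` = 1500 m/s
(configurable; open-water nominal), sample rate 48 kHz (comfortably
above twice the 10 kHz analysis band).  Levels are dB re 1 µPa (p-p
convention); only level *differences* matter anywhere in the package,
so the p-p/RMS distinction is treated as an opaque constant.
`calibration_db` (default 170, the loudest interference level used in
the experiment grids) maps the physical dB scale to digital full scale;
samples beyond ±1 are hard-clipped and the clipped fraction is always
reported on the rendered audio, never silently discarded.

Refraction, multipath, absorption, Doppler, and sea-state noise are out
of scope.  Interfering noise is rendered as a *positioned point source*
by default so the localizer can lock onto an interfering vessel exactly
as happens at sea when the interference dominates a window; a diffuse
uncorrelated-noise term exists (`Scenario.diffuse_noise_db`) but is off
by default.

Fractional delays use a 64-tap Kaiser-windowed (β = 8.6) sinc
interpolator.  Nearest-sample rounding would quantize TDOAs to ±0.5
samples (≈ 0.2° of bearing on these apertures), an order of magnitude
above the accuracy the chirp benchmark demonstrates; with the windowed
sinc, rendered inter-channel delays match exact geometry to well under
0.1 sample across the 800 Hz – 11 kHz band.

The interference-noise position (1000 m range at its stated bearing)
was fixed by consistency: with target SL 156 and noise levels 167/170
it reproduces all three reference SNR examples (−14.0, −9.3, −6.6 dB)
and the grid extremes (+3.0 to −14.2 dB) exactly, which pins the range
uniquely.

## Signal surrogates

Real orca call recordings are not redistributable, so the generators
produce structural surrogates: a 2 ms linear chirp (500 Hz – 11 kHz,
light Tukey taper) as the Dirac-like probe with a sharp autocorrelation;
harmonic stacks (1/k amplitude roll-off, interpolated fundamental
contour) as tonal calls, with two presets — `N-flat` (constant 2.2 kHz
contour, emulating the near-constant call types whose self-similarity
makes correlation-based TDOA less reliable) and `N-mod` (frequency
modulated, typical of the remaining repertoire); white and
low-frequency-weighted "boat" noise (first-order roll-off above 300 Hz
plus a 120 Hz engine-harmonic comb) as interference surrogates.  All
generators are deterministic given their parameters and seed.

Filters (500 Hz – 10 kHz band-pass, 1.5 kHz high-pass — the field
presets for stripping vessel rumble and electronic interference) are
zero-phase forward-backward Butterworth (order 4 per pass), chosen so
that filtering cannot bias TDOA estimates; the effective stop-band
attenuation exceeds 40 dB.

## Detection

The front-end mirrors a CNN-style input pipeline: Hann STFT (2048
points, 75 % overlap — only the output shape and band are canonical, so
these are package choices), power → dB with a 1e-20 power floor (−200
dB, far below any renderable signal, so digital silence never masks a
real one), crop to 800 Hz – 10 kHz, bilinear resample to 256 × 128,
min-max normalize to [0, 1].  A constant window is flagged degenerate
rather than divided by zero.

The baseline `EnergyClassifier` stands in for a trained network behind
the same contract (deterministic spectrogram → confidence map).  Its
statistic is the peak-over-frames mean in-band power (dB) computed
before normalization; confidence is a logistic in that statistic minus
the recording's noise floor (median per-window statistic), scale 4 dB.
The peak-frame form makes a 2 ms transient in a 2 s window fully
visible to the detector.  Defaults: window 2 s, step 0.5 s, threshold
0.92 (configurable down to 0.40 for weak targets).  Maximal runs of
consecutive positive windows merge into events with first /
intermediate / last position labels; a single-window event is "first".

An energy classifier is *not* a neural detector: it has no selectivity
for call structure, so detection-rate numbers from the synthetic grids
characterize the energy margin of the scenes, not the discrimination
performance of a trained network.  Confidence is provably monotone in
in-band energy, which is what the SNR-response properties test.

## Localization

TDOAs: GCC of one reference channel (default 0) against all others,
plain cross-correlation by default (PHAT optional), search clamped to
±(baseline/c + 1 sample), 3-point parabolic sub-sample refinement.
Positive delay = later arrival than the reference.

Bearing: least-squares fit of the far-field plane-wave delay model over
a full spherical grid, default 1° resolution, scanned azimuth-major
with elevation ascending; ties take the first minimum in scan order,
which for the up/down-ambiguous planar surface array resolves toward
non-positive elevation (sources are at or below a surface-towed array).
A separable parabolic fit over the 3×3 neighborhood (azimuth wrapping
circularly, offsets clamped to one cell) gives sub-grid precision.

**Pairing.**  The grid-search cost defaults to *all* hydrophone pairs,
derived from the reference-vs-all measurements by differencing
(`τ_ij = τ_j − τ_i`).  This is deliberate: at 200 m range on a ~12 m
aperture the wavefront is measurably curved, and fitting a plane-wave
model with a reference-anchored cost leaves a systematic azimuth bias
of ≈ 0.17° mean (long array, exact delays) because the reference
hydrophone's curvature error propagates into every term.  Summing over
all pairs balances the curvature contributions and reduces the bias to
≈ 0.003° on the same test — the difference between meeting and missing
a 0.035° accuracy target.  `pairing="ref"` remains available.

The alignment-offset estimator for field deployments without a surveyed
array heading assumes bearing errors are zero-mean about an unknown
constant offset and iterates
`δ ← δ + mean(wrap(measured − reference − δ))` until the mean signed
error is below tolerance (default 0.01°); non-convergence raises an
error carrying the last iterate.

## Experiment grids

Five presets mirror a staged evaluation design: `exp1` noiseless 2 ms
chirps, 200 m, both arrays (systematic-error floor and directional
dependency); `exp2` call structures at 200–400 m with medium vessel
noise (SNR +3 to −4 dB); `exp3` the full SNR ladder, 200–1000 m ×
{0, 100, 200} m depth × {none, medium 167 dB, strong 170 dB} noise
(+3 to −14.2 dB); `exp4` drift (a = 15°) and sinking (e = −3°, −5°,
−90°) rendered with the rotated geometry but localized with the nominal
one; `exp5` two simultaneous callers (second caller at twice the range,
+77° offset, 0.1 s later) with light white noise at 305° (+3 to −3 dB).
The full direction grid is 120 emissions at 3° steps; desk-scaled
defaults thin directions (and for the larger grids some parameter
levels) to keep single-CPU runs in the minutes range — the complete
grids are available via `desk_scale=False` / `--full`.

Scenario layout: calls (1 s) are embedded at onset 3 s in 12 s
recordings, chirps in 8 s recordings, so that windows containing the
event are a minority and the median-based noise floor is uncontaminated.
An embedded event counts as detected when at least one positive window
overlaps its arrival span (the granularity of "detected" is otherwise a
matter of convention).  Error aggregates are reported per localized
window by default, with per-event averaging (`mode="event"`) as the
alternative; per-seed determinism derives every scenario's noise seed
from the config seed and the combination index.

SNR-response curves fit a 3rd-degree polynomial through per-SNR-bin
means.  On desk-scaled grids the detection transition is sharp, and a
cubic through a step overshoots (Runge behaviour); monotonicity checks
therefore read the bin means, not the interpolant.

## What the benchmarks show — and don't

The chirp sweep bounds the *systematic* error of the chain
(rendering + GCC + grid search) under ideal conditions: ≈ 0.003° mean
azimuth error on both arrays, errors at cardinal bearings smaller than
at diagonals, no mirror asymmetry.  Real deployments add hardware
mismatch between hydrophones, impulsive interference, multipath, and
array-shape uncertainty, none of which the simulator models — field
bearing errors of tens of degrees are consistent with this chain even
when the geometric core is exact.  Likewise the synthetic detection
rates characterize energy margins of the rendered scenes, not a trained
classifier's selectivity.  What transfers to the field is the geometric
machinery: the TDOA sign conventions, the grid-search behaviour
(including its curvature bias and the all-pairs remedy), the
drift/sink sensitivities, and the alignment-offset estimator.

## Known limitations

- Planar surface arrays cannot distinguish up from down; elevation is
  reported but only meaningful up to that ambiguity (resolved downward).
- The far-field model is biased at short range; below ~100 m on these
  apertures even the all-pairs cost degrades, and range estimation is
  explicitly out of scope.
- Constant-frequency tonal calls are self-similar; correlation peaks
  can lock one period off, which is the structural reason flat call
  types localize worse than modulated ones.
- The energy classifier ignores spectro-temporal structure entirely;
  any detection-rate number from it is a lower-bound sanity check, not
  a CNN benchmark.
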