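# Methods

## Measurement model

A fixed camera photographs the crop daily together with a vertical marker
bar of known geometry (default: 250 cm long, buried 20 cm, so 230 cm above
ground, painted in 10 cm red/white stripes). The canopy occludes the bar
from below, so the visible bar length is a proxy for crop height. With
`I` (px) and `L` (cm) the visible bar in the *initial* frame and `R` (cm)
the crop height on that day, a later detection of `M` px gives

    H = ((I - M) / I) * L + R.

The model assumes a fixed camera and bar (one calibration per deployment),
an approximately uniform cm-per-pixel scale along the bar (the camera is
far enough away that perspective nonlinearity is negligible), and a crop
front that rises roughly evenly at the bar's position. `H` is a point
measurement at the bar, not a field average.

Because `I` is *measured by the pipeline itself* on the initial frame, any
systematic bias of the detector (see below) enters numerator and
denominator alike and largely cancels; calibrating `I` from geometry alone
would convert that bias into a height offset.

## Pipeline stages and parameters

**Feature plane.** `excess_green` (default): ExG = 2G − R − B, signed and
unclipped; both stripe colours score ≤ 0 while green or gold vegetation
scores high, and additive channel-common illumination shifts cancel
exactly. `red_band` uses the inverted red band 255 − R so that the bar is
dark in both feature spaces and one sign convention serves both; under a
zero-sum kernel the inversion is observationally identical to running the
raw band with flipped polarity.

**Marker kernel.** Side `2w + 1` for a bar `w` px wide (default w = 5 →
11×11), central `w` columns −(w+1), flanking (w+1)/2 columns per side +w.
The magnitudes are the smallest integers giving zero row sums for every
odd `w`; only the sign structure and zero-sum property are constrained by
the design, so any other zero-row-sum choice merely rescales the response
and the threshold with it. `w` must match the bar's apparent width: halve
the image resolution and w = 3 (7×7) is appropriate, enlarge it and w = 7
(15×15) is. Convolution is correlation with edge replication (output size
= input size, so run lengths are comparable across frames); every shipped
kernel is mirror-symmetric about its vertical centre line, so the
flip/no-flip distinction is unobservable.

**Threshold.** Strictly greater → 1, equal → 0. The shipped default 2000
is in response units of the ExG + 11×11 kernel pipeline at the reference
scale; `select_threshold` formalises the histogram-based manual choice as
the midpoint of the gap between labelled marker and background samples
and refuses to guess when the classes overlap. A midpoint-learned
threshold sits high above the noise floor and is therefore *less* robust
to global contrast loss than the fixed default, which sits just above the
background tail — this is why the series pipeline runs ExG with the fixed
default while a red-band pipeline, whose response units differ, must
learn its level per deployment.

**Detection.** The bar is the longest maximal contiguous run of 1-pixels
within a single column; no gap bridging (the kernel is designed to make
the bar solid, and its height — always exceeding one stripe period —
guarantees at least one red row in every window along the bar).
Tie-breaks are leftmost column then topmost row, fixing determinism. The
detected run systematically overhangs the true bar by up to half a kernel
at each end (windows centred just beyond the bar still cover red rows);
self-calibration of `I` absorbs this. `n` bars in the field are recovered
as the `n` longest runs. An optional ROI rectangle restricts the search;
coordinates are reported in the full-image frame.

**Reference adjustment.** When the bar's topmost white stripe cannot be
separated from sky, `adjust_reference_for_sky` removes whole stripes from
`L` and scales `I` proportionally (nearest pixel, half away from zero),
preserving the cm-per-pixel ratio within rounding.

**Series analysis.** Light classes from the pyranometer: darkness
< 400 W/m², brightness > 1000 W/m², with the boundary values belonging to
normal (the extreme classes are strict inequalities). Rain rate > 0 mm/h
flags a frame under either feature; darkness additionally flags red-band
frames. Correction strategies: `linear` (time-weighted between nearest
reliable neighbours; single nearest neighbour at series ends — the rule a
one-sided gap forces) and `previous` (carry the last reliable value
forward; provided because a field log's worked rain-day replacement can
equal the previous day's value, which is what `previous` produces when
the neighbours are one day away and the series is flat). Corrections are
stored beside the raw estimate with their strategy, never overwriting it,
making the operation idempotent. Error summaries use the sample (n−1)
standard deviation; feature comparison uses Welch's unequal-variance t
(the variant that reproduces the published statistic from the published
error columns, which differ in spread by a factor of five).

## Synthetic scenes

The generator emulates the deployment scene, not its photometry: a pale
neutral sky (ExG ≈ 0), a soil band, a canopy of seeded per-pixel colour
jitter (sd 6 intensity units) around a green (ExG ≈ +170) or gold
(ExG ≈ +50, red ≈ 190 — deliberately close to the stripes' red values, as
in a senesced paddy) base, and the striped bar at image centre, default
1 cm/px. Stripes are indexed red-first from the bar top: the all-white
crown a real bar loses against the sky is treated as already cut from the
reference. Weather transforms, applied whole-frame:

- darkness: contrast compression toward mid-gray, v → 90 + 0.5 (v − 128).
  Chosen to reflect the darkness/normal irradiance ratio (< 400 vs
  400–1000 W/m²) under a camera whose exposure partially compensates;
  compression halves every zero-sum filter response, which the fixed ExG
  threshold survives with margin while a midpoint-learned red-band
  threshold does not — reproducing the red band's darkness failures.
- brightness: stretch with offset, v → 128 + 1.3 (v − 128) + 30, giving
  mild highlight clipping.
- drizzle: Gaussian blur σ = 1.2 px (droplets on the housing after rain).
- rainfall: blur σ = 4 px plus additive Gaussian noise sd 25, sized so
  segmentation visibly truncates the bar — the failure mode the hybrid
  correction exists to repair (raw rain-day estimates overshoot by ~40%,
  as in the field).

`reference_season()` returns the packaged 48-day season (1 July – 17
August 2012: heights 77 → 119 → 100 cm and the per-day condition labels),
so a synthetic season reproduces the real season's shape and weather mix;
`generate_series` derives one seed per day from the base seed and emits
frames plus a truth table in the series CSV schema, with sensor readings
implied by each condition (e.g. rainfall → 10.2 mm/h).

What the synthetics do *not* model: perspective and lens distortion, bar
sway, real canopy texture and self-shadowing, mixed pixels at the
bar/canopy boundary, raindrop optics, and exposure hunting. Passing
end-to-end tests therefore demonstrates the pipeline's logic — band
arithmetic, kernel response, threshold separation, run geometry,
calibration algebra, flagging and correction — under controlled
occlusion and weather surrogates, not field-grade photometric robustness.

## Numerical and interface choices

- All image arithmetic in float64; excess indices unclipped.
- Pixel coordinates 0-based, x rightward, y downward, in every module.
- Run detection errors (`DetectionError`), class overlap
  (`SeparationError`), impossible geometry (`CalibrationError`) and
  uncorrectable series (`CorrectionError`) are distinct exception types
  under one package base class.
- In batch experiments that *compare* features, a frame whose bar
  disappears entirely is scored as the fully-hidden-bar reading
  (H = L + R), the limit the formula assigns to M → 0; the core pipeline
  itself raises rather than guessing.
- Frames are matched to dates by parsing file stems with a configurable
  strftime pattern (default `%Y-%m-%d`); unreadable or undated frames are
  skipped with a logged warning, never silently.
- Determinism: scene rendering and sampling take explicit seeds;
  re-running any command with the same inputs and seed produces
  byte-identical CSVs.

## Test problem sizes

Synthetic experiments run at the deployment's native 720 × 480 frame
size: the end-to-end recovery sweep covers 22 heights spanning the bar's
usable range [0, 210 cm] (tolerance one stripe, ±10 cm), the darkness
comparison 8 frames per feature, and the orchestration tests a 6-day
season with one darkness and one rainfall day. A full 48-day season
renders and measures in a few seconds.

## Known limitations

- One bar, one point: no spatial averaging over the field (multiple bars
  would use `longest_vertical_runs(n=k)` with per-bar kernels).
- Heights are quantized by the stripe period interacting with the
  threshold: estimates move in steps of roughly one stripe near stripe
  boundaries, bounding best-case accuracy at about half a stripe.
- A bar narrower than ~1 px at the sensor cannot be extracted; a bar too
  close to the camera violates the uniform-scale assumption.
- The red-band mode is retained for comparison and for deployments with
  markers designed for it; with striped red/white bars it is fragile in
  darkness and after the crop turns gold, which is the documented reason
  excess green is the default.
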