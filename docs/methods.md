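# Methods

## The measurement model

The ACR large phantom presents, on eleven axial analysis slices S1–S11, a
fixed inventory of inserts from which seven image-quality parameters are
read.  `acrqa` reproduces the classic semiautomatic workup as a four-stage
pipeline: DICOM processing, image recognition, parameter calculation,
results record.

**Segmentation and frame.**  Each slice is thresholded globally (Otsu),
morphologically closed, reduced to its largest connected component and
hole-filled.  The phantom's centroid and equivalent diameter define a
*phantom frame*: every insert position is a fixed offset (mm) from the
centroid, scaled by measured-diameter / 190 mm.  This makes recognition
deterministic, translation-invariant (verified to 15 px) and invariant to
any positive intensity scaling.  The insert coordinate table in
`acrqa/layout.py` is an idealization of the published ACR internal layout —
it is the single shared prior for both the recognizer and the synthetic
renderer, and the place to edit should a unit differ.

**Role assignment.**  Roles are assigned by position along the scan axis:
canonical role positions (10 mm apart, centred on the series) are mapped to
the nearest acquired slice, which handles both the standard 11 × (5 mm + 5 mm
gap) protocol and contiguous thin-slice protocols (42 × 2.5 mm head,
21 × 5 mm body).  The S1 end is auto-detected from feature evidence — only
S1 carries the ramp and resolution housings, while the far end carries bars
only — and feature evidence is preferred over any header-order convention.
If neither direction shows S1 evidence the series is rejected rather than
guessed.

**Edge criterion.**  All length measurements (diameters, ramp lengths, bar
lengths) use half-maximum crossings with linear sub-pixel interpolation, the
conventional ACR choice.  Diameter profiles take the *outermost* crossings
(dark inserts inside the phantom must not truncate a diameter) and an angle
whose crossing lands at the image border is flagged not-evaluated instead of
returning the FOV size.  Ramp and bar profiles take the crossings walking
outward from the profile peak, because pixels at the insert-housing edge
partially sample the bright phantom interior.  The ramp plateau must exceed
three times the background noise or slice thickness is reported
not-evaluated (low-ramp-signal sequences genuinely cannot be measured).

**Uniformity.**  PIU uses the extrema of 1 cm² disk-kernel local means,
searched exhaustively over every centre whose whole ROI lies inside the
centred 200 cm² circle — the operator's "hunt for the brightest/darkest
small ROI" made exact.  The kernel is a pixel-coverage disk (elliptical in
pixel space for anisotropic spacing) whose pixelized area is required to be
within 2 % of nominal.  The uniform slice defaults to S7 and is
configurable to S5 (`piu_slice`): both conventions appear in practice and
the package does not guess which one a site prefers.

**Ghosting.**  Four 10 cm² background rectangles are placed midway between
the phantom edge and the FOV edge on each side, long axis tangent.  GR is
computed signed, exactly as defined ((FE-side sum − PE-side sum) / 2·mean);
because ghosting conventionally reports a magnitude, |GR| in percent is the
headline value and the sign is kept in provenance.  If any side lacks
sufficient background margin, GR is not-evaluated.

**HCSR.**  Each hole array is a 4 × 4 grid with pitch twice the hole
diameter, rows staggered by a quarter pitch as on the physical insert.  For
each of the four row profiles, local maxima separated by valleys at least
0.25 of the profile's peak-to-valley range (configurable) are counted; a
size is resolved when at least one row shows four distinct holes — the ACR
scoring rule, which the stagger exists to support.  When no size resolves,
the metric reports the sentinel 1.2 mm and displays ">1.1".  At the standard
256 / 250 mm grid the 0.9 mm array (1.8 mm pitch) is below the sampling
limit in most row phases; resolvability is decided by partial volume at the
acquisition matrix, which is exactly what the synthetic recovery tests
exercise.

**LCD.**  Each spoke's three disks are scored by a matched filter (coverage
disk-kernel mean minus local annulus mean) normalized by a high-pass noise
estimate from the spoke-free interior ring; a spoke is complete when all
three disks reach CNR ≥ 2 (configurable) and clear an absolute amplitude
floor of 0.1 % of the interior signal (so quantization-level residue cannot
count on noise-free data).  Counting proceeds clockwise from the largest
spoke and stops at the first incomplete spoke; the total over S8–S11 (max
40) is the reported value.  The CNR threshold and the HCSR valley fraction
stand in for the physicist's judgment; review mode (`--review` /
`--decisions`) exposes both for operator override and logs every override in
the report's provenance.

**Criteria.**  Pass/fail bounds live in a YAML config
(`acrqa/data/criteria.yaml`) with ACR-conventional defaults: PIU ≥ 82 %,
|GR| ≤ 2.5 %, ST within ±0.7 mm of nominal, |displacement| ≤ 5 mm, LCD ≥ 37,
HCSR ≤ 1.0 mm, |%GD| ≤ 1 % (≈ 2 mm on this phantom; an absolute-mm bound is
a one-line config change).  Evaluation is tri-state — pass / fail /
not-evaluated — and a metric that could not be measured never silently
passes or reads zero.

## The synthetic phantom

The renderer draws every insert from the shared layout prior on a 4×
super-sampled canvas and box-downsamples, so edges carry physically
meaningful partial volume and the FWHM oracles are exact to a fraction of a
pixel.  Corruptions are applied in fixed order: geometry (isotropic scale,
sub-pixel translation) → features → multiplicative low-order polynomial bias
field → ghost → noise.  The ghost is a single half-FOV-shifted attenuated
replica along the phase-encode axis — sufficient to exercise the GR
definition.  Noise is Gaussian, not Rician: at phantom SNR the difference is
immaterial to these metrics and Gaussian keeps the sidecar expectations
analytic.  Pixels are stored as uint16 with rescale slope 0.1 and negatives
clipped (magnitude-image convention); the in-memory path applies the same
quantization, so the DICOM and in-memory routes are bit-identical.

Defaults describe an in-tolerance standard acquisition: 11 × 5 mm slices at
25 cm FOV and 256², interior signal 1000, bias amplitude 0.08 (PIU in the
mid-90s), ghost fraction 0.002, noise σ = 5 (SNR 200, typical for a 3 T
head-coil phantom scan), no geometric scaling.

Each generated series carries a ground-truth sidecar: %GD = 100·(1 − scale);
displacement = encoded bar offset × scale; ST = true thickness × scale (ramp
lengths are 10× the excited thickness); PIU from the exact disk-kernel
extrema of the noise-free image; expected |GR| from the replica's overlap
with the background ROIs, including the analytic mean of clipped Gaussian
noise (E[max(0, a + σN)] = aΦ(a/σ) + σφ(a/σ)), which is what a
magnitude-convention measurement can actually see; LCD from the rendered
spoke inventory; HCSR judged on the noise-free render at the exact geometry
by an independently written peak counter (no closed form exists — partial
volume at the acquisition matrix *is* the physics).

**What the generator does not emulate** — and hence what passing recovery
tests do not certify on scanner data: pulse-sequence contrast physics (T1/T2
weighting, flip-angle effects), Rician noise statistics at low SNR,
susceptibility/eddy-current distortion fields (only affine scaling is
modelled), structured/multi-replica ghosts, coil-element sensitivity
patterns beyond a smooth polynomial, and oblique or interpolated slice
profiles.  Recovery tests certify the *measurement machinery*; scanner
validation still requires a physical phantom.

## Numerical choices and degenerate inputs

- Diameter profiles are sampled at 0.25 mm with bilinear interpolation;
  plateau = median of the central half, half-maximum = plateau/2 (background
  is air).  Ramp/bar profiles estimate plateau and background from the 90th
  / 10th percentiles inside the housing.
- Reports serialize with fixed field order; identical inputs give
  byte-identical JSON.  The report's timestamp field is null unless
  explicitly stamped (`--stamp`), precisely so the determinism contract and
  golden-report regression hold.
- Tie-breaks: role positions equidistant between two slices take the lower
  index (generator and classifier share the rule); equal-height HCSR peaks
  merge toward the earlier maximum.
- Degenerate inputs fail loudly: blank slices and ambiguous double-phantom
  scenes raise "phantom not found"/"multiple candidates"; mixed series UIDs
  name both series; a missing phase-encode direction is an error unless
  overridden, since GR is undefined without it.
- Problem sizes in the test suite are chosen to keep the full run around a
  minute: recovery uses a 3 scales × 3 ghost fractions × 2 noise levels grid
  of full 11-slice series at 256², which is ample to pin every tolerance
  (±0.3 %GD points, ±10 % ST, ±0.5 px displacement, ±2 PIU points, ±30 %
  relative GR with a 0.05-point floor near zero, exact LCD/HCSR equality on
  noise-free renders).

## Known limitations

- The insert layout is an idealization; against a physical series the
  offsets in `layout.py` may need unit-level adjustment.
- HCSR/LCD thresholds encode one reasonable reading of "distinct" and
  "complete"; sites that score differently should calibrate the valley
  fraction / CNR threshold against their physicist in review mode.
- Off-centre analyses are supported through translation invariance of the
  recognition; no gradient-nonlinearity model is fitted.
- Multi-frame/enhanced DICOM and non-axial acquisitions are out of scope.
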