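# Methods

This note records the models, parameter choices and numerical decisions
behind `blinkscope`, and what the synthetic tests do and do not establish
about real video.

## Signal model

A blink video is an ordered stack of 8-bit grayscale frames (Rec.601 luma
for color input; row 0 is the image top) at frame rate `f` (default
240 Hz — comparable to EOG sampling rates and a multiple of common
mains-flicker frequencies, so flicker averages out of the smoothed
profiles). Two 1-D summaries drive detection:

* **Mean intensity** `ȳ(t)`: covering the dark eye with brighter skin
  raises the frame mean roughly in proportion to the covered area. The
  blink polarity (peak vs dip) is auto-detected per video from the sign of
  the larger excursion about the median.
* **Simulated dynamic-vision events**: each pixel keeps a reference level
  initialized at frame 0 and fires — resetting the reference — when
  `|current − reference|` exceeds a threshold (default 15 of 255,
  config-exposed; the value is an artifact choice). Events are unsigned
  and strictly causal. Counts are zero at frame 0 by construction.

## Detection and filters

The intensity profile is smoothed with a `round(f/48)`-frame moving
average (≈5 frames at 240 fps, edge-replicated so the baseline is not
dragged toward zero). Peaks must clear a prominence floor of
`max(4·MAD(Δp), 8·MAD(p))` — the first term tracks frame-to-frame noise,
the second suppresses wiggles on quiet stretches. From each apex the
bounds are walked outward to within 2 % of the peak excursion of the
baseline and then widened to the first/last event burst nearby; a
candidate must show at least two event bursts (closing and opening) inside
its span, which is what rejects global illumination changes. Overlapping
candidate spans are merged (a consecutive blink produces two intensity
peaks over one motion run but must count as one event).

Fixed method constants: blink duration 50–1500 ms (outside: eyelid
flutter / micro-sleep), 20 % rise/fall symmetry gate with
`max(rise, fall)` as denominator, clip padding 12 frames (50 ms at
240 fps).

## Eyelid estimation

Per clip: a 256-bin histogram of the first frame is smoothed (5-bin moving
average) and the deepest valley between the two tallest peaks is the
binarization threshold (Otsu fallback for unimodal histograms; a constant
frame is an error). Binary differences between consecutive frames are
accumulated into a dynamic image; thresholding it at 25 % of its maximum
and taking the 8-connected component with the largest summed accumulation
gives the eye ROI (margin 5 px). The raw upper-eyelid curve is the topmost
dark pixel of each ROI column.

Outlier removal fits a degree-2 polynomial (the eyelid arch is close to
parabolic) to the current inliers and discards columns whose **leave-one-out
(PRESS) residual** `|e|/(1−h)` exceeds `max(tol, 3·median)`, with
`tol = 3 px`, up to 20 iterations. Three robustness details matter in
heavily contaminated frames: plain residuals let a high-leverage endpoint
outlier hide inside the fit (hence the leverage correction); a large
outlier fraction can inflate the median residual until the gate stalls, in
which case the single grossest point (> 10·tol) is trimmed alone; and the
final inlier set is re-derived as every column within the gate of the
cleaned fit (a consensus pass — the trimming order can otherwise discard
sound points while the fit is still skewed). The initial inlier set drops
points further than 5·tol from the median of their ±3 neighbours, the
"differs from adjacent pixels" idea in its simplest form. On randomized
contaminated instances (≤15 points, ≤4 planted outliers displaced beyond
10·tol) the final inlier set matches exhaustive-sampling RANSAC's
consensus in ≈99 % of cases; sampling RANSAC itself remains in the test
suite only, as an oracle. Interior gaps are filled from the fitted
polynomial; columns outside the inlier span stay missing and are handled
by the matrix conformance step.

## Blink matrix and normalization

The common domain is the modal defined-curve length (ties to the larger).
Longer curves are center-trimmed (odd excess: extra column off the right);
shorter ones are extended by evaluating the fitted polynomial, split as
evenly as possible. Rows are resampled to exactly 500 columns by linear
interpolation, negated (upward-positive height) and mapped affinely so the
first frame's extent spans [0.2, 0.7]. The mapping is stored as
`(h0, scale)` for inversion. Reading "the first frame's displacement runs
0.2–0.7" as an *extent* map keeps the arithmetic of an incomplete blink
consistent: with the open eyelid center at the arch apex, the center
starts at 0.7 and a complete closure reaches 0.2, so a minimum of 0.456
means the lid moved 0.244 of the 0.5-unit range. A flat first-frame curve
(no vertical extent) is degenerate; the documented fallback maps its
center to 0.7 and one aperture (ROI height) to the full span. The
projection image colors the matrix with the jet palette and draws red
dotted vertical lines at every interior multiple of 0.1 s; the 3-D surface
is cosmetic output.

## Displacement, phases, classification

The displacement trace is the mean of the matrix's 10 central columns.
Segmentation on one padded clip:

* **Complete-closed phase**: the contiguous interval around the global
  minimum where `d < 0.25` (the lower 10 % of the initial span). If
  `min d ≥ 0.25` no closed phase exists; if additionally `min d > 0.3` the
  blink is *incomplete*. The band 0.25–0.3 is left as "no closed phase but
  not incomplete" (the gap rule): closure there is essentially full, so
  the label stays normal.
* **Onset / end**: found as sub-frame crossings of 2 % of the span below
  the open level, extrapolated to the true motion boundary with a
  two-level rule `t0 = 2·t(e) − t(4e)` — exact when the flank leaves or
  joins a hold parabolically, and needing no local slope estimate (pixel
  quantization makes single-frame slopes unreliable). The raw and the
  Savitzky–Golay-smoothed trace (window 9, order 2) err in complementary
  ways near these boundaries — quantized plateaus versus junction
  blending — so the mean of both estimates is used. The same construction
  locates the first attainment of the minimum when no closed phase exists,
  with crossing levels at ≥0.01 normalized units (~1 px) because the last
  sub-pixel of approach carries no timing information.
* **Consecutive blinks**: at least two dips (prominence ≥ 10 % of span)
  whose intervening maximum stays below the 90 %-reopen level *and* rises
  at least 10 % of the span above the dips — the second condition keeps
  micro-wiggles on a flat closed bottom from counting as two blinks. Two
  blinks separated by a full return to the open level are two events, not
  one consecutive event.

Parameters per blink: phase durations (ms), closed-phase ratio (%),
closing/opening speeds (`Δd` over phase duration, units/s; a zero-length
phase reports a missing speed rather than infinity), total displacement
`d[0] − min d`, minimum displacement. Per video: blink rate per minute,
mean and population-SD duration, closure proportion (summed blink time
over total time), incomplete ratio.

## Synthetic eye and ground truth

The renderer draws bright skin (180), a dark eye region (40) bounded above
by a downward-opening parabolic arch (curvature 0.02 px/px², aperture
80 px in a 320×240 frame — proportions of a ~0.5 MP eye-region video), a
4 px lash band that keeps the lid margin visible at full closure, optional
per-pixel Gaussian noise and global sinusoidal flicker, all with a seeded
RNG (same seed → bit-identical frames). The eye half-width is
`sqrt(aperture/curvature)`, so the open arch's vertical extent equals one
aperture and the renderer's displacement scale coincides with the matrix
normalization.

Blink phase durations in `BlinkSpec` are *rule durations* — the durations
the displacement segmentation reports. For a complete blink
(amplitude > 0.9, hold below 0.25) the trajectory uses quarter-cosine
flanks: a smooth shoulder leaving the open level and a contact stop at the
lower lid (closing `x = 1 − cos(πu/2)`, opening `x = 1 − sin(πu/2)`), and
the internal segment lengths are solved in closed form so the requested
rule durations are realized exactly. Symmetric raised-cosine flanks cannot
do this: any smooth approach to a sub-0.25 hold spends ≈0.2 of each flank
below 0.25, forcing a rule-measured closed phase of ≥~85 ms even when a
~30 ms one is wanted. Incomplete blinks (amplitude ≤ 0.9) reverse without
lid contact and use full raised-cosine flanks. Ground-truth phase labels
and durations apply the same displacement rule to the analytic trajectory,
so recovery tests measure estimation error, not rule mismatch;
ms→frame conversion rounds half-up.

What the generator does **not** emulate: eyelashes and iris texture,
specular tear film, head motion, perspective, occlusion by glasses or
hair, rolling-shutter artifacts, or compression noise. Passing tests
therefore demonstrate the correctness of the algorithmic chain under
controlled contrast and noise, not robustness to uncontrolled real-world
footage; the histogram-valley threshold and the motion-blob ROI are the
stages most sensitive to those unmodeled effects.

## Problem sizes in the test suite

The bundled fixtures are ~2 s, 320×240, 240 fps renders (noise sd 2); the
parameter-recovery sweep uses a 5×4×3 grid (closing 80–150 ms × closed
30–200 ms × amplitude {1.0, 0.95, 0.5}) with three seeds at noise sd 3,
320×240 — 180 videos, chosen to exercise short/long holds and complete,
borderline and half-amplitude blinks at realistic eye-region resolution.
Blink-free controls add flicker (amplitude 3, 60 Hz) to noise. Randomized
oracle checks use 120 outlier-removal instances and 1000×50 event traces.

## Known limitations

* Boundary recovery is quantization-limited: with an 80 px aperture,
  0.01 normalized units ≈ 1 px, and slow flanks spend several frames
  within the last pixel of travel; recovered phase durations are accurate
  to ±2 frames at 240 fps, not better.
* The two-level boundary extrapolation assumes a parabolic (smooth-stop)
  shoulder; a strictly linear flank would be dated slightly late, by up to
  ~2 % of the flank duration.
* One eye region per video; the ROI is the single dominant motion blob, so
  two faces or large head motion inside a clip break the localization.
* Candidate bounds `x₁, x₃` from the intensity/event walk are coarse
  (several frames); they only need to bracket the blink for clip cutting,
  and all reported durations come from the displacement trace.
* Video containers require an ffmpeg-capable imageio plugin at runtime;
  PNG/TIFF frame directories are the always-available path.
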