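# Methods

This note documents the models, conventions, numerical choices, and known
limits of `wormtrace`. Everything stated here about accuracy is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Coordinate conventions

Pixel coordinates are 0-based, origin top-left, x rightward, y downward.
Stage and world coordinates are micrometers with the same axis directions.
World position = stage position (latest stage entry at or before the frame
time) + pixel position × µm/px. The outline polygon is oriented to positive
shoelace area in (x, y); "counterclockwise" therefore refers to these
coordinates, which appear clockwise on screen where y points down.

File dialects (stage `<name>.txt`, time `<name>_times.txt`, spline
`<name>_spline.txt`, metadata `<name>_meta.txt`) are tab-separated with a
one-line header; floats are written with Python's shortest round-trip `repr`,
so write-then-read is bit-exact. The time file carries stage-movement
timestamps in a `# moves` section. Marker 1 of a spline record is the head
tip; this is fixed by this implementation and documented rather than inferred.

## Segmentation and midline

Per frame: threshold (worm-dark: foreground strictly below threshold) →
8-connected component filter at 3,000 px (a 3,000 px component is kept;
2,999 is debris) → boundary of the largest component via sub-pixel contour
extraction, resampled to ~1 px vertex spacing and smoothed by a circular
moving average (window 5 vertices, configurable — the smoothing method is an
implementation choice).

Corner sharpness at a vertex is the angle subtended by the vertices `k = 15`
steps away on either side (configurable); smaller angle = sharper. The tail is
the sharpest corner and the head the second sharpest, searched at least 10% of
the perimeter away from the tail. With a previous-frame head position the
nearer candidate becomes the head; without one the assignment is returned
unconfirmed, and a sharpness tie within 2° (e.g., a symmetric ellipse) raises
an ambiguity error. The synthetic worm's tail tapers over 30% of the body
(linear) and the head over 15% (square-root), giving the tail the sharper tip
as in the real animal.

The midline is built by pairing the two outline flanks at matched normalized
arc length and averaging, then refined by one pass of normal-based re-pairing
(each interior point is re-centered between the flank intersections of its
local normal — arc-length pairing alone biases the midline toward the outer
flank on bends), lightly smoothed, and finally tip-extended: the end tangents
are cast out to the *unsmoothed* contour, because outline smoothing cuts the
sharp tail corner and would otherwise shorten the midline and drag every
equal-arc marker headward. A cubic spline through the result is resampled at
400 points; 13 markers sit at equal arc length (spacing equal to 0.02%
relative spread, asserted on every fit). A self-intersecting midline (omega
posture) raises a fit failure; coiled worms are a documented limitation and
in batch mode such frames are recorded as failed and skipped downstream.

Failed fits retry with adjusted thresholds alternating ±5 intensity levels
around the user threshold (±5, −5, +10, −10, …), up to 10 retries; an
unsegmentable frame therefore consumes exactly 11 attempts. Note that with
this alternating schedule a frame whose only usable threshold is `t₀ + 10`
succeeds on attempt 6, after +5, −5, +10 (too dark in this renderer), −10.
Fitting runs at full resolution; no temporary downsampling is used, which
affects speed only.

Measured on 50 rendered sinusoidal poses (amplitude 0–120 µm, wavelength
800–1,400 µm, all orientations, noise σ = 5): mean marker error ≈ 1 px,
maximum ≈ 4.7–5.6 px depending on the seed stream (the worst cases are the
most curved tails, amplitude/wavelength ≳ 0.12), length error ≤ 3%. Across a
rendered 50-frame crawl the head identity never flips given a correct frame-1
seed.

## Locomotion

Speed and distance follow the chosen marker (default: centroid); direction
labels always come from the centroid velocity versus the head vector, with a
zero projection classified backward (the strict "otherwise") and zero-velocity
steps excluded from both fractions. Elapsed time comes from the time log, not
frame count ÷ fps, so timing jitter does not bias speeds. 15 FPS tracks are
decimated to frames 1, 6, 11, … (phase configurable); 1/3/5 FPS tracks are
used as-is; other rates are rejected rather than silently resampled.

Per-frame amplitude uses the velocity of the step ending at the current frame
(window configurable); the summary reports the per-frame mean and maximum, and
A/L = mean amplitude / mean length. Worm length is always the straightened
spline through the 13 markers — one implementation (`_midline.resample_midline`)
shared by locomotion and curvature.

## Bending

Bend angle at marker i (1–11): magnitude is the angle in [0°, 90°] between the
vector (marker i − marker i+1) and the undirected line through markers i+1 and
i+2 (collinear markers give 0°); the sign is the cross product of the line
direction with that vector, multiplied by −1 for ventral-left (`L_`)
recordings so that ventral is positive whenever orientation is known. Flipping
the recorded orientation negates every angle and leaves RMS, dominant
frequency, and maximum bend magnitude unchanged (property-tested).

RMS bend is the nonnegative √(Σx²/n). (A signed RMS would contradict the
formula; only the nonnegative value is computed, and displayed values are the
absolute values by construction.) Gaps from failed fits are excluded from the
RMS sample count but linearly interpolated before the Fourier transform, which
needs uniform sampling. The spectrum is computed without a window by default
(appropriate for 30–60 s traces); a Hann taper is available behind a flag.
The dominant frequency is the maximum-magnitude non-DC bin, reported together
with the resolution fs/n. Maximum bend replaces interactive peak-picking with
automatic extrema detection: local maxima ≥ +20° and minima ≤ −20° qualify,
consecutive same-sign extrema merge keeping the larger magnitude, and the
result is mean(peaks) − mean(troughs). All 11 markers are computed; summary
sheets report mid-body marker 6 by default (configurable).

## Curvature

The 13 markers are resampled to a 100-point midline, smoothed with a 7-point
moving average; signed curvature comes from three-point finite differences
(all three knobs configurable). Inflections are curvature sign changes.
Sub-3% segments are removed in a single pass — an interior short run's span is
absorbed and its same-sign flanks coalesce; a terminal short run is annexed by
its only neighbor — the pass is not re-run after merging (a possible cascade
is accepted and documented). A midline whose normalized curvature never
leaves ±0.2 is returned as a single segment flagged near-straight.

The Kasa fit solves the linear least-squares system for (a, b, c) in
x² + y² = 2ax + 2by + c; r = √(a² + b² + c). It is exact on noiseless circles
(relative radius error ~1e−13) and identical to explicit normal equations on
noisy ones. Collinear segments report curvature 0. L/r is scale-invariant
(tested over scales 0.1–42) and reflection swaps ventral/dorsal labels while
preserving magnitudes. The primary-curvature filter iteratively drops V1/D1
values below 2.5 and promotes the subsequent ranks; a side can end up empty
and is then reported missing.

## Sleep

Displacement strictly below 10 µm between consecutive frames is motionless;
exactly 10 µm is active (the boundary is unassigned by the strict
inequalities; it is resolved to active here and documented). A bout opens at
the first frame of ≥3 consecutive motionless frames and its end is trimmed to
the end of the last ≥3-motionless run. What *ends* a bout is not prescribed
anywhere authoritative; this implementation defines awakening as ≥ `wake_k`
consecutive active frames with `wake_k = 3` by symmetry with onset
(configurable, and flagged prominently as an interpretation). Frames lost to
segmentation failure break runs — motionlessness cannot be asserted — and
terminate a candidate bout. Interior active runs shorter than `wake_k` are
active events; motionless sleep = bout duration − Σ active events, exactly.
Both the summed sleep and the single longest bout are reported, since either
may be the per-animal measure of interest. A caller-supplied list of invalid
time ranges (e.g., chamber-edge contact) flags overlapping bouts.

Bout boundaries equal an independent brute-force run-scan oracle on 500 random
label sequences, and raising the displacement threshold never decreases total
sleep time on random actograms.

## Action potentials

Traces are uniform-dt mV series (CSV: two columns, jittered timebases
rejected; ABF via optional `pyabf`, each sweep analyzed independently and
never concatenated). Peaks are prominent local maxima (defaults: prominence
≥ 20 mV, peak ≥ −20 mV, refractory gap 5 ms — two spikes 2 ms apart merge, a
documented limitation).

The fixed-lead threshold has **no default lead**: it is a required user
parameter, applied identically to every AP. The inflection threshold is the
last upward crossing of the smoothed dV/dt (central differences, 3-sample
smoothing) through the criterion before the peak; "stays above until the peak"
cannot hold literally for smooth peaks where dV/dt falls to zero, so the last
*upward* crossing is used. A second method (maximum second derivative) is
available behind a flag. The criterion default is 10 mV/ms (configurable);
threshold voltage increases monotonically with the criterion on exponential
upstrokes.

RMP: mean of the 20 ms window preceding the reference point (fixed-lead), or
the minimum 3 ms sliding sub-window mean within that window (inflection). The
reference point is an explicit parameter (the threshold time in the built-in
pipeline). A window truncated by the trace start raises an error advising
manual RMP measurement from an AP-free segment. Sub-sample crossings (APD50,
decay) use linear interpolation. The AHP search runs from the decay crossing
to the next AP's threshold or a 200 ms cap; an AP that never recrosses its
threshold voltage reports decay and AHP as unavailable rather than guessing.
All metrics except the absolute voltages are invariant to adding a constant to
the trace.

On piecewise-linear templates the recovered metrics are exact (amplitude
24 mV, APD50 3 ms, slopes +12/−6 mV/ms for the documented triangle); on smooth
templates with an analytic exponential take-off, threshold time and APD50 are
recovered within one 10 kHz sample and the AHP within 0.01 mV. The maximum
phase-plot slope of the smooth template is underestimated by the discrete
derivative (≈54 of 60 mV/ms at dt = 0.1 ms, τ = 1 ms) because the template's
slope maximum is instantaneous; this is a property of any sampled derivative,
not of the detector.

## Synthetic data: what it emulates and what it does not

The worm model is a sinusoidal midline with lateral offset a·sin(2πs/λ + φ),
rendered dark (intensity 40) on a bright background (200) with additive
Gaussian noise, at the default scale of a 1,000 µm worm at 5 µm/px and a body
area of ≈8,000 px (maximum half-width 125 µm), comfortably above the debris
threshold. Poses are checked for self-intersection before rendering. Crawls
translate the pose at constant speed with the undulation phase advancing at
the chosen frequency; stage recentering applies corrections at 1 s intervals
between acquisitions, exactly as the world-coordinate reconstruction assumes.
Sleep actograms draw quiescent steps ≪ 10 µm and active steps ≫ 10 µm with
bout edges snapped to the frame grid; AP trains paste analytic templates
(piecewise-linear triangle or exponential-take-off smooth template) whose true
metrics are closed-form.

Not emulated: bacterial-lawn background texture, illumination gradients,
worm-shape irregularities beyond the sinusoid, self-occluding (coiled)
postures, omega turns, multi-worm scenes, behavioral state switching within a
recording, and biological AP waveform variability. Passing tests therefore
demonstrate correctness of the *analysis rules and reconstructions* under
controlled conditions, not robustness to every imaging artifact of real
recordings. Pose amplitudes up to 0.15 of the wavelength are exercised; at the
top of that range midline recovery degrades to ~5 px worst-case marker error
at the tail.

## Sizes and determinism

Every generator is deterministic per seed. The test suite uses fixed seeds
throughout (hypothesis runs derandomized); the acceptance script derives all
randomness from its `--seed`. Problem sizes — 50 rendered poses, 20 simulated
crawls and undulation runs, 500 random sleep sequences, trains of 5–7 APs at
10 kHz — were chosen so the whole suite runs in about a minute on one CPU
while still exercising every rule boundary and recovery path.
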