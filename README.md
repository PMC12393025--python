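# wormtrace

Quantification of *C. elegans* locomotion, body bending, body curvature,
sleep-like quiescence, and action-potential properties — as an offline,
scriptable Python library.

Single-worm tracking rigs record image sequences of a crawling animal together
with motorized-stage logs; electrophysiology rigs record current-clamp voltage
traces from body-wall muscle cells and neurons. `wormtrace` implements the
analysis side of such a rig: it turns frames into poses, poses into kinematic
and bending metrics, centroid time series into sleep bouts, and voltage traces
into per-AP feature tables. A synthetic-data module generates ground-truthed
worm images, crawl recordings, actograms, and AP trains, so the entire
analysis stack is testable without a microscope or amplifier.

## The core quantities

**Pose.** Each frame is thresholded into a binary mask (debris components
smaller than 3,000 px removed), the outline is traced and smoothed, the tail
and head are identified as the sharpest and second-sharpest outline corners
(disambiguated by the previous frame's head position), and a midline is fitted
between the tips. The universal pose unit is a **13-marker spline**: markers at
equal arc-length intervals with marker 1 at the head tip; the centroid is the
mean marker position, and the worm length *L* is the straightened spline.

**Locomotion.** World position = stage position + pixel position × µm/px, so
compensating stage moves cancel exactly. Speed, total and net distance, and
per-step direction follow: the worm moves *forward* iff the head vector
(centroid → head tip) projects positively onto the velocity vector. Amplitude
*A* is the width of the smallest rectangle parallel to the velocity vector
enclosing all 13 markers; *A/L* normalizes for body size. Recordings at 1/3/5
frames per second are analyzed at their actual rate; 15 FPS recordings are
analyzed at an effective 3 FPS.

**Bending.** The bend angle at marker *i* (1–11) is measured against the
straight line through markers *i*+1 and *i*+2, signed ventral-positive when
the recording's `R_`/`L_` orientation is known. From the 11 × T bend trace:
RMS bend = √(Σᵢxᵢ²/n) per marker, Sum of All Bends (the 11 RMS values summed),
the dominant bending frequency (largest non-DC peak of the Fourier magnitude
spectrum), and the maximum bend (mean qualifying ventral peak − mean
qualifying dorsal trough, 20° qualification gate).

**Curvature.** The smoothed dense midline is split at inflection points
(curvature sign changes); segments shorter than 3% of body length are removed.
Each segment gets a least-squares circle by the Kasa method — minimize
Σ(x² + y² − 2ax − 2by − c)² — and is reported as the dimensionless curvature
*L/r*, ranked V1, V2, …/D1, D2, … head-to-tail per side. A primary-curvature
filter drops leading values below 2.5 and promotes the next rank.

**Sleep.** At 1 frame/10 s, a frame is *motionless* when the centroid moved
less than 10 µm. A sleep bout runs from the start of three consecutive
motionless frames to the end of the last three; brief interior activity counts
as active events, and motionless sleep = bout duration − active-event time.

**Action potentials.** Two threshold methods: a **fixed lead** (membrane
potential at a user-defined time before the peak, for APs without a
preupstroke inflection, as in body-wall muscle) and an **inflection** method
(last upward crossing of a dV/dt criterion, default 10 mV/ms). RMP is the
20 ms pre-reference average (fixed-lead) or the lowest 3 ms sub-window average
within that window (inflection). Per AP: amplitude (peak − threshold), APD50
(width at half amplitude), rise and decay times, AHP as actual membrane
voltage, and the phase-plot maximum/minimum slopes.

## Worked example

`examples/locomotion_metrics.py` renders an 8 s recording of a worm crawling
at 150 µm/s with stage recentering, fits every frame, and recovers the
kinematics:

```
frames fitted        : 24/24
average speed        :   149.7 um/s (ground truth 149.2)
total distance       :  1148.0 um
net distance         :  1147.8 um
forward time fraction:    1.00
worm length          :   997.4 um
amplitude A (mean)   :   209.7 um; A/L = 0.210
```

Speed is recovered within 0.4%, the length within 0.3% of the true 1,000 µm,
and every step is labeled forward (the head leads the motion). The other
scripts in `examples/` cover one capability each: single-frame midline
fitting, the bending spectrum, curvature segments, sleep bouts, and AP
features — for instance `examples/ap_features.py` prints the closed-form
triangle-template metrics (threshold −4 mV, amplitude 24 mV, APD50 3 ms,
slopes +12/−6 mV/ms).

A thin CLI mirrors the batch workflows (`wormtrace fit-spline`, `analyze`,
`batch-analyze`, `curve`, `sleep`, `ap`, `synth crawl|sleep|ap`,
`calibrate`); results export to XLSX workbooks, one sheet per metric family.

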