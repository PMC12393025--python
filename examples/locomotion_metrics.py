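"""Track a simulated crawl end to end and print its movement summary.

Renders a short recording (worm crawling at 150 um/s with stage recentering),
fits the 13-marker midline to every frame, merges the splines with the stage
log into absolute coordinates, and prints the recovered kinematics next to the
generator's ground truth.
"""

import tempfile
from pathlib import Path

from wormtrace import locomotion
from wormtrace.formats import resolve_recording
from wormtrace.segmentation import SegmentationConfig, fit_recording
from wormtrace.synth import simulate_crawl

with tempfile.TemporaryDirectory() as tmp:
    sim = simulate_crawl(out_dir=tmp, name="wt1", duration_s=8, fps=3,
                         speed_um_per_s=150.0, seed=1)
    bundle = resolve_recording(Path(tmp) / "wt1")
    config = SegmentationConfig(threshold=120.0,
                                head_seed=tuple(sim.truth_frames[0].markers_px[0]))
    splines = fit_recording(bundle, config)

    track = locomotion.to_world(splines, bundle.stage_log, bundle.time_log,
                                bundle.um_per_px, bundle.fps)
    metrics = locomotion.movement_metrics(locomotion.effective_frames(track))

print(f"frames fitted        : {len(splines.fitted_records())}/{len(splines)}")
print(f"average speed        : {metrics.avg_speed_um_per_s:7.1f} um/s "
      f"(ground truth {sim.true_speed_um_per_s:.1f})")
print(f"total distance       : {metrics.total_distance_um:7.1f} um")
print(f"net distance         : {metrics.net_distance_um:7.1f} um")
print(f"forward time fraction: {metrics.forward_time_fraction:7.2f}")
print(f"worm length          : {metrics.length_um:7.1f} um")
print(f"amplitude A (mean)   : {metrics.amplitude_mean_um:7.1f} um; A/L = {metrics.a_over_l:.3f}")
# A/L normalizes the crawl's lateral envelope by body length, so it compares
# across worms of different sizes; forward fraction 1.0 means no reversals.
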