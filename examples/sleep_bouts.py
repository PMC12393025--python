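"""Detect sleep bouts in a simulated 2 h actogram (1 frame / 10 s).

Plants one 30 min quiescence bout containing two brief active events and
recovers it from centroid displacements.
"""

from wormtrace import sleep
from wormtrace.synth import simulate_sleep_trace

sim = simulate_sleep_trace(
    duration_s=7200.0,
    bouts=((1800.0, 3600.0),),
    spike_times=(2400.0, 3000.0),
    seed=8,
)
series = sleep.classify_motion(sim.centroids, timestamps=sim.timestamps)
bouts = sleep.detect_sleep_bouts(series)
summary = sleep.sleep_summary(bouts, recording_span_s=7200.0)

for bout in bouts:
    print(f"bout {bout.start_time:6.0f}-{bout.end_time:6.0f} s "
          f"(total {bout.total_duration:.0f} s, "
          f"{len(bout.active_events)} active events, "
          f"motionless {bout.motionless_duration:.0f} s)")
print(f"planted bout             : {sim.true_bouts[0][0]:.0f}-{sim.true_bouts[0][1]:.0f} s")
print(f"total sleep              : {summary.total_sleep_s:.0f} s")
print(f"motionless sleep duration: {summary.motionless_sleep_s:.0f} s")
# A frame is motionless when the centroid moved < 10 um in 10 s; the bout runs
# from the first of three consecutive motionless frames to the end of the last
# three, and interior activity shorter than the awakening rule counts as
# active events subtracted from motionless sleep.
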