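"""Action-potential metrics with both threshold methods.

A muscle-style train (no preupstroke inflection: fixed-lead threshold, 2 ms
before the peak) and a neuron-style train (automatic inflection threshold at
the 10 mV/ms dV/dt crossing).
"""

from wormtrace import ap
from wormtrace.synth import SmoothAP, TriangleAP, simulate_ap_train

muscle, _ = simulate_ap_train(n_aps=7, template=TriangleAP(), lead_ms=2.0)
events = ap.analyze_trace(muscle, method="fixed-lead", lead_ms=2.0)
ev = events[0]
print("muscle-style AP (fixed 2 ms lead):")
print(f"  threshold {ev.threshold_v_mv:6.1f} mV   amplitude {ev.amplitude_mv:5.1f} mV")
print(f"  APD50     {ev.apd50_ms:6.2f} ms   rise {ev.rise_time_ms:.2f} ms   "
      f"decay {ev.decay_time_ms:.2f} ms")
print(f"  slopes    max {ev.max_slope_mv_per_ms:+5.1f}  min {ev.min_slope_mv_per_ms:+5.1f} mV/ms")

neuron, truth = simulate_ap_train(n_aps=5, template=SmoothAP(), dvdt_criterion=10.0)
events = ap.analyze_trace(neuron, method="inflection")
ev = events[0]
print("neuron-style AP (inflection threshold, 10 mV/ms):")
print(f"  threshold {ev.threshold_v_mv:6.1f} mV (analytic take-off {truth[0]['threshold_v']:.1f})")
print(f"  RMP {ev.rmp_mv:6.1f} mV   AHP {ev.ahp_v_mv:6.1f} mV   APD50 {ev.apd50_ms:.2f} ms")
# Amplitude is peak minus threshold; the AHP is reported as the actual
# membrane-voltage minimum after repolarization, not relative to baseline.
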