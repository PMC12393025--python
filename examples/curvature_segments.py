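"""Normalized body curvature (L/r) of an S-shaped midline.

Builds a worm posed as two circular arcs of radius L/3 each, segments the
midline at its inflection point, Kasa-fits a circle to each segment, and
applies the primary-curvature filter.
"""

import numpy as np

from wormtrace.curvature import curvatures, filter_primary_curvatures
from wormtrace.formats import Orientation


def s_shaped_markers(r0=300.0, arc=1.5):
    a = np.linspace(0, arc, 400)
    arc1 = np.column_stack([r0 * np.sin(a), r0 * (1 - np.cos(a))])
    tangent = np.array([np.cos(arc), np.sin(arc)])
    center2 = arc1[-1] + np.array([np.sin(arc), -np.cos(arc)]) * r0
    start = arc1[-1] - center2
    rot = lambda v, th: np.array(
        [np.cos(th) * v[0] + np.sin(th) * v[1], -np.sin(th) * v[0] + np.cos(th) * v[1]]
    )
    arc2 = np.array([center2 + rot(start, th) for th in a[1:]])
    curve = np.vstack([arc1, arc2])
    s = np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(curve, axis=0), axis=1))])
    t = np.linspace(0, s[-1], 13)
    return np.column_stack([np.interp(t, s, curve[:, 0]), np.interp(t, s, curve[:, 1])])


segments = curvatures(s_shaped_markers(), Orientation.VENTRAL_RIGHT)
print("rank  side     span (body frac)   radius     L/r")
for seg in segments:
    print(f"{seg.rank:4}  {seg.side:8} {seg.start_frac:.2f}-{seg.end_frac:.2f}"
          f"         {seg.r:7.1f}  {seg.curvature:6.2f}")

primary = filter_primary_curvatures(segments, min_value=2.5)
print("after the 2.5 primary-curvature filter:",
      [(s.rank, round(s.curvature, 2)) for s in primary])
# Each arc has radius r = L/3, so L/r is 3 on both the ventral and dorsal side;
# both exceed 2.5 and survive the primary filter unchanged.
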