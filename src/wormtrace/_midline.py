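"""Shared dense-midline resampling from 13 markers (single source of worm length)."""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


def resample_midline(markers: np.ndarray, n: int = 200) -> tuple[np.ndarray, float]:
    """Cubic-spline the 13 markers into ``n`` dense points.

    Returns the dense (n, 2) polyline and its arc length (same units as the
    marker coordinates).
    """
    markers = np.asarray(markers, dtype=float)
    seg = np.linalg.norm(np.diff(markers, axis=0), axis=1)
    if np.any(seg <= 0):
        raise ValueError("coincident midline markers")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    cs_x = CubicSpline(s, markers[:, 0])
    cs_y = CubicSpline(s, markers[:, 1])
    sd = np.linspace(0.0, s[-1], n)
    dense = np.column_stack([cs_x(sd), cs_y(sd)])
    length = float(np.sum(np.linalg.norm(np.diff(dense, axis=0), axis=1)))
    return dense, length


def midline_length(markers: np.ndarray) -> float:
    """Arc length of the straightened midline through the 13 markers."""
    return resample_midline(markers, n=400)[1]
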