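"""Body-curvature quantification by least-squares circle fitting.

The 13-marker spline is resampled to a dense midline, smoothed, and split at
inflection points (sign changes of the local signed curvature).  Segments
shorter than 3% of the body length are removed (their span merged into the
flanking segments).  A circle is fitted to each retained segment with the Kasa
method and the segment's normalized curvature is reported as L/r, where L is
the worm length and r the fitted radius.  Segments are labeled ventral/dorsal
from the bending sign convention and ranked head-to-tail per side (V1, V2, ...,
D1, D2, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from ._midline import resample_midline
from .bending import orientation_sign
from .errors import AnalysisError
from .formats import Orientation
from .segmentation import Spline13

#: dimensionless L/r below which a segment counts as essentially straight
NEAR_ZERO_CURVATURE = 0.2


@dataclass
class CurvatureSegment:
    """One inflection-bounded midline stretch with its fitted circle."""

    start_frac: float  # fraction of body length, head = 0
    end_frac: float
    midpoint: np.ndarray  # average of start/end positions
    r: float  # fitted circle radius (marker units)
    curvature: float  # L/r, dimensionless
    side: str  # ventral | dorsal | undifferentiated
    rank: str  # V1/V2/D1/... (U1/... when undifferentiated)
    low_curvature: bool = False  # flagged near-straight segment


@dataclass
class _Run:
    start: int  # dense-point index, inclusive
    end: int  # inclusive
    sign: float


def kasa_fit(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares circle through ``points`` by the Kasa method.

    Minimizes the algebraic residual sum((x^2 + y^2 - 2ax - 2by - c)^2) via
    linear least squares; returns the center (a, b) and radius
    sqrt(a^2 + b^2 + c).  Collinear points raise :class:`AnalysisError`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(pts))])
    rhs = x**2 + y**2
    sol, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 3:
        raise AnalysisError("collinear points: circle radius is infinite")
    a, b, c = sol
    r2 = c + a**2 + b**2
    if r2 <= 0:
        raise AnalysisError("degenerate circle fit")
    return np.array([a, b]), float(np.sqrt(r2))


def _signed_curvature(points: np.ndarray) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    dx, dy = np.gradient(x), np.gradient(y)
    ddx, ddy = np.gradient(dx), np.gradient(dy)
    denom = np.maximum((dx**2 + dy**2) ** 1.5, 1e-12)
    return (dx * ddy - dy * ddx) / denom


def _runs_of_sign(sign: np.ndarray) -> list[_Run]:
    runs: list[_Run] = []
    start = 0
    for i in range(1, len(sign)):
        if sign[i] != sign[i - 1]:
            runs.append(_Run(start, i - 1, sign[start]))
            start = i
    runs.append(_Run(start, len(sign) - 1, sign[start]))
    return runs


def detect_inflections(
    spline: Spline13 | np.ndarray,
    n_dense: int = 100,
    smooth_window: int = 7,
    min_frac: float = 0.03,
) -> tuple[list[_Run], np.ndarray, np.ndarray, float]:
    """Split the smoothed dense midline at curvature sign changes.

    Returns (runs, dense_points, arc_fractions, length).  Runs shorter than
    ``min_frac`` of the body length are removed in a single pass: interior
    short runs are absorbed by coalescing their (same-sign) flanking runs,
    terminal ones are annexed by their only neighbor.  A worm whose curvature
    never leaves the near-zero band yields a single full-length run.
    """
    markers = spline.markers if isinstance(spline, Spline13) else np.asarray(spline)
    dense, length = resample_midline(markers, n=n_dense)
    dense = uniform_filter1d(dense, size=smooth_window, axis=0, mode="nearest")
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    frac = s / s[-1]
    kappa = _signed_curvature(dense)

    if np.max(np.abs(kappa)) * length < NEAR_ZERO_CURVATURE:
        return [_Run(0, n_dense - 1, float(np.sign(kappa.mean()) or 1.0))], dense, frac, length

    sign = np.where(kappa >= 0, 1.0, -1.0)
    runs = _runs_of_sign(sign)

    def run_frac(r: _Run) -> float:
        return float(frac[r.end] - frac[r.start])

    kept: list[_Run] = []
    pending_start: int | None = None  # start index carried over a dropped run
    for r in runs:
        start = pending_start if pending_start is not None else r.start
        pending_start = None
        if run_frac(r) >= min_frac:
            if kept and kept[-1].sign == r.sign:
                kept[-1] = _Run(kept[-1].start, r.end, r.sign)
            else:
                kept.append(_Run(start, r.end, r.sign))
        else:
            if kept:
                kept[-1] = _Run(kept[-1].start, r.end, kept[-1].sign)
            else:
                pending_start = start  # leading short run: annex into the next
    # coalesce same-sign neighbors created by removals
    merged: list[_Run] = []
    for r in kept:
        if merged and merged[-1].sign == r.sign:
            merged[-1] = _Run(merged[-1].start, r.end, r.sign)
        else:
            merged.append(r)
    if not merged:
        merged = [_Run(0, n_dense - 1, 1.0)]
    return merged, dense, frac, length


def curvatures(
    spline: Spline13 | np.ndarray,
    orientation: Orientation = Orientation.UNKNOWN,
    n_dense: int = 100,
    smooth_window: int = 7,
    min_frac: float = 0.03,
) -> list[CurvatureSegment]:
    """Per-segment normalized curvatures L/r with ventral/dorsal ranks."""
    runs, dense, frac, length = detect_inflections(
        spline, n_dense=n_dense, smooth_window=smooth_window, min_frac=min_frac
    )
    factor = orientation_sign(orientation)
    segments: list[CurvatureSegment] = []
    counters = {"ventral": 0, "dorsal": 0, "undifferentiated": 0}
    for run in runs:
        pts = dense[run.start : run.end + 1]
        try:
            _, r = kasa_fit(pts)
            curv = length / r
        except AnalysisError:
            r = float("inf")
            curv = 0.0
        if orientation is Orientation.UNKNOWN:
            side = "undifferentiated"
            prefix = "U"
        else:
            side = "ventral" if run.sign * factor > 0 else "dorsal"
            prefix = "V" if side == "ventral" else "D"
        counters[side] += 1
        segments.append(
            CurvatureSegment(
                start_frac=float(frac[run.start]),
                end_frac=float(frac[run.end]),
                midpoint=0.5 * (dense[run.start] + dense[run.end]),
                r=r,
                curvature=float(curv),
                side=side,
                rank=f"{prefix}{counters[side]}",
                low_curvature=curv <= NEAR_ZERO_CURVATURE,
            )
        )
    return segments


def filter_primary_curvatures(
    segments: list[CurvatureSegment], min_value: float = 2.5
) -> list[CurvatureSegment]:
    """Drop weak leading curvatures and promote the following ranks.

    Per side, while the first-ranked segment's curvature is below
    ``min_value``, it is excluded and the subsequent segments move up one rank
    (V2 becomes V1, and so on).  A side can end up empty.
    """
    out: list[CurvatureSegment] = []
    for side in ("ventral", "dorsal", "undifferentiated"):
        ranked = [s for s in segments if s.side == side]
        while ranked and ranked[0].curvature < min_value:
            ranked.pop(0)
        prefix = {"ventral": "V", "dorsal": "D", "undifferentiated": "U"}[side]
        for j, s in enumerate(ranked, start=1):
            out.append(replace(s, rank=f"{prefix}{j}"))
    out.sort(key=lambda s: s.start_frac)
    return out
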