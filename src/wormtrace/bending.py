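"""Bend-angle traces and derived bending metrics.

Bending at spline markers 1-11 is quantified relative to the straight line
through the two subsequent markers: the bend angle at marker i is the angle
between the vector (marker i - marker i+1) and that line, signed positive when
marker i lies on the animal's ventral side (known from the recording's R_/L_
orientation; without orientation a fixed cross-product convention is used and
the trace is flagged undifferentiated).

From the 11 x T trace this module derives the per-marker RMS bend
sqrt(sum(x_i^2)/n), the Sum of All Bends (total of the 11 RMS values), the
dominant bending frequency (most prominent non-DC peak of the Fourier
magnitude spectrum), and the maximum bend (mean of qualifying ventral peaks
minus mean of qualifying dorsal troughs, with a 20 degree qualification gate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import AnalysisError
from .formats import Orientation, SplineFile

N_BEND_MARKERS = 11


def orientation_sign(orientation: Orientation) -> float:
    """Sign factor mapping the raw cross-product convention to ventral-positive."""
    return -1.0 if orientation is Orientation.VENTRAL_LEFT else 1.0


@dataclass
class BendTrace:
    """Signed bend angles (degrees, ventral positive) at markers 1-11 over time."""

    angles: np.ndarray  # (11, T); NaN where the frame's fit failed
    timestamps: np.ndarray  # (T,) seconds
    orientation: Orientation = Orientation.UNKNOWN

    @property
    def undifferentiated(self) -> bool:
        return self.orientation is Orientation.UNKNOWN

    @property
    def fs(self) -> float:
        dt = np.diff(self.timestamps)
        if len(dt) == 0 or np.median(dt) <= 0:
            raise AnalysisError("cannot infer sampling rate from timestamps")
        return 1.0 / float(np.median(dt))

    def n_samples(self, marker: int) -> int:
        return int(np.isfinite(self._row(marker)).sum())

    def _row(self, marker: int) -> np.ndarray:
        if not 1 <= marker <= N_BEND_MARKERS:
            raise ValueError(f"bend marker must be 1..{N_BEND_MARKERS}")
        return self.angles[marker - 1]


def bend_angle(
    markers: np.ndarray,
    i: int,
    orientation: Orientation = Orientation.UNKNOWN,
) -> float:
    """Signed bend angle (degrees) at marker ``i`` (1-based, 1..11).

    Magnitude is the angle between the vector (marker i - marker i+1) and the
    straight line through markers i+1 and i+2, in [0, 90].  Collinear markers
    give 0.
    """
    markers = np.asarray(markers, dtype=float)
    if not 1 <= i <= N_BEND_MARKERS:
        raise ValueError(f"marker index must be 1..{N_BEND_MARKERS}")
    a, b, c = markers[i - 1], markers[i], markers[i + 1]
    v = a - b
    d = c - b
    nv, nd = np.linalg.norm(v), np.linalg.norm(d)
    if nv == 0 or nd == 0:
        raise AnalysisError(f"coincident markers around marker {i}")
    cosang = float(np.dot(v, d)) / (nv * nd)
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))  # angle to d, [0, 180]
    magnitude = min(theta, 180.0 - theta)  # angle to the (undirected) line
    cross = d[0] * v[1] - d[1] * v[0]
    sign = np.sign(cross) if cross != 0 else 0.0
    return float(magnitude * sign * orientation_sign(orientation))


def bend_trace(
    splines: SplineFile | np.ndarray,
    timestamps: np.ndarray,
    orientation: Orientation = Orientation.UNKNOWN,
) -> BendTrace:
    """11 x T bend-angle matrix; failed frames leave NaN gaps."""
    if isinstance(splines, SplineFile):
        marker_stack = np.full((len(splines.records), 13, 2), np.nan)
        for k, rec in enumerate(splines.records):
            if rec.ok:
                marker_stack[k] = rec.markers
    else:
        marker_stack = np.asarray(splines, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if len(timestamps) != len(marker_stack):
        raise ValueError("timestamps and spline track lengths differ")
    T = len(marker_stack)
    angles = np.full((N_BEND_MARKERS, T), np.nan)
    for t in range(T):
        if not np.isfinite(marker_stack[t]).all():
            continue
        for i in range(1, N_BEND_MARKERS + 1):
            angles[i - 1, t] = bend_angle(marker_stack[t], i, orientation)
    return BendTrace(angles=angles, timestamps=timestamps, orientation=orientation)


def rms_bend(trace: BendTrace, i: int) -> float:
    """Root-mean-square bend at marker ``i``: sqrt(sum(x^2)/n), nonnegative."""
    row = trace._row(i)
    x = row[np.isfinite(row)]
    if x.size == 0:
        raise AnalysisError(f"no samples at marker {i}")
    return float(np.sqrt(np.sum(x**2) / x.size))


def sum_of_all_bends(trace: BendTrace) -> float:
    """Total of the 11 per-marker RMS bends (degrees)."""
    return float(sum(rms_bend(trace, i) for i in range(1, N_BEND_MARKERS + 1)))


def _fill_gaps(row: np.ndarray) -> np.ndarray:
    finite = np.isfinite(row)
    if finite.all():
        return row
    if not finite.any():
        raise AnalysisError("trace is all gaps")
    idx = np.arange(len(row))
    return np.interp(idx, idx[finite], row[finite])


@dataclass
class Spectrum:
    frequencies_hz: np.ndarray
    magnitude: np.ndarray
    dominant_hz: float
    resolution_hz: float


def dominant_frequency(
    trace: BendTrace, i: int, window: str | None = None, min_samples: int = 16
) -> Spectrum:
    """Dominant bending frequency at marker ``i`` from the Fourier spectrum.

    The row is mean-subtracted (gaps linearly interpolated first) and the
    dominant frequency is the non-DC bin of maximum magnitude.  Frequency
    resolution fs/n is reported alongside.  ``window="hann"`` applies a Hann
    taper before the transform.
    """
    row = _fill_gaps(trace._row(i))
    n = len(row)
    if n < min_samples:
        raise AnalysisError(f"need >= {min_samples} samples, got {n}")
    x = row - row.mean()
    if window == "hann":
        x = x * np.hanning(n)
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    mag = np.abs(np.fft.rfft(x))
    fs = trace.fs
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    dom = int(np.argmax(mag[1:])) + 1  # exclude DC
    return Spectrum(
        frequencies_hz=freqs,
        magnitude=mag,
        dominant_hz=float(freqs[dom]),
        resolution_hz=fs / n,
    )


def _alternating_extrema(
    values: np.ndarray, peak_idx: np.ndarray, trough_idx: np.ndarray
) -> tuple[list[float], list[float]]:
    """Enforce peak/trough alternation, keeping the larger of same-sign runs."""
    events = sorted(
        [(int(k), +1) for k in peak_idx] + [(int(k), -1) for k in trough_idx]
    )
    kept: list[tuple[int, int]] = []
    for k, sign in events:
        if kept and kept[-1][1] == sign:
            if abs(values[k]) > abs(values[kept[-1][0]]):
                kept[-1] = (k, sign)
        else:
            kept.append((k, sign))
    peaks = [float(values[k]) for k, s in kept if s > 0]
    troughs = [float(values[k]) for k, s in kept if s < 0]
    return peaks, troughs


def maximum_bend(trace: BendTrace, i: int, min_angle: float = 20.0) -> float:
    """Maximum bend at marker ``i``: mean ventral peak minus mean dorsal trough.

    Local maxima >= +``min_angle`` qualify as ventral peaks and local minima
    <= -``min_angle`` as dorsal troughs (the 20 degree gate); consecutive
    same-sign extrema are merged keeping the larger magnitude.  Raises
    :class:`AnalysisError` when either side has no qualifying extremum.
    """
    row = _fill_gaps(trace._row(i))
    peak_idx, _ = find_peaks(row, height=min_angle)
    trough_idx, _ = find_peaks(-row, height=min_angle)
    if len(peak_idx) == 0 or len(trough_idx) == 0:
        raise AnalysisError(
            f"no qualifying extrema at marker {i} with the {min_angle} degree gate"
        )
    peaks, troughs = _alternating_extrema(row, peak_idx, trough_idx)
    if not peaks or not troughs:
        raise AnalysisError("alternation left one side empty")
    return float(np.mean(peaks) - np.mean(troughs))
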