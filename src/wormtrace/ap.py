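"""Action-potential feature extraction from current-clamp voltage traces.

Designed around 10 kHz recordings.  Two threshold methods are provided:

* fixed lead -- the membrane potential at a user-defined time before the AP
  peak, for APs lacking a preupstroke inflection point (e.g., C. elegans
  body-wall muscle).  The lead has deliberately no default: it is a required
  user parameter, applied identically to every AP of an analysis.
* inflection -- the last point before the peak where the smoothed dV/dt rises
  through a criterion (default 10 mV/ms), for APs with a clear preupstroke
  inflection (e.g., mammalian neurons).

The resting membrane potential (RMP) is the 20 ms average preceding the
reference point for the fixed-lead method, and the lowest 3 ms sub-window
average within that 20 ms window for the inflection method.  Per-AP metrics:
amplitude (peak minus threshold), APD50 (width at half amplitude, sub-sample
crossings by linear interpolation), rise time (threshold to peak), decay time
(peak back to the threshold voltage), AHP (actual membrane-voltage minimum
after repolarization), and maximum/minimum phase-plot slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .errors import AnalysisError, FormatError, NoInflectionError


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane potential (mV)."""

    v: np.ndarray  # (N,) mV
    dt: float  # sampling interval, s
    source: str = ""
    sweep: int = 0

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.dt <= 0 or len(self.v) < 2:
            raise ValueError("need dt > 0 and >= 2 samples")

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.v)) * self.dt

    @property
    def fs(self) -> float:
        return 1.0 / self.dt


@dataclass
class ThresholdPoint:
    index: int
    time_s: float
    v_mv: float
    method: str  # "fixed-lead" | "inflection"


@dataclass
class APEvent:
    """One action potential with its derived metrics (None = unavailable)."""

    peak_time_s: float
    peak_v_mv: float
    threshold_time_s: float
    threshold_v_mv: float
    method: str
    rmp_mv: float
    amplitude_mv: float
    apd50_ms: float | None
    ahp_v_mv: float | None
    rise_time_ms: float
    decay_time_ms: float | None
    max_slope_mv_per_ms: float
    min_slope_mv_per_ms: float

    def to_row(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# loading


def load_trace(path: Path | str, rel_tol: float = 1e-6) -> list[VoltageTrace]:
    """Load sweeps from a two-column CSV (time s, voltage mV) or an ABF file.

    CSV files must have a uniform timebase; jittered timestamps are rejected.
    ABF support requires the optional ``pyabf`` dependency.
    """
    path = Path(path)
    if path.suffix.lower() == ".abf":
        try:
            import pyabf
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise FormatError(
                "reading ABF files requires the optional 'pyabf' package; "
                "export the trace to CSV instead"
            ) from exc
        abf = pyabf.ABF(str(path))
        traces = []
        for sweep in range(abf.sweepCount):
            abf.setSweep(sweep)
            traces.append(
                VoltageTrace(
                    v=np.asarray(abf.sweepY, dtype=float),
                    dt=1.0 / abf.dataRate,
                    source=str(path),
                    sweep=sweep,
                )
            )
        return traces

    data = np.loadtxt(path, delimiter=",", skiprows=_csv_header_rows(path))
    if data.ndim != 2 or data.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns (time_s, voltage_mv)")
    t, v = data[:, 0], data[:, 1]
    dts = np.diff(t)
    dt = float(np.median(dts))
    if dt <= 0 or np.any(np.abs(dts - dt) > rel_tol * dt + 1e-12):
        raise FormatError(f"{path}: nonuniform timebase (jittered timestamps)")
    return [VoltageTrace(v=v, dt=dt, source=str(path))]


def _csv_header_rows(path: Path) -> int:
    with open(path) as fh:
        first = fh.readline()
    try:
        float(first.split(",")[0])
        return 0
    except ValueError:
        return 1


def save_trace_csv(trace: VoltageTrace, path: Path | str) -> None:
    np.savetxt(
        path,
        np.column_stack([trace.t, trace.v]),
        delimiter=",",
        header="time_s,voltage_mv",
        comments="",
    )


# ---------------------------------------------------------------------------
# detection and thresholds


def detect_aps(
    trace: VoltageTrace,
    min_prominence_mv: float = 20.0,
    min_peak_v_mv: float = -20.0,
    refractory_ms: float = 5.0,
) -> np.ndarray:
    """Indices of AP peaks: prominent local maxima separated by a refractory gap."""
    distance = max(1, int(round(refractory_ms * 1e-3 / trace.dt)))
    peaks, _ = find_peaks(
        trace.v,
        height=min_peak_v_mv,
        prominence=min_prominence_mv,
        distance=distance,
    )
    return peaks


def dvdt(trace: VoltageTrace, smooth_samples: int = 3) -> np.ndarray:
    """Smoothed dV/dt in mV/ms (central differences)."""
    raw = np.gradient(trace.v) / (trace.dt * 1e3)
    if smooth_samples > 1:
        raw = uniform_filter1d(raw, size=smooth_samples)
    return raw


def threshold_fixed_lead(
    trace: VoltageTrace, peak_idx: int, lead_ms: float
) -> ThresholdPoint:
    """Threshold = sample at ``lead_ms`` before the peak (user-defined lead).

    The same lead must be applied to every AP of an analysis so parameters are
    standardized across recordings.
    """
    if lead_ms == 0:
        warnings.warn("lead of 0 ms makes the threshold equal the peak", stacklevel=2)
    idx = peak_idx - int(round(lead_ms * 1e-3 / trace.dt))
    if idx < 0:
        raise AnalysisError("fixed lead extends before the start of the trace")
    return ThresholdPoint(
        index=idx, time_s=idx * trace.dt, v_mv=float(trace.v[idx]), method="fixed-lead"
    )


def threshold_inflection(
    trace: VoltageTrace,
    peak_idx: int,
    dvdt_criterion_mv_per_ms: float = 10.0,
    search_window_ms: float = 20.0,
    smooth_samples: int = 3,
    method: str = "dvdt",
) -> ThresholdPoint:
    """Automatic threshold at the preupstroke inflection.

    ``method="dvdt"`` (default): the last upward crossing of the dV/dt
    criterion before the peak.  ``method="d2v"``: the maximum of the second
    derivative within the search window, offered for comparison.  Raises
    :class:`NoInflectionError` when the criterion is never reached, in which
    case the fixed-lead method should be used.
    """
    w0 = max(0, peak_idx - int(round(search_window_ms * 1e-3 / trace.dt)))
    slope = dvdt(trace, smooth_samples=smooth_samples)
    if method == "d2v":
        accel = np.gradient(slope)
        idx = w0 + int(np.argmax(accel[w0 : peak_idx + 1]))
        return ThresholdPoint(idx, idx * trace.dt, float(trace.v[idx]), "inflection")
    if method != "dvdt":
        raise ValueError(f"unknown inflection method {method!r}")
    window = slope[w0 : peak_idx + 1]
    if np.max(window) < dvdt_criterion_mv_per_ms:
        raise NoInflectionError(
            f"dV/dt never reaches {dvdt_criterion_mv_per_ms} mV/ms before the peak"
        )
    above = window >= dvdt_criterion_mv_per_ms
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if len(crossings) == 0:
        # already above the criterion at the window start
        idx = w0
    else:
        idx = w0 + int(crossings[-1])
    return ThresholdPoint(
        index=idx, time_s=idx * trace.dt, v_mv=float(trace.v[idx]), method="inflection"
    )


def rmp(
    trace: VoltageTrace,
    ref_time_s: float,
    mode: str,
    window_ms: float = 20.0,
    sub_ms: float = 3.0,
) -> float:
    """Resting membrane potential from the window preceding ``ref_time_s``.

    ``mode="fixed-lead"``: mean of the whole 20 ms window.  ``mode="inflection"``:
    the minimum over all 3 ms sliding sub-windows of the sub-window mean.
    """
    ref_idx = int(round(ref_time_s / trace.dt))
    n_w = int(round(window_ms * 1e-3 / trace.dt))
    start = ref_idx - n_w
    if start < 0:
        raise AnalysisError(
            "RMP window truncated by the trace start; measure the RMP manually "
            "from a segment of the recording without APs"
        )
    window = trace.v[start:ref_idx]
    if mode == "fixed-lead":
        return float(window.mean())
    if mode == "inflection":
        n_s = max(1, int(round(sub_ms * 1e-3 / trace.dt)))
        if n_s > len(window):
            raise AnalysisError("sub-window longer than the RMP window")
        csum = np.concatenate([[0.0], np.cumsum(window)])
        means = (csum[n_s:] - csum[:-n_s]) / n_s
        return float(means.min())
    raise ValueError(f"unknown RMP mode {mode!r}")


# ---------------------------------------------------------------------------
# per-AP metrics


def _cross_time(trace: VoltageTrace, i0: int, i1: int, level: float) -> float:
    """Sub-sample time where v crosses ``level`` between samples i0 and i1."""
    v0, v1 = trace.v[i0], trace.v[i1]
    if v1 == v0:
        return i1 * trace.dt
    frac = (level - v0) / (v1 - v0)
    return (i0 + frac * (i1 - i0)) * trace.dt


def ap_metrics(
    trace: VoltageTrace,
    peak_idx: int,
    threshold: ThresholdPoint,
    rmp_mv: float,
    next_threshold_idx: int | None = None,
    ahp_cap_ms: float = 200.0,
) -> APEvent:
    """Derive all per-AP metrics from a peak, its threshold point, and the RMP."""
    if threshold.index >= peak_idx:
        raise AnalysisError("threshold must precede the peak")
    v = trace.v
    dt_ms = trace.dt * 1e3
    peak_v = float(v[peak_idx])
    amplitude = peak_v - threshold.v_mv
    if amplitude <= 0:
        raise AnalysisError("nonpositive amplitude: threshold above peak")
    half = threshold.v_mv + amplitude / 2.0

    # upstroke half-level crossing (search back from the peak)
    i = peak_idx
    while i > threshold.index and v[i - 1] >= half:
        i -= 1
    t_up = _cross_time(trace, i - 1, i, half) if v[i - 1] < half else i * trace.dt

    # downstroke crossings: half level, then the threshold voltage
    end = len(v) if next_threshold_idx is None else min(len(v), next_threshold_idx)
    cap_end = min(end, peak_idx + int(round(ahp_cap_ms / dt_ms)) + 1)
    t_down = None
    decay_time = None
    decay_idx = None
    j = peak_idx + 1
    while j < end:
        if t_down is None and v[j] <= half:
            t_down = _cross_time(trace, j - 1, j, half)
        if v[j] <= threshold.v_mv:
            decay_time = _cross_time(trace, j - 1, j, threshold.v_mv) - peak_idx * trace.dt
            decay_idx = j
            break
        j += 1
    apd50 = None if t_down is None else (t_down - t_up) * 1e3

    ahp_v = None
    if decay_idx is not None:
        seg = v[decay_idx:cap_end]
        if len(seg):
            ahp_v = float(seg.min())

    slope = dvdt(trace, smooth_samples=1)
    window = slope[threshold.index : cap_end if decay_idx is None else max(cap_end, decay_idx + 1)]
    return APEvent(
        peak_time_s=peak_idx * trace.dt,
        peak_v_mv=peak_v,
        threshold_time_s=threshold.time_s,
        threshold_v_mv=threshold.v_mv,
        method=threshold.method,
        rmp_mv=rmp_mv,
        amplitude_mv=amplitude,
        apd50_ms=apd50,
        ahp_v_mv=ahp_v,
        rise_time_ms=(peak_idx - threshold.index) * dt_ms,
        decay_time_ms=None if decay_time is None else decay_time * 1e3,
        max_slope_mv_per_ms=float(window.max()),
        min_slope_mv_per_ms=float(window.min()),
    )


@dataclass
class PhasePlot:
    v_mv: np.ndarray
    dvdt_mv_per_ms: np.ndarray
    max_slope_mv_per_ms: float
    min_slope_mv_per_ms: float


def phase_plot(
    trace: VoltageTrace, peak_idx: int, pre_ms: float = 10.0, post_ms: float = 10.0
) -> PhasePlot:
    """(V, dV/dt) curve around one peak with its extreme slopes."""
    i0 = max(0, peak_idx - int(round(pre_ms * 1e-3 / trace.dt)))
    i1 = min(len(trace.v), peak_idx + int(round(post_ms * 1e-3 / trace.dt)) + 1)
    slope = dvdt(trace, smooth_samples=1)[i0:i1]
    return PhasePlot(
        v_mv=trace.v[i0:i1].copy(),
        dvdt_mv_per_ms=slope,
        max_slope_mv_per_ms=float(slope.max()),
        min_slope_mv_per_ms=float(slope.min()),
    )


def average_ap(
    trace: VoltageTrace,
    peaks: np.ndarray,
    pre_ms: float = 10.0,
    post_ms: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Peak-aligned sample-wise mean AP.

    Returns (time relative to peak in ms, mean voltage, number of APs used);
    APs whose window would run off either end of the trace are dropped.
    """
    n_pre = int(round(pre_ms * 1e-3 / trace.dt))
    n_post = int(round(post_ms * 1e-3 / trace.dt))
    windows = [
        trace.v[p - n_pre : p + n_post + 1]
        for p in np.atleast_1d(peaks)
        if p - n_pre >= 0 and p + n_post < len(trace.v)
    ]
    if not windows:
        raise AnalysisError("no AP window fits inside the trace")
    mean = np.mean(windows, axis=0)
    t_rel = (np.arange(-n_pre, n_post + 1)) * trace.dt * 1e3
    return t_rel, mean, len(windows)


def analyze_trace(
    trace: VoltageTrace,
    method: str = "auto",
    lead_ms: float | None = None,
    dvdt_criterion_mv_per_ms: float = 10.0,
    rmp_window_ms: float = 20.0,
    rmp_sub_ms: float = 3.0,
    **detect_kwargs,
) -> list[APEvent]:
    """Detect and quantify every AP in one sweep.

    ``method`` is ``"inflection"``, ``"fixed-lead"`` (requires ``lead_ms``), or
    ``"auto"`` (inflection with fixed-lead fallback, which then also requires
    ``lead_ms``).
    """
    peaks = detect_aps(trace, **detect_kwargs)
    events: list[APEvent] = []
    thresholds: list[ThresholdPoint] = []
    for p in peaks:
        if method in ("inflection", "auto"):
            try:
                tp = threshold_inflection(trace, int(p), dvdt_criterion_mv_per_ms)
            except NoInflectionError:
                if method == "inflection":
                    raise
                if lead_ms is None:
                    raise AnalysisError(
                        "no preupstroke inflection; provide lead_ms for the "
                        "fixed-lead fallback"
                    ) from None
                tp = threshold_fixed_lead(trace, int(p), lead_ms)
        elif method == "fixed-lead":
            if lead_ms is None:
                raise AnalysisError("the fixed-lead method requires lead_ms")
            tp = threshold_fixed_lead(trace, int(p), lead_ms)
        else:
            raise ValueError(f"unknown method {method!r}")
        thresholds.append(tp)
    for k, (p, tp) in enumerate(zip(peaks, thresholds)):
        rmp_mode = "inflection" if tp.method == "inflection" else "fixed-lead"
        rmp_mv = rmp(trace, tp.time_s, rmp_mode, rmp_window_ms, rmp_sub_ms)
        nxt = thresholds[k + 1].index if k + 1 < len(thresholds) else None
        events.append(ap_metrics(trace, int(p), tp, rmp_mv, next_threshold_idx=nxt))
    return events
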