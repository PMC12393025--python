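"""Sleep-like quiescence detection from centroid displacement.

Frames (nominally 1 per 10 s) are labeled motionless when the centroid moved
less than 10 um since the previous frame, active otherwise (a displacement of
exactly 10 um counts as active: the motionless inequality is strict).  A sleep
bout opens at the start of three consecutive motionless frames and ends at the
end of the last run of three consecutive motionless frames; it is terminated
by an awakening, defined here as three consecutive active frames (the bout-end
rule is an interpretation, configurable via ``wake_k``).  Shorter active runs
inside a bout are recorded as active events; motionless sleep duration is the
bout duration minus the total active-event duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError

MOTIONLESS = "motionless"
ACTIVE = "active"
GAP = "gap"  # missing centroid: motionlessness cannot be asserted


@dataclass
class MotionSeries:
    """Per-transition displacement labels; transition j spans [t_j, t_{j+1})."""

    timestamps: np.ndarray  # (N,) frame times, seconds
    displacements: np.ndarray  # (N-1,) um; NaN at gaps
    labels: list[str]  # (N-1,) motionless | active | gap
    threshold_um: float = 10.0


@dataclass
class SleepBout:
    start_time: float
    end_time: float
    active_events: list[tuple[float, float]] = field(default_factory=list)  # (start, duration)
    flagged: bool = False  # overlaps a caller-invalidated time range

    @property
    def total_duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def motionless_duration(self) -> float:
        return self.total_duration - sum(d for _, d in self.active_events)


def classify_motion(
    centroids: np.ndarray,
    timestamps: np.ndarray | None = None,
    threshold_um: float = 10.0,
    frame_interval_s: float = 10.0,
) -> MotionSeries:
    """Label each inter-frame transition motionless or active.

    ``centroids`` is an (N, 2) um array; rows with NaN (failed segmentation)
    yield ``gap`` labels on both adjacent transitions.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[1] != 2 or len(centroids) < 2:
        raise AnalysisError("need an (N >= 2, 2) centroid array")
    if timestamps is None:
        timestamps = np.arange(len(centroids)) * frame_interval_s
    timestamps = np.asarray(timestamps, dtype=float)
    disp = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    labels = []
    for d in disp:
        if not np.isfinite(d):
            labels.append(GAP)
        elif d < threshold_um:
            labels.append(MOTIONLESS)
        else:
            labels.append(ACTIVE)
    return MotionSeries(
        timestamps=timestamps,
        displacements=disp,
        labels=labels,
        threshold_um=threshold_um,
    )


def _runs(labels: list[str]) -> list[tuple[int, int, str]]:
    """Maximal runs as (start, end_inclusive, label)."""
    out = []
    start = 0
    for i in range(1, len(labels)):
        if labels[i] != labels[i - 1]:
            out.append((start, i - 1, labels[i - 1]))
            start = i
    out.append((start, len(labels) - 1, labels[-1]))
    return out


def detect_sleep_bouts(
    series: MotionSeries,
    k: int = 3,
    wake_k: int = 3,
    invalid_ranges: list[tuple[float, float]] | None = None,
) -> list[SleepBout]:
    """Scan the label sequence for sleep bouts.

    A bout opens at the first frame of a run of >= ``k`` motionless labels and
    is closed by an awakening (>= ``wake_k`` consecutive active labels), a gap,
    or the end of the recording; its end is trimmed back to the end of the last
    >= ``k`` motionless run.  Bouts overlapping any ``invalid_ranges`` (e.g.,
    chamber-edge contact) are flagged rather than dropped.
    """
    labels = series.labels
    t = series.timestamps
    runs = _runs(labels)
    bouts: list[SleepBout] = []

    i = 0
    while i < len(runs):
        start_run, end_run, label = runs[i]
        if label != MOTIONLESS or (end_run - start_run + 1) < k:
            i += 1
            continue
        # candidate bout opens here; find the terminator
        j = i
        last_long_m = i
        while j < len(runs):
            s, e, lab = runs[j]
            if lab == GAP:
                break
            if lab == ACTIVE and (e - s + 1) >= wake_k:
                break
            if lab == MOTIONLESS and (e - s + 1) >= k:
                last_long_m = j
            j += 1
        bout_start_idx = runs[i][0]
        bout_end_idx = runs[last_long_m][1]
        start_time = float(t[bout_start_idx])
        end_time = float(t[bout_end_idx + 1])
        events = [
            (float(t[s]), float(t[e + 1] - t[s]))
            for s, e, lab in runs[i:last_long_m]
            if lab == ACTIVE
        ]
        bout = SleepBout(start_time=start_time, end_time=end_time, active_events=events)
        if invalid_ranges:
            bout.flagged = any(
                bout.start_time < hi and bout.end_time > lo for lo, hi in invalid_ranges
            )
        bouts.append(bout)
        i = j + 1
    return bouts


@dataclass
class SleepSummary:
    total_sleep_s: float
    bout_count: int
    mean_bout_s: float
    longest_bout_s: float
    active_event_count: int
    active_event_total_s: float
    motionless_sleep_s: float
    recording_span_s: float

    def to_row(self) -> dict[str, float]:
        from dataclasses import fields

        return {f.name: getattr(self, f.name) for f in fields(self)}


def sleep_summary(bouts: list[SleepBout], recording_span_s: float) -> SleepSummary:
    """Totals across bouts; both the summed and the longest bout are reported."""
    durations = [b.total_duration for b in bouts]
    events = [ev for b in bouts for ev in b.active_events]
    return SleepSummary(
        total_sleep_s=float(sum(durations)),
        bout_count=len(bouts),
        mean_bout_s=float(np.mean(durations)) if durations else 0.0,
        longest_bout_s=float(max(durations)) if durations else 0.0,
        active_event_count=len(events),
        active_event_total_s=float(sum(d for _, d in events)),
        motionless_sleep_s=float(sum(b.motionless_duration for b in bouts)),
        recording_span_s=float(recording_span_s),
    )
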