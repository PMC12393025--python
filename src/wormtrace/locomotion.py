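"""Locomotion kinematics: world-coordinate tracks, speed, direction, amplitude.

Splines are merged with the stage log into absolute micrometer coordinates
(world position = stage position at the latest stage entry at or before the
frame time, plus pixel position x um_per_px), so compensating stage moves
produce no spurious worm displacement.  Movement metrics are computed on the
actual frames for 1/3/5 FPS recordings but on an effective 3 FPS decimation
(every 5th frame) for 15 FPS recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from ._midline import midline_length
from .errors import AnalysisError
from .formats import N_MARKERS, Orientation, SplineFile, StageLog, TimeLog
from .segmentation import Spline13

VALID_FPS = (1, 3, 5, 15)


@dataclass
class WorldTrack:
    """Time series of worm poses in absolute (stage-corrected) micrometers."""

    times: np.ndarray  # (T,) seconds
    markers_um: np.ndarray  # (T, 13, 2); NaN rows for failed fits
    lengths_um: np.ndarray  # (T,) straightened spline length; NaN for failed fits
    um_per_px: float
    fps_nominal: int
    fps_effective: int
    orientation: Orientation = Orientation.UNKNOWN

    @property
    def centroids(self) -> np.ndarray:
        return self.markers_um.mean(axis=1)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.markers_um).all(axis=(1, 2))

    def positions(self, marker: int | str = "centroid") -> np.ndarray:
        """Positions of one marker (1-based index 1..13) or the centroid."""
        if marker == "centroid":
            return self.centroids
        idx = int(marker)
        if not 1 <= idx <= N_MARKERS:
            raise ValueError(f"marker index must be 1..{N_MARKERS} or 'centroid'")
        return self.markers_um[:, idx - 1, :]


@dataclass
class MovementSummary:
    avg_speed_um_per_s: float
    total_distance_um: float
    net_distance_um: float
    forward_distance_um: float
    backward_distance_um: float
    forward_speed_um_per_s: float
    backward_speed_um_per_s: float
    forward_time_fraction: float
    backward_time_fraction: float
    amplitude_mean_um: float
    amplitude_max_um: float
    a_over_l: float
    length_um: float

    def to_row(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def to_world(
    spline_file: SplineFile,
    stage_log: StageLog,
    time_log: TimeLog,
    um_per_px: float,
    fps: int,
    orientation: Orientation = Orientation.UNKNOWN,
) -> WorldTrack:
    """Merge a spline track with the stage log into absolute coordinates."""
    frame_to_time = {int(f): t for f, t in time_log.frame_times}
    T = len(spline_file.records)
    times = np.empty(T)
    markers = np.full((T, N_MARKERS, 2), np.nan)
    lengths = np.full(T, np.nan)
    for i, rec in enumerate(spline_file.records):
        t = frame_to_time.get(rec.frame)
        if t is None:
            # no logged timestamp: fall back to the nominal frame interval
            t = (rec.frame - 1) / fps
        times[i] = t
        if rec.ok:
            offset = stage_log.position_at(t)
            markers[i] = rec.markers * um_per_px + offset
            lengths[i] = midline_length(rec.markers) * um_per_px
    return WorldTrack(
        times=times,
        markers_um=markers,
        lengths_um=lengths,
        um_per_px=um_per_px,
        fps_nominal=int(fps),
        fps_effective=int(fps),
        orientation=orientation,
    )


def effective_frames(track: WorldTrack, phase: int = 0) -> WorldTrack:
    """Decimate a 15 FPS track to the 3 FPS analysis rate (every 5th frame).

    Tracks recorded at 1, 3, or 5 FPS are returned unchanged.
    """
    if track.fps_nominal not in VALID_FPS:
        raise AnalysisError(
            f"frame rate {track.fps_nominal} not in {VALID_FPS}; resample explicitly"
        )
    if track.fps_nominal != 15:
        return track
    sel = slice(phase, None, 5)
    return WorldTrack(
        times=track.times[sel],
        markers_um=track.markers_um[sel],
        lengths_um=track.lengths_um[sel],
        um_per_px=track.um_per_px,
        fps_nominal=track.fps_nominal,
        fps_effective=3,
        orientation=track.orientation,
    )


def classify_direction(
    prev_centroid: np.ndarray, centroid: np.ndarray, head_tip: np.ndarray
) -> str:
    """Forward/backward call from the velocity and head vectors.

    The worm moves forward iff the head vector (centroid -> head tip) projects
    onto the positive side of the velocity vector (previous -> current
    centroid); a zero or negative projection is backward.  A zero velocity is
    labeled stationary.
    """
    velocity = np.asarray(centroid, float) - np.asarray(prev_centroid, float)
    if np.allclose(velocity, 0.0):
        return "stationary"
    head_vec = np.asarray(head_tip, float) - np.asarray(centroid, float)
    return "forward" if float(np.dot(velocity, head_vec)) > 0 else "backward"


def amplitude_and_length(
    spline: Spline13 | np.ndarray,
    velocity: np.ndarray,
    um_per_px: float = 1.0,
) -> tuple[float, float, float]:
    """Amplitude A, length L, and A/L for one pose.

    A is the width of the smallest rectangle parallel to the velocity vector
    that encloses all 13 markers; L is the straightened-spline arc length.
    """
    markers = spline.markers if isinstance(spline, Spline13) else np.asarray(spline, float)
    velocity = np.asarray(velocity, dtype=float)
    norm = np.linalg.norm(velocity)
    if norm == 0:
        raise AnalysisError("amplitude undefined for zero velocity")
    perp = np.array([-velocity[1], velocity[0]]) / norm
    proj = markers @ perp
    amplitude = float(proj.max() - proj.min()) * um_per_px
    length = midline_length(markers) * um_per_px
    return amplitude, length, amplitude / length


def _step_labels(track: WorldTrack) -> tuple[np.ndarray, list[str]]:
    """Indices of valid frames and the direction label of each consecutive step."""
    idx = np.flatnonzero(track.valid)
    cent = track.centroids
    heads = track.markers_um[:, 0, :]
    labels = [
        classify_direction(cent[i], cent[j], heads[j]) for i, j in zip(idx[:-1], idx[1:])
    ]
    return idx, labels


def movement_metrics(track: WorldTrack, marker: int | str = "centroid") -> MovementSummary:
    """Speed/distance/direction/amplitude summary for one recording.

    Distances follow the chosen marker (or the centroid); direction labels
    always come from the centroid velocity versus the head vector.
    """
    idx = np.flatnonzero(track.valid)
    if len(idx) < 2:
        raise AnalysisError("need at least 2 fitted frames")
    pos = track.positions(marker)[idx]
    times = track.times[idx]
    disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    dt = np.diff(times)
    elapsed = float(times[-1] - times[0])
    if elapsed <= 0:
        raise AnalysisError("recording spans no time")
    _, labels = _step_labels(track)
    labels_arr = np.array(labels)

    total = float(disp.sum())
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    fwd = labels_arr == "forward"
    bwd = labels_arr == "backward"
    fwd_dist, bwd_dist = float(disp[fwd].sum()), float(disp[bwd].sum())
    fwd_time, bwd_time = float(dt[fwd].sum()), float(dt[bwd].sum())

    cent = track.centroids[idx]
    amplitudes = []
    ratios = []
    for k in range(1, len(idx)):
        velocity = cent[k] - cent[k - 1]
        if np.allclose(velocity, 0.0):
            continue  # amplitude undefined for stationary steps
        a, l, r = amplitude_and_length(track.markers_um[idx[k]], velocity)
        amplitudes.append(a)
        ratios.append(r)
    mean_len = float(np.nanmean(track.lengths_um[idx]))
    amp_mean = float(np.mean(amplitudes)) if amplitudes else float("nan")
    amp_max = float(np.max(amplitudes)) if amplitudes else float("nan")

    return MovementSummary(
        avg_speed_um_per_s=total / elapsed,
        total_distance_um=total,
        net_distance_um=net,
        forward_distance_um=fwd_dist,
        backward_distance_um=bwd_dist,
        forward_speed_um_per_s=fwd_dist / fwd_time if fwd_time > 0 else 0.0,
        backward_speed_um_per_s=bwd_dist / bwd_time if bwd_time > 0 else 0.0,
        forward_time_fraction=fwd_time / elapsed,
        backward_time_fraction=bwd_time / elapsed,
        amplitude_mean_um=amp_mean,
        amplitude_max_um=amp_max,
        a_over_l=amp_mean / mean_len,
        length_um=mean_len,
    )


@dataclass
class TravelPath:
    times: np.ndarray  # (K,) valid-frame timestamps
    positions: np.ndarray  # (K, 2) micrometers
    step_speeds: np.ndarray  # (K-1,) um/s per inter-frame step
    step_labels: list[str]  # forward | backward | stationary per step
    bin_times: np.ndarray | None = None
    bin_speeds: np.ndarray | None = None


def travel_path(
    track: WorldTrack, marker: int | str = "centroid", bin_s: float | None = None
) -> TravelPath:
    """Reconstructed travel path of one marker (or the centroid).

    With ``bin_s``, speeds are also averaged into fixed-width time bins
    (bin speed = distance in bin / time in bin).
    """
    idx = np.flatnonzero(track.valid)
    if len(idx) < 2:
        raise AnalysisError("need at least 2 fitted frames")
    pos = track.positions(marker)[idx]
    times = track.times[idx]
    disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    dt = np.diff(times)
    speeds = np.divide(disp, dt, out=np.zeros_like(disp), where=dt > 0)
    _, labels = _step_labels(track)

    bin_times = bin_speeds = None
    if bin_s is not None:
        t0 = times[0]
        edges = np.arange(t0, times[-1] + bin_s, bin_s)
        if edges[-1] < times[-1]:
            edges = np.append(edges, times[-1])
        mid = np.asarray(0.5 * (times[:-1] + times[1:]))
        which = np.clip(np.searchsorted(edges, mid, side="right") - 1, 0, len(edges) - 2)
        bt, bs = [], []
        for b in range(len(edges) - 1):
            sel = which == b
            if not sel.any():
                continue
            bt.append(0.5 * (edges[b] + edges[b + 1]))
            bs.append(disp[sel].sum() / dt[sel].sum())
        bin_times, bin_speeds = np.array(bt), np.array(bs)
    return TravelPath(
        times=times,
        positions=pos,
        step_speeds=speeds,
        step_labels=labels,
        bin_times=bin_times,
        bin_speeds=bin_speeds,
    )
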