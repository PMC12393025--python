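"""Ground-truthed synthetic inputs: rendered worms, crawls, actograms, AP trains.

These generators replace the microscope, motorized stage, and patch-clamp rig:
every dataset is emitted together with its exact ground truth (midline markers,
trajectories, bout schedules, AP parameters), is deterministic per seed, and is
written in the same file dialects the analysis modules read.

The worm model is a sinusoidal midline (lateral offset a*sin(2*pi*s/lambda +
phi) along a heading) with a smoothly tapered width profile whose tail tapers
more sharply than the head, giving corner detection the same asymmetry the
real animal provides.  At the default scale (1,000 um worm at 5 um/px) the
rendered body covers roughly 8,000 px, comfortably above the 3,000 px debris
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .formats import (
    N_MARKERS,
    SplineFile,
    SplineRecord,
    StageLog,
    TimeLog,
    write_meta_file,
    write_spline_file,
    write_stage_file,
    write_time_file,
)

# ---------------------------------------------------------------------------
# worm pose and rendering


@dataclass
class WormPose:
    """Parametric worm midline in world micrometers (head at arc position 0)."""

    length_um: float = 1000.0
    amplitude_um: float = 100.0
    wavelength_um: float = 1000.0
    phase: float = 0.0
    heading_rad: float = 0.0
    position_um: tuple[float, float] = (0.0, 0.0)  # head-end anchor
    max_half_width_um: float = 125.0
    head_taper: float = 0.15  # blunt head: short sqrt taper
    tail_taper: float = 0.30  # sharp tail: long linear taper

    def midline(self, n: int = 2000) -> np.ndarray:
        """``n`` points at equal arc-length spacing from head to tail (um)."""
        # dense parameter sweep, then arc-length reparameterization
        u_max = self.length_um * 1.6
        u = np.linspace(0.0, u_max, 8 * n)
        y = self.amplitude_um * np.sin(2 * np.pi * u / self.wavelength_um + self.phase)
        pts = np.column_stack([u, y])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if s[-1] < self.length_um:
            raise ValueError("parameter sweep too short for requested length")
        targets = np.linspace(0.0, self.length_um, n)
        xs = np.interp(targets, s, pts[:, 0])
        ys = np.interp(targets, s, pts[:, 1])
        local = np.column_stack([xs, ys])
        c, sn = np.cos(self.heading_rad), np.sin(self.heading_rad)
        rot = np.array([[c, -sn], [sn, c]])
        return local @ rot.T + np.asarray(self.position_um)

    def half_widths(self, n: int = 2000) -> np.ndarray:
        """Half-width (um) at each of ``n`` equal arc positions."""
        sf = np.linspace(0.0, 1.0, n)
        head = np.minimum(1.0, sf / self.head_taper) ** 0.5
        tail = np.minimum(1.0, (1.0 - sf) / self.tail_taper)
        return self.max_half_width_um * head * tail

    def true_markers(self, n_dense: int = 4000) -> np.ndarray:
        """The 13 equal-arc-length midline markers (world um)."""
        dense = self.midline(n_dense)
        seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        targets = np.linspace(0.0, s[-1], N_MARKERS)
        return np.column_stack(
            [np.interp(targets, s, dense[:, 0]), np.interp(targets, s, dense[:, 1])]
        )


def true_bend_angles(markers: np.ndarray) -> np.ndarray:
    """Ground-truth signed bend angles (deg) at markers 1-11, raw sign convention."""
    out = np.empty(11)
    for i in range(11):
        a, b, c = markers[i], markers[i + 1], markers[i + 2]
        v, d = a - b, c - b
        cosang = np.dot(v, d) / (np.linalg.norm(v) * np.linalg.norm(d))
        theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        mag = min(theta, 180.0 - theta)
        cross = d[0] * v[1] - d[1] * v[0]
        out[i] = mag * (np.sign(cross) if cross else 0.0)
    return out


def _check_no_self_intersection(dense: np.ndarray, widths: np.ndarray) -> None:
    # vectorized on a subsample: points far apart along the body must not touch
    step = max(1, len(dense) // 250)
    pts, w = dense[::step], widths[::step]
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])[::step]
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    touch = w[:, None] + w[None, :]
    arc = np.abs(s[:, None] - s[None, :])
    bad = (arc > 2.0 * touch) & (d2 < touch**2)
    if bad.any():
        raise ValueError("pose is self-intersecting (body touches itself)")


@dataclass
class GroundTruthFrame:
    markers_px: np.ndarray  # (13, 2) pixel coordinates
    markers_um: np.ndarray  # (13, 2) world micrometers
    length_um: float
    bend_angles_deg: np.ndarray  # (11,) raw-convention signs
    mask: np.ndarray | None = None  # true body mask (rendered frames only)

    @property
    def centroid_px(self) -> np.ndarray:
        return self.markers_px.mean(axis=0)

    @property
    def head_px(self) -> np.ndarray:
        return self.markers_px[0]


def render_worm(
    pose: WormPose,
    um_per_px: float = 5.0,
    image_shape: tuple[int, int] | None = None,
    origin_um: np.ndarray | None = None,
    body_intensity: float = 40.0,
    background_intensity: float = 200.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    n_dense: int = 1500,
) -> tuple[np.ndarray, GroundTruthFrame]:
    """Render a dark worm on a bright background with exact ground truth.

    Pixel = (world - origin) / um_per_px.  With ``image_shape=None`` the image
    is sized to the body with a 20 px margin.  Deterministic per seed.
    """
    dense = pose.midline(n_dense)
    widths = pose.half_widths(n_dense)
    _check_no_self_intersection(dense, widths)

    if origin_um is None:
        lo = (dense - widths[:, None]).min(axis=0)
        origin_um = lo - 20.0 * um_per_px
    origin_um = np.asarray(origin_um, dtype=float)
    if image_shape is None:
        hi = (dense + widths[:, None]).max(axis=0)
        extent_px = (hi - origin_um) / um_per_px + 20.0
        image_shape = (int(np.ceil(extent_px[1])), int(np.ceil(extent_px[0])))

    dense_px = (dense - origin_um) / um_per_px
    widths_px = widths / um_per_px
    h, w = image_shape
    # query only the body's bounding box; everything else is background
    wmax = float(widths_px.max())
    x0 = max(0, int(np.floor(dense_px[:, 0].min() - wmax - 2)))
    x1 = min(w, int(np.ceil(dense_px[:, 0].max() + wmax + 2)) + 1)
    y0 = max(0, int(np.floor(dense_px[:, 1].min() - wmax - 2)))
    y1 = min(h, int(np.ceil(dense_px[:, 1].max() + wmax + 2)) + 1)
    mask = np.zeros((h, w), dtype=bool)
    if x1 > x0 and y1 > y0:
        yy, xx = np.mgrid[y0:y1, x0:x1]
        grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        dist, idx = cKDTree(dense_px).query(grid, workers=-1)
        mask[y0:y1, x0:x1] = (dist <= widths_px[idx]).reshape(y1 - y0, x1 - x0)

    image = np.full(image_shape, background_intensity, dtype=float)
    image[mask] = body_intensity
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)

    markers_um = pose.true_markers()
    truth = GroundTruthFrame(
        markers_px=(markers_um - origin_um) / um_per_px,
        markers_um=markers_um,
        length_um=pose.length_um,
        bend_angles_deg=true_bend_angles(markers_um),
        mask=mask,
    )
    return image, truth


def analytic_body_area_um2(pose: WormPose, n: int = 20000) -> float:
    """Closed-form body area: integral of 2 x half-width along the midline."""
    sf = np.linspace(0.0, 1.0, n)
    head = np.minimum(1.0, sf / pose.head_taper) ** 0.5
    tail = np.minimum(1.0, (1.0 - sf) / pose.tail_taper)
    return float(np.trapezoid(2.0 * pose.max_half_width_um * head * tail, sf * pose.length_um))


# ---------------------------------------------------------------------------
# crawl simulation (recording bundle with known trajectory)


@dataclass
class CrawlSim:
    """A simulated tracked recording with exact ground truth."""

    times: np.ndarray  # (T,)
    truth_frames: list[GroundTruthFrame]
    spline_file: SplineFile  # ground-truth 13-marker records in pixel coords
    stage_log: StageLog
    time_log: TimeLog
    um_per_px: float
    fps: int
    true_speed_um_per_s: float  # mean centroid speed along the true world path
    direction: str  # forward | backward
    undulation_hz: float
    folder: Path | None = None

    @property
    def world_centroids(self) -> np.ndarray:
        return np.array([f.markers_um.mean(axis=0) for f in self.truth_frames])

    @property
    def world_markers(self) -> np.ndarray:
        return np.array([f.markers_um for f in self.truth_frames])


def simulate_crawl(
    out_dir: Path | str | None = None,
    name: str = "wt1",
    duration_s: float = 10.0,
    fps: int = 5,
    speed_um_per_s: float = 150.0,
    undulation_hz: float = 0.5,
    amplitude_um: float = 100.0,
    wavelength_um: float = 1000.0,
    length_um: float = 1000.0,
    um_per_px: float = 5.0,
    heading_deg: float = 0.0,
    reverse: bool = False,
    recenter: bool = True,
    noise_sigma: float = 5.0,
    image_shape: tuple[int, int] = (300, 340),
    seed: int = 0,
) -> CrawlSim:
    """Simulate a worm crawling at constant speed with sinusoidal undulation.

    With ``out_dir`` set, a fully formed recording bundle is written there
    (``img%05d.png`` frames, stage file, time file, metadata sidecar) that
    :func:`wormtrace.formats.resolve_recording` can load; with ``out_dir=None``
    only the in-memory ground truth is produced (no rendering).  Stage
    recentering mimics the 1 s interval corrections of a motorized stage,
    applied between image acquisitions.  The worm's head leads the motion
    unless ``reverse`` is set.
    """
    n_frames = int(round(duration_s * fps))
    times = np.arange(n_frames) / fps
    heading = np.deg2rad(heading_deg)
    direction = np.array([np.cos(heading), np.sin(heading)])
    # the body extends opposite the travel direction from the head anchor
    body_heading = heading + np.pi
    velocity = -speed_um_per_s if reverse else speed_um_per_s

    center_px = np.array([image_shape[1] / 2.0, image_shape[0] / 2.0])

    poses = []
    for t in times:
        poses.append(
            WormPose(
                length_um=length_um,
                amplitude_um=amplitude_um,
                wavelength_um=wavelength_um,
                phase=-2 * np.pi * undulation_hz * t,
                heading_rad=body_heading,
                position_um=tuple(direction * velocity * t),
            )
        )

    # stage schedule: recentering moves at 1 s intervals, between acquisitions
    entries = []
    if recenter:
        move_times = np.arange(0.0, duration_s, 1.0) + 0.5 / fps
        move_times = move_times[move_times < times[-1]] if n_frames > 1 else move_times[:1]
        probe = [0.0] + list(move_times)
        for tm in probe:
            # center the worm's true centroid in the image after each move
            nearest = poses[min(int(round(tm * fps)), n_frames - 1)]
            centroid = nearest.true_markers().mean(axis=0)
            stage = centroid - center_px * um_per_px
            entries.append([tm, stage[0], stage[1]])
        # the t=0 entry must predate frame 1 strictly? position_at uses <=, fine
        stage_log = StageLog(np.asarray(entries))
        mv = np.asarray(probe[1:])
    else:
        stage_log = StageLog(np.array([[0.0, 0.0, 0.0]]))
        mv = np.empty(0)
    time_log = TimeLog(np.column_stack([np.arange(1, n_frames + 1), times]), mv)

    truth_frames: list[GroundTruthFrame] = []
    records: list[SplineRecord] = []
    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir) / name
        out_path.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    for i, (t, pose) in enumerate(zip(times, poses), start=1):
        stage = stage_log.position_at(t)
        markers_um = pose.true_markers()
        markers_px = (markers_um - stage) / um_per_px
        truth = GroundTruthFrame(
            markers_px=markers_px,
            markers_um=markers_um,
            length_um=length_um,
            bend_angles_deg=true_bend_angles(markers_um),
        )
        truth_frames.append(truth)
        records.append(SplineRecord(i, True, 120.0, markers_px))
        if out_path is not None:
            import imageio.v3 as iio

            image, _ = render_worm(
                pose,
                um_per_px=um_per_px,
                image_shape=image_shape,
                origin_um=stage,
                noise_sigma=noise_sigma,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            iio.imwrite(out_path / f"img{i:05d}.png", image)

    spline_file = SplineFile(records)
    if out_path is not None:
        write_stage_file(stage_log, out_path / f"{name}.txt")
        write_time_file(time_log, out_path / f"{name}_times.txt")
        write_meta_file(out_path / f"{name}_meta.txt", um_per_px, fps)

    cents = np.array([f.markers_um.mean(axis=0) for f in truth_frames])
    dist = float(np.sum(np.linalg.norm(np.diff(cents, axis=0), axis=1)))
    elapsed = float(times[-1] - times[0]) if n_frames > 1 else 1.0
    return CrawlSim(
        times=times,
        truth_frames=truth_frames,
        spline_file=spline_file,
        stage_log=stage_log,
        time_log=time_log,
        um_per_px=um_per_px,
        fps=fps,
        true_speed_um_per_s=dist / elapsed,
        direction="backward" if reverse else "forward",
        undulation_hz=undulation_hz,
        folder=out_path,
    )


# ---------------------------------------------------------------------------
# sleep actogram simulation


@dataclass
class SleepSim:
    timestamps: np.ndarray
    centroids: np.ndarray  # (N, 2) um
    true_bouts: list[tuple[float, float]]  # (start_s, end_s) on the frame grid
    spike_times: list[float]  # planted brief active events inside bouts


def simulate_sleep_trace(
    duration_s: float = 7200.0,
    frame_interval_s: float = 10.0,
    bouts: tuple[tuple[float, float], ...] = ((1800.0, 3600.0),),
    spike_times: tuple[float, ...] = (),
    quiet_step_um: float = 2.0,
    quiet_sd_um: float = 1.0,
    active_step_um: float = 40.0,
    active_sd_um: float = 10.0,
    seed: int = 0,
) -> SleepSim:
    """Centroid series with planted sleep bouts and optional brief active spikes.

    Active epochs draw displacement steps well above the 10 um motion boundary
    (mean 40 um), quiescent epochs well below (mean 2 um, clipped under 9 um);
    ``spike_times`` plant single active frames inside bouts.  Bout edges snap
    to the frame grid so detection can be checked to within one frame interval.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s / frame_interval_s)) + 1
    t = np.arange(n_frames) * frame_interval_s
    n_steps = n_frames - 1

    def snap(x: float) -> int:
        return int(round(x / frame_interval_s))

    quiet = np.zeros(n_steps, dtype=bool)
    true_bouts = []
    for start, end in bouts:
        i0, i1 = snap(start), snap(end)
        quiet[i0:i1] = True
        true_bouts.append((t[i0], t[i1]))
    spike_steps = []
    for ts in spike_times:
        j = snap(ts)
        if quiet[j]:
            quiet[j] = False
            spike_steps.append(float(t[j]))

    steps = np.where(
        quiet,
        np.clip(np.abs(rng.normal(quiet_step_um, quiet_sd_um, n_steps)), 0.0, 9.0),
        np.clip(rng.normal(active_step_um, active_sd_um, n_steps), 12.0, None),
    )
    theta = rng.uniform(0, 2 * np.pi, n_steps)
    deltas = steps[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
    centroids = np.vstack([[0.0, 0.0], np.cumsum(deltas, axis=0)])
    return SleepSim(
        timestamps=t, centroids=centroids, true_bouts=true_bouts, spike_times=spike_steps
    )


# ---------------------------------------------------------------------------
# action-potential train simulation


@dataclass
class TriangleAP:
    """Piecewise-linear AP template with closed-form metrics."""

    baseline_mv: float = -40.0
    peak_mv: float = 20.0
    rise_ms: float = 5.0
    fall_ms: float = 10.0
    ahp_mv: float | None = None  # continue below baseline to this level
    recover_ms: float = 20.0  # linear return from AHP to baseline

    @property
    def rise_slope(self) -> float:  # mV/ms
        return (self.peak_mv - self.baseline_mv) / self.rise_ms

    @property
    def fall_slope(self) -> float:
        return -(self.peak_mv - self.baseline_mv) / self.fall_ms

    @property
    def span_ms(self) -> float:
        extra = 0.0
        if self.ahp_mv is not None:
            extra = (self.baseline_mv - self.ahp_mv) / -self.fall_slope + self.recover_ms
        return self.rise_ms + self.fall_ms + extra

    def value(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        v = np.full_like(t, self.baseline_mv)
        rising = (t >= 0) & (t < self.rise_ms)
        v[rising] = self.baseline_mv + self.rise_slope * t[rising]
        fall_end = self.rise_ms + self.fall_ms
        if self.ahp_mv is not None:
            fall_end = self.rise_ms + (self.peak_mv - self.ahp_mv) / -self.fall_slope
        falling = (t >= self.rise_ms) & (t < fall_end)
        v[falling] = self.peak_mv + self.fall_slope * (t[falling] - self.rise_ms)
        if self.ahp_mv is not None:
            rec_end = fall_end + self.recover_ms
            rec = (t >= fall_end) & (t < rec_end)
            v[rec] = self.ahp_mv + (self.baseline_mv - self.ahp_mv) * (
                (t[rec] - fall_end) / self.recover_ms
            )
        return v

    def truth(self, lead_ms: float) -> dict:
        thr_v = self.peak_mv + self.rise_slope * (-lead_ms)  # on the rising limb
        amplitude = self.peak_mv - thr_v
        half = thr_v + amplitude / 2.0
        t_up = (half - self.baseline_mv) / self.rise_slope
        t_down = self.rise_ms + (half - self.peak_mv) / self.fall_slope
        decay_cross = self.rise_ms + (thr_v - self.peak_mv) / self.fall_slope
        return {
            "peak_time_ms": self.rise_ms,
            "peak_v": self.peak_mv,
            "threshold_time_ms": self.rise_ms - lead_ms,
            "threshold_v": thr_v,
            "amplitude": amplitude,
            "apd50_ms": t_down - t_up,
            "rise_time_ms": lead_ms,
            "decay_time_ms": decay_cross - self.rise_ms,
            "ahp_v": self.ahp_mv if self.ahp_mv is not None else self.baseline_mv,
            "max_slope": self.rise_slope,
            "min_slope": self.fall_slope,
        }


@dataclass
class SmoothAP:
    """Neuron-style template: exponential take-off, cosine cap and decay.

    The upstroke V(t) = b + c*(exp(t/tau) - 1) has dV/dt = (c/tau)*exp(t/tau),
    so the voltage at any dV/dt criterion is available in closed form:
    V* = b + crit*tau - c at t* = tau*ln(crit*tau/c).
    """

    baseline_mv: float = -60.0
    c_mv: float = 2.0
    tau_ms: float = 1.0
    max_slope_mv_per_ms: float = 60.0
    cap_mv: float = 12.0
    ahp_mv: float = -68.0
    decay_ms: float = 8.0
    recover_tau_ms: float = 15.0

    @property
    def t1_ms(self) -> float:  # end of the exponential upstroke
        return self.tau_ms * np.log(self.max_slope_mv_per_ms * self.tau_ms / self.c_mv)

    @property
    def t2_ms(self) -> float:  # quarter-cosine cap duration
        return self.cap_mv * np.pi / (2.0 * self.max_slope_mv_per_ms)

    @property
    def peak_time_ms(self) -> float:
        return self.t1_ms + self.t2_ms

    @property
    def peak_mv(self) -> float:
        v1 = self.baseline_mv + self.c_mv * (np.exp(self.t1_ms / self.tau_ms) - 1.0)
        return v1 + self.cap_mv

    @property
    def span_ms(self) -> float:
        return self.peak_time_ms + self.decay_ms + 6.0 * self.recover_tau_ms

    def value(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        b, tau = self.baseline_mv, self.tau_ms
        t1, t2, tp = self.t1_ms, self.t2_ms, self.peak_time_ms
        vp, d = self.peak_mv, self.decay_ms
        v = np.full_like(t, b)
        up = (t >= 0) & (t < t1)
        v[up] = b + self.c_mv * (np.exp(t[up] / tau) - 1.0)
        cap = (t >= t1) & (t < tp)
        v[cap] = vp - self.cap_mv * np.cos(np.pi * (t[cap] - t1) / (2.0 * t2))
        dec = (t >= tp) & (t < tp + d)
        v[dec] = self.ahp_mv + (vp - self.ahp_mv) * (1 + np.cos(np.pi * (t[dec] - tp) / d)) / 2
        rec = t >= tp + d
        v[rec] = b + (self.ahp_mv - b) * np.exp(-(t[rec] - tp - d) / self.recover_tau_ms)
        return v

    def truth(self, dvdt_criterion: float = 10.0) -> dict:
        b, c, tau = self.baseline_mv, self.c_mv, self.tau_ms
        t_star = tau * np.log(dvdt_criterion * tau / c)
        v_star = b + dvdt_criterion * tau - c
        vp, tp = self.peak_mv, self.peak_time_ms
        amplitude = vp - v_star
        half = v_star + amplitude / 2.0
        t_up = tau * np.log((half - b) / c + 1.0)
        theta = np.arccos(2.0 * (half - self.ahp_mv) / (vp - self.ahp_mv) - 1.0)
        t_down = tp + self.decay_ms * theta / np.pi
        theta_thr = np.arccos(2.0 * (v_star - self.ahp_mv) / (vp - self.ahp_mv) - 1.0)
        t_decay = tp + self.decay_ms * theta_thr / np.pi
        return {
            "peak_time_ms": tp,
            "peak_v": vp,
            "threshold_time_ms": t_star,
            "threshold_v": v_star,
            "amplitude": amplitude,
            "apd50_ms": t_down - t_up,
            "rise_time_ms": tp - t_star,
            "decay_time_ms": t_decay - tp,
            "ahp_v": self.ahp_mv,
            "max_slope": self.max_slope_mv_per_ms,
            "min_slope": -np.pi * (vp - self.ahp_mv) / (2.0 * self.decay_ms),
        }


def simulate_ap_train(
    n_aps: int = 7,
    interval_ms: float = 120.0,
    template: TriangleAP | SmoothAP | None = None,
    fs_hz: float = 10000.0,
    noise_sigma_mv: float = 0.0,
    pad_ms: float = 40.0,
    seed: int = 0,
    lead_ms: float | None = None,
    dvdt_criterion: float = 10.0,
):
    """10 kHz voltage trace with ``n_aps`` planted template APs and true metrics.

    Returns (VoltageTrace, list of per-event truth dicts with absolute times).
    The truth uses ``lead_ms`` for triangle templates (fixed-lead threshold) and
    ``dvdt_criterion`` for smooth ones (inflection threshold).
    """
    from .ap import VoltageTrace

    if template is None:
        template = TriangleAP()
    if interval_ms <= template.span_ms - 6.0 * getattr(template, "recover_tau_ms", 0.0):
        raise ValueError("interval shorter than the template duration")
    dt_ms = 1e3 / fs_hz
    total_ms = pad_ms + n_aps * interval_ms + pad_ms
    t = np.arange(0.0, total_ms, dt_ms)
    v = np.full_like(t, template.baseline_mv)
    onsets = pad_ms + np.arange(n_aps) * interval_ms
    for onset in onsets:
        v += template.value(t - onset) - template.baseline_mv
    if noise_sigma_mv > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sigma_mv, size=v.shape)

    if isinstance(template, TriangleAP):
        base = template.truth(lead_ms if lead_ms is not None else 2.0)
    else:
        base = template.truth(dvdt_criterion)
    events = []
    for onset in onsets:
        ev = dict(base)
        ev["peak_time_ms"] = base["peak_time_ms"] + onset
        ev["threshold_time_ms"] = base["threshold_time_ms"] + onset
        events.append(ev)
    return VoltageTrace(v=v, dt=1.0 / fs_hz, source="synthetic"), events


# ---------------------------------------------------------------------------
# convenience: write a parent folder of synthetic recordings


def write_crawl_batch(
    parent: Path | str,
    n_recordings: int = 3,
    prefix: str = "wt",
    seed: int = 0,
    **crawl_kwargs,
) -> list[CrawlSim]:
    """Write ``wt1..wtN`` style recording folders under one parent folder."""
    parent = Path(parent)
    sims = []
    for k in range(1, n_recordings + 1):
        sims.append(
            simulate_crawl(out_dir=parent, name=f"{prefix}{k}", seed=seed + k, **crawl_kwargs)
        )
    return sims
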