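"""Frame segmentation and 13-marker midline extraction.

Pipeline per frame: brightness thresholding -> debris removal (connected
components smaller than 3,000 px dropped) -> outline extraction and smoothing
-> head/tail identification by corner sharpness (tail = sharpest corner,
head = second sharpest, disambiguated by the previous frame's head position)
-> midline construction by pairing the two outline flanks and cubic
interpolation, with 13 markers placed at equal arc-length intervals
(marker 1 = head tip).  A failed fit triggers up to 10 automatic threshold
adjustments, alternating +/- one step around the user threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d
from shapely.geometry import LinearRing, LineString
from skimage import measure

from .errors import (
    AmbiguousHeadError,
    MidlineFitError,
    SegmentationError,
    UnusableMaskError,
)
from .formats import N_MARKERS, RecordingBundle, SplineFile, SplineRecord

# ---------------------------------------------------------------------------
# domain types


@dataclass
class Outline:
    """Closed, smoothed worm boundary polygon (vertices not repeated)."""

    vertices: np.ndarray  # (N, 2) x, y
    corner_scores: np.ndarray | None = None  # subtended angle per vertex, radians
    raw: np.ndarray | None = None  # unsmoothed resampled contour (tip refinement)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.vertices, self.vertices[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class Spline13:
    """13 ordered midline markers (marker 1 = head tip) plus dense arc length."""

    markers: np.ndarray  # (13, 2)
    length_px: float

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=float)
        if self.markers.shape != (N_MARKERS, 2):
            raise ValueError(f"expected ({N_MARKERS}, 2) markers, got {self.markers.shape}")

    @property
    def centroid(self) -> np.ndarray:
        return self.markers.mean(axis=0)

    @property
    def head(self) -> np.ndarray:
        return self.markers[0]

    @property
    def tail(self) -> np.ndarray:
        return self.markers[-1]


@dataclass
class HeadTail:
    head: np.ndarray
    tail: np.ndarray
    confirmed: bool  # False when no previous-frame reference was available


@dataclass
class FitResult:
    spline: Spline13 | None
    threshold_used: float
    attempts: int
    head_confirmed: bool = False
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.spline is not None


@dataclass
class SegmentationConfig:
    """Knobs of the per-frame fitting pipeline."""

    threshold: float = 120.0
    polarity: str = "worm-dark"  # or "worm-bright"
    min_area: int = 3000
    smooth_window: int = 5  # outline moving-average window, vertices
    corner_span: int = 15  # k: vertices on each side when scoring corner sharpness
    threshold_step: float = 5.0
    max_retries: int = 10
    head_seed: tuple[float, float] | None = None  # frame-1 head hint


# ---------------------------------------------------------------------------
# operations


def binarize(image: np.ndarray, threshold: float, polarity: str = "worm-dark") -> np.ndarray:
    """Threshold a grayscale frame into a boolean worm mask.

    ``worm-dark`` marks pixels strictly below the threshold as foreground
    (transmitted-light recordings show the worm dark on a bright background);
    ``worm-bright`` is the complement.
    """
    image = np.asarray(image)
    if polarity == "worm-dark":
        mask = image < threshold
    elif polarity == "worm-bright":
        mask = image >= threshold
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    if mask.all() or not mask.any():
        raise UnusableMaskError(
            f"threshold {threshold} yields an all-{'foreground' if mask.all() else 'background'} mask"
        )
    return mask


def remove_debris(mask: np.ndarray, min_area: int = 3000) -> np.ndarray:
    """Drop every 8-connected component smaller than ``min_area`` pixels."""
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise UnusableMaskError("empty mask: nothing to keep after debris removal")
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    keep = np.flatnonzero(areas >= min_area)
    if keep.size == 0:
        raise UnusableMaskError(
            f"no component reaches the {min_area}-pixel debris threshold"
        )
    return np.isin(labels, keep)


def _resample_closed(vertices: np.ndarray, n: int) -> np.ndarray:
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    u = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(u, s, closed[:, 0])
    y = np.interp(u, s, closed[:, 1])
    return np.column_stack([x, y])


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def extract_outline(mask: np.ndarray, smooth_window: int = 5) -> Outline:
    """Boundary of the largest foreground component, smoothed by a moving average.

    The returned polygon is oriented counterclockwise (positive shoelace area
    in x/y coordinates) and resampled to roughly 1-pixel vertex spacing; the
    unsmoothed contour is kept alongside for tip refinement.
    """
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise SegmentationError("cannot extract outline from an empty mask")
    if labels.max() > 1:
        import warnings

        warnings.warn("multiple components in mask; using the largest", stacklevel=2)
        areas = np.bincount(labels.ravel())
        areas[0] = 0
        mask = labels == int(np.argmax(areas))
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    # find_contours returns (row, col); convert to (x, y) and undo padding
    xy = np.column_stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0])
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    if len(xy) < 8:
        raise SegmentationError("component too small to trace an outline")
    perim = Outline(xy).perimeter
    n = int(max(100, round(perim)))
    resampled = _resample_closed(xy, n)
    smoothed = uniform_filter1d(resampled, size=max(1, smooth_window), axis=0, mode="wrap")
    if _signed_area(smoothed) < 0:
        smoothed = smoothed[::-1]
        resampled = resampled[::-1]
    if len(smoothed) < 40:
        raise SegmentationError(f"outline has only {len(smoothed)} vertices (< 40)")
    return Outline(
        np.ascontiguousarray(smoothed), raw=np.ascontiguousarray(resampled)
    )


def corner_angles(outline: Outline, span: int = 15) -> np.ndarray:
    """Angle (radians) subtended at each vertex by the vertices ``span`` away.

    Sharper corners subtend smaller angles.
    """
    p = outline.vertices
    a = np.roll(p, span, axis=0) - p
    b = np.roll(p, -span, axis=0) - p
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    cosang = np.einsum("ij,ij->i", a, b) / np.maximum(na * nb, 1e-12)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def detect_head_tail(
    outline: Outline,
    prev_head: np.ndarray | None = None,
    span: int = 15,
    min_separation_frac: float = 0.10,
    ambiguity_tol_deg: float = 2.0,
) -> HeadTail:
    """Locate head and tail tips as the two sharpest outline corners.

    The tail is the sharpest corner and the head the second sharpest; the two
    candidates must be at least ``min_separation_frac`` of the perimeter apart.
    When ``prev_head`` is given, the candidate nearer to it becomes the head
    (previous-frame spatial reference); otherwise the sharpness-based
    assignment is returned unconfirmed, and a sharpness tie raises
    :class:`AmbiguousHeadError` (e.g., a symmetric ellipse).
    """
    angles = corner_angles(outline, span=span)
    outline.corner_scores = angles
    n = len(outline)
    min_sep = max(int(round(min_separation_frac * n)), span)

    c1 = int(np.argmin(angles))
    dist = np.minimum((np.arange(n) - c1) % n, (c1 - np.arange(n)) % n)
    far = dist >= min_sep
    if not far.any():
        raise AmbiguousHeadError("outline too small to separate head and tail")
    masked = np.where(far, angles, np.inf)
    c2 = int(np.argmin(masked))
    if dist[c2] < min_sep:
        raise AmbiguousHeadError(
            "head/tail candidates closer than "
            f"{min_separation_frac:.0%} of the outline perimeter"
        )

    p1, p2 = outline.vertices[c1], outline.vertices[c2]
    if prev_head is not None:
        prev_head = np.asarray(prev_head, dtype=float)
        d1 = np.linalg.norm(p1 - prev_head)
        d2 = np.linalg.norm(p2 - prev_head)
        head, tail = (p1, p2) if d1 < d2 else (p2, p1)
        return HeadTail(head=head, tail=tail, confirmed=True)
    if abs(angles[c1] - angles[c2]) < np.deg2rad(ambiguity_tol_deg):
        raise AmbiguousHeadError(
            "head and tail corners equally sharp; a previous-frame head "
            "reference (or a frame-1 user seed) is required"
        )
    return HeadTail(head=p2, tail=p1, confirmed=False)


def _nearest_vertex(outline: Outline, point: np.ndarray) -> int:
    return int(np.argmin(np.linalg.norm(outline.vertices - point, axis=1)))


def _arc_resample_open(points: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise MidlineFitError("degenerate flank (zero length)")
    u = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(u, s, points[:, 0]), np.interp(u, s, points[:, 1])])


def _repair_normals(
    mid: np.ndarray, flank_a: np.ndarray, flank_b: np.ndarray, max_reach: float = 60.0
) -> np.ndarray:
    """One pass of normal-based re-pairing of the midline between its flanks.

    Arc-length pairing biases the midline toward the (longer) outer flank on
    bends; re-centering each interior point between the flank intersections of
    its local normal removes that bias.
    """
    out = mid.copy()
    for i in range(2, len(mid) - 2):
        t = mid[i + 2] - mid[i - 2]
        norm = np.linalg.norm(t)
        if norm == 0:
            continue
        t = t / norm
        n = np.array([-t[1], t[0]])
        p = mid[i]
        hits = []
        for flank in (flank_a, flank_b):
            q1, q2 = flank[:-1], flank[1:]
            d = q2 - q1
            det = n[0] * (-d[:, 1]) - (-d[:, 0]) * n[1]
            r0, r1 = q1[:, 0] - p[0], q1[:, 1] - p[1]
            with np.errstate(divide="ignore", invalid="ignore"):
                s = (r0 * (-d[:, 1]) - (-d[:, 0]) * r1) / det
                u = (n[0] * r1 - r0 * n[1]) / det
            ok = np.isfinite(s) & (u >= 0) & (u <= 1) & (np.abs(s) < max_reach)
            if ok.any():
                j = int(np.argmin(np.abs(s[ok])))
                hits.append(p + s[ok][j] * n)
        if len(hits) == 2:
            out[i] = 0.5 * (hits[0] + hits[1])
    return out


def _extend_tips(mid: np.ndarray, raw_contour: np.ndarray, reach_px: float = 15.0) -> None:
    """Push the midline endpoints out to the unsmoothed contour (in place).

    Outline smoothing cuts the sharp head/tail corners, which shortens the
    midline and drags every equal-arc marker toward the head; casting the end
    tangent out to the raw contour restores the lost tip length.
    """
    ring = LinearRing(np.vstack([raw_contour, raw_contour[:1]]))
    for end, ref in ((0, 3), (-1, -4)):
        t = mid[end] - mid[ref]
        norm = np.linalg.norm(t)
        if norm == 0:
            continue
        t = t / norm
        ray = LineString([mid[end] - t, mid[end] + reach_px * t])
        hit = ray.intersection(ring)
        if hit.is_empty:
            continue
        candidates = [
            np.asarray(g.coords[0])
            for g in getattr(hit, "geoms", [hit])
            if g.geom_type == "Point"
        ]
        if not candidates:
            continue
        gains = [float(np.dot(c - mid[end], t)) for c in candidates]
        best = int(np.argmax(gains))
        if gains[best] > 0:
            mid[end] = candidates[best]


def fit_midline(
    outline: Outline,
    head: np.ndarray,
    tail: np.ndarray,
    n_pairs: int = 150,
    n_dense: int = 400,
) -> Spline13:
    """Construct the 13-marker midline between the head and tail tips.

    The outline is split at the head and tail into two flanks; flank points are
    paired by normalized arc length and averaged, the paired midpoints are
    smoothed and interpolated with a cubic spline, and 13 markers are placed at
    equal arc-length intervals (marker 1 = head).  A self-intersecting midline
    (omega posture) raises :class:`MidlineFitError`.
    """
    i_head = _nearest_vertex(outline, np.asarray(head, dtype=float))
    i_tail = _nearest_vertex(outline, np.asarray(tail, dtype=float))
    if i_head == i_tail:
        raise MidlineFitError("head and tail map to the same outline vertex")
    v = outline.vertices
    n = len(v)
    if i_head < i_tail:
        flank_a = v[i_head : i_tail + 1]
        flank_b = np.vstack([v[i_tail:], v[: i_head + 1]])[::-1]
    else:
        flank_a = np.vstack([v[i_head:], v[: i_tail + 1]])
        flank_b = v[i_tail : i_head + 1][::-1]
    if len(flank_a) < 4 or len(flank_b) < 4:
        raise MidlineFitError("flanks too short to pair")

    a = _arc_resample_open(flank_a, n_pairs)
    b = _arc_resample_open(flank_b, n_pairs)
    mid = 0.5 * (a + b)
    mid = uniform_filter1d(mid, size=5, axis=0, mode="nearest")
    mid = _repair_normals(mid, flank_a, flank_b)
    mid = uniform_filter1d(mid, size=3, axis=0, mode="nearest")
    # pin the tips: flank pairing makes both flanks start/end at the tips
    mid[0] = 0.5 * (flank_a[0] + flank_b[0])
    mid[-1] = 0.5 * (flank_a[-1] + flank_b[-1])
    if outline.raw is not None:
        _extend_tips(mid, outline.raw)

    if not LineString(mid).is_simple:
        raise MidlineFitError("self-intersecting midline (omega posture)")

    seg = np.linalg.norm(np.diff(mid, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise MidlineFitError("zero-length midline")
    keep = np.concatenate([[True], seg > 1e-9])
    s_u, mid_u = s[keep], mid[keep]
    cs_x = CubicSpline(s_u, mid_u[:, 0])
    cs_y = CubicSpline(s_u, mid_u[:, 1])
    sd = np.linspace(0.0, s_u[-1], n_dense)
    dense = np.column_stack([cs_x(sd), cs_y(sd)])

    dseg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    ds = np.concatenate([[0.0], np.cumsum(dseg)])
    length = float(ds[-1])
    targets = np.linspace(0.0, length, N_MARKERS)
    markers = np.column_stack(
        [np.interp(targets, ds, dense[:, 0]), np.interp(targets, ds, dense[:, 1])]
    )
    return Spline13(markers=markers, length_px=length)


def _threshold_schedule(t0: float, step: float, max_retries: int) -> list[float]:
    # t0, t0+step, t0-step, t0+2*step, t0-2*step, ...
    out = [t0]
    k = 1
    while len(out) < 1 + max_retries:
        out.append(t0 + k * step)
        if len(out) < 1 + max_retries:
            out.append(t0 - k * step)
        k += 1
    return out


def fit_frame(
    image: np.ndarray,
    config: SegmentationConfig,
    prev: FitResult | None = None,
) -> FitResult:
    """Run the full per-frame pipeline with automatic threshold retry.

    Up to ``config.max_retries`` adjusted thresholds (alternating +/- one step
    around the user threshold) are tried after the initial attempt; the result
    records how many attempts were needed.
    """
    prev_head = None
    if prev is not None and prev.ok:
        prev_head = prev.spline.markers[0]
    elif config.head_seed is not None:
        prev_head = np.asarray(config.head_seed, dtype=float)

    last_error = "no attempts made"
    thresholds = _threshold_schedule(
        config.threshold, config.threshold_step, config.max_retries
    )
    for attempts, threshold in enumerate(thresholds, start=1):
        try:
            mask = binarize(image, threshold, config.polarity)
            mask = remove_debris(mask, config.min_area)
            outline = extract_outline(mask, config.smooth_window)
            ht = detect_head_tail(outline, prev_head=prev_head, span=config.corner_span)
            spline = fit_midline(outline, ht.head, ht.tail)
            return FitResult(
                spline=spline,
                threshold_used=threshold,
                attempts=attempts,
                head_confirmed=ht.confirmed,
            )
        except SegmentationError as exc:
            last_error = str(exc)
    return FitResult(
        spline=None,
        threshold_used=thresholds[-1],
        attempts=len(thresholds),
        error=last_error,
    )


def _load_gray(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return np.asarray(img, dtype=float)


def fit_recording(
    bundle: RecordingBundle,
    config: SegmentationConfig,
    log_path: Path | str | None = None,
) -> SplineFile:
    """Fit every frame of a recording, propagating the head between frames."""
    records: list[SplineRecord] = []
    prev: FitResult | None = None
    log_lines: list[str] = []
    for i, path in enumerate(bundle.image_paths, start=1):
        image = _load_gray(path)
        result = fit_frame(image, config, prev=prev)
        if result.ok:
            records.append(
                SplineRecord(i, True, result.threshold_used, result.spline.markers)
            )
            prev = result
        else:
            records.append(SplineRecord(i, False, result.threshold_used))
        log_lines.append(
            f"frame {i}\tattempts {result.attempts}\tthreshold {result.threshold_used}"
            f"\t{'ok' if result.ok else 'FAILED: ' + str(result.error)}"
        )
    if log_path is not None:
        Path(log_path).write_text("\n".join(log_lines) + "\n")
    return SplineFile(records)


def override_markers(
    spline_file: SplineFile, frame: int, markers: np.ndarray
) -> SplineFile:
    """Programmatic stand-in for interactive spline correction of one frame."""
    for idx, rec in enumerate(spline_file.records):
        if rec.frame == frame:
            spline_file.records[idx] = SplineRecord(frame, True, rec.threshold, markers)
            return spline_file
    raise KeyError(f"no record for frame {frame}")
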