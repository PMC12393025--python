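"""Recording-bundle I/O.

A recording is a folder of sequentially numbered grayscale frames
(``img00001.jpeg`` ...) plus two companion text logs named after the folder:
``<name>.txt`` (stage positions) and ``<name>_times.txt`` (frame and
stage-movement timestamps).  A fitted spline file ``<name>_spline.txt`` lives
in the *parent* folder.  Folders prefixed ``R_`` or ``L_`` record whether the
animal's ventral side faced right or left in the image.

The internal layout of these text files was never standardized by the original
acquisition tools, so this module defines self-describing tab-separated
dialects (one header line each) and guarantees bit-exact round trips.  Pixel coordinates are 0-based with the
origin at the top-left corner, x rightward and y downward; stage/world
coordinates are micrometers with the same axis directions.
"""

from __future__ import annotations

import re
import shutil
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

FRAME_PATTERN = re.compile(r"^img(\d{5})\.(jpeg|jpg|png)$", re.IGNORECASE)

#: markers per fitted frame; the universal pose discretization
N_MARKERS = 13


class Orientation(str, Enum):
    """Ventral-side orientation encoded in the ``R_``/``L_`` folder prefix."""

    VENTRAL_RIGHT = "ventral-right"
    VENTRAL_LEFT = "ventral-left"
    UNKNOWN = "unknown"

    def flipped(self) -> "Orientation":
        if self is Orientation.VENTRAL_RIGHT:
            return Orientation.VENTRAL_LEFT
        if self is Orientation.VENTRAL_LEFT:
            return Orientation.VENTRAL_RIGHT
        return Orientation.UNKNOWN


def _fmt(v: float) -> str:
    # repr of a Python float is the shortest string that round-trips exactly
    return repr(float(v))


@dataclass
class StageLog:
    """Absolute motorized-stage positions over time.

    ``entries`` is an (N, 3) float array of (timestamp_s, x_um, y_um) rows with
    strictly increasing timestamps.
    """

    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float).reshape(-1, 3)
        t = self.entries[:, 0]
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise FormatError("stage log timestamps must be strictly increasing")

    def position_at(self, t: float) -> np.ndarray:
        """Stage (x, y) at the latest entry with timestamp <= t.

        Frame times before the first entry use the first entry (nearest).
        """
        if len(self.entries) == 0:
            return np.zeros(2)
        idx = int(np.searchsorted(self.entries[:, 0], t, side="right")) - 1
        idx = max(idx, 0)
        return self.entries[idx, 1:3].copy()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, StageLog) and np.array_equal(self.entries, other.entries)


@dataclass
class TimeLog:
    """Frame timestamps plus the timestamps of stage movements."""

    frame_times: np.ndarray  # (F, 2): frame index (1-based), timestamp s
    move_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float).reshape(-1, 2)
        self.move_times = np.asarray(self.move_times, dtype=float).ravel()
        ts = self.frame_times[:, 1]
        if len(ts) > 1 and np.any(np.diff(ts) < 0):
            raise FormatError("frame timestamps must be nondecreasing")

    @property
    def timestamps(self) -> np.ndarray:
        return self.frame_times[:, 1]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TimeLog)
            and np.array_equal(self.frame_times, other.frame_times)
            and np.array_equal(self.move_times, other.move_times)
        )


@dataclass
class SplineRecord:
    """One frame's fit: 13 (x, y) pixel markers, or a recorded failure."""

    frame: int
    ok: bool
    threshold: float
    markers: np.ndarray | None = None  # (13, 2) pixel coords when ok

    def __post_init__(self) -> None:
        if self.ok:
            m = np.asarray(self.markers, dtype=float)
            if m.shape != (N_MARKERS, 2):
                raise FormatError(
                    f"frame {self.frame}: fitted record needs {N_MARKERS} marker pairs, "
                    f"got shape {m.shape}"
                )
            self.markers = m
        else:
            self.markers = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SplineRecord):
            return NotImplemented
        same_meta = (
            self.frame == other.frame
            and self.ok == other.ok
            and self.threshold == other.threshold
        )
        if not same_meta:
            return False
        if self.markers is None or other.markers is None:
            return self.markers is None and other.markers is None
        return np.array_equal(self.markers, other.markers)


@dataclass
class SplineFile:
    """Per-frame 13-marker midline records for one recording."""

    records: list[SplineRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SplineFile) and self.records == other.records

    def fitted_records(self) -> list[SplineRecord]:
        return [r for r in self.records if r.ok]


@dataclass
class RecordingBundle:
    """A resolved recording folder with all companion files located."""

    name: str
    folder: Path
    image_paths: list[Path]
    stage_log: StageLog
    time_log: TimeLog
    orientation: Orientation
    um_per_px: float
    fps: int
    spline_path: Path | None = None
    stage_free: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.image_paths)


# ---------------------------------------------------------------------------
# stage / time / spline dialects

_STAGE_HEADER = "time_s\tx_um\ty_um"
_TIME_HEADER = "frame\ttime_s"
_MOVES_MARKER = "# moves"


def write_stage_file(log: StageLog, path: Path | str) -> None:
    lines = [_STAGE_HEADER]
    for t, x, y in log.entries:
        lines.append(f"{_fmt(t)}\t{_fmt(x)}\t{_fmt(y)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_stage_file(path: Path | str) -> StageLog:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _STAGE_HEADER:
        raise FormatError(f"{path}: not a stage file (bad header)")
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}: malformed stage row at line {i}")
        rows.append([float(p) for p in parts])
    return StageLog(np.asarray(rows, dtype=float).reshape(-1, 3))


def write_time_file(log: TimeLog, path: Path | str) -> None:
    lines = [_TIME_HEADER]
    for frame, t in log.frame_times:
        lines.append(f"{int(frame)}\t{_fmt(t)}")
    lines.append(_MOVES_MARKER)
    for t in log.move_times:
        lines.append(_fmt(t))
    Path(path).write_text("\n".join(lines) + "\n")


def read_time_file(path: Path | str) -> TimeLog:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _TIME_HEADER:
        raise FormatError(f"{path}: not a time file (bad header)")
    frames: list[list[float]] = []
    moves: list[float] = []
    in_moves = False
    for i, line in enumerate(lines[1:], start=2):
        if line == _MOVES_MARKER:
            in_moves = True
            continue
        if not line.strip():
            continue
        if in_moves:
            moves.append(float(line))
        else:
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: malformed time row at line {i}")
            frames.append([float(parts[0]), float(parts[1])])
    return TimeLog(
        np.asarray(frames, dtype=float).reshape(-1, 2), np.asarray(moves, dtype=float)
    )


_SPLINE_HEADER = (
    "frame\tstatus\tthreshold\t"
    + "\t".join(f"x{i}\ty{i}" for i in range(1, N_MARKERS + 1))
)


def write_spline_file(spline: SplineFile, path: Path | str) -> None:
    lines = [_SPLINE_HEADER]
    for rec in spline.records:
        cells = [str(rec.frame), "ok" if rec.ok else "failed", _fmt(rec.threshold)]
        if rec.ok:
            assert rec.markers is not None
            for x, y in rec.markers:
                cells.extend([_fmt(x), _fmt(y)])
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_spline_file(path: Path | str) -> SplineFile:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _SPLINE_HEADER:
        raise FormatError(f"{path}: not a spline file (bad header)")
    records = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: malformed spline row at line {i}")
        frame, status, threshold = int(parts[0]), parts[1], float(parts[2])
        if status == "ok":
            coords = parts[3:]
            if len(coords) != 2 * N_MARKERS:
                raise FormatError(
                    f"{path}: frame {frame} (line {i}) has {len(coords) // 2} "
                    f"coordinate pairs, expected {N_MARKERS}"
                )
            markers = np.array([float(c) for c in coords]).reshape(N_MARKERS, 2)
            records.append(SplineRecord(frame, True, threshold, markers))
        elif status == "failed":
            records.append(SplineRecord(frame, False, threshold))
        else:
            raise FormatError(f"{path}: unknown status {status!r} at line {i}")
    return SplineFile(records)


# ---------------------------------------------------------------------------
# metadata sidecar (calibration + nominal frame rate)


def write_meta_file(path: Path | str, um_per_px: float, fps: int) -> None:
    Path(path).write_text(f"um_per_px\t{_fmt(um_per_px)}\nfps\t{int(fps)}\n")


def read_meta_file(path: Path | str) -> dict[str, float]:
    meta: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, value = line.split("\t")
        meta[key] = float(value)
    return meta


# ---------------------------------------------------------------------------
# recording resolution


def _decode_orientation(name: str) -> Orientation:
    if name.startswith("R_"):
        return Orientation.VENTRAL_RIGHT
    if name.startswith("L_"):
        return Orientation.VENTRAL_LEFT
    return Orientation.UNKNOWN


def list_frames(folder: Path) -> list[Path]:
    """Frame images ``img%05d.{jpeg,jpg,png}``, sorted and checked contiguous from 1."""
    frames: dict[int, Path] = {}
    for p in folder.iterdir():
        m = FRAME_PATTERN.match(p.name)
        if m:
            frames[int(m.group(1))] = p
    if not frames:
        raise FormatError(f"{folder}: no frame images (img00001.jpeg ...) found")
    indices = sorted(frames)
    if indices != list(range(1, len(indices) + 1)):
        raise FormatError(f"{folder}: frame indices not contiguous from 1")
    return [frames[i] for i in indices]


def resolve_recording(
    recording_folder: Path | str,
    um_per_px: float | None = None,
    fps: int | None = None,
) -> RecordingBundle:
    """Locate every companion file of a recording folder by naming convention.

    Missing stage/time files yield a *stage-free* bundle (all stage offsets
    zero, frame times derived from the nominal frame rate) with a warning.
    A spline file ``<name>_spline.txt`` in the parent folder, if present, is
    attached.
    """
    folder = Path(recording_folder)
    if not folder.is_dir():
        raise FormatError(f"{folder}: recording folder does not exist")
    name = folder.name
    image_paths = list_frames(folder)

    meta_path = folder / f"{name}_meta.txt"
    meta = read_meta_file(meta_path) if meta_path.exists() else {}
    if um_per_px is None:
        um_per_px = float(meta.get("um_per_px", 5.0))
    if um_per_px <= 0:
        raise FormatError("um_per_px must be positive")

    stage_path = folder / f"{name}.txt"
    time_path = folder / f"{name}_times.txt"
    stage_free = False
    if stage_path.exists() and time_path.exists():
        stage_log = read_stage_file(stage_path)
        time_log = read_time_file(time_path)
    else:
        stage_free = True
        warnings.warn(
            f"{folder}: stage/time files missing; treating recording as stage-free",
            stacklevel=2,
        )
        stage_log = StageLog(np.empty((0, 3)))
        nominal = int(fps or meta.get("fps", 3))
        ts = np.arange(len(image_paths)) / nominal
        time_log = TimeLog(np.column_stack([np.arange(1, len(image_paths) + 1), ts]))

    if fps is None:
        if "fps" in meta:
            fps = int(meta["fps"])
        elif len(time_log.frame_times) > 1:
            dt = float(np.median(np.diff(time_log.timestamps)))
            fps = int(round(1.0 / dt)) if dt > 0 else 3
        else:
            fps = 3

    spline_path = folder.parent / f"{name}_spline.txt"
    return RecordingBundle(
        name=name,
        folder=folder,
        image_paths=image_paths,
        stage_log=stage_log,
        time_log=time_log,
        orientation=_decode_orientation(name),
        um_per_px=float(um_per_px),
        fps=int(fps),
        spline_path=spline_path if spline_path.exists() else None,
        stage_free=stage_free,
    )


# ---------------------------------------------------------------------------
# spreadsheet export


def export_results(tables: dict[str, pd.DataFrame], path: Path | str) -> None:
    """Write one workbook sheet per metric family.

    Column headers are expected to carry units (e.g., ``avg_speed_um_per_s``).
    """
    if not tables:
        raise ValueError("no result tables to export")
    for name, df in tables.items():
        if df.empty:
            raise ValueError(f"result table {name!r} is empty")
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for name, df in tables.items():
            df.to_excel(writer, sheet_name=name[:31], index=False)


# ---------------------------------------------------------------------------
# frame-rate reduction bookkeeping (pure file operations)


def reduce_framerate(recording_folder: Path | str, keep_every: int) -> None:
    """Move all but every ``keep_every``-th frame into ``Removed/``.

    The time file is rewritten to cover only the kept frames; the original is
    renamed ``<name>_times_before_RF.txt`` so :func:`restore_framerate` can
    revert everything.
    """
    folder = Path(recording_folder)
    if keep_every < 2:
        raise ValueError("keep_every must be >= 2")
    frames = list_frames(folder)
    name = folder.name
    time_path = folder / f"{name}_times.txt"
    backup = folder / f"{name}_times_before_RF.txt"
    if backup.exists():
        raise FormatError(f"{folder}: frame rate already reduced (restore first)")
    time_log = read_time_file(time_path) if time_path.exists() else None

    removed_dir = folder / "Removed"
    removed_dir.mkdir(exist_ok=True)
    kept_indices = set(range(1, len(frames) + 1, keep_every))
    for i, p in enumerate(frames, start=1):
        if i not in kept_indices:
            shutil.move(str(p), removed_dir / p.name)
    if time_log is not None:
        shutil.move(str(time_path), backup)
        keep_mask = np.isin(time_log.frame_times[:, 0].astype(int), sorted(kept_indices))
        write_time_file(
            TimeLog(time_log.frame_times[keep_mask], time_log.move_times), time_path
        )


def restore_framerate(recording_folder: Path | str) -> None:
    """Undo :func:`reduce_framerate`: move frames back and restore the time file."""
    folder = Path(recording_folder)
    removed_dir = folder / "Removed"
    if removed_dir.is_dir():
        for p in sorted(removed_dir.iterdir()):
            shutil.move(str(p), folder / p.name)
        removed_dir.rmdir()
    name = folder.name
    backup = folder / f"{name}_times_before_RF.txt"
    if backup.exists():
        shutil.move(str(backup), folder / f"{name}_times.txt")
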