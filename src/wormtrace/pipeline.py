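"""End-to-end analysis of resolved recordings, single or batch."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bending, curvature, locomotion
from .config import AnalysisConfig
from .errors import AnalysisError, WormtraceError
from .formats import (
    RecordingBundle,
    SplineFile,
    export_results,
    read_spline_file,
    resolve_recording,
    write_spline_file,
)
from .segmentation import SegmentationConfig, fit_recording

log = logging.getLogger("wormtrace")


def segmentation_config(cfg: AnalysisConfig) -> SegmentationConfig:
    return SegmentationConfig(
        threshold=cfg.threshold,
        polarity=cfg.polarity,
        min_area=cfg.min_area,
        smooth_window=cfg.smooth_window,
        corner_span=cfg.corner_span,
        threshold_step=cfg.threshold_step,
        max_retries=cfg.max_retries,
    )


def fit_bundle(bundle: RecordingBundle, cfg: AnalysisConfig) -> SplineFile:
    """Fit (or load) the spline file of one recording.

    An existing ``<name>_spline.txt`` in the parent folder is reused; otherwise
    every frame is fitted and the file written there, mirroring the spline-file
    placement convention.
    """
    if bundle.spline_path is not None:
        return read_spline_file(bundle.spline_path)
    spline = fit_recording(bundle, segmentation_config(cfg))
    out = bundle.folder.parent / f"{bundle.name}_spline.txt"
    write_spline_file(spline, out)
    bundle.spline_path = out
    return spline


def analyze_recording(
    bundle: RecordingBundle,
    spline_file: SplineFile | None = None,
    cfg: AnalysisConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Movement, bending, and curvature tables for one recording."""
    cfg = cfg or AnalysisConfig(um_per_px=bundle.um_per_px, fps=bundle.fps)
    if spline_file is None:
        spline_file = fit_bundle(bundle, cfg)

    track = locomotion.to_world(
        spline_file,
        bundle.stage_log,
        bundle.time_log,
        bundle.um_per_px,
        bundle.fps,
        bundle.orientation,
    )
    eff = locomotion.effective_frames(track)
    marker = cfg.movement_marker if cfg.movement_marker == "centroid" else int(cfg.movement_marker)
    movement = locomotion.movement_metrics(eff, marker=marker)

    # bending uses the full-rate trace; frame decimation applies to movement only
    trace = bending.bend_trace(spline_file, track.times, bundle.orientation)
    m = cfg.bending_marker
    bend_row: dict[str, float] = {"recording": bundle.name, "marker": m}
    bend_row["rms_bend_deg"] = bending.rms_bend(trace, m)
    bend_row["sum_of_all_bends_deg"] = bending.sum_of_all_bends(trace)
    try:
        spec = bending.dominant_frequency(trace, m)
        bend_row["dominant_frequency_hz"] = spec.dominant_hz
        bend_row["frequency_resolution_hz"] = spec.resolution_hz
    except AnalysisError:
        bend_row["dominant_frequency_hz"] = np.nan
        bend_row["frequency_resolution_hz"] = np.nan
    try:
        bend_row["maximum_bend_deg"] = bending.maximum_bend(
            trace, m, cfg.max_bend_min_angle_deg
        )
    except AnalysisError:
        bend_row["maximum_bend_deg"] = np.nan

    curve_rows = []
    for rec in spline_file.fitted_records():
        for seg in curvature.curvatures(
            rec.markers, bundle.orientation, min_frac=cfg.curvature_min_frac
        ):
            curve_rows.append(
                {
                    "recording": bundle.name,
                    "frame": rec.frame,
                    "rank": seg.rank,
                    "side": seg.side,
                    "start_frac": seg.start_frac,
                    "end_frac": seg.end_frac,
                    "curvature_L_over_r": seg.curvature,
                    "radius_um": seg.r * bundle.um_per_px,
                }
            )

    movement_row = {"recording": bundle.name, **movement.to_row()}
    return {
        "movement": pd.DataFrame([movement_row]),
        "bending": pd.DataFrame([bend_row]),
        "curvature": pd.DataFrame(curve_rows),
    }


def run_batch(
    parent_folder: Path | str,
    cfg: AnalysisConfig,
    out_workbook: Path | str | None = None,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Analyze every resolvable recording subfolder of a parent folder.

    Failures are isolated per recording and reported in the returned list; the
    combined per-recording tables are optionally written as one workbook in the
    parent folder.
    """
    parent = Path(parent_folder)
    failures: list[str] = []
    combined: dict[str, list[pd.DataFrame]] = {}
    n_resolved = 0
    for sub in sorted(p for p in parent.iterdir() if p.is_dir()):
        try:
            bundle = resolve_recording(sub, um_per_px=cfg.um_per_px)
        except WormtraceError as exc:
            log.warning("skipping %s: %s", sub.name, exc)
            continue
        n_resolved += 1
        try:
            tables = analyze_recording(bundle, cfg=cfg)
        except WormtraceError as exc:
            failures.append(f"{sub.name}: {exc}")
            log.error("analysis failed for %s: %s", sub.name, exc)
            continue
        for key, df in tables.items():
            combined.setdefault(key, []).append(df)
    if n_resolved == 0:
        raise AnalysisError(f"{parent}: no resolvable recording subfolders")
    result = {k: pd.concat(v, ignore_index=True) for k, v in combined.items() if v}
    if out_workbook is not None and result:
        export_results(result, out_workbook)
    return result, failures
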