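"""End-to-end orchestration: preprocessing → detection → tracking → metrics.

`run_process` executes the full analysis on one calibrated time-lapse and
(optionally) writes every intermediate artifact — aligned stack, mask series,
drift trace, threshold log, per-frame instance table, track table, event log
and metrics — together with a machine-readable run log carrying the effective
configuration, its hash, package versions and per-stage timings.

`run_stats` turns per-cell metric tables from several groups into the
statistics table (omnibus test, Bonferroni-corrected pairwise comparisons and
BCa bootstrap effect sizes per metric).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from protrudyn import __version__
from protrudyn.errors import ProtrudynError, StructuralError
from protrudyn.imgpipe import (
    BinaryMaskSeries,
    DriftTrace,
    TimelapseStack,
    binarize_and_outline,
    correct_drift,
    gaussian_lowpass,
    max_z_project,
    triangle_threshold,
)
from protrudyn.protdetect import (
    LENGTH_MAX_UM,
    LENGTH_MIN_UM,
    ShaftModel,
    estimate_shaft,
    extract_protrusions,
    filter_by_length,
)
from protrudyn.protrack import (
    EventLog,
    ProtrusionTrack,
    aggregate_events,
    classify_track,
    link_tracks,
)
from protrudyn.dynmetrics import DynamicsMetrics, compute_metrics
from protrudyn.estimstats import compare_all

logger = logging.getLogger("protrudyn")

__all__ = ["RunConfig", "ProcessResult", "run_process", "run_stats", "read_stack"]


@dataclass(frozen=True)
class RunConfig:
    """Effective parameters of one processing run (all stages)."""

    pixel_size_um: float = 0.06
    frame_interval_s: float = 5.0
    # preprocessing
    register: bool = True
    registration_reference: int = 0
    gaussian_kernel_px: float = 2.0
    threshold_per_frame: bool = True
    # detection
    max_protrusion_width_um: float = 1.6
    length_min_um: float = LENGTH_MIN_UM
    length_max_um: float = LENGTH_MAX_UM
    # tracking
    linkage_radius_um: float = 1.0
    max_gap_frames: int = 1
    motility_threshold_um: float = 0.25
    min_track_frames: int = 2  # single-frame blips are detection noise
    # statistics
    n_boot: int = 5000
    alpha: float = 0.05
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ProcessResult:
    """All artifacts of one processed time-lapse."""

    aligned: np.ndarray
    drift: DriftTrace | None
    masks: BinaryMaskSeries
    overlay: np.ndarray
    shaft: ShaftModel
    instances_per_frame: list
    tracks: list[ProtrusionTrack]
    event_log: EventLog
    metrics: DynamicsMetrics
    config: RunConfig
    timings_s: dict[str, float] = field(default_factory=dict)
    flagged_frames: list[int] = field(default_factory=list)

    def instance_table(self) -> pd.DataFrame:
        rows = []
        for insts in self.instances_per_frame:
            for p in insts:
                rows.append(
                    {
                        "frame": p.frame,
                        "instance_id": p.instance_id,
                        "base_y": p.base[0],
                        "base_x": p.base[1],
                        "tip_y": p.tip[0],
                        "tip_x": p.tip[1],
                        "length_um": p.length_um,
                        "base_position_um": p.base_position_um,
                        "border_flag": p.touches_border,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "frame", "instance_id", "base_y", "base_x", "tip_y", "tip_x",
                "length_um", "base_position_um", "border_flag",
            ],
        )

    def track_table(self) -> pd.DataFrame:
        rows = [
            {
                "track_id": t.track_id,
                "first_frame": t.first_frame,
                "last_frame": t.last_frame,
                "category": t.category,
                "motile": bool(t.motile),
                "n_extensions": t.n_extensions,
                "n_retractions": t.n_retractions,
                "mean_length_um": t.mean_length_um(),
            }
            for t in self.tracks
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "track_id", "first_frame", "last_frame", "category", "motile",
                "n_extensions", "n_retractions", "mean_length_um",
            ],
        )


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> TimelapseStack:
    """Read a multi-page TIFF time-lapse, with calibration from metadata.

    Calibration stored by this package (ImageJ-style metadata) is read back
    automatically; explicit arguments override it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.imagej_metadata or {}
    if pixel_size_um is None:
        pixel_size_um = float(meta.get("pixel_size_um", 0) or 0) or None
    if frame_interval_s is None:
        frame_interval_s = float(meta.get("finterval", 0) or 0) or None
    if pixel_size_um is None or frame_interval_s is None:
        raise ProtrudynError(
            f"{path}: calibration missing from TIFF metadata; pass "
            "pixel_size_um and frame_interval_s explicitly"
        )
    return TimelapseStack(
        data=data, pixel_size=pixel_size_um, frame_interval=frame_interval_s
    )


def write_stack(stack_data: np.ndarray, path: str | Path, pixel_size_um: float,
                frame_interval_s: float) -> None:
    """Write a (t, y, x) array as a calibrated multi-page TIFF."""
    tifffile.imwrite(
        Path(path),
        np.asarray(stack_data, dtype=np.float32),
        imagej=True,
        resolution=(1.0 / pixel_size_um, 1.0 / pixel_size_um),
        metadata={
            "unit": "um",
            "finterval": frame_interval_s,
            "pixel_size_um": pixel_size_um,
        },
    )


def run_process(
    stack: TimelapseStack,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> ProcessResult:
    """Run the full analysis chain on one calibrated time-lapse.

    Stages: maximum z-projection (if a z axis is present), rigid drift
    correction, Gaussian low-pass, per-frame triangle thresholding, shaft
    estimation, protrusion extraction with the length gate, track linking,
    event classification and metric computation. When ``out_dir`` is given,
    every intermediate artifact is written there along with a run log.

    Frames whose mask is empty after thresholding are flagged (a heuristic
    for focal-plane loss — a frame-mean intensity drop of more than 50 %
    relative to the first frame — only flags, it never excludes).
    """
    if config is None:
        config = RunConfig(
            pixel_size_um=stack.pixel_size, frame_interval_s=stack.frame_interval
        )
    timings: dict[str, float] = {}

    def _tic() -> float:
        return time.perf_counter()

    t0 = _tic()
    if stack.has_z:
        stack = max_z_project(stack)
    frames = np.asarray(stack.data, dtype=float)
    timings["projection"] = _tic() - t0

    t0 = _tic()
    drift = None
    if config.register and frames.shape[0] >= 2:
        frames, drift = correct_drift(frames, config.registration_reference)
    timings["registration"] = _tic() - t0

    t0 = _tic()
    blurred = np.stack(
        [gaussian_lowpass(f, config.gaussian_kernel_px) for f in frames]
    )
    if config.threshold_per_frame:
        levels = np.array([triangle_threshold(f) for f in blurred])
    else:
        levels = np.full(frames.shape[0], triangle_threshold(blurred))
    masks, overlay = binarize_and_outline(
        blurred, levels, per_frame=config.threshold_per_frame
    )
    timings["threshold"] = _tic() - t0

    # focal-loss heuristic: flag (never exclude) big frame-mean drops
    means = frames.mean(axis=(1, 2))
    flagged = sorted(
        set(np.flatnonzero(means < 0.5 * means[0]).tolist()) | set(masks.empty_frames)
    )
    if flagged:
        logger.warning("flagged frames (possible focal loss): %s", flagged)

    t0 = _tic()
    shaft0 = estimate_shaft(
        masks.masks[0], config.max_protrusion_width_um, stack.pixel_size
    )
    instances_per_frame = []
    for t in range(frames.shape[0]):
        if t in masks.empty_frames:
            instances_per_frame.append([])
            continue
        shaft_t = (
            shaft0
            if t == 0
            else estimate_shaft(
                masks.masks[t], config.max_protrusion_width_um, stack.pixel_size
            )
        )
        # base positions are always measured along the frame-0 centerline so
        # tracks share one coordinate system
        shaft_t = ShaftModel(
            mask=shaft_t.mask,
            centerline=shaft0.centerline,
            length_um=shaft0.length_um,
            pixel_size=stack.pixel_size,
            half_width_px=shaft_t.half_width_px,
        )
        insts = extract_protrusions(masks.masks[t], shaft_t, stack.pixel_size, frame=t)
        instances_per_frame.append(
            filter_by_length(insts, config.length_min_um, config.length_max_um)
        )
    timings["detection"] = _tic() - t0

    t0 = _tic()
    tracks = link_tracks(
        instances_per_frame, config.linkage_radius_um, config.max_gap_frames
    )
    # a protrusion seen in a single frame (5 s) is a detection blip, far
    # below any plausible labile lifetime; drop before classification
    tracks = [
        t
        for t in tracks
        if (t.last_frame - t.first_frame + 1) >= config.min_track_frames
    ]
    for track in tracks:
        classify_track(track, frames.shape[0], config.motility_threshold_um)
    event_log = aggregate_events(tracks, frames.shape[0], stack.frame_interval)
    metrics = compute_metrics(event_log, shaft0.length_um)
    timings["tracking"] = _tic() - t0

    result = ProcessResult(
        aligned=frames,
        drift=drift,
        masks=masks,
        overlay=overlay,
        shaft=shaft0,
        instances_per_frame=instances_per_frame,
        tracks=tracks,
        event_log=event_log,
        metrics=metrics,
        config=config,
        timings_s=timings,
        flagged_frames=flagged,
    )
    if out_dir is not None:
        _write_artifacts(result, stack, Path(out_dir))
    return result


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.6g")


def _write_artifacts(result: ProcessResult, stack: TimelapseStack, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    h = result.config.hash()
    write_stack(result.aligned, out / "aligned.tif", stack.pixel_size, stack.frame_interval)
    write_stack(
        result.masks.masks.astype(np.uint8) * 255,
        out / "masks.tif",
        stack.pixel_size,
        stack.frame_interval,
    )
    if result.drift is not None:
        drift_df = pd.DataFrame(
            {
                "frame": np.arange(result.drift.offsets.shape[0]),
                "dy_px": result.drift.offsets[:, 0],
                "dx_px": result.drift.offsets[:, 1],
            }
        )
        _write_csv(drift_df, out / "drift.csv", h)
    _write_csv(
        pd.DataFrame(
            {
                "frame": np.arange(result.masks.levels.size),
                "level": result.masks.levels,
                "per_frame": result.masks.per_frame,
            }
        ),
        out / "thresholds.csv",
        h,
    )
    _write_csv(result.instance_table(), out / "instances.csv", h)
    _write_csv(result.track_table(), out / "tracks.csv", h)
    log = result.event_log
    (out / "event_log.json").write_text(
        json.dumps(
            {
                "config_hash": h,
                "N0": log.n0,
                "N_end": log.n_end,
                "F": log.formed,
                "E": log.eliminated,
                "L": log.labile,
                "M": log.motile,
                "recording_duration_min": log.recording_duration_min,
            },
            indent=2,
        )
    )
    _write_csv(
        pd.DataFrame([result.metrics.as_dict()]), out / "metrics.csv", h
    )
    (out / "run_log.json").write_text(
        json.dumps(
            {
                "package": "protrudyn",
                "version": __version__,
                "config": dataclasses.asdict(result.config),
                "config_hash": h,
                "segment_length_um": result.shaft.length_um,
                "flagged_frames": result.flagged_frames,
                "timings_s": result.timings_s,
            },
            indent=2,
        )
    )


def run_stats(
    per_cell: pd.DataFrame,
    metrics: list[str],
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Statistics table over the 2×2 design for each requested metric.

    ``per_cell`` needs ``genotype`` and ``plasmid`` columns plus one column
    per metric. The output mirrors the usual statistical-table layout:
    comparison, effect size with 95 % CI, adjusted p, and the omnibus
    statistic of the route chosen by the normality gate.
    """
    for col in ("genotype", "plasmid"):
        if col not in per_cell.columns:
            raise StructuralError(f"missing design column {col!r}")
    rows = []
    for metric in metrics:
        tests, estimates = compare_all(
            per_cell, metric, n_boot=n_boot, seed=seed, alpha=alpha
        )
        omnibus = [t for t in tests if t.comparison in ("omnibus", "genotype", "plasmid", "interaction")]
        pairwise = {t.comparison: t for t in tests if " vs " in t.comparison}
        omni_desc = "; ".join(
            f"{t.test} {t.comparison}: stat={t.statistic:.4g}, df={t.df}, p={t.p_raw:.4g}"
            for t in omnibus
        )
        for est in estimates:
            t = pairwise[est.comparison]
            rows.append(
                {
                    "metric": metric,
                    "comparison": est.comparison,
                    "effect_size": est.effect_size,
                    "ci95_low": est.ci_low,
                    "ci95_high": est.ci_high,
                    "n_boot": est.n_boot,
                    "test": t.test,
                    "p_adjusted": t.p_adjusted,
                    "omnibus": omni_desc,
                }
            )
    return pd.DataFrame(rows)
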