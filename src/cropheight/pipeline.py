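"""Frame- and series-level orchestration of the measurement stages.

A frame runs through: colour feature -> marker kernel -> clip level ->
longest vertical run -> pixel-to-cm conversion. A season of frames adds
sensor-driven condition flagging, optional hybrid gap correction and
evaluation against reference heights. Every stage logs the detected run
(column, top, bottom, length) so a mis-detection on a bad frame can be
diagnosed from the log alone.
"""

from __future__ import annotations

import datetime as _dt
import logging
import os
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .color_features import excess_green, read_rgb, split_bands, validate_rgb
from .config import PipelineConfig
from .exceptions import DetectionError
from .filtering import convolve, modified_kernel
from .marker_geometry import MarkerReference, RunSegment, compute_height, longest_vertical_runs
from .segmentation import ThresholdModel, apply_threshold, select_threshold
from .series_analysis import (
    DailyRecord,
    HeightSeries,
    classify_light,
    flag_unreliable,
    interpolate_flagged,
    relative_error,
    summarize_errors,
)

__all__ = [
    "feature_plane",
    "response_plane",
    "estimate_frame",
    "calibrate_from_frame",
    "run_series",
]

logger = logging.getLogger("cropheight")

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


def feature_plane(img: np.ndarray, feature: str) -> np.ndarray:
    """Scalar feature plane in which the marker bar is dark.

    ``excess_green`` is 2G - R - B (both stripe colours score at or below
    zero against vegetation). ``red_band`` uses the inverted red band
    (255 - R): the bar is bright in raw red, and inverting it lets the
    same negative-centre kernel and strictly-greater threshold rule serve
    both features; under a zero-sum kernel the inversion is exactly
    equivalent to running the raw band with the opposite sign convention.
    """
    if feature == "excess_green":
        return excess_green(img)
    if feature == "red_band":
        red, _, _ = split_bands(img)
        return 255.0 - red
    raise ValueError(f"unknown feature {feature!r}")


def response_plane(img: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Feature plane convolved with the marker kernel (ROI not applied)."""
    plane = feature_plane(validate_rgb(img), config.feature)
    return convolve(plane, modified_kernel(config.marker_width_px))


def _resolve_threshold(
    config: PipelineConfig, threshold: ThresholdModel | float | None
) -> ThresholdModel:
    if threshold is not None:
        if isinstance(threshold, ThresholdModel):
            return threshold
        return ThresholdModel(float(threshold), provenance="fixed")
    if isinstance(config.threshold, str):  # "learn"
        raise ValueError(
            "config requests a learned threshold; pass the ThresholdModel "
            "from calibrate_from_frame/select_threshold explicitly"
        )
    return ThresholdModel(float(config.threshold), provenance="fixed")


def estimate_frame(
    image: np.ndarray | str | os.PathLike,
    config: PipelineConfig,
    date: _dt.date | None = None,
    threshold: ThresholdModel | float | None = None,
    frame_id: str | None = None,
) -> tuple[float, RunSegment]:
    """Measure crop height (cm) on one frame.

    Returns ``(height_cm, run)`` where ``run`` is the detected marker
    segment. ``image`` may be an array or a path. A
    :class:`DetectionError` is re-raised with the frame identifier when
    nothing survives thresholding.
    """
    if isinstance(image, (str, os.PathLike)):
        frame_id = frame_id or str(image)
        image = read_rgb(image)
    model = _resolve_threshold(config, threshold)
    resp = response_plane(image, config)
    mask = apply_threshold(resp, model)
    try:
        run = longest_vertical_runs(mask, roi=config.roi, n=1)[0]
    except DetectionError as exc:
        raise DetectionError(f"frame {frame_id or '<array>'}: {exc}") from exc
    height = compute_height(config.marker, run.length)
    logger.info(
        "frame %s: run col=%d rows=%d..%d len=%d px -> height %.1f cm",
        frame_id or "<array>", run.column, run.top_row, run.bottom_row,
        run.length, height,
    )
    return height, run


def _sample_roi(
    plane: np.ndarray, roi: tuple[int, int, int, int], n: int, rng: np.random.Generator
) -> np.ndarray:
    x0, y0, w, h = roi
    rows = rng.integers(y0, y0 + h, size=n)
    cols = rng.integers(x0, x0 + w, size=n)
    return np.asarray(plane, dtype=np.float64)[rows, cols]


def calibrate_from_frame(
    image: np.ndarray | str | os.PathLike,
    config: PipelineConfig,
    marker_roi: tuple[int, int, int, int],
    background_roi: tuple[int, int, int, int],
    n_samples: int = 200,
    seed: int | None = None,
) -> tuple[ThresholdModel, RunSegment]:
    """Learn the clip level and measure the initial bar on a labelled frame.

    ``n_samples`` response values are drawn from each of the two rectangles
    (the bar, and a bar-free background region); the threshold is the
    midpoint of the gap between the classes. The bar is then detected with
    that threshold, giving the initial visible length in pixels that the
    calibration block needs.
    """
    if isinstance(image, (str, os.PathLike)):
        image = read_rgb(image)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    resp = response_plane(image, config)
    marker = _sample_roi(resp, marker_roi, n_samples, rng)
    other = _sample_roi(resp, background_roi, n_samples, rng)
    model = select_threshold(marker, other)
    run = longest_vertical_runs(apply_threshold(resp, model), roi=config.roi, n=1)[0]
    logger.info(
        "calibration: threshold %.1f (learned), initial bar %d px at col %d",
        model.threshold, run.length, run.column,
    )
    return model, run


def _load_sensors(path: str | os.PathLike) -> dict[_dt.date, tuple[float | None, float | None]]:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        day = pd.Timestamp(row["date"]).date()
        light = None if pd.isna(row.get("light_wm2")) else float(row["light_wm2"])
        rain = None if pd.isna(row.get("rain_mmh")) else float(row["rain_mmh"])
        out[day] = (light, rain)
    return out


def _load_reference(path: str | os.PathLike) -> dict[_dt.date, float]:
    df = pd.read_csv(path)
    col = "reference_cm" if "reference_cm" in df.columns else "referenced_cm"
    return {
        pd.Timestamp(row["date"]).date(): float(row[col])
        for _, row in df.iterrows()
        if not pd.isna(row[col])
    }


def run_series(
    image_dir: str | os.PathLike,
    config: PipelineConfig,
    threshold: ThresholdModel | float | None = None,
) -> tuple[HeightSeries, dict]:
    """Estimate every dated frame in a directory and assemble the season.

    Frames are matched to dates by parsing the file stem with the
    config's strftime pattern. Unreadable or undetectable frames are
    skipped with a logged warning. With a sensor log, each day is classed
    from the pyranometer and flagged from the rain gauge (plus darkness
    days under the red band); flagged estimates are hybrid-corrected when
    the config asks for interpolation. With a reference CSV, the report
    carries per-day relative errors and their mean/sd.

    Returns ``(series, report)``; the report's ``mean_error_pct`` /
    ``sd_error_pct`` always equal ``summarize_errors`` of its own
    ``errors_pct`` column.
    """
    image_dir = Path(image_dir)
    candidates = sorted(
        p for p in image_dir.iterdir()
        if p.suffix.lower() in _IMAGE_SUFFIXES
    ) if image_dir.is_dir() else []
    if not candidates:
        raise ValueError(f"no frames found in {image_dir}")
    sensors = _load_sensors(config.sensor_csv) if config.sensor_csv else {}
    reference = _load_reference(config.reference_csv) if config.reference_csv else {}

    records: list[DailyRecord] = []
    skipped: list[str] = []
    for path in candidates:
        try:
            day = _dt.datetime.strptime(path.stem, config.date_pattern).date()
        except ValueError:
            logger.warning("skipping %s: name does not match %r", path.name, config.date_pattern)
            skipped.append(path.name)
            continue
        try:
            height, run = estimate_frame(path, config, date=day, threshold=threshold)
        except (OSError, DetectionError) as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            skipped.append(path.name)
            continue
        light, rain = sensors.get(day, (None, None))
        if rain is not None and rain > 0:
            condition = "rainfall"
        elif light is not None:
            condition = classify_light(light)
        else:
            condition = "normal"
        rec = DailyRecord(
            date=day,
            estimated_cm=height,
            reference_cm=reference.get(day),
            condition=condition,
            light_wm2=light,
            rain_mmh=rain,
        )
        if rain is not None:
            rec = replace(rec, flagged=flag_unreliable(rec, mode=config.feature))
        records.append(rec)
    if not records:
        raise ValueError(f"no usable frames in {image_dir}")
    records.sort(key=lambda r: r.date)
    series = HeightSeries(records=tuple(records), marker=config.marker)
    if config.interpolation != "none" and any(r.flagged for r in series):
        series = interpolate_flagged(series, strategy=config.interpolation)

    report: dict = {"n_frames": len(series), "skipped": skipped}
    evaluated = [
        (r.date, relative_error(r.best_estimate_cm, r.reference_cm))
        for r in series
        if r.reference_cm is not None
    ]
    if evaluated:
        errors = [e for _, e in evaluated]
        mean, sd = summarize_errors(errors)
        report.update(
            dates=[d.isoformat() for d, _ in evaluated],
            errors_pct=errors,
            mean_error_pct=mean,
            sd_error_pct=sd,
        )
    if config.output_csv:
        series.to_csv(config.output_csv)
        logger.info("wrote %s", config.output_csv)
    return series, report
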