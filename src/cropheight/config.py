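"""Declarative pipeline configuration (YAML).

A config names the colour feature, the marker-kernel width, the clip
level (a number, or ``learn`` to require an explicitly learned model),
an optional region of interest, the marker calibration block, and the
series-level options (interpolation strategy, sensor log, outputs, seed).

Example
-------
.. code-block:: yaml

    feature: excess_green
    marker_width_px: 5
    threshold: 2000
    roi: null              # or [x0, y0, width, height]
    marker:
      initial_px: 153
      initial_cm: 153.0
      initial_crop_cm: 77.0
      total_cm: 250.0      # or above_ground_cm directly
      buried_cm: 20.0
      stripe_cm: 10.0
      marker_width_px: 5
    interpolation: linear  # linear | previous | none
    sensor_csv: sensors.csv
    reference_csv: null
    output_csv: heights.csv
    date_pattern: "%Y-%m-%d"
    seed: 0
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import yaml

from .marker_geometry import MarkerReference, above_ground_length

__all__ = ["PipelineConfig", "load_config", "marker_from_dict"]

FEATURES = ("excess_green", "red_band")
INTERPOLATIONS = ("linear", "previous", "none")


def marker_from_dict(d: dict) -> MarkerReference:
    """Build a :class:`MarkerReference` from a config mapping.

    ``above_ground_cm`` may be given directly or as ``total_cm`` plus
    ``buried_cm``.
    """
    if "above_ground_cm" in d:
        above = float(d["above_ground_cm"])
    else:
        above = above_ground_length(float(d["total_cm"]), float(d["buried_cm"]))
    return MarkerReference(
        initial_px=int(d["initial_px"]),
        initial_cm=float(d["initial_cm"]),
        initial_crop_cm=float(d["initial_crop_cm"]),
        above_ground_cm=above,
        stripe_cm=float(d["stripe_cm"]),
        marker_width_px=int(d.get("marker_width_px", 5)),
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Validated settings for a measurement run."""

    marker: MarkerReference
    feature: str = "excess_green"
    marker_width_px: int = 5
    threshold: float | str = 2000.0
    roi: tuple[int, int, int, int] | None = None
    interpolation: str = "linear"
    sensor_csv: str | None = None
    reference_csv: str | None = None
    output_csv: str | None = None
    date_pattern: str = "%Y-%m-%d"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(f"feature must be one of {FEATURES}, got {self.feature!r}")
        if self.interpolation not in INTERPOLATIONS:
            raise ValueError(
                f"interpolation must be one of {INTERPOLATIONS}, "
                f"got {self.interpolation!r}"
            )
        if isinstance(self.threshold, str):
            if self.threshold != "learn":
                raise ValueError(
                    f"threshold must be a number or 'learn', got {self.threshold!r}"
                )
        elif self.threshold <= 0:
            raise ValueError("a fixed threshold must be positive")
        if self.roi is not None:
            object.__setattr__(self, "roi", tuple(int(v) for v in self.roi))
            if len(self.roi) != 4:
                raise ValueError("roi must be (x0, y0, width, height)")


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Read a YAML pipeline config from disk."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "marker" not in raw:
        raise ValueError(f"{path}: config must be a mapping with a 'marker' block")
    marker = marker_from_dict(raw["marker"])
    kwargs = {
        k: raw[k]
        for k in (
            "feature",
            "marker_width_px",
            "threshold",
            "roi",
            "interpolation",
            "sensor_csv",
            "reference_csv",
            "output_csv",
            "date_pattern",
            "seed",
        )
        if k in raw and raw[k] is not None
    }
    return PipelineConfig(marker=marker, **kwargs)
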