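"""Synthetic field scenes with known ground truth.

Real deployment frames are not redistributable, so this module renders the
scene the pipeline was built for: a sky band, a vegetation canopy growing
up from the bottom, and a vertical marker bar of alternating red and white
stripes whose lower part is hidden by the canopy. Every render is fully
determined by its :class:`SceneSpec` (the seed fixes the canopy texture
and weather noise), and the truth record carries the visible bar length in
pixels plus the bar's position so tests can sample training pixels.

Weather is applied as a whole-frame transform mimicking what each
condition does to the camera:

* ``darkness``   - contrast compression toward mid-gray (overcast light),
  v -> 90 + 0.5 (v - 128) per channel. Channel-common compression halves
  every zero-sum filter response but leaves excess-green geometry intact.
* ``brightness`` - contrast stretch with a positive offset (and hence some
  highlight clipping), v -> 128 + 1.3 (v - 128) + 30.
* ``drizzle``    - mild Gaussian blur (residual droplets on the housing).
* ``rainfall``   - strong blur plus additive noise, enough that
  segmentation visibly truncates the bar — the failure mode that the
  series-level hybrid correction exists to repair.

The camera model is orthographic: one uniform cm-per-pixel scale along the
bar. Canopy texture is seeded per-pixel colour jitter around a green or
gold base; only occlusion and colour statistics matter to the estimator.
"""

from __future__ import annotations

import datetime as _dt
import os
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy import ndimage

from .color_features import validate_rgb

__all__ = [
    "SceneSpec",
    "render_scene",
    "generate_series",
    "reference_season",
    "sample_training_values",
    "SKY_RGB",
    "CANOPY_GREEN_RGB",
    "CANOPY_GOLD_RGB",
    "STRIPE_RED_RGB",
    "STRIPE_WHITE_RGB",
    "SOIL_RGB",
]

# Scene palette. Sky is a pale neutral whose excess-green index is ~0, like
# the real hazy sky the bar top is seen against; the stripe red is saturated
# (strongly negative excess green); canopy bases have high (green) or
# moderate (gold, senesced crop) excess green and red-band values that
# approach the stripes' once the crop turns gold.
SKY_RGB = (150, 170, 190)
CANOPY_GREEN_RGB = (70, 150, 60)
CANOPY_GOLD_RGB = (190, 160, 80)
STRIPE_RED_RGB = (200, 15, 25)
STRIPE_WHITE_RGB = (235, 235, 235)
SOIL_RGB = (120, 100, 70)

#: Rows between the bar's base (ground line) and the bottom image edge.
_GROUND_MARGIN_ROWS = 40

_CONDITIONS = ("normal", "darkness", "brightness", "drizzle", "rainfall")
#: Default blur radius (px) per condition where the spec leaves it None.
_CONDITION_BLUR = {"drizzle": 1.2, "rainfall": 4.0}
#: Additive sensor/rain noise sd per condition.
_CONDITION_NOISE = {"rainfall": 25.0}


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to render one frame deterministically."""

    width: int = 720
    height: int = 480
    marker_total_cm: float = 250.0
    buried_cm: float = 20.0
    stripe_cm: float = 10.0
    marker_width_px: int = 5
    cm_per_px: float = 1.0
    crop_height_cm: float = 77.0
    canopy: str = "green"
    condition: str = "normal"
    canopy_jitter: float = 6.0
    blur_radius_px: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cm_per_px <= 0:
            raise ValueError("cm_per_px must be positive")
        if self.canopy not in ("green", "gold"):
            raise ValueError(f"canopy must be 'green' or 'gold', got {self.canopy!r}")
        if self.condition not in _CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.crop_height_cm < 0:
            raise ValueError("crop height must be >= 0")
        if self.buried_cm < 0 or self.buried_cm >= self.marker_total_cm:
            raise ValueError("buried length must lie in [0, total)")

    @property
    def above_ground_cm(self) -> float:
        return self.marker_total_cm - self.buried_cm

    @property
    def above_ground_px(self) -> int:
        return int(round(self.above_ground_cm / self.cm_per_px))


def _weather(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    out = img.astype(np.float64)
    if spec.condition == "darkness":
        out = 90.0 + 0.5 * (out - 128.0)
    elif spec.condition == "brightness":
        out = 128.0 + 1.3 * (out - 128.0) + 30.0
    blur = spec.blur_radius_px
    if blur is None:
        blur = _CONDITION_BLUR.get(spec.condition, 0.0)
    if blur > 0:
        out = ndimage.gaussian_filter(out, sigma=(blur, blur, 0.0))
    noise_sd = _CONDITION_NOISE.get(spec.condition, 0.0)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return np.clip(out, 0.0, 255.0).astype(np.uint8)


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, dict]:
    """Render one frame; return (RGB uint8 image, ground-truth record).

    The truth record holds ``visible_marker_px`` (= round(visible cm /
    cm-per-pixel)), ``crop_height_cm``, and the bar's location
    (``marker_column``, ``marker_top_row``, ``marker_bottom_row``) for
    training-sample extraction. Identical specs render identical images.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    ground_row = H - _GROUND_MARGIN_ROWS
    marker_top = ground_row - spec.above_ground_px
    if marker_top < 0:
        raise ValueError(
            f"marker ({spec.above_ground_px} px above ground) does not fit in a "
            f"{H}-row image with the ground line at row {ground_row}"
        )
    crop_px = int(round(spec.crop_height_cm / spec.cm_per_px))
    canopy_top = ground_row - crop_px
    if canopy_top < 0:
        raise ValueError("crop height exceeds the ground line height in the image")

    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = SKY_RGB
    img[ground_row:, :] = SOIL_RGB
    if crop_px > 0:
        base = CANOPY_GREEN_RGB if spec.canopy == "green" else CANOPY_GOLD_RGB
        jitter = rng.normal(0.0, spec.canopy_jitter, size=(crop_px, W, 3))
        img[canopy_top:ground_row, :] = np.asarray(base, dtype=np.float64) + jitter

    # Visible bar: from its fixed top down to the canopy line. Stripes are
    # indexed from the top of the bar, red first (the all-white crown that a
    # real bar loses against the sky is treated as already cut from the
    # reference, see marker_geometry.adjust_reference_for_sky).
    half_w = spec.marker_width_px // 2
    c0 = W // 2 - half_w
    c1 = c0 + spec.marker_width_px
    visible_bottom = min(canopy_top, ground_row) - 1
    for row in range(marker_top, visible_bottom + 1):
        cm_from_top = (row - marker_top) * spec.cm_per_px
        stripe = int(cm_from_top // spec.stripe_cm)
        color = STRIPE_RED_RGB if stripe % 2 == 0 else STRIPE_WHITE_RGB
        img[row, c0:c1] = color

    img = _weather(np.clip(img, 0.0, 255.0).astype(np.uint8), spec, rng)

    visible_cm = max(spec.above_ground_cm - spec.crop_height_cm, 0.0)
    truth = {
        "visible_marker_px": int(round(visible_cm / spec.cm_per_px)),
        "crop_height_cm": float(spec.crop_height_cm),
        "marker_column": W // 2,
        "marker_top_row": int(marker_top),
        "marker_bottom_row": int(visible_bottom),
        "ground_row": int(ground_row),
        "condition": spec.condition,
    }
    return validate_rgb(img), truth


# Plausible sensor readings implied by each condition, used when a series
# is generated without an explicit sensor log.
_CONDITION_SENSORS = {
    "normal": (700.0, 0.0),
    "darkness": (250.0, 0.0),
    "brightness": (1200.0, 0.0),
    "drizzle": (600.0, 0.0),  # after the rain: gauge already back to zero
    "rainfall": (350.0, 10.2),
}


def generate_series(
    base: SceneSpec,
    heights,
    conditions,
    start_date: _dt.date = _dt.date(2012, 7, 1),
    gold_from_cm: float = 110.0,
    out_dir: str | os.PathLike | None = None,
):
    """One frame per day plus a truth table aligned to the series format.

    ``heights`` and ``conditions`` must have equal length; day *i* is
    rendered at ``heights[i]`` under ``conditions[i]`` with a per-day seed
    derived from ``base.seed``. The canopy turns from green to gold once
    the crop passes ``gold_from_cm`` (senescence late in the season). The
    truth table carries date, reference_cm (the true height), condition
    and the sensor readings each condition implies. With ``out_dir`` set,
    frames are written as ``YYYY-MM-DD.png`` plus ``truth.csv``.

    Returns ``(frames, truths, truth_frame)`` where ``frames`` and
    ``truths`` are per-day lists and ``truth_frame`` is a DataFrame.
    """
    import pandas as pd

    heights = list(heights)
    conditions = list(conditions)
    if len(heights) != len(conditions):
        raise ValueError(
            f"{len(heights)} heights vs {len(conditions)} conditions"
        )
    frames, truths, rows = [], [], []
    for i, (h, cond) in enumerate(zip(heights, conditions)):
        day = start_date + _dt.timedelta(days=i)
        spec = replace(
            base,
            crop_height_cm=float(h),
            condition=cond,
            canopy="gold" if h >= gold_from_cm else "green",
            seed=(base.seed * 100003 + i) % (2**31),
        )
        img, truth = render_scene(spec)
        light, rain = _CONDITION_SENSORS[cond]
        truth = dict(truth, date=day.isoformat(), light_wm2=light, rain_mmh=rain)
        frames.append(img)
        truths.append(truth)
        rows.append(
            {
                "date": day.isoformat(),
                "estimated_cm": np.nan,
                "reference_cm": float(h),
                "condition": cond,
                "light_wm2": light,
                "rain_mmh": rain,
                "flagged": False,
                "corrected_cm": np.nan,
            }
        )
    truth_frame = pd.DataFrame(
        rows,
        columns=[
            "date",
            "estimated_cm",
            "reference_cm",
            "condition",
            "light_wm2",
            "rain_mmh",
            "flagged",
            "corrected_cm",
        ],
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for img, t in zip(frames, truths):
            Image.fromarray(img).save(os.path.join(out_dir, f"{t['date']}.png"))
        truth_frame.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    return frames, truths, truth_frame


def reference_season() -> tuple[list[float], list[str]]:
    """The packaged 48-day reference season as a synthetic-series recipe.

    Returns ``(heights_cm, conditions)`` for 1 July - 17 August 2012: the
    per-day reference crop heights and field conditions from the packaged
    evaluation table, so a synthetic season reproduces the real season's
    shape (growth 77 -> 119 cm, easing to 100 cm) and weather mix.
    """
    from .series_analysis import load_reference_table

    table = load_reference_table("excess_green")
    return (
        [float(v) for v in table["referenced_cm"]],
        [str(c) for c in table["condition"]],
    )


def sample_training_values(
    plane: np.ndarray,
    truth: dict,
    kernel_size: int,
    n: int = 200,
    rng: np.random.Generator | int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw marker and background response samples from a filtered plane.

    Mimics the manual labelling step used to pick the clip level: ``n``
    values from the bar's centre column (inset by half a kernel from both
    visible ends, so every sampled window sits fully on the bar) and ``n``
    from columns at least one kernel width away from the bar.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    arr = np.asarray(plane, dtype=np.float64)
    col = truth["marker_column"]
    inset = kernel_size // 2
    top = truth["marker_top_row"] + inset
    bottom = truth["marker_bottom_row"] - inset
    if bottom < top:
        raise ValueError("visible marker too short to sample from")
    marker_rows = rng.integers(top, bottom + 1, size=n)
    marker = arr[marker_rows, col]
    far = np.abs(np.arange(arr.shape[1]) - col) > kernel_size
    bg_cols = np.flatnonzero(far)
    other = arr[
        rng.integers(0, arr.shape[0], size=n),
        rng.choice(bg_cols, size=n),
    ]
    return marker, other
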