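"""Daily height series: quality flagging, gap correction and evaluation.

A season of daily estimates is evaluated against reference heights with
the relative-error index  |est - ref| / ref * 100.  The station's own
sensors decide which frames to distrust: the rain gauge flags frames taken
during rainfall (rain blurs the image and truncates the segmented bar),
and the pyranometer classes each day's light as darkness (< 400 W/m^2),
normal (400-1000 inclusive) or brightness (> 1000). With the excess-green
feature only rain frames need flagging; with the raw red band, darkness
frames fail as well. Flagged estimates are replaced from reliable
neighbouring days ("hybrid" correction), either by time-weighted linear
interpolation or by carrying the previous reliable value forward.

Feature comparison uses Welch's unequal-variance two-sample t-test on the
two per-day relative-error columns.
"""

from __future__ import annotations

import datetime as _dt
import os
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CorrectionError
from .marker_geometry import MarkerReference

__all__ = [
    "CONDITIONS",
    "DailyRecord",
    "HeightSeries",
    "relative_error",
    "classify_light",
    "flag_unreliable",
    "interpolate_flagged",
    "summarize_errors",
    "compare_features_t",
    "load_reference_table",
    "load_reference_errors",
]

#: The five field conditions distinguished by the study.
CONDITIONS = ("normal", "darkness", "brightness", "drizzle", "rainfall")

_CSV_COLUMNS = [
    "date",
    "estimated_cm",
    "reference_cm",
    "condition",
    "light_wm2",
    "rain_mmh",
    "flagged",
    "corrected_cm",
]


@dataclass(frozen=True)
class DailyRecord:
    """One dated height estimate with its condition and sensor context."""

    date: _dt.date
    estimated_cm: float
    reference_cm: float | None = None
    condition: str = "normal"
    light_wm2: float | None = None
    rain_mmh: float | None = None
    flagged: bool = False
    corrected_cm: float | None = None
    correction_source: str | None = None

    def __post_init__(self) -> None:
        if self.estimated_cm < 0:
            raise ValueError("estimated_cm must be >= 0")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    @property
    def best_estimate_cm(self) -> float:
        """Corrected value when present, raw estimate otherwise."""
        return self.corrected_cm if self.corrected_cm is not None else self.estimated_cm


@dataclass(frozen=True)
class HeightSeries:
    """An ordered run of daily records plus the calibration they used."""

    records: tuple[DailyRecord, ...]
    marker: MarkerReference | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        recs = tuple(self.records)
        object.__setattr__(self, "records", recs)
        dates = [r.date for r in recs]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("record dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the standard CSV columns."""
        return pd.DataFrame(
            {
                "date": [r.date.isoformat() for r in self.records],
                "estimated_cm": [r.estimated_cm for r in self.records],
                "reference_cm": [r.reference_cm for r in self.records],
                "condition": [r.condition for r in self.records],
                "light_wm2": [r.light_wm2 for r in self.records],
                "rain_mmh": [r.rain_mmh for r in self.records],
                "flagged": [r.flagged for r in self.records],
                "corrected_cm": [r.corrected_cm for r in self.records],
            },
            columns=_CSV_COLUMNS,
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, marker: MarkerReference | None = None
    ) -> "HeightSeries":
        def _opt(row, col):
            if col not in row or pd.isna(row[col]):
                return None
            return float(row[col])

        records = []
        for _, row in df.iterrows():
            records.append(
                DailyRecord(
                    date=pd.Timestamp(row["date"]).date(),
                    estimated_cm=(
                        0.0 if pd.isna(row.get("estimated_cm"))
                        else float(row["estimated_cm"])
                    ),
                    reference_cm=_opt(row, "reference_cm"),
                    condition=(
                        str(row["condition"]).lower()
                        if "condition" in row and not pd.isna(row["condition"])
                        else "normal"
                    ),
                    light_wm2=_opt(row, "light_wm2"),
                    rain_mmh=_opt(row, "rain_mmh"),
                    flagged=bool(row.get("flagged", False))
                    and not pd.isna(row.get("flagged")),
                    corrected_cm=_opt(row, "corrected_cm"),
                )
            )
        return cls(records=tuple(records), marker=marker)

    @classmethod
    def from_csv(
        cls, path: str | os.PathLike, marker: MarkerReference | None = None
    ) -> "HeightSeries":
        return cls.from_frame(pd.read_csv(path), marker=marker)


def relative_error(estimated_cm: float, reference_cm: float) -> float:
    """|estimated - reference| / reference * 100, in percent."""
    if reference_cm <= 0:
        raise ValueError("reference height must be positive")
    return abs(estimated_cm - reference_cm) / reference_cm * 100.0


def classify_light(light_wm2: float) -> str:
    """Pyranometer reading -> light class.

    < 400 W/m^2 is darkness, > 1000 is brightness; 400 and 1000 themselves
    fall in the normal band (the extreme classes are strict inequalities).
    """
    if light_wm2 < 0:
        raise ValueError("light intensity must be >= 0")
    if light_wm2 < 400.0:
        return "darkness"
    if light_wm2 <= 1000.0:
        return "normal"
    return "brightness"


def flag_unreliable(record: DailyRecord, mode: str = "excess_green") -> bool:
    """Should this frame's estimate be distrusted, given the feature used?

    ``excess_green`` flags only active rainfall (rain rate > 0 mm/h);
    drizzle after rain leaves the index usable. ``red_band`` additionally
    flags darkness days, where the single band loses contrast.
    """
    if mode not in ("excess_green", "red_band"):
        raise ValueError(f"mode must be 'excess_green' or 'red_band', got {mode!r}")
    if record.rain_mmh is None:
        raise ValueError("flagging needs a rain-gauge value (rain_mmh)")
    if record.rain_mmh > 0:
        return True
    if mode == "red_band":
        if record.light_wm2 is None:
            raise ValueError("red-band flagging needs a light value (light_wm2)")
        return classify_light(record.light_wm2) == "darkness"
    return False


def interpolate_flagged(
    series: HeightSeries, strategy: str = "linear"
) -> HeightSeries:
    """Replace flagged estimates from reliable neighbouring days.

    ``linear`` takes the time-weighted straight line between the nearest
    unflagged neighbours on either side (the single nearest neighbour at a
    series end); ``previous`` carries the last unflagged value forward
    (the next unflagged value backward at the very start). Unflagged
    records are never altered; replacements land in ``corrected_cm`` with
    their strategy recorded, so re-running the correction is a no-op.
    """
    if strategy not in ("linear", "previous"):
        raise ValueError(f"strategy must be 'linear' or 'previous', got {strategy!r}")
    recs = list(series.records)
    ok_idx = [i for i, r in enumerate(recs) if not r.flagged]
    if not ok_idx:
        raise CorrectionError("every record is flagged; nothing to interpolate from")
    out = []
    for i, rec in enumerate(recs):
        if not rec.flagged:
            out.append(rec)
            continue
        prev = max((j for j in ok_idx if j < i), default=None)
        nxt = min((j for j in ok_idx if j > i), default=None)
        if strategy == "previous":
            j = prev if prev is not None else nxt
            value = recs[j].estimated_cm
        elif prev is None:
            value = recs[nxt].estimated_cm
        elif nxt is None:
            value = recs[prev].estimated_cm
        else:
            t0 = (recs[i].date - recs[prev].date).days
            t1 = (recs[nxt].date - recs[prev].date).days
            y0, y1 = recs[prev].estimated_cm, recs[nxt].estimated_cm
            value = y0 + (y1 - y0) * (t0 / t1)
        out.append(replace(rec, corrected_cm=value, correction_source=strategy))
    return HeightSeries(records=tuple(out), marker=series.marker)


def summarize_errors(errors) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation of percent errors."""
    arr = np.asarray(list(errors), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("error list must be non-empty")
    sd = 0.0 if arr.size == 1 else float(np.std(arr, ddof=1))
    return float(np.mean(arr)), sd


def compare_features_t(errors_a, errors_b) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test on two error columns.

    Returns (t statistic, two-tailed p) with Welch-Satterthwaite degrees
    of freedom. Antisymmetric in its arguments: swapping the columns flips
    the sign of t and leaves p unchanged.
    """
    a = np.asarray(list(errors_a), dtype=np.float64)
    b = np.asarray(list(errors_b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each error list needs at least two values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


_TABLE_FILES = {
    "red_band": "red_band_table.csv",
    "excess_green": "excess_green_table.csv",
}


def load_reference_table(feature: str) -> pd.DataFrame:
    """Published per-day evaluation table for one feature.

    Columns: date, rice_color, condition, referenced_cm, estimated_cm,
    relative_error_pct — the 48-day season (1 July - 17 August 2012) as
    printed for the red-band and excess-green variants of the method.
    """
    try:
        fname = _TABLE_FILES[feature]
    except KeyError:
        raise ValueError(
            f"feature must be 'red_band' or 'excess_green', got {feature!r}"
        ) from None
    with resources.files("cropheight.data").joinpath(fname).open("r") as fh:
        return pd.read_csv(fh)


def load_reference_errors(feature: str) -> np.ndarray:
    """The printed relative-error column (percent) for one feature."""
    return load_reference_table(feature)["relative_error_pct"].to_numpy()
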