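"""Preclinical tumor-volume analytics.

Volumes follow the ellipsoid approximation V = 3.1416/6 * L * W^2 (the literal
constant 3.1416 is used rather than pi so recomputed volumes match tables
produced with the same formula digit for digit).  Two response summaries are
computed per animal:

* short-term response, STR(%) = (V48 - V0) / V0 * 100, the percent volume
  change 48 h after treatment start;
* best response, BR(%) = (mean(Vmin1..Vmin3) - V0) / V0 * 100, where
  Vmin1..Vmin3 is the window of three consecutive on-treatment volumes with
  the smallest mean.

Both are scale-free percentages of the baseline volume V0 at treatment start.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger("persistkit")

__all__ = [
    "VOLUME_CONSTANT",
    "TumorVolumeSeries",
    "ResponseMetrics",
    "tumor_volume",
    "short_term_response",
    "best_response",
    "initiation_day",
    "response_metrics",
    "waterfall_table",
]

#: literal constant from the ellipsoid volume formula; intentionally not math.pi
VOLUME_CONSTANT = 3.1416


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid tumor volume in mm^3 from caliper length and width.

    Width must not exceed length; if the caliper orientation is swapped the
    two are exchanged with a logged note (the formula is not symmetric).
    """
    if length_mm < 0 or width_mm < 0:
        raise ValueError(f"negative caliper measurement: L={length_mm}, W={width_mm}")
    if width_mm > length_mm:
        logger.warning("width %.3g > length %.3g; swapping orientation", width_mm, length_mm)
        length_mm, width_mm = width_mm, length_mm
    # multiply before dividing: matches the printed-precision arithmetic
    # of the formula (e.g. L=6, W=3 -> exactly 28.2744)
    return VOLUME_CONSTANT * length_mm * width_mm**2 / 6.0


@dataclass
class TumorVolumeSeries:
    """Timed caliper measurements for one animal, anchored at treatment start.

    ``measurements`` has columns ``day``, ``length_mm``, ``width_mm`` and
    ``volume_mm3``; days are relative calendar days (strictly increasing) and
    ``treatment_start_day`` marks when dosing began.  ``baseline_volume`` is
    V0, the volume at treatment start.
    """

    animal_id: str
    measurements: pd.DataFrame
    arm: str = ""
    treatment_start_day: float = 0.0
    baseline_volume: float | None = None

    def __post_init__(self) -> None:
        m = self.measurements
        required = {"day", "volume_mm3"}
        if not required.issubset(m.columns):
            missing = required - set(m.columns)
            raise ValueError(f"measurements missing columns {sorted(missing)}")
        days = m["day"].to_numpy(dtype=float)
        if len(days) and not np.all(np.diff(days) > 0):
            raise ValueError(f"animal {self.animal_id}: measurement days not strictly increasing")
        if (m["volume_mm3"] < 0).any():
            raise ValueError(f"animal {self.animal_id}: negative volume")
        if self.baseline_volume is None:
            at_start = m.loc[np.isclose(days, self.treatment_start_day), "volume_mm3"]
            if len(at_start):
                self.baseline_volume = float(at_start.iloc[0])

    def post_treatment(self) -> pd.DataFrame:
        """Measurements strictly after treatment start (the on-treatment course)."""
        return self.measurements[self.measurements["day"] > self.treatment_start_day]

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        animal_id: str,
        arm: str = "",
        treatment_start_day: float = 0.0,
    ) -> "TumorVolumeSeries":
        """Build a series from a raw table, computing volumes from L/W if absent."""
        df = df.sort_values("day").reset_index(drop=True).copy()
        if "volume_mm3" not in df.columns:
            df["volume_mm3"] = [
                tumor_volume(r.length_mm, r.width_mm) for r in df.itertuples()
            ]
        return cls(
            animal_id=animal_id,
            measurements=df,
            arm=arm,
            treatment_start_day=treatment_start_day,
        )


@dataclass
class ResponseMetrics:
    animal_id: str
    arm: str = ""
    str_pct: float | None = None
    br_pct: float | None = None
    initiation_day: float | None = None


def short_term_response(
    series: TumorVolumeSeries,
    window_hours: float = 48.0,
    tolerance_hours: float = 12.0,
) -> float | None:
    """STR(%): percent volume change at the measurement nearest 48 h post start.

    Returns None (with a logged reason) when no measurement falls within
    ``tolerance_hours`` of the window — measurement schedules use whole days,
    so an exact 48 h point is not guaranteed.
    """
    v0 = series.baseline_volume
    if v0 is None:
        raise ValueError(f"animal {series.animal_id}: no baseline volume at treatment start")
    if v0 <= 0:
        raise ValueError(f"animal {series.animal_id}: baseline volume must be > 0")
    target_day = series.treatment_start_day + window_hours / 24.0
    post = series.post_treatment()
    if post.empty:
        logger.warning("animal %s: no post-treatment measurements for STR", series.animal_id)
        return None
    gaps = (post["day"] - target_day).abs()
    if gaps.min() > tolerance_hours / 24.0:
        logger.warning(
            "animal %s: nearest measurement is %.2f d from the %.0f h window",
            series.animal_id, gaps.min(), window_hours,
        )
        return None
    v48 = float(post.loc[gaps.idxmin(), "volume_mm3"])
    return (v48 - v0) / v0 * 100.0


def best_response(series: TumorVolumeSeries) -> float:
    """BR(%): percent change of the smallest mean of 3 consecutive on-treatment volumes.

    Windows start strictly after treatment start (the baseline measurement is
    not part of the treatment course).
    """
    v0 = series.baseline_volume
    if v0 is None or v0 <= 0:
        raise ValueError(f"animal {series.animal_id}: baseline volume must be > 0")
    post = series.post_treatment()["volume_mm3"].to_numpy(dtype=float)
    if len(post) < 3:
        raise ValueError(
            f"animal {series.animal_id}: best response needs >= 3 post-treatment "
            f"measurements, got {len(post)}"
        )
    window_means = (post[:-2] + post[1:-1] + post[2:]) / 3.0
    vmin_mean = float(window_means.min())
    return (vmin_mean - v0) / v0 * 100.0


def initiation_day(series: TumorVolumeSeries, palpable_volume: float = 50.0) -> float | None:
    """First measurement day at which the tumor reached ``palpable_volume`` mm^3.

    Returns None if the threshold was never reached.  The palpable threshold
    is a configurable convention (50 mm^3 by default).
    """
    if palpable_volume <= 0:
        raise ValueError("palpable_volume must be > 0")
    m = series.measurements
    crossed = m[m["volume_mm3"] >= palpable_volume]
    return float(crossed["day"].iloc[0]) if len(crossed) else None


def response_metrics(
    series: TumorVolumeSeries,
    window_hours: float = 48.0,
    tolerance_hours: float = 12.0,
    palpable_volume: float = 50.0,
) -> ResponseMetrics:
    """All per-animal response summaries in one pass."""
    return ResponseMetrics(
        animal_id=series.animal_id,
        arm=series.arm,
        str_pct=short_term_response(series, window_hours, tolerance_hours),
        br_pct=best_response(series),
        initiation_day=initiation_day(series, palpable_volume),
    )


def waterfall_table(
    metrics: Iterable[ResponseMetrics],
    value: str = "br_pct",
) -> tuple[pd.DataFrame, float]:
    """Waterfall ordering plus a one-way ANOVA across treatment arms.

    Animals are sorted by descending response within each arm (the usual
    waterfall-plot convention).  Returns ``(table, anova_p)`` where the p
    value compares arm means; with a single arm (or zero residual degrees of
    freedom) the p value is NaN.
    """
    rows = [
        {"animal_id": m.animal_id, "arm": m.arm, "value": getattr(m, value)}
        for m in metrics
    ]
    if not rows:
        raise ValueError("waterfall_table needs at least one response metric")
    table = pd.DataFrame(rows).dropna(subset=["value"])
    table = (
        table.sort_values(["arm", "value"], ascending=[True, False])
        .reset_index(drop=True)
    )
    arms = [g["value"].to_numpy(dtype=float) for _, g in table.groupby("arm")]
    if len(arms) < 2 or any(len(a) < 2 for a in arms):
        p = math.nan
    else:
        values = np.concatenate(arms)
        if np.allclose(values, values[0]):
            p = 1.0
        else:
            p = float(scipy.stats.f_oneway(*arms).pvalue)
    return table, p
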