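"""Foundational water-isotope types and statistics.

Every water sample in this package is located in dual-isotope space by its
(δ¹⁸O, δ²H) pair, expressed in per mil (‰) relative to Vienna Standard Mean
Ocean Water (VSMOW).  Local precipitation defines a local meteoric water line
(LMWL), a regression of δ²H on δ¹⁸O; when the regression is weighted by event
rainfall depth the line is an *amount-weighted* LMWL.  Waters displaced below
the line carry an evaporative-enrichment signal.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "IsotopeComposition",
    "MeteoricWaterLine",
    "Source",
    "SlopePosition",
    "WaterSample",
    "amount_weighted_mean",
    "delta_from_ratio",
    "fit_meteoric_line",
    "offset_from_line",
    "season_of",
    "seasonal_weighted_means",
]

#: plausible ranges for natural waters (‰ VSMOW); exceeding them warns, never raises
PLAUSIBLE_D18O = (-50.0, 20.0)
PLAUSIBLE_D2H = (-400.0, 100.0)


class Source(str, Enum):
    """Which water pool a sample was drawn from."""

    PRECIPITATION = "precipitation"
    BULK_SOIL = "bulk_soil"
    MOBILE_SOIL = "mobile_soil"
    GROUNDWATER = "groundwater"
    XYLEM = "xylem"


class SlopePosition(str, Enum):
    """Topographic category within the catchment."""

    VALLEY = "valley"
    MIDSLOPE = "midslope"
    RIDGE = "ridge"


@dataclass(frozen=True)
class IsotopeComposition:
    """A (δ¹⁸O, δ²H) coordinate in ‰ VSMOW."""

    d18O: float
    d2H: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d18O) and np.isfinite(self.d2H)):
            raise ValueError(
                f"isotope values must be finite, got ({self.d18O}, {self.d2H})"
            )
        lo18, hi18 = PLAUSIBLE_D18O
        lo2, hi2 = PLAUSIBLE_D2H
        if not (lo18 <= self.d18O <= hi18 and lo2 <= self.d2H <= hi2):
            warnings.warn(
                f"composition ({self.d18O}, {self.d2H}) ‰ is outside the "
                "plausible range for natural waters",
                stacklevel=3,
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.d18O, self.d2H], dtype=float)


@dataclass(frozen=True)
class MeteoricWaterLine:
    """δ²H = slope × δ¹⁸O + intercept, optionally amount-weighted."""

    slope: float
    intercept: float
    weighted: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("meteoric line parameters must be finite")
        if self.slope <= 0:
            raise ValueError(
                f"meteoric line slope must be positive, got {self.slope}"
            )

    def predict_d2H(self, d18O: float) -> float:
        return self.slope * d18O + self.intercept


@dataclass(frozen=True)
class WaterSample:
    """A single analysed water sample.

    depth_cm applies to soil waters, amount_mm to precipitation events, and
    slope_position to samples tied to a topographic category.
    """

    sample_id: str
    source: Source
    date: dt.date
    composition: IsotopeComposition
    depth_cm: float | None = None
    slope_position: SlopePosition | None = None
    amount_mm: float | None = None

    def __post_init__(self) -> None:
        if self.depth_cm is not None and self.depth_cm < 0:
            raise ValueError(f"depth_cm must be >= 0, got {self.depth_cm}")
        if self.amount_mm is not None and self.amount_mm < 0:
            raise ValueError(f"amount_mm must be >= 0, got {self.amount_mm}")


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Delta notation: per-mil deviation of a heavy/light isotope ratio
    from the standard's ratio, ((R_sample / R_standard) − 1) × 1000."""
    if not (r_sample > 0 and r_standard > 0):
        raise ValueError(
            f"isotope ratios must be positive, got {r_sample} and {r_standard}"
        )
    return (r_sample / r_standard - 1.0) * 1000.0


def amount_weighted_mean(
    samples: Iterable[tuple[IsotopeComposition, float]],
) -> IsotopeComposition:
    """Component-wise weighted mean of compositions (weights in mm of rain)."""
    pairs = list(samples)
    if not pairs:
        raise ValueError("amount_weighted_mean requires at least one sample")
    weights = np.array([w for _, w in pairs], dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    coords = np.array([c.as_array() for c, _ in pairs])
    mean = weights @ coords / total
    return IsotopeComposition(float(mean[0]), float(mean[1]))


def fit_meteoric_line(
    precip: Sequence[WaterSample], weighted: bool = True
) -> MeteoricWaterLine:
    """Least-squares regression of δ²H on δ¹⁸O over precipitation events.

    When ``weighted``, regression weights are proportional to event amount
    (mm); missing amounts are a hard error rather than a silent fall-back to
    an unweighted fit.
    """
    if len(precip) < 2:
        raise ValueError("need at least two precipitation samples")
    x = np.array([s.composition.d18O for s in precip])
    y = np.array([s.composition.d2H for s in precip])
    if np.unique(x).size < 2:
        raise ValueError("degenerate fit: all d18O values identical")
    if weighted:
        if any(s.amount_mm is None for s in precip):
            raise ValueError("weighted fit requires amount_mm on every event")
        w = np.array([s.amount_mm for s in precip], dtype=float)
        if w.sum() <= 0:
            raise ValueError("total event amount must be positive")
        model = sm.WLS(y, sm.add_constant(x), weights=w)
    else:
        model = sm.OLS(y, sm.add_constant(x))
    res = model.fit()
    intercept, slope = res.params
    return MeteoricWaterLine(float(slope), float(intercept), weighted=weighted)


def offset_from_line(c: IsotopeComposition, line: MeteoricWaterLine) -> float:
    """δ²H displacement (‰) from the meteoric line; negative means below the
    line, i.e. evaporative enrichment."""
    return c.d2H - line.predict_d2H(c.d18O)


_SEASONS = {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
            6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}


def season_of(date: dt.date) -> str:
    """Meteorological season (quarter) of a calendar date."""
    return _SEASONS[date.month]


def seasonal_weighted_means(
    precip: Sequence[WaterSample],
) -> dict[str, IsotopeComposition]:
    """Amount-weighted mean precipitation composition per meteorological
    season (DJF/MAM/JJA/SON); seasons without events are absent."""
    buckets: dict[str, list[tuple[IsotopeComposition, float]]] = {}
    for s in precip:
        if s.amount_mm is None:
            raise ValueError("seasonal weighting requires amount_mm on every event")
        buckets.setdefault(season_of(s.date), []).append(
            (s.composition, s.amount_mm)
        )
    return {k: amount_weighted_mean(v) for k, v in buckets.items()}
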