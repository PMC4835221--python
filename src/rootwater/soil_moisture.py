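"""Soil-moisture bookkeeping: storage, depletion, dry cycles, dry dates.

Sensor profiles report volumetric water content (VWC, m³ m⁻³) at a handful
of depths.  Storage over the profile is the depth integral of VWC using the
midpoints between sensor depths as layer boundaries (the first layer starts
at the surface; the deepest layer extends half the last inter-sensor spacing
below the deepest sensor).  A *dry cycle* is a maximal run of at least five
consecutive days without rain, and a tree-sampling date is *dry* when the
two preceding days together received less than 0.2 mm.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DryCycle",
    "VWCProfile",
    "detect_dry_cycles",
    "is_dry_date",
    "layer_thicknesses",
    "profile_storage",
    "relative_vwc",
    "storage_depletion",
]

#: daily rainfall (mm) below which a day counts as rain-free
DEFAULT_RAIN_THRESHOLD_MM = 0.2
#: minimum rain-free run length for a dry cycle (days)
DEFAULT_MIN_DRY_DAYS = 5
#: shallow/deep partition boundary (cm)
DEFAULT_SPLIT_CM = 40.0


@dataclass(frozen=True)
class DryCycle:
    start_date: dt.date
    end_date: dt.date

    @property
    def length_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i) for i in range(self.length_days)]


@dataclass
class VWCProfile:
    """VWC time series for one site: ``series`` is indexed by timestamp with
    one column per sensor depth (cm), columns strictly increasing."""

    site_id: str
    sensor_depths_cm: np.ndarray
    series: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        depths = np.asarray(self.sensor_depths_cm, dtype=float)
        if depths.ndim != 1 or depths.size == 0:
            raise ValueError("need at least one sensor depth")
        if np.any(depths <= 0) or np.any(np.diff(depths) <= 0):
            raise ValueError("sensor depths must be positive and strictly increasing")
        if list(self.series.columns) != list(depths):
            raise ValueError("series columns must equal sensor depths, in order")
        vals = self.series.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("VWC values must lie in [0, 1]")
        self.sensor_depths_cm = depths

    @property
    def bottom_cm(self) -> float:
        return float(np.sum(layer_thicknesses(self.sensor_depths_cm)))


def layer_thicknesses(sensor_depths_cm) -> np.ndarray:
    """Layer thickness (cm) represented by each sensor.

    Layer i spans from the midpoint with the previous sensor (the surface,
    0 cm, for the shallowest) to the midpoint with the next sensor; the
    deepest layer ends half the last spacing below the deepest sensor (for a
    single sensor: twice its depth).  Thicknesses sum to the bottom boundary.
    """
    depths = np.asarray(sensor_depths_cm, dtype=float)
    if depths.size == 0:
        raise ValueError("need at least one sensor depth")
    if np.any(depths <= 0) or np.any(np.diff(depths) <= 0):
        raise ValueError("sensor depths must be positive and strictly increasing")
    bounds = _layer_bounds(depths)
    return np.diff(bounds)


def _layer_bounds(depths: np.ndarray) -> np.ndarray:
    """Layer boundaries: 0, midpoints, bottom (n+1 values)."""
    if depths.size == 1:
        return np.array([0.0, 2.0 * depths[0]])
    mids = (depths[:-1] + depths[1:]) / 2.0
    bottom = depths[-1] + (depths[-1] - depths[-2]) / 2.0
    return np.concatenate([[0.0], mids, [bottom]])


def _storage_from_vwc(
    depths: np.ndarray, vwc: np.ndarray, depth_range: tuple[float, float]
) -> float:
    lo, hi = depth_range
    bounds = _layer_bounds(depths)
    if hi <= bounds[0] or lo >= bounds[-1] or hi <= lo:
        raise ValueError(
            f"depth range {depth_range} does not intersect profile "
            f"coverage [0, {bounds[-1]}] cm"
        )
    # pro-rate each layer by its overlap with [lo, hi); cm of water → mm is ×10
    overlap = np.clip(np.minimum(bounds[1:], hi) - np.maximum(bounds[:-1], lo), 0, None)
    return float(np.nansum(vwc * overlap) * 10.0)


def profile_storage(
    profile: VWCProfile,
    t: pd.Timestamp | dt.datetime | dt.date,
    depth_range: tuple[float, float] | None = None,
) -> float:
    """Water storage (mm) over a depth range at the reading nearest ``t``
    (dates are taken at midnight): Σ VWC_i × thickness_i × 10."""
    row = _reading_at(profile, t)
    if depth_range is None:
        depth_range = (0.0, profile.bottom_cm)
    return _storage_from_vwc(profile.sensor_depths_cm, row, depth_range)


def _reading_at(profile: VWCProfile, t) -> np.ndarray:
    ts = pd.Timestamp(t)
    idx = profile.series.index
    if ts < idx.min() or ts > idx.max():
        raise ValueError(f"timestamp {ts} outside series span [{idx.min()}, {idx.max()}]")
    pos = idx.get_indexer([ts], method="nearest")[0]
    return profile.series.iloc[pos].to_numpy(dtype=float)


def storage_depletion(
    profile: VWCProfile,
    cycle: DryCycle,
    split_cm: float = DEFAULT_SPLIT_CM,
) -> tuple[float, float]:
    """Start-minus-end storage change (mm) over a dry cycle, partitioned into
    the shallow [0, split) and deep [split, bottom] layers; positive values
    are depletion.  Boundary storages use the first and the last reading
    inside the cycle's calendar span (so the rewetting that ends the cycle
    never contaminates the end reading).
    """
    span_start = pd.Timestamp(cycle.start_date)
    span_end = pd.Timestamp(cycle.end_date) + pd.Timedelta(days=1)
    idx = profile.series.index
    inside = idx[(idx >= span_start) & (idx < span_end)]
    if inside.empty:
        raise ValueError("dry cycle lies outside the sensor record")
    start, end = inside[0], inside[-1]
    bottom = profile.bottom_cm
    shallow = profile_storage(profile, start, (0.0, split_cm)) - profile_storage(
        profile, end, (0.0, split_cm)
    )
    deep = profile_storage(profile, start, (split_cm, bottom)) - profile_storage(
        profile, end, (split_cm, bottom)
    )
    return shallow, deep


def relative_vwc(profile: VWCProfile) -> pd.DataFrame:
    """Daily-maximum VWC per sensor as a percentage of that sensor's maximum
    over the whole record; all values ≤ 100 with at least one 100% day per
    sensor.  Sensors with no finite data are dropped with a warning."""
    if profile.series.empty:
        raise ValueError("empty sensor series")
    daily_max = profile.series.resample("1D").max()
    study_max = profile.series.max()
    dead = study_max.index[~np.isfinite(study_max.to_numpy(dtype=float))]
    if len(dead):
        warnings.warn(
            f"dropping all-missing sensors at depths {list(dead)} cm at site "
            f"{profile.site_id}"
        )
        daily_max = daily_max.drop(columns=dead)
        study_max = study_max.drop(dead)
    return daily_max.div(study_max, axis=1) * 100.0


def _as_daily_series(p: pd.Series) -> pd.Series:
    s = p.copy()
    s.index = pd.to_datetime(s.index)
    if (s < 0).any():
        raise ValueError("daily precipitation totals must be non-negative")
    return s.sort_index()


def detect_dry_cycles(
    precip: pd.Series,
    min_days: int = DEFAULT_MIN_DRY_DAYS,
    rain_threshold_mm: float = DEFAULT_RAIN_THRESHOLD_MM,
) -> list[DryCycle]:
    """Maximal runs of ≥ ``min_days`` consecutive days with daily rainfall
    below ``rain_threshold_mm``, in chronological order.

    ``precip`` is a contiguous daily series of rainfall totals (mm) indexed
    by date.
    """
    s = _as_daily_series(precip)
    if s.empty:
        return []
    if not (s.index.to_series().diff().dropna() == pd.Timedelta(days=1)).all():
        raise ValueError("precipitation record must be contiguous daily totals")
    dry = (s < rain_threshold_mm).to_numpy()
    cycles: list[DryCycle] = []
    i = 0
    n = len(dry)
    while i < n:
        if dry[i]:
            j = i
            while j + 1 < n and dry[j + 1]:
                j += 1
            if j - i + 1 >= min_days:
                cycles.append(
                    DryCycle(s.index[i].date(), s.index[j].date())
                )
            i = j + 1
        else:
            i += 1
    return cycles


def is_dry_date(
    precip: pd.Series,
    d: dt.date,
    threshold_mm: float = DEFAULT_RAIN_THRESHOLD_MM,
) -> bool:
    """True when the summed rainfall of the two preceding calendar days is
    below ``threshold_mm`` (0.2 mm)."""
    s = _as_daily_series(precip)
    prev = [pd.Timestamp(d) - pd.Timedelta(days=k) for k in (1, 2)]
    missing = [p for p in prev if p not in s.index]
    if missing:
        raise ValueError(
            f"precipitation record missing preceding days {missing} for {d}"
        )
    return float(s.loc[prev].sum()) < threshold_mm
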