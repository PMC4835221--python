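"""Sap-flux dry-cycle diagnostics.

Heat-dissipation sap-flux series (already calibrated to flux density; units
are instrument-dependent and all comparisons here are relative) are reduced
to daytime (7 am–7 pm local clock) daily means after excluding observations
at very low atmospheric demand (VPD < 0.1 kPa), normalised to the maximum
over a dry-cycle week, and compared between the start and end of the cycle.
Crown conductance — daily sap flux divided by daily daytime VPD — indexes
canopy stomatal control.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .soil_moisture import DEFAULT_RAIN_THRESHOLD_MM, DryCycle

__all__ = [
    "DryCycleResponse",
    "SapFluxSeries",
    "crown_conductance",
    "daily_daytime_mean",
    "dry_cycle_response",
    "normalize_pct_max",
]

DEFAULT_VPD_MIN_KPA = 0.1
DAYTIME_START_HOUR = 7
DAYTIME_END_HOUR = 19
DEFAULT_EDGE_DAYS = 2


@dataclass
class SapFluxSeries:
    """Sub-daily flux and VPD observations for one tree.

    ``series`` is indexed by timestamp with columns ``flux`` and ``vpd_kpa``.
    Multiple probes on a tree are expected to be averaged upstream into one
    tree-level series.
    """

    tree_id: str
    genus: str
    series: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = {"flux", "vpd_kpa"} - set(self.series.columns)
        if missing:
            raise ValueError(f"series missing columns {missing}")
        vals = self.series[["flux", "vpd_kpa"]].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and finite.min() < 0:
            raise ValueError("flux and vpd_kpa must be non-negative")


@dataclass(frozen=True)
class DryCycleResponse:
    """Start-versus-end change in daily sap flux over a dry cycle."""

    tree_id: str
    start_mean: float
    end_mean: float

    @property
    def pct_change(self) -> float:
        """Percent change from the start-of-cycle base; positive = increase."""
        return (self.end_mean - self.start_mean) / self.start_mean * 100.0


def _daytime_mask(idx: pd.DatetimeIndex) -> np.ndarray:
    return (idx.hour >= DAYTIME_START_HOUR) & (idx.hour < DAYTIME_END_HOUR)


def daily_daytime_mean(
    s: SapFluxSeries,
    day: dt.date,
    vpd_min_kpa: float = DEFAULT_VPD_MIN_KPA,
    column: str = "flux",
) -> float:
    """Mean of ``column`` over 07:00–19:00 of ``day`` after dropping records
    with VPD below ``vpd_min_kpa``; NaN marks a day with no surviving
    observations (a missing day, never zero)."""
    frame = s.series.loc[str(day)]
    if frame.empty:
        return float("nan")
    keep = _daytime_mask(frame.index) & (
        frame["vpd_kpa"].to_numpy(dtype=float) >= vpd_min_kpa
    )
    vals = frame.loc[keep, column].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def daily_daytime_means(
    s: SapFluxSeries,
    days: list[dt.date],
    vpd_min_kpa: float = DEFAULT_VPD_MIN_KPA,
    column: str = "flux",
) -> pd.Series:
    """daily_daytime_mean over a list of days, as a date-indexed series."""
    return pd.Series(
        [daily_daytime_mean(s, d, vpd_min_kpa, column) for d in days],
        index=pd.Index(days, name="date"),
        name=column,
    )


def normalize_pct_max(daily_means: pd.Series) -> pd.Series:
    """Each day's value as a percent of the window maximum (the max day is
    100%); NaN days pass through."""
    vals = daily_means.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("no non-missing days to normalise")
    top = finite.max()
    if top <= 0:
        raise ValueError("degenerate normalisation: window maximum is not positive")
    return daily_means / top * 100.0


def crown_conductance(
    daily_flux: float, daily_vpd_kpa: float, unit_factor: float = 1.0
) -> float:
    """Crown-conductance index: daily flux / daily daytime VPD (kPa), with an
    optional unit-conversion factor."""
    if not daily_vpd_kpa > 0:
        raise ValueError("crown conductance undefined at zero VPD")
    return daily_flux / daily_vpd_kpa * unit_factor


def dry_cycle_response(
    s: SapFluxSeries,
    cycle: DryCycle,
    edge_days: int = DEFAULT_EDGE_DAYS,
    precip: pd.Series | None = None,
    vpd_min_kpa: float = DEFAULT_VPD_MIN_KPA,
    rain_threshold_mm: float = DEFAULT_RAIN_THRESHOLD_MM,
) -> DryCycleResponse:
    """Compare mean daily sap flux at the start of a dry cycle (first
    ``edge_days`` days) with its end (last ``edge_days`` days).

    If a daily precipitation series is supplied, days inside the window with
    rainfall at or above ``rain_threshold_mm`` are omitted before taking the
    edges (rain days contaminate the drying signal).
    """
    days = cycle.dates()
    if precip is not None:
        p = precip.copy()
        p.index = pd.to_datetime(p.index)
        days = [
            d
            for d in days
            if pd.Timestamp(d) not in p.index
            or float(p.loc[pd.Timestamp(d)]) < rain_threshold_mm
        ]
    if len(days) < 2 * edge_days:
        raise ValueError(
            f"dry cycle has {len(days)} usable days; need >= {2 * edge_days}"
        )
    means = daily_daytime_means(s, days, vpd_min_kpa=vpd_min_kpa)
    start = float(np.nanmean(means.iloc[:edge_days]))
    end = float(np.nanmean(means.iloc[-edge_days:]))
    return DryCycleResponse(tree_id=s.tree_id, start_mean=start, end_mean=end)
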