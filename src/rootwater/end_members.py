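"""Mixing-model end members.

The two-end-member geometry of the rooting-depth model needs (a) a *surface*
soil-water composition per slope position — taken as the y-intercept (value
at 0 cm depth) of per-isotope regressions of bulk soil-water δ against
sampling depth — and (b) a mean *groundwater* composition.  Slope positions
are assigned from elevation bands surveyed for the catchment (valley floor
266–268 m, midslope 269–291 m, ridge 292–300 m); the printed bands leave
1-m gaps, so midpoint cut-offs (268.5 and 291.5 m) make the assignment
total, and elevations outside the survey range are clamped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .isotope import IsotopeComposition, SlopePosition, Source, WaterSample

__all__ = [
    "CATCHMENT",
    "DepthProfileFit",
    "EndMemberSet",
    "assign_slope_position",
    "build_end_member_sets",
    "fit_surface_end_member",
    "groundwater_end_member",
]

logger = logging.getLogger(__name__)

#: tag for the pooled, catchment-wide end-member set
CATCHMENT = "catchment"

_VALLEY_MAX_M = 268.5
_MIDSLOPE_MAX_M = 291.5
_SURVEY_RANGE_M = (266.0, 300.0)

DEFAULT_MAX_DEPTH_CM = 120.0


class Isotope(str, Enum):
    D18O = "d18O"
    D2H = "d2H"


@dataclass(frozen=True)
class DepthProfileFit:
    """Per-isotope linear fit of δ against depth for one slope position."""

    slope_position: SlopePosition | str
    isotope: Isotope
    slope: float  # ‰ per cm
    intercept: float  # ‰ at 0 cm
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("depth-profile fit requires n >= 2 samples")
        if not np.isfinite(self.intercept):
            raise ValueError("intercept must be finite")


@dataclass(frozen=True)
class EndMemberSet:
    """Surface and groundwater end members for one slope position (or the
    pooled catchment), with the maximum mixing depth they stand for."""

    slope_position: SlopePosition | str
    surface: IsotopeComposition
    groundwater: IsotopeComposition
    max_depth_cm: float = DEFAULT_MAX_DEPTH_CM

    def __post_init__(self) -> None:
        if self.max_depth_cm <= 0:
            raise ValueError("max_depth_cm must be positive")
        d = self.surface.as_array() - self.groundwater.as_array()
        if float(np.hypot(*d)) <= 0:
            raise ValueError(
                "degenerate geometry: surface and groundwater end members coincide"
            )

    def with_max_depth(self, max_depth_cm: float) -> "EndMemberSet":
        return EndMemberSet(
            self.slope_position, self.surface, self.groundwater, max_depth_cm
        )


def assign_slope_position(elevation_m: float) -> SlopePosition:
    """Map an elevation (m) to a slope-position band; total over all finite
    elevations, clamping (with a log warning) outside the surveyed range."""
    if not np.isfinite(elevation_m):
        raise ValueError("elevation must be finite")
    lo, hi = _SURVEY_RANGE_M
    if elevation_m < lo or elevation_m > hi:
        logger.warning(
            "elevation %.1f m outside surveyed bands %s; clamping", elevation_m,
            _SURVEY_RANGE_M,
        )
    if elevation_m <= _VALLEY_MAX_M:
        return SlopePosition.VALLEY
    if elevation_m <= _MIDSLOPE_MAX_M:
        return SlopePosition.MIDSLOPE
    return SlopePosition.RIDGE


def _fit_one_isotope(
    depths: np.ndarray, values: np.ndarray, pos: SlopePosition | str, iso: Isotope
) -> DepthProfileFit:
    res = sm.OLS(values, sm.add_constant(depths)).fit()
    intercept, slope = res.params
    return DepthProfileFit(pos, iso, float(slope), float(intercept), n=len(values))


def fit_surface_end_member(
    bulk: Sequence[WaterSample],
) -> tuple[DepthProfileFit, DepthProfileFit, IsotopeComposition]:
    """Regress bulk soil-water δ¹⁸O and δ²H separately on depth; the two
    y-intercepts define the surface (0 cm) end member.

    All samples must carry a depth and share one slope position (or all have
    none, giving the pooled catchment fit).
    """
    samples = list(bulk)
    if not samples:
        raise ValueError("no bulk soil-water samples supplied")
    positions = {s.slope_position for s in samples}
    if len(positions) > 1:
        raise ValueError(f"samples span several slope positions: {positions}")
    pos = positions.pop() or CATCHMENT
    if any(s.depth_cm is None for s in samples):
        raise ValueError("every bulk sample needs a depth_cm")
    depths = np.array([s.depth_cm for s in samples], dtype=float)
    if np.unique(depths).size < 2:
        raise ValueError("degenerate fit: need at least two distinct depths")
    d18O = np.array([s.composition.d18O for s in samples])
    d2H = np.array([s.composition.d2H for s in samples])
    fit18 = _fit_one_isotope(depths, d18O, pos, Isotope.D18O)
    fit2 = _fit_one_isotope(depths, d2H, pos, Isotope.D2H)
    surface = IsotopeComposition(fit18.intercept, fit2.intercept)
    return fit18, fit2, surface


def groundwater_end_member(gw: Iterable[WaterSample]) -> IsotopeComposition:
    """Unweighted arithmetic mean groundwater composition over the study
    period."""
    samples = list(gw)
    if not samples:
        raise ValueError("no groundwater samples supplied")
    coords = np.array([s.composition.as_array() for s in samples])
    mean = coords.mean(axis=0)
    return IsotopeComposition(float(mean[0]), float(mean[1]))


def build_end_member_sets(
    bulk: Sequence[WaterSample],
    gw: Sequence[WaterSample],
    max_depth_cm: float = DEFAULT_MAX_DEPTH_CM,
    include_catchment: bool = True,
) -> dict[SlopePosition | str, EndMemberSet]:
    """Construct per-slope-position end-member sets (plus an optional pooled
    'catchment' set) from bulk soil-water and groundwater samples."""
    bulk = [s for s in bulk if s.source == Source.BULK_SOIL]
    gw = [s for s in gw if s.source == Source.GROUNDWATER]
    gw_comp = groundwater_end_member(gw)
    sets: dict[SlopePosition | str, EndMemberSet] = {}
    for pos in SlopePosition:
        subset = [s for s in bulk if s.slope_position == pos]
        if not subset:
            continue
        *_, surface = fit_surface_end_member(subset)
        sets[pos] = EndMemberSet(pos, surface, gw_comp, max_depth_cm)
    if include_catchment and bulk:
        pooled = [
            WaterSample(s.sample_id, s.source, s.date, s.composition,
                        depth_cm=s.depth_cm, amount_mm=s.amount_mm)
            for s in bulk
        ]
        *_, surface = fit_surface_end_member(pooled)
        sets[CATCHMENT] = EndMemberSet(CATCHMENT, surface, gw_comp, max_depth_cm)
    if not sets:
        raise ValueError("no bulk soil-water samples to build end members from")
    return sets
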