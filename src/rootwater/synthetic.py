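"""Seeded synthetic catchment with known ground truth.

Generates a virtual forested headwater catchment — seasonal precipitation
isotopes along a configured meteoric line, depth-damped bulk soil-water
profiles, near-constant groundwater, trees whose xylem water is formed at a
KNOWN uptake depth plus analytical noise, drying soil-moisture profiles and
VPD-driven sap flux — so every stage of the rooting-depth pipeline can be
exercised and its parameter recovery measured without field data.

Random streams are partitioned per generator (precipitation / soils /
trees / field series) from one top-level seed, so e.g. changing the number
of trees does not perturb the precipitation draw, and the same seed always
reproduces every table bit-for-bit.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .isotope import IsotopeComposition, SlopePosition, Source, WaterSample
from .mixing import TreeRecord
from .sap_flux import SapFluxSeries
from .soil_moisture import VWCProfile

__all__ = [
    "ScenarioConfig",
    "SyntheticCatchment",
    "generate_catchment",
    "generate_precip",
    "generate_soil_and_groundwater",
    "generate_trees",
    "generate_field_series",
    "soil_composition_at_depth",
]

#: genus mix of the 60 sampled trees (Acer 13, Carya 8, Pinus 8, Quercus 31)
GENUS_WEIGHTS = {"Acer": 13, "Carya": 8, "Pinus": 8, "Quercus": 31}
GENUS_SPECIES = {
    "Acer": "saccharum",
    "Carya": "glabra",
    "Pinus": "strobus",
    "Quercus": "prinus",
}
GENUS_DBH_CM = {"Acer": 23.0, "Carya": 31.6, "Pinus": 33.2, "Quercus": 38.0}
GENUS_HEIGHT_M = {"Acer": 16.2, "Carya": 22.0, "Pinus": 21.4, "Quercus": 22.0}


def _default_surfaces() -> dict[SlopePosition, IsotopeComposition]:
    # anchored to the shallow (10 cm) bulk soil-water mean, with the ridge
    # slightly less depleted than midslope and valley
    return {
        SlopePosition.VALLEY: IsotopeComposition(-6.4, -46.6),
        SlopePosition.MIDSLOPE: IsotopeComposition(-6.2, -45.6),
        SlopePosition.RIDGE: IsotopeComposition(-6.0, -44.6),
    }


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of the stated synthetic world, with field-realistic
    defaults anchored to the study catchment where values are printed."""

    seed: int = 0
    # trees
    n_trees: int = 60
    true_depth_model: str = "fixed"  # fixed | uniform_range | genus_shifted
    true_depth_cm: float = 40.0
    depth_range_cm: tuple[float, float] = (10.0, 110.0)
    genus_depth_cm: Mapping[str, float] = field(
        default_factory=lambda: {"Acer": 20.0, "Carya": 45.0, "Pinus": 50.0,
                                 "Quercus": 55.0}
    )
    genus_depth_jitter_cm: float = 5.0
    # meteoric line and end members
    mwl_slope: float = 8.4
    mwl_intercept: float = 15.8
    surface_composition: Mapping[SlopePosition, IsotopeComposition] = field(
        default_factory=_default_surfaces
    )
    groundwater_composition: IsotopeComposition = IsotopeComposition(-8.6, -54.6)
    # soil profile shape
    profile_shape: str = "linear"  # linear | exponential
    profile_length_scale_cm: float = 40.0
    max_depth_cm: float = 120.0
    evap_offset_permil: float = 0.0  # extra below-line d2H shift at 0 cm
    # analytical noise (cryogenic extraction + IRMS long-term precision)
    noise_d18O: float = 0.12
    noise_d2H: float = 0.80
    # precipitation
    n_days: int = 210
    start_date: dt.date = dt.date(2009, 4, 1)
    rain_prob: float = 0.35
    rain_mean_mm: float = 8.0
    precip_d18O_mean: float = -9.0
    precip_season_amplitude: float = 3.0
    precip_noise_d18O: float = 1.5
    precip_line_noise_d2H: float = 1.0
    dry_run_start_day: int = 120
    dry_run_days: int = 6
    # soil sampling
    bulk_depths_cm: tuple[float, ...] = (10.0, 20.0, 30.0)
    n_bulk_sites_per_position: int = 4
    n_gw_samples: int = 12
    gw_noise_d18O: float = 0.10
    gw_noise_d2H: float = 0.50
    # soil-moisture sensors
    n_vwc_sites: int = 3
    sensor_depths_cm: tuple[float, ...] = (5, 10, 20, 40, 60, 80, 100, 120, 162)
    drydown_rate_surface: float = 0.06  # fraction of drainable water per day at 0 cm
    drydown_rate_scale_cm: float = 20.0  # e-folding depth of the drydown rate
    vwc_residual: float = 0.08
    # sap flux
    sapflux_trees: Mapping[str, int] = field(
        default_factory=lambda: {"Acer": 2, "Quercus": 3, "Pinus": 1}
    )
    jmax: float = 100.0
    vpd_halfsat_kpa: float = 0.6
    soil_sensitivity: Mapping[str, float] = field(
        default_factory=lambda: {"Acer": 0.0, "Quercus": 0.85, "Pinus": 0.95}
    )

    def with_(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


@dataclass
class SyntheticCatchment:
    """One generated scenario: every observation table plus the hidden truth."""

    config: ScenarioConfig
    precip_events: pd.DataFrame
    daily_precip: pd.Series
    bulk_soil: list[WaterSample]
    groundwater: list[WaterSample]
    trees: list[TreeRecord]
    truth: pd.DataFrame  # tree_id, true_depth_cm
    vwc: list[VWCProfile]
    sapflux: list[SapFluxSeries]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("precip", "soil", "trees", "field")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------- precipitation

def generate_precip(
    cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Precipitation events plus the daily total series.

    Rain days are Bernoulli draws; amounts are gamma-distributed; event δ¹⁸O
    follows a seasonal sinusoid (heavy-isotope enriched in summer) and δ²H
    scatters about the configured meteoric line.  A rain-free run of
    ``dry_run_days`` is embedded at ``dry_run_start_day`` and bounded by
    forced rain days so dry-cycle detection has a known answer.
    """
    if cfg.n_days < 30:
        raise ValueError("need at least 30 days of record")
    rng = rng if rng is not None else _streams(cfg.seed)["precip"]
    dates = pd.date_range(cfg.start_date, periods=cfg.n_days, freq="1D")
    wet = rng.random(cfg.n_days) < cfg.rain_prob
    i0, i1 = cfg.dry_run_start_day, cfg.dry_run_start_day + cfg.dry_run_days
    if i1 + 1 > cfg.n_days:
        raise ValueError("embedded dry run extends past the record")
    wet[i0:i1] = False
    if i0 > 0:
        wet[i0 - 1] = True
    wet[i1] = True
    amounts = np.zeros(cfg.n_days)
    shape = 0.8
    amounts[wet] = rng.gamma(shape, cfg.rain_mean_mm / shape, size=int(wet.sum()))
    amounts[wet] = np.maximum(amounts[wet], 0.3)  # a wet day is a real event
    doy = dates.dayofyear.to_numpy()
    d18O = (
        cfg.precip_d18O_mean
        + cfg.precip_season_amplitude * np.cos(2 * np.pi * (doy - 196) / 365.0)
        + rng.normal(0.0, cfg.precip_noise_d18O, cfg.n_days)
    )
    d2H = (
        cfg.mwl_slope * d18O
        + cfg.mwl_intercept
        + rng.normal(0.0, cfg.precip_line_noise_d2H, cfg.n_days)
    )
    events = pd.DataFrame(
        {
            "date": dates[wet].date,
            "amount_mm": amounts[wet],
            "d18O_permil": d18O[wet],
            "d2H_permil": d2H[wet],
        }
    )
    daily = pd.Series(amounts, index=dates, name="precip_mm")
    return events, daily


# ----------------------------------------------------------------- soil column

def soil_composition_at_depth(
    cfg: ScenarioConfig, slope_position: SlopePosition, z_cm: float
) -> IsotopeComposition:
    """Noise-free bulk soil-water composition at depth ``z_cm``.

    Interpolates from the slope position's surface composition at 0 cm to
    groundwater at ``max_depth_cm`` — linearly, or with an exponential
    length scale (the seasonal damping picture).  An extra evaporative
    below-line δ²H displacement of ``evap_offset_permil`` at the surface
    decays *linearly* to zero at max depth, so a linear profile stays
    exactly linear.
    """
    if z_cm < 0:
        raise ValueError("depth must be non-negative")
    s = cfg.surface_composition[slope_position].as_array()
    g = cfg.groundwater_composition.as_array()
    zmax = cfg.max_depth_cm
    if cfg.profile_shape == "linear":
        frac = min(z_cm, zmax) / zmax
        comp = s + (g - s) * frac
    elif cfg.profile_shape == "exponential":
        w = np.exp(-z_cm / cfg.profile_length_scale_cm)
        comp = g + (s - g) * w
    else:
        raise ValueError(f"unknown profile shape {cfg.profile_shape!r}")
    evap = cfg.evap_offset_permil * max(0.0, 1.0 - z_cm / zmax)
    return IsotopeComposition(float(comp[0]), float(comp[1] - evap))


def generate_soil_and_groundwater(
    cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[list[WaterSample], list[WaterSample]]:
    """Bulk soil-water core samples (per slope position × site × depth) and
    repeated groundwater-well samples, with analytical noise."""
    rng = rng if rng is not None else _streams(cfg.seed)["soil"]
    date = cfg.start_date + dt.timedelta(days=cfg.n_days // 2)
    bulk: list[WaterSample] = []
    for pos in SlopePosition:
        for site in range(cfg.n_bulk_sites_per_position):
            for z in cfg.bulk_depths_cm:
                true = soil_composition_at_depth(cfg, pos, z)
                comp = IsotopeComposition(
                    true.d18O + rng.normal(0.0, cfg.noise_d18O),
                    true.d2H + rng.normal(0.0, cfg.noise_d2H),
                )
                bulk.append(
                    WaterSample(
                        sample_id=f"bulk-{pos.value}-{site}-{int(z)}",
                        source=Source.BULK_SOIL,
                        date=date,
                        composition=comp,
                        depth_cm=float(z),
                        slope_position=pos,
                    )
                )
    gw: list[WaterSample] = []
    g = cfg.groundwater_composition
    for k in range(cfg.n_gw_samples):
        comp = IsotopeComposition(
            g.d18O + rng.normal(0.0, cfg.gw_noise_d18O),
            g.d2H + rng.normal(0.0, cfg.gw_noise_d2H),
        )
        gw.append(
            WaterSample(
                sample_id=f"gw-{k}",
                source=Source.GROUNDWATER,
                date=cfg.start_date + dt.timedelta(days=k * max(cfg.n_days // max(cfg.n_gw_samples, 1), 1)),
                composition=comp,
            )
        )
    return bulk, gw


# ---------------------------------------------------------------------- trees

def _true_depths(cfg: ScenarioConfig, genera: list[str],
                 rng: np.random.Generator) -> np.ndarray:
    n = len(genera)
    if cfg.true_depth_model == "fixed":
        return np.full(n, cfg.true_depth_cm)
    if cfg.true_depth_model == "uniform_range":
        lo, hi = cfg.depth_range_cm
        return rng.uniform(lo, hi, n)
    if cfg.true_depth_model == "genus_shifted":
        base = np.array([cfg.genus_depth_cm[g] for g in genera])
        jitter = rng.normal(0.0, cfg.genus_depth_jitter_cm, n)
        return np.clip(base + jitter, 2.0, cfg.max_depth_cm - 2.0)
    raise ValueError(f"unknown true_depth_model {cfg.true_depth_model!r}")


def generate_trees(
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
    daily_precip: pd.Series | None = None,
) -> tuple[list[TreeRecord], pd.DataFrame]:
    """Trees with hidden true uptake depths and noisy xylem compositions.

    Each tree's xylem water is the soil water at its true depth for its slope
    position plus independent analytical noise.  When a daily precipitation
    series is given, sampling dates are drawn from days whose preceding two
    days total < 0.2 mm, so the default scenario survives dry-date filtering.
    """
    from .end_members import assign_slope_position
    from .soil_moisture import is_dry_date

    rng = rng if rng is not None else _streams(cfg.seed)["trees"]
    genera = list(GENUS_WEIGHTS)
    probs = np.array(list(GENUS_WEIGHTS.values()), dtype=float)
    probs /= probs.sum()
    tree_genera = [genera[i] for i in rng.choice(len(genera), cfg.n_trees, p=probs)]
    depths = _true_depths(cfg, tree_genera, rng)

    if daily_precip is not None:
        candidates = [
            d.date()
            for d in daily_precip.index[2:]
            if is_dry_date(daily_precip, d.date())
        ]
    else:
        candidates = []
    fallback = cfg.start_date + dt.timedelta(days=cfg.n_days // 2)

    trees: list[TreeRecord] = []
    rows = []
    for i, (genus, depth) in enumerate(zip(tree_genera, depths)):
        elev = rng.uniform(266.0, 300.0)
        pos = assign_slope_position(elev)
        true = soil_composition_at_depth(cfg, pos, float(depth))
        xylem = IsotopeComposition(
            true.d18O + rng.normal(0.0, cfg.noise_d18O),
            true.d2H + rng.normal(0.0, cfg.noise_d2H),
        )
        date = (
            candidates[int(rng.integers(len(candidates)))] if candidates else fallback
        )
        tid = f"T{i + 1:03d}"
        trees.append(
            TreeRecord(
                tree_id=tid,
                genus=genus,
                species=GENUS_SPECIES[genus],
                dbh_cm=float(max(rng.normal(GENUS_DBH_CM[genus], 6.0), 18.0)),
                height_m=float(max(rng.normal(GENUS_HEIGHT_M[genus], 3.0), 5.0)),
                elevation_m=float(elev),
                soil_depth_cm=float(np.clip(rng.normal(50.0, 20.0), 10.0, 140.0)),
                slope_position=pos,
                xylem=xylem,
                date=date,
            )
        )
        rows.append({"tree_id": tid, "true_depth_cm": float(depth)})
    return trees, pd.DataFrame(rows)


# --------------------------------------------------------------- field series

def generate_field_series(
    cfg: ScenarioConfig,
    daily_precip: pd.Series,
    rng: np.random.Generator | None = None,
) -> tuple[list[VWCProfile], list[SapFluxSeries]]:
    """Soil-moisture profiles and sap-flux series driven by the rain record.

    VWC at each sensor depth resets to a wet baseline on rain days and decays
    exponentially toward a residual during rain-free runs, faster near the
    surface.  Sap flux is a saturating function of a diurnal VPD cycle (with
    an amplified VPD ramp through the embedded dry run), down-regulated by
    shallow soil-moisture status with genus-specific sensitivity; nighttime
    VPD sits below the 0.1-kPa analysis floor.
    """
    rng = rng if rng is not None else _streams(cfg.seed)["field"]
    dates = daily_precip.index
    n = len(dates)
    rain = daily_precip.to_numpy() >= 0.2
    depths = np.asarray(cfg.sensor_depths_cm, dtype=float)
    rates = cfg.drydown_rate_surface * np.exp(-depths / cfg.drydown_rate_scale_cm)

    profiles: list[VWCProfile] = []
    shallow_rel = None
    for site in range(cfg.n_vwc_sites):
        base = 0.22 + 0.12 * np.minimum(depths, 100.0) / 100.0
        base = base + rng.normal(0.0, 0.01, depths.size)
        v = np.empty((n, depths.size))
        cur = base.copy()
        for t in range(n):
            if rain[t]:
                cur = base.copy()
            else:
                cur = cfg.vwc_residual + (cur - cfg.vwc_residual) * np.exp(-rates)
            v[t] = cur
        frame = pd.DataFrame(v, index=dates, columns=depths)
        profiles.append(VWCProfile(f"SM{site + 1}", depths, frame))
        if shallow_rel is None:
            sh = depths < 40.0
            drain = base[sh] - cfg.vwc_residual
            shallow_rel = ((v[:, sh] - cfg.vwc_residual) / drain).mean(axis=1)

    # daily peak VPD: modest baseline, suppressed on rain days, ramping +~34%
    # through the embedded dry run
    peak = np.full(n, 0.9)
    peak[rain] = 0.45
    i0, i1 = cfg.dry_run_start_day, cfg.dry_run_start_day + cfg.dry_run_days
    ramp = np.linspace(0.9, 1.2, max(i1 - i0, 1))
    peak[i0:i1] = ramp[: i1 - i0]

    hours = np.arange(24)
    diurnal = np.clip(np.sin(np.pi * (hours - 6) / 14.0), 0.0, None)
    ts = pd.DatetimeIndex(
        np.repeat(dates.values, 24) + np.tile(hours, n) * np.timedelta64(1, "h")
    )
    vpd_grid = np.outer(peak, diurnal) + 0.02

    flux_series: list[SapFluxSeries] = []
    k = 0
    for genus, count in cfg.sapflux_trees.items():
        sens = cfg.soil_sensitivity.get(genus, 0.0)
        for _ in range(count):
            k += 1
            moist = 1.0 - sens * (1.0 - shallow_rel)
            fl = (
                cfg.jmax
                * (1.0 - np.exp(-vpd_grid / cfg.vpd_halfsat_kpa))
                * moist[:, None]
            )
            frame = pd.DataFrame(
                {"flux": fl.ravel(), "vpd_kpa": vpd_grid.ravel()}, index=ts
            )
            flux_series.append(SapFluxSeries(f"SF{k:02d}", genus, frame))
    return profiles, flux_series


# ----------------------------------------------------------------- whole world

def generate_catchment(
    cfg: ScenarioConfig, include_field_series: bool = True
) -> SyntheticCatchment:
    """Generate the full scenario from one seed (bit-for-bit reproducible)."""
    rngs = _streams(cfg.seed)
    events, daily = generate_precip(cfg, rngs["precip"])
    bulk, gw = generate_soil_and_groundwater(cfg, rngs["soil"])
    trees, truth = generate_trees(cfg, rngs["trees"], daily_precip=daily)
    if include_field_series:
        vwc, sap = generate_field_series(cfg, daily, rngs["field"])
    else:
        vwc, sap = [], []
    return SyntheticCatchment(
        config=cfg,
        precip_events=events,
        daily_precip=daily,
        bulk_soil=bulk,
        groundwater=gw,
        trees=trees,
        truth=truth,
        vwc=vwc,
        sapflux=sap,
    )
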