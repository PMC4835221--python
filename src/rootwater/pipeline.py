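"""End-to-end orchestration: simulate or ingest, derive end members, run the
mixing model (120-cm and 30-cm variants), and attach the soil-moisture and
sap-flux dry-cycle diagnostics, all from one config and one seed."""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__, io
from .end_members import CATCHMENT, build_end_member_sets
from .isotope import IsotopeComposition, SlopePosition, Source, fit_meteoric_line
from .mixing import grand_mean_ci, run_mixing
from .sap_flux import dry_cycle_response
from .soil_moisture import (
    DEFAULT_MIN_DRY_DAYS,
    DEFAULT_RAIN_THRESHOLD_MM,
    DEFAULT_SPLIT_CM,
    detect_dry_cycles,
    is_dry_date,
    storage_depletion,
)
from .synthetic import ScenarioConfig, generate_catchment

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)

RESTRICTED_MAX_DEPTH_CM = 30.0


def _scenario_from_config(cfg: Mapping[str, Any], seed: int | None) -> ScenarioConfig:
    kw = dict(cfg.get("scenario", {}))
    if seed is not None:
        kw["seed"] = seed
    if "surface_composition" in kw:
        kw["surface_composition"] = {
            SlopePosition(k): IsotopeComposition(*v)
            for k, v in kw["surface_composition"].items()
        }
    if "groundwater_composition" in kw:
        kw["groundwater_composition"] = IsotopeComposition(
            *kw["groundwater_composition"]
        )
    return ScenarioConfig(**kw)


def _summarize(results, level, method, max_depth, seed):
    mean, lo, hi = grand_mean_ci(
        results, level=level, method=method, max_depth_cm=max_depth, seed=seed
    )
    return {
        "grand_mean_cm": mean,
        "ci_lower_cm": lo,
        "ci_upper_cm": hi,
        "level": level,
        "method": method,
        "max_depth_cm": max_depth,
        "n_trees": len({r.tree_id for r in results}),
        "n_observations": len(results),
        "n_clamped": int(sum(r.clamped for r in results)),
    }


def run_pipeline(
    config: Mapping[str, Any] | str | Path,
    out: str | Path | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Run every stage in fixed order and return the machine-readable report.

    ``config`` is a mapping (or a path to a YAML file) with either a
    ``scenario`` section (synthetic run) or input CSV paths
    (``water_samples``, ``trees``, ``precip_daily``, ``soil_moisture``,
    ``sap_flux``).  When ``out`` is given, per-stage CSVs and the report
    JSON are written there.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text()) or {}
    level = float(config.get("ci_level", 0.95))
    ci_method = str(config.get("ci_method", "t"))
    rain_threshold = float(config.get("rain_threshold_mm", DEFAULT_RAIN_THRESHOLD_MM))
    min_dry_days = int(config.get("min_dry_days", DEFAULT_MIN_DRY_DAYS))
    split_cm = float(config.get("split_cm", DEFAULT_SPLIT_CM))

    outdir = Path(out) if out is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------ inputs
    if "scenario" in config or not config.get("water_samples"):
        scen = _scenario_from_config(config, seed)
        catchment = generate_catchment(scen)
        logger.info("simulated catchment: seed=%d, %d trees", scen.seed, scen.n_trees)
        precip = [
            s
            for s in _precip_samples(catchment)
        ]
        bulk = catchment.bulk_soil
        gw = catchment.groundwater
        trees = catchment.trees
        daily_precip = catchment.daily_precip
        vwc = catchment.vwc
        sap = catchment.sapflux
        used_seed = scen.seed
        if outdir is not None:
            io.write_catchment_bundle(catchment, outdir / "inputs")
    else:
        samples = io.read_water_samples(config["water_samples"])
        precip = [s for s in samples if s.source == Source.PRECIPITATION]
        bulk = [s for s in samples if s.source == Source.BULK_SOIL]
        gw = [s for s in samples if s.source == Source.GROUNDWATER]
        trees = io.read_trees(config["trees"])
        daily_precip = (
            io.read_precip_daily(config["precip_daily"])
            if config.get("precip_daily")
            else None
        )
        vwc = (
            io.read_vwc_profiles(config["soil_moisture"])
            if config.get("soil_moisture")
            else []
        )
        sap = io.read_sapflux(config["sap_flux"]) if config.get("sap_flux") else []
        used_seed = seed

    # ----------------------------------------------------- meteoric line
    lmwl = None
    if len(precip) >= 2 and all(s.amount_mm is not None for s in precip):
        line = fit_meteoric_line(precip, weighted=True)
        lmwl = {"slope": line.slope, "intercept": line.intercept, "weighted": True}

    # ------------------------------------------------------- end members
    end_members = build_end_member_sets(bulk, gw)
    logger.info("end members for %d slope positions", len(end_members) - 1)
    if outdir is not None:
        io.write_end_members(end_members, outdir / "end_members.csv")

    # ------------------------------------------------- dry-date filtering
    n_total = len(trees)
    if daily_precip is not None:
        trees_used = [t for t in trees if is_dry_date(daily_precip, t.date)]
        logger.info("dry-date filter kept %d / %d trees", len(trees_used), n_total)
        if not trees_used:
            logger.warning("no tree dates pass the dry-date rule; using all dates")
            trees_used = list(trees)
    else:
        logger.info("no precipitation record; using all %d tree dates", n_total)
        trees_used = list(trees)

    # ------------------------------------------------------------ mixing
    results_120 = run_mixing(trees_used, end_members, max_depth_cm=120.0)
    results_30 = run_mixing(
        trees_used, end_members, max_depth_cm=RESTRICTED_MAX_DEPTH_CM
    )
    summary_120 = _summarize(results_120, level, ci_method, 120.0, used_seed)
    summary_30 = _summarize(
        results_30, level, ci_method, RESTRICTED_MAX_DEPTH_CM, used_seed
    )
    if outdir is not None:
        io.write_mixing_results(results_120, outdir / "mixing_120cm.csv")
        io.write_mixing_results(results_30, outdir / "mixing_30cm.csv")

    # -------------------------------------------- soil moisture diagnostics
    cycles = (
        detect_dry_cycles(daily_precip, min_days=min_dry_days,
                          rain_threshold_mm=rain_threshold)
        if daily_precip is not None
        else []
    )
    logger.info("detected %d dry cycles", len(cycles))
    depletion = []
    for cycle in cycles:
        for prof in vwc:
            try:
                shallow, deep = storage_depletion(prof, cycle, split_cm=split_cm)
            except ValueError:
                continue
            depletion.append(
                {
                    "site_id": prof.site_id,
                    "start": cycle.start_date.isoformat(),
                    "end": cycle.end_date.isoformat(),
                    "length_days": cycle.length_days,
                    "shallow_mm": shallow,
                    "deep_mm": deep,
                }
            )

    # ------------------------------------------------ sap flux diagnostics
    responses = []
    for cycle in cycles:
        for s in sap:
            try:
                r = dry_cycle_response(s, cycle, precip=daily_precip)
            except ValueError:
                continue
            responses.append(
                {
                    "tree_id": r.tree_id,
                    "genus": s.genus,
                    "start": cycle.start_date.isoformat(),
                    "end": cycle.end_date.isoformat(),
                    "start_mean": r.start_mean,
                    "end_mean": r.end_mean,
                    "pct_change": r.pct_change,
                }
            )
    genus_response = (
        pd.DataFrame(responses).groupby("genus")["pct_change"].mean().to_dict()
        if responses
        else {}
    )

    report = {
        "software_version": __version__,
        "seed": used_seed,
        "generated": dt.datetime.now().isoformat(timespec="seconds"),
        "n_trees_input": n_total,
        "n_trees_used": len(trees_used),
        "lmwl": lmwl,
        "end_members": {
            (k.value if isinstance(k, SlopePosition) else str(k)): {
                "surface": [v.surface.d18O, v.surface.d2H],
                "groundwater": [v.groundwater.d18O, v.groundwater.d2H],
            }
            for k, v in end_members.items()
        },
        "rooting_depth_120cm": summary_120,
        "rooting_depth_30cm": summary_30,
        "dry_cycles": [
            {
                "start": c.start_date.isoformat(),
                "end": c.end_date.isoformat(),
                "length_days": c.length_days,
            }
            for c in cycles
        ],
        "storage_depletion": depletion,
        "sap_flux_response_by_genus": genus_response,
    }
    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        if depletion:
            pd.DataFrame(depletion).to_csv(outdir / "storage_depletion.csv", index=False)
        if responses:
            pd.DataFrame(responses).to_csv(outdir / "sap_flux_response.csv", index=False)
    return report


def _precip_samples(catchment):
    from .isotope import WaterSample

    for i, row in catchment.precip_events.iterrows():
        yield WaterSample(
            sample_id=f"P{i:03d}",
            source=Source.PRECIPITATION,
            date=row["date"],
            composition=IsotopeComposition(row["d18O_permil"], row["d2H_permil"]),
            amount_mm=float(row["amount_mm"]),
        )
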