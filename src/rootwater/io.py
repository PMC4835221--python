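"""CSV schemas for every observation stream.

Water samples:  sample_id, source, date (ISO-8601), depth_cm, slope_position,
                d18O_permil, d2H_permil, amount_mm  (blank = absent)
Trees:          tree_id, genus, species, dbh_cm, height_m, elevation_m,
                soil_depth_cm, slope_position, date, d18O_permil, d2H_permil
End members:    slope_position, surface_d18O, surface_d2H, gw_d18O, gw_d2H,
                max_depth_cm
Soil moisture:  long format site_id, sensor_depth_cm, timestamp, vwc
Daily precip:   date, precip_mm
Sap flux:       tree_id, genus, timestamp, flux, vpd_kpa
Root cores:     site_id, slope_position, core_id, depth_top_cm,
                depth_bottom_cm, root_length_cm, core_radius_cm
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .end_members import CATCHMENT, EndMemberSet, assign_slope_position
from .isotope import IsotopeComposition, SlopePosition, Source, WaterSample
from .mixing import MixingResult, TreeRecord
from .roots import RootCoreSample
from .sap_flux import SapFluxSeries
from .soil_moisture import VWCProfile
from .synthetic import SyntheticCatchment

__all__ = [
    "read_end_members",
    "read_precip_daily",
    "read_root_cores",
    "read_sapflux",
    "read_trees",
    "read_vwc_profiles",
    "read_water_samples",
    "write_catchment_bundle",
    "write_end_members",
    "write_mixing_results",
    "write_water_samples",
]


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def _pos(value) -> SlopePosition | None:
    if pd.isna(value) or value == "":
        return None
    return SlopePosition(value)


def _err(path, row, col, exc) -> ValueError:
    return ValueError(f"{path}: row {row}, column {col!r}: {exc}")


def read_water_samples(path: str | Path) -> list[WaterSample]:
    df = pd.read_csv(path)
    required = {"sample_id", "source", "date", "d18O_permil", "d2H_permil"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                WaterSample(
                    sample_id=str(row["sample_id"]),
                    source=Source(row["source"]),
                    date=dt.date.fromisoformat(str(row["date"])),
                    composition=IsotopeComposition(
                        float(row["d18O_permil"]), float(row["d2H_permil"])
                    ),
                    depth_cm=_opt(row.get("depth_cm")),
                    slope_position=_pos(row.get("slope_position")),
                    amount_mm=_opt(row.get("amount_mm")),
                )
            )
        except (ValueError, KeyError) as exc:
            raise _err(path, i, "water_sample", exc) from exc
    return out


def write_water_samples(samples: Iterable[WaterSample], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "source": s.source.value,
            "date": s.date.isoformat(),
            "depth_cm": s.depth_cm,
            "slope_position": s.slope_position.value if s.slope_position else None,
            "d18O_permil": s.composition.d18O,
            "d2H_permil": s.composition.d2H,
            "amount_mm": s.amount_mm,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trees(path: str | Path) -> list[TreeRecord]:
    df = pd.read_csv(path)
    out = []
    for i, row in df.iterrows():
        try:
            pos = _pos(row.get("slope_position"))
            if pos is None:
                pos = assign_slope_position(float(row["elevation_m"]))
            out.append(
                TreeRecord(
                    tree_id=str(row["tree_id"]),
                    genus=str(row["genus"]),
                    species=str(row.get("species", "")),
                    dbh_cm=float(row["dbh_cm"]),
                    height_m=_opt(row.get("height_m")),
                    elevation_m=float(row["elevation_m"]),
                    soil_depth_cm=_opt(row.get("soil_depth_cm")),
                    slope_position=pos,
                    xylem=IsotopeComposition(
                        float(row["d18O_permil"]), float(row["d2H_permil"])
                    ),
                    date=dt.date.fromisoformat(str(row["date"])),
                )
            )
        except (ValueError, KeyError) as exc:
            raise _err(path, i, "tree", exc) from exc
    return out


def write_trees(trees: Iterable[TreeRecord], path: str | Path) -> None:
    rows = [
        {
            "tree_id": t.tree_id,
            "genus": t.genus,
            "species": t.species,
            "dbh_cm": t.dbh_cm,
            "height_m": t.height_m,
            "elevation_m": t.elevation_m,
            "soil_depth_cm": t.soil_depth_cm,
            "slope_position": t.slope_position.value,
            "date": t.date.isoformat(),
            "d18O_permil": t.xylem.d18O,
            "d2H_permil": t.xylem.d2H,
        }
        for t in trees
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_end_members(
    sets: Mapping[SlopePosition | str, EndMemberSet], path: str | Path
) -> None:
    rows = []
    for key, em in sets.items():
        tag = key.value if isinstance(key, SlopePosition) else str(key)
        rows.append(
            {
                "slope_position": tag,
                "surface_d18O": em.surface.d18O,
                "surface_d2H": em.surface.d2H,
                "gw_d18O": em.groundwater.d18O,
                "gw_d2H": em.groundwater.d2H,
                "max_depth_cm": em.max_depth_cm,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_end_members(path: str | Path) -> dict[SlopePosition | str, EndMemberSet]:
    df = pd.read_csv(path)
    sets: dict[SlopePosition | str, EndMemberSet] = {}
    for i, row in df.iterrows():
        try:
            tag = str(row["slope_position"])
            key: SlopePosition | str = (
                CATCHMENT if tag == CATCHMENT else SlopePosition(tag)
            )
            sets[key] = EndMemberSet(
                slope_position=key,
                surface=IsotopeComposition(
                    float(row["surface_d18O"]), float(row["surface_d2H"])
                ),
                groundwater=IsotopeComposition(
                    float(row["gw_d18O"]), float(row["gw_d2H"])
                ),
                max_depth_cm=float(row["max_depth_cm"]),
            )
        except (ValueError, KeyError) as exc:
            raise _err(path, i, "end_member", exc) from exc
    return sets


def write_mixing_results(results: Sequence[MixingResult], path: str | Path) -> None:
    rows = [
        {
            "tree_id": r.tree_id,
            "date": r.date.isoformat() if r.date else None,
            "d_sg_permil": r.d_sg,
            "d_st_permil": r.d_st,
            "p_g": r.p_g,
            "dw_cm": r.dw_cm,
            "clamped": r.clamped,
            "end_members_used": (
                r.end_members_used.value
                if isinstance(r.end_members_used, SlopePosition)
                else str(r.end_members_used)
            ),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_precip_daily(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, parse_dates=["date"])
    s = pd.Series(df["precip_mm"].to_numpy(dtype=float), index=df["date"])
    return s.sort_index()


def read_vwc_profiles(path: str | Path) -> list[VWCProfile]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    profiles = []
    for site_id, grp in df.groupby("site_id", sort=True):
        wide = grp.pivot_table(
            index="timestamp", columns="sensor_depth_cm", values="vwc"
        ).sort_index()
        depths = np.array(sorted(wide.columns), dtype=float)
        wide = wide[depths]
        wide.columns = depths
        profiles.append(VWCProfile(str(site_id), depths, wide))
    return profiles


def read_sapflux(path: str | Path) -> list[SapFluxSeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for (tree_id, genus), grp in df.groupby(["tree_id", "genus"], sort=True):
        frame = grp.set_index("timestamp")[["flux", "vpd_kpa"]].sort_index()
        out.append(SapFluxSeries(str(tree_id), str(genus), frame))
    return out


def read_root_cores(path: str | Path) -> list[RootCoreSample]:
    df = pd.read_csv(path)
    out = []
    for i, row in df.iterrows():
        try:
            cid = row.get("core_id")
            out.append(
                RootCoreSample(
                    site_id=str(row["site_id"]),
                    slope_position=_pos(row.get("slope_position")),
                    core_id=None if pd.isna(cid) else str(cid),
                    depth_top_cm=float(row["depth_top_cm"]),
                    depth_bottom_cm=float(row["depth_bottom_cm"]),
                    root_length_cm=float(row["root_length_cm"]),
                    core_radius_cm=float(row["core_radius_cm"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise _err(path, i, "root_core", exc) from exc
    return out


def write_catchment_bundle(catchment: SyntheticCatchment, outdir: str | Path) -> None:
    """Write every generated table of a synthetic catchment as CSV."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ev = catchment.precip_events
    precip_samples = [
        WaterSample(
            sample_id=f"P{i:03d}",
            source=Source.PRECIPITATION,
            date=row["date"],
            composition=IsotopeComposition(row["d18O_permil"], row["d2H_permil"]),
            amount_mm=float(row["amount_mm"]),
        )
        for i, row in ev.iterrows()
    ]
    write_water_samples(
        precip_samples + catchment.bulk_soil + catchment.groundwater,
        out / "water_samples.csv",
    )
    write_trees(catchment.trees, out / "trees.csv")
    catchment.truth.to_csv(out / "truth.csv", index=False)
    pd.DataFrame(
        {
            "date": catchment.daily_precip.index.date,
            "precip_mm": catchment.daily_precip.to_numpy(),
        }
    ).to_csv(out / "precip_daily.csv", index=False)
    vwc_rows = []
    for prof in catchment.vwc:
        long = prof.series.stack()
        for (ts, depth), v in long.items():
            vwc_rows.append(
                {
                    "site_id": prof.site_id,
                    "sensor_depth_cm": depth,
                    "timestamp": ts,
                    "vwc": v,
                }
            )
    if vwc_rows:
        pd.DataFrame(vwc_rows).to_csv(out / "soil_moisture.csv", index=False)
    sap_rows = []
    for s in catchment.sapflux:
        frame = s.series.reset_index(names="timestamp")
        frame.insert(0, "tree_id", s.tree_id)
        frame.insert(1, "genus", s.genus)
        sap_rows.append(frame)
    if sap_rows:
        pd.concat(sap_rows).to_csv(out / "sap_flux.csv", index=False)
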