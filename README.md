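# rootwater

Effective rooting depth of forest trees from dual water isotopes.

`rootwater` is for ecohydrologists and plant ecophysiologists who want to
infer **where in the soil column trees take up water** from natural-
abundance stable isotopes (δ¹⁸O, δ²H) of precipitation, soil water,
groundwater and tree xylem water — and to corroborate the inference with
soil-moisture depletion and sap-flux behaviour over rain-free periods.

## The model

Every water sample is a point in dual-isotope space. Two end members frame
the mixing geometry: the **surface soil water** *s* (the 0-cm intercept of
per-isotope regressions of bulk soil-water δ against depth, per slope
position) and the **groundwater** mean *g*. For a tree's xylem water *t*,
with Euclidean distances D in (δ¹⁸O, δ²H) space,

    P_g = D(s,t) / D(s,g)        (groundwater fraction)
    DW  = P_g × 120 cm           (effective rooting depth)

A 30-cm restricted variant (`max_depth_cm=30`) limits the model to the
sampled soil column. Grand means over trees get a Student-t (or seeded
bootstrap) confidence interval truncated to the physical range. Supporting
modules handle the amount-weighted local meteoric water line, slope-position
assignment from elevation, dry-date selection (< 0.2 mm rain in the two
preceding days), dry-cycle detection (≥ 5 rain-free days), midpoint-weighted
soil-water storage and its shallow/deep depletion partition, VPD-filtered
sap-flux daily means and crown conductance, and root-length density
profiles. A seeded synthetic catchment with known true uptake depths makes
every stage testable end-to-end. See `docs/methods.md` for the full account.

## Worked example

The catchment-mean compositions (‰ VSMOW) — tree xylem water on dry dates
(−5.4, −42.7), shallow 10-cm bulk soil water (−6.2, −45.6) as the surface
end member, and groundwater (−8.6, −54.6):

```python
from rootwater import EndMemberSet, IsotopeComposition
from rootwater.mixing import groundwater_fraction, effective_rooting_depth

surface = IsotopeComposition(-6.2, -45.6)
groundwater = IsotopeComposition(-8.6, -54.6)
tree = IsotopeComposition(-5.4, -42.7)

em = EndMemberSet("catchment", surface, groundwater, max_depth_cm=120)
p_g, clamped = groundwater_fraction(em, tree)
print(f"P_g = {p_g:.4f}, DW = {effective_rooting_depth(p_g, 120):.1f} cm")
```

prints

```
P_g = 0.3230, DW = 38.8 cm
```

i.e. the average tree water looks like a ~32% groundwater mixture, an
effective uptake depth of ~39 cm — shallow water dominates.

## An end-to-end synthetic run

The `analysis/` scripts are a numbered narrative over the same library:
simulate a catchment, fit the meteoric line, derive end members, run the
mixing model, and check the soil-moisture and sap-flux diagnostics.

```bash
python analysis/01_simulate_catchment.py --seed 0
python analysis/02_meteoric_line.py
python analysis/03_end_members.py
python analysis/04_rooting_depth.py
python analysis/05_soil_moisture.py
python analysis/06_sap_flux.py
python analysis/07_root_profiles.py
```

With seed 0 (60 trees whose true uptake depth is 40 cm, analytical noise
0.12/0.80 ‰) this prints, among other things:

```
weighted LMWL over 71 events: d2H = 8.44 d18O + 16.28
max depth 120 cm: grand mean  32.6 cm (95% CI 30.4-34.8)
max depth  30 cm: grand mean   8.1 cm (95% CI 7.6-8.7)
recovery vs truth: mean error -7.44 cm, RMSE 11.23 cm
longest cycle (12 d starting 2009-06-15): site means shallow 14.8 mm, deep 4.0 mm
  Acer     mean increase of   1.9% start-to-end
  Quercus  mean decline of  12.7% start-to-end
```

The grand mean sits a few cm below truth here because the surface end
members are themselves estimated from noisy bulk profiles — a shared error
source the t-interval cannot see (discussed in `docs/methods.md`). Tables
land under `results/`. The same stages are available as a CLI
(`rootwater simulate|endmembers|mix|soil|sapflux|roots|run`), e.g.

```bash
rootwater run --seed 0 --out results/full_run
```

## Acceptance script

`scripts/acceptance.py` recomputes the worked-example effective rooting
depth from scratch — building the end-member set from the catchment-mean
compositions and running the mixing model — and writes the targets as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
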