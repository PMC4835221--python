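# Methods

## The model

Tree xylem water carries the isotopic signature of the soil depths the tree
draws from. In a catchment where shallow soil water is enriched in heavy
isotopes (summer precipitation plus evaporative enrichment) and deep soil
water converges on the groundwater signature, the depth of water uptake can
be read off from where the xylem composition falls between two end members
in (δ¹⁸O, δ²H) space:

- **surface end member** *s*: the soil-water composition extrapolated to
  0 cm depth — the y-intercept of per-isotope ordinary least-squares
  regressions of bulk soil-water δ¹⁸O and δ²H on sampling depth, fitted per
  slope position (valley / midslope / ridge, assigned from elevation bands);
- **groundwater end member** *g*: the unweighted mean groundwater
  composition over the study period.

With Euclidean distances in dual-isotope space,
D(s,g) between the end members and D(s,t) from surface to tree water *t*,
the groundwater fraction is

    P_g = D(s,t) / D(s,g)

and the effective rooting depth is DW = P_g × z_max with z_max = 120 cm
(deep soil water approaches the groundwater signature there). A restricted
variant uses z_max = 30 cm, the bottom of the sampled soil column, which by
construction scales every depth by 1/4.

### Assumptions and their consequences

- The soil-water profile is treated as **linear in depth** between the two
  end members. If the true profile is curved (e.g. exponential damping of
  the seasonal signal), the inferred depth is biased; the synthetic
  generator's `profile_shape="exponential"` option exists to demonstrate
  this, and only monotonicity — not unbiasedness — holds there.
- P_g is a **ratio of unsigned distances**, exactly as the model is defined.
  Off the s–g segment it is not an orthogonal projection: a tree *more
  enriched* than the surface end member still has positive D(s,t) and maps
  to a positive fraction (the catchment-mean worked example is such a
  point, giving P_g ≈ 0.32 and DW ≈ 38.8 cm). The raw ratio therefore can
  never be negative; values above 1 (tree beyond groundwater) are clamped
  to 1 with a flag.
- δ¹⁸O and δ²H enter the distance with **equal weight** despite their ~8×
  scale difference, following the model's definition; no standardisation is
  applied, so δ²H differences dominate the geometry in practice.

### Summary statistics

One depth per tree (observations on multiple dates averaged first), then a
grand mean with a two-sided Student-t confidence interval, truncated to the
physical range [0, z_max]. The t-interval is a package choice — no method
is prescribed by the model — and a seeded percentile bootstrap
(2,000 resamples) is available behind `method="bootstrap"`. With very small
n the 95% t-interval can exceed the physical range; truncation then makes
it asymmetric by design.

When a daily precipitation record is available, tree sampling dates are
filtered to **dry dates**: summed rainfall of the two preceding calendar
days < 0.2 mm. The wording "less than 0.2 mm in the preceding 2 days" is
ambiguous between a per-day and a summed rule; the summed rule is stricter
and is what is implemented.

## Corroborating diagnostics

**Soil moisture.** Storage over a sensor profile is Σ VWC_i × Δz_i × 10 mm,
with layer boundaries at midpoints between sensor depths; the first layer
starts at the surface and the deepest extends half the last inter-sensor
spacing below the deepest sensor (no deeper information exists). A dry
cycle is a maximal run of ≥ 5 days with daily rainfall < 0.2 mm (reusing
the dry-date threshold as the only printed rain threshold). Depletion over
a cycle is start-minus-end storage, partitioned at 40 cm; boundary readings
are the first and last readings inside the cycle's calendar span, so the
rewetting that terminates a cycle never contaminates the end reading.
Relative VWC normalises each sensor's daily maximum by its study-period
maximum.

**Sap flux.** Daily means are taken over the 7 am–7 pm local-clock window
after excluding records with VPD < 0.1 kPa; a day with no surviving
records is missing, never zero. Percent-of-maximum normalisation is over
the dry-cycle window per tree. Crown conductance is daily flux / daily
daytime VPD (an index; raw flux units are instrument-dependent and every
comparison is relative, so the module is unit-agnostic). The dry-cycle
response compares the mean of the first two usable days with the last two,
as percent change on the start-of-cycle base; days with rain inside the
window are omitted first when a precipitation record is supplied.

**Root profiles.** Per-volume density divides increment root length by core
volume (π r² × thickness); per-area totals sum a core's increments over its
cross-section and average replicate cores; cumulative fractions pro-rate
partial increments assuming uniform density within an increment.
Open-ended bottom increments must carry the depth of refusal as their
bottom boundary.

## The synthetic catchment

The generator emulates the structure the pipeline consumes, not the physics
behind it (no infiltration or isotope-transport modelling):

- **Precipitation**: Bernoulli rain days (p = 0.35) with gamma-distributed
  amounts (mean 8 mm; ~1000 mm yr⁻¹ equivalent), event δ¹⁸O on a seasonal
  sinusoid (mean −9 ‰, amplitude 3 ‰, summer-enriched) and δ²H scattered
  about the configured meteoric line (slope 8.4, intercept 15.8). A
  rain-free run of configurable length (default 6 days) is embedded and
  bounded by forced rain days.
- **Soil water**: compositions interpolate from a per-slope-position
  surface composition at 0 cm to groundwater (−8.6, −54.6) ‰ at 120 cm.
  The default surface anchor (−6.2, −45.6) ‰ is the shallow bulk soil-water
  mean, which already sits ~9 ‰ below the meteoric line, so the evaporative
  signal is embedded in the anchor; the separate `evap_offset_permil`
  (default 0) adds an extra below-line δ²H displacement decaying *linearly*
  to zero at 120 cm — linear rather than exponential so that the composite
  linear profile stays exactly linear and the zero-noise inversion remains
  exact.
- **Trees**: true uptake depths from a fixed value (default 40 cm), a
  uniform range, or genus-shifted means; xylem composition is the soil
  water at the true depth plus independent Gaussian analytical noise with
  σ = 0.12 ‰ (δ¹⁸O) and 0.80 ‰ (δ²H), the long-term external precision of
  cryogenic extraction + IRMS. Covariates (genus mix 13/8/8/31 for
  Acer/Carya/Pinus/Quercus, DBH, height, elevation) are drawn from ranges
  consistent with the study stand. Sampling dates are drawn from dry dates.
- **Field series**: VWC resets to a wet baseline on rain days and decays
  toward a residual during dry runs at a rate that e-folds with depth
  (surface rate 0.06 d⁻¹, length scale 20 cm — chosen so a one-week dry
  cycle depletes ~8–12 mm above 40 cm and ~2–4 mm below, the observed
  shallow-dominant partition). Sap flux is a saturating function of a
  diurnal VPD cycle (VPD ramps ~+34% through the embedded dry run),
  down-regulated by shallow soil-moisture status with genus-specific
  sensitivity (Acer 0, Quercus 0.85, Pinus 0.95); nights sit below the
  0.1-kPa VPD floor so the exclusion rule is exercised daily.

Random streams are partitioned per generator from a single seed
(`numpy` `SeedSequence.spawn`), so tables are bit-for-bit reproducible and
changing one generator's demands does not perturb another's draws.

### What a green parameter-recovery test establishes — and what it does not

The recovery experiment (60 trees, true depth 40 cm, default analytical
noise, 200 seeded replicates) measures the estimator's behaviour **given
the true end-member geometry**: end members are fitted from noise-free bulk
profiles (an exact round-trip), so replicate-to-replicate error reflects
xylem analytical noise alone (per-tree depth s.d. ≈ 11 cm, grand-mean
s.e. ≈ 1.4 cm). When the bulk samples carry the same analytical noise, the
fitted surface intercepts acquire a shared per-replicate error that shifts
the whole grand mean by ≈ 3.4 cm s.d. — and because that error is common to
all trees in a replicate, the t-interval (which sees only between-tree
spread) does not cover it: measured coverage drops to ~56%. Real-data
intervals therefore understate uncertainty from end-member estimation; a
green recovery test does not certify otherwise. The generator also does not
emulate: multiple isotopically distinct soil-water pools (bulk vs mobile),
within-tree heterogeneity, instrument drift, or data gaps.

## Numerical choices

- Weighted meteoric-line fits use weights proportional to event amount
  (statsmodels WLS); missing amounts in a weighted fit are a hard error.
- Seasonal precipitation averages use meteorological quarters
  (DJF/MAM/JJA/SON).
- Elevation bands are closed with midpoint cut-offs (268.5 m, 291.5 m)
  because the surveyed bands leave 1-m gaps; out-of-survey elevations are
  clamped into the nearest band with a logged warning.
- Implausible isotope values (outside −50…+20 ‰ δ¹⁸O, −400…+100 ‰ δ²H)
  warn but do not raise; non-finite values raise.
- Degenerate geometry (coincident end members), degenerate fits (a single
  depth or identical δ¹⁸O values) and empty aggregations raise `ValueError`
  rather than returning NaN.

## Known limitations

- The mixing model is strictly two-end-member; no Bayesian multi-source
  partitioning.
- Fall-season precipitation outliers (e.g. a single early snowstorm) are
  not specially handled.
- Bulk-soil regressions pool all sites within a slope position rather than
  fitting site-wise and averaging; with few sites the intercept is
  sensitive to single cores.
- The 30-cm variant is a pure rescaling of P_g, not a re-derivation of the
  surface end member from a 30-cm profile.
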