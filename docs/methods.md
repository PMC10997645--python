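# Methods

This note documents the models and procedures `ozoneyield` implements, the
defaults it ships, the choices made where the design was genuinely open, and
what its synthetic fixtures do and do not establish about real data.

## Exposure metric

The dose metric is POD₃IAM: phytotoxic ozone dose above a stomatal-flux
threshold of 3 nmol m⁻² s⁻¹, parameterised for integrated-assessment
modelling (a vegetation-type rather than species-specific flux model), in
mmol m⁻² accumulated.  The package consumes *daily POD increments*
(mmol m⁻² d⁻¹) as its primary input, as produced by a chemical-transport
model with an embedded stomatal-conductance scheme.  It deliberately does
not model stomatal conductance itself (light/temperature/VPD/soil-moisture
multipliers): pretending to re-derive the flux from concentration would
misrepresent the provenance of the input.  A convenience path integrates
hourly flux over the threshold — per cell and day,
Σ max(flux − 3, 0) × 3600 × 10⁻⁶ — for callers who have hourly flux; any
daylight-hours masking is left to the caller, since conventions differ
between producers of flux data.

Seasonal dose is the inclusive sum over fixed Julian day-of-year windows,
each 90 days: 91–180 (April–June, season 1), 257–346 (mid-September to
mid-December, season 2) and 182–271 (July–September) for the unimodal
sub-region.  Fixed day-of-year windows are kept as-is in leap years.
Missing days inside a window are an error by default; `skip` and `scale`
(rescale the partial sum by 90/valid-days) policies are available but must
be requested explicitly, so silent under-accumulation cannot happen.

Only the non-irrigated dose pathway is represented: irrigation raises ozone
uptake, but the assessed system is overwhelmingly rainfed.  An irrigated
cube can be assessed as a second run; it is not a code path.

## Flux–effect relationship

Experimental (dose, relative-yield) points are fitted with

    relative_yield = intercept + b · POD,  sd(ε_i) = σ · POD_i^δ

δ is profiled over the grid {0, 0.25, …, 2} by maximising the Gaussian
likelihood; at each candidate δ the line is a weighted least-squares fit
(weights POD⁻²ᵟ, zero-dose points given the weight of the smallest positive
dose).  The power law is the standard way to encode variance growing with
dose; the exact variance structure is not identifiable from small
experiments, so the selected δ is recorded in the model metadata rather than
asserted as a property of the data.  Reported intervals and p-values are
conditional on the selected δ; Monte-Carlo checks in the test suite show
~95% coverage of the slope CI under a noise law (sd = 2 + 0.5·dose) that is
deliberately *not* a pure power law.

Risk is quantified with the slope only:

    %YL = slope × max(POD − POD_ref, 0),  capped at 99.9%

Zero exposure is anchored to zero effect; the intercept's CI should bracket
100 in a well-behaved experiment and the intercept is not used.  The shipped
bean default is slope 1.175 % per mmol m⁻², intercept 100, reference dose 0
(a constant 10 ppb reference atmosphere over 90 days drives no flux over the
3 nmol m⁻² s⁻¹ threshold).  The default model is *constructed* from these
published constants, not refit: the underlying experimental points are not
distributed with the package, so refitting is exercised on synthetic data
only.  The cap at 99.9% (not 100%) keeps the production-loss division
defined; observed losses top out near 27.5%, far from the cap.

## Production accounting

    RY = 1 − %YL/100
    Production loss = P/RY − P = P · %YL/(100 − %YL)

The loss is measured against the pre-loss potential: loss/(P + loss) =
%YL/100.  An alternative literal reading of the relative-yield definition
(RY = 1/(%YL/100)) circulates in print; it is dimensionally inconsistent
(undefined at 0% loss, negative losses for %YL < 100) and is implemented
only behind an explicit `literal_eq2` flag so the two readings can be
compared, never as a default.

Base-year production rasters are moved to the study year by per-region
multiplicative conversion factors.  When derived from two survey snapshots,
regional totals are interpolated linearly in time and the factor is
interp(target)/interp(base).  Linear interpolation is the minimal model of
"how production changed between two surveys"; it ignores within-region
reallocation and year-to-year fluctuation, and the output metadata records
the method.

Annual production splits per sub-region into two harvests (default 60:40,
with per-sub-region overrides; shipped overrides 30:70, 69:31 and 61:39 for
the three sub-regions with published splits).  Unimodal sub-regions carry
(1, 0) and are assessed once, in their own window.  The split conserves
tonnes exactly; splitting an already-split raster is refused.

## Aggregation rules

Sub-region mean %YL is the unweighted mean over cells *with production
data*, zero-production cells included — such cells mark land that could
grow the crop and belong in the risk picture.  Production losses sum over
cells with production > 0 only.  National rows aggregate at cell level
(mean over all contributing cells; sum of losses), which is deliberately
not the mean of sub-region means: sub-regions have very different cell
counts.  A production-weighted %YL mean is available as a config switch
(`yl_mean_weighting`).  Cells with missing dose are excluded from means,
contribute zero loss, and are counted in the result object.

The loss-table arithmetic (row annual totals, national totals over a
season-column table with missing cells for unimodal seasons) is exposed as
`aggregate_loss_table`, and the package ships the published per-sub-region
seasonal production-loss table for Ugandan beans in 2015 as reference data;
re-aggregating those printed (rounded) cells reproduces the published
national totals to within 1 t of independent rounding.

## Spatial conventions

Cell footprints are half-open boxes on the planar degree grid; indices are
0-based, row 0 southernmost.  All overlap areas are planar products of 1-D
interval overlaps (the domain is equatorial, where the area distortion of
treating degrees as planar is far below any quantity of interest), which
keeps every assignment and regridding weight exactly reproducible by brute
force.  Cells are assigned to the polygon with the greatest overlap area
(ties broken by polygon order), the same majority rule used to rasterise
district flood levels.  Regridding offers area-weighted means (intensive),
sum-conserving redistribution (extensive; conserves the domain total to
1e-9 relative), majority (categorical) and nearest (target-centre lookup).
The coarse exposure grid is sampled onto the fine production grid by
`nearest` by default — each fine cell inherits the coarse cell containing
its centre, the conventional reading of "the dose at this location" —
with `area_weighted_mean` as the alternative for callers who prefer
smoothing across coarse-cell boundaries.  Statistics over zero contributing
cells are missing, never zero.

## Stress scoring

Each layer maps to an ordinal 1–5 score (very low to very high risk to
yield); six layers sum to a composite in [6, 30].  Continuous layers are
binned by four half-open breakpoints with an orientation flag; categorical
layers by an explicit table.  The shipped breakpoints are package defaults,
all overrideable in config: the five soil-constraint classes score 1–5 in
ladder order; SPEI uses the standard dryness categories (≥0 → 1 … <−1.5 →
5, lower is worse); flood counts 0/1/2–3/4–5/≥6 → 1–5; temperature
<28/28–29.5/29.5–32/32–35/≥35 °C → 1–5, anchored on bean physiology
(optimal to 28 °C, tolerated to 29.5 °C, blossom abortion near 35 °C);
deprivation quintiles of the 0–100 index; ozone %YL bands
0–5/5–10/10–16/16–22/>22.  Ozone enters as the season-1 yield-loss surface,
the season with most production.  Cells missing any layer are missing in
the composite.  The composite flags co-location only; no interaction
between stresses is modelled.

## Synthetic data

The generator emulates the statistical structure of the real inputs: a
daily dose field max(0, baseline + gradient·nw + seasonal sinusoid +
Gaussian noise) on the coarse grid (north-west high, as in the emulated
exposure fields); Bernoulli(occupancy) × log-normal production on the fine
grid; a rectangular partition into 14 named sub-regions in 4 parent
regions, one flagged unimodal; survey tables scaled from the raster's exact
regional sums so factor derivation has known truth; and six stress layers
within the emulated products' ranges (SPEI in [−2.5, 2.5], deprivation in
[0, 100], temperature ≈ 20–38 °C).  Defaults: 0.3° coarse cells (16×14)
and 0.0833° fine cells (57×50) over a ~4.8°×4.2° equatorial domain;
baseline dose 0.10 mmol m⁻² d⁻¹ with gradient 0.12 and seasonal amplitude
0.05, which yields seasonal doses around 12–22 mmol m⁻² and mean yield
losses in the mid-teens to low twenties of percent — the scale of the
assessed system; occupancy 0.6 and mean 40 t/cell give regional production
totals in the tens of thousands of tonnes at this reduced domain size.
All draws derive from a single seed through named substreams (one per
generator), so outputs are byte-stable and adding a generator never
perturbs existing fixtures.

What passing tests on synthetic data show: the pipeline's arithmetic,
aggregation, conservation and statistical properties are correct under
known truth.  What they do not show: anything about the fidelity of a real
chemical-transport model's dose fields, a real allocation model's
production surfaces, or real stress datasets — the generator has smooth
gradients and independent noise where real fields have weather, terrain and
spatially correlated error.

## Numerical choices and limitations

Tolerances: conservation and closed-form recovery are asserted at 1e-9
relative; the sum-conserving regrid distributes source quantities by exact
interval-overlap fractions.  Degenerate inputs fail loudly: zero-area
polygons, disjoint grids, constant-dose fits, shares not summing to 1,
negative doses or production, re-splitting a split raster.  File formats
are NetCDF (classic), GeoJSON and CSV; grid specs are stored in NetCDF
global attributes so write→read round-trips are value-identical.

Known limitations: no map projections or great-circle areas (equatorial
planar approximation); a single linear dose–response per crop (no cultivar
mixture, no concentration-based metrics); conversion factors are linear in
time at parent-region level; the stress composite is additive with package
default breakpoints where the emulated products' own class definitions are
not distributed.
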