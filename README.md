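# ozoneyield

Tropospheric ozone is taken up by crop leaves through their stomata and
damages yield in sensitive species.  `ozoneyield` is a Python library (with a
thin CLI) for estimating crop yield and production losses from modelled
stomatal ozone flux, and for mapping where ozone stress coincides with other
constraints on yield.  It was built around the assessment of common bean
(*Phaseolus vulgaris*) in Uganda — a bimodal-season, smallholder, rainfed
system — but every stage is parameterised and works on any rectilinear
lon/lat grids.

The pipeline:

1. **Dose** — accumulate the phytotoxic ozone dose POD₃IAM (stomatal flux
   above 3 nmol m⁻² s⁻¹, integrated over time) over crop-specific 90-day
   windows before harvest: day-of-year 91–180 (season 1), 257–346
   (season 2), and 182–271 for the unimodal sub-region.
2. **Yield loss** — convert dose to percentage yield loss through a linear
   flux–effect relationship, slope-only with zero effect at zero exposure:

   `%YL = 1.175 × POD₃IAM`  (% per mmol m⁻²; the shipped bean default)

   The fitting side estimates this relationship from experimental
   (dose, relative-yield) points by weighted least squares with a profiled
   power-law variance model (residual sd ∝ dose^δ), because scatter in yield
   data grows with dose.
3. **Production loss** — against gridded tonnes-per-cell production
   (survey-adjusted between years and split per sub-region into the two
   harvests, 60:40 nationally by default):

   `Production loss = P / RY − P = P × %YL / (100 − %YL)`, with
   `RY = 1 − %YL/100`.
4. **Aggregation** — per-cell results roll up to administrative sub-regions
   and a national row (cell-level aggregation, not a mean of means).
5. **Stress co-location** — soil-nutrient constraints, SPEI drought,
   district flood occurrence, daily-max temperature, deprivation and ozone
   yield loss each scored 1–5 and summed into a per-cell crop-stress score
   (range 6–30 for six layers).

A seeded synthetic-data module generates every input — dose cubes,
production rasters, region partitions, survey tables, stress layers — so the
full pipeline runs and is testable offline, with closed-form ground truth.

## Worked example

Run the end-to-end assessment on a synthetic scenario:

```sh
python examples/03_loss_assessment.py
```

```
national rows (mean % yield loss over cells with production data;
losses in tonnes, summed over producing cells):
sub_region region   season  mean_yield_loss_pct  production_t  production_loss_t
     Total    NaN  season1                 21.5      34,389.5            9,481.8
     Total    NaN  season2                 12.1      22,926.4            3,188.2
     Total    NaN karamoja                 16.0       5,045.0              961.2
```

Season 1 sees both the higher dose (the seasonal cycle peaks inside its
window) and the larger production share, so it carries most of the loss:
here a 21.5% mean yield loss turns 34,390 t of harvested production into a
9,482 t shortfall relative to an ozone-free season (loss = P·yl/(100−yl),
i.e. the loss is expressed against the pre-loss potential, not the observed
harvest).  The unimodal sub-region is assessed once, in its own July–
September window.

Other examples, one per capability: `01_accumulate_dose.py` (90-day POD
accumulation), `02_fit_dose_response.py` (heteroscedastic flux–effect fit),
`04_stress_score.py` (composite stress score), and
`05_published_table_arithmetic.py`, which re-aggregates the published
per-sub-region production-loss cells for Ugandan beans in 2015 (shipped in
`src/ozoneyield/data/`) into row and national totals.

The same pipeline is scriptable from a shell:

```sh
ozoneyield simulate --seed 7 --out fixtures/
ozoneyield accumulate --cube fixtures/flux.nc --season season1 --year 2015 --out pod_s1.nc
ozoneyield run-all --config run.yaml --out results/
```

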