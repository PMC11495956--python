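# Methods

This note documents the models and procedures implemented in
`nectarscape`, the assumptions they make, the defaults they ship with,
and what the synthetic study system does and does not capture.

## The scientific question

Residential gardens occupy a small fraction (typically ~2%) of temperate
farmland landscapes, yet field studies repeatedly find farmland
bumblebee populations doing better near gardens.  The package
operationalizes one candidate mechanism: farmland floral resources are
concentrated in a spring and a summer bloom pulse, leaving early-spring
and late-summer "hunger gaps", while gardens — being species-rich and
deliberately planted for long flowering — supply a small but temporally
flat stream of nectar that is disproportionately valuable exactly when
farmland supply collapses.  The pipeline quantifies that timing
complementarity four ways: a landscape nectar budget, a bee-activity
ratio, a colony-dynamics simulation experiment, and a spatial reach
analysis.

## Nectar phenology estimation

Floral surveys record open floral units per species per sampled area.
Conversion to a resource currency is multiplicative:

    sugar density (g m^-2 day^-1) = floral units / sampled area
                                    x sugar per floral unit per 24 h

Counts of trees and shrubs cover a 5 m vertical column only and are
multiplied by `height / 5` first.  Gardens are sampled as whole units
(the whole-garden area is the sampled area); farmland uses 1 m^2
quadrats.  Both flow through the same formula.

The seasonal curve is estimated by a penalized regression spline of
quadrat-level sugar density on day of year, pooled across sites.  The
basis is a cubic B-spline (default 24 basis functions, capped at
`n_dates - 1`), built with `statsmodels`' `BSplines`; the fit is a
penalized weighted least-squares solve with the smoothing parameter
chosen by generalized cross-validation over a 57-point log-spaced grid
(lambda in 10^-6..10^8).  Records are first collapsed to per-date means
(duplicates of a sampling unit are averaged, species summed within a
unit, units averaged within a date) with weights proportional to the
number of sampling units; weights are normalized to mean 1, which makes
the fit invariant to record order and to wholesale duplication of the
table.  Predictions are clipped at zero after fitting; a log-link is
deliberately not the default because the curves are reported and
consumed on the natural (g m^-2 day^-1) scale and clipping keeps the
standard-error band interpretable there.  Pointwise standard errors come
from the penalized-fit covariance `sigma^2 (X'WX + lambda S)^-1` with
`sigma^2` estimated from the weighted residuals at the effective degrees
of freedom.

The basis dimension default of 24 was chosen because the farmland bloom
pulses in the synthetic system are sharp (sd ~8-12 days); a coarser
basis structurally under-resolves them regardless of the penalty, while
GCV keeps the effective degrees of freedom modest when the data are
smooth (monthly garden samples are fitted with at most 7 basis
functions).  The error model is Gaussian on density; zeros are ordinary
observations.  An independent cross-check against `mgcv`'s thin-plate
GCV fit on the same per-date means is part of the test suite.

Farmland and garden curves, sampled in different years, are merged onto
a single day-of-year grid with no between-year adjustment.

## Landscape budget

The landscape supply curve is the area-weighted sum of habitat curves,
with habitat fits treated as independent for error propagation
(root-sum-square of area-scaled standard errors).  Arable and
urban-other areas are conventionally nectarless unless a curve is
supplied.  All budget arithmetic runs on a daily grid (the finest grid
for which the deficit search has an exact day-by-day oracle); weekly
summaries are derivable but not primitive.

Per-bee supply divides the landscape curve by a daily bee head count
built from per-species colony density x colony size x monthly activity
weights (step functions at month boundaries, as the underlying
monitoring data are monthly).  Days with zero bees are excluded and
flagged, never silently divided.

The demand side is a per-bee daily sugar requirement: a baseline of
0.12 g sugar bee^-1 day^-1 (resting plus foraging costs for a worker),
multiplied by 3 during the early-spring window (days 60-120) when
nest-founding queens — much heavier than workers — dominate the foraging
population.  Colony densities (29/68/117 colonies km^-2) and sizes
(300/100/150) for the three common farmland species are
implementer-supplied values within published ranges; none of these
demand-side numbers is a measured quantity, and conclusions are only
drawn from with-versus-without-garden comparisons that share them.

Deficit ("hunger gap") intervals are maximal runs of consecutive days
with per-bee supply below requirement, each annotated with its maximum
shortfall.

## Activity ratios

Transect records are filtered to sections whose primary habitat is
unambiguously farmland or garden; sections primarily agricultural but
secondarily garden are dropped, as are males (their foraging phenology
differs from females').  Encounter rates are total bees per km of
transect walked in a habitat-month; transect length is counted once per
section-visit however many species rows it produced, and zero-count
section rows therefore matter and are preserved by the generator.  The
garden:farmland ratio is reported per species and pooled; a month with
zero farmland effort or zero farmland count yields a missing value,
never infinity.  Uncertainty is a nonparametric bootstrap over transect
sections (the sampling unit), resampled within habitat.

## Colony simulator

The agent-based model is a structurally faithful but simplified
single-species (*Bombus terrestris*) daily-timestep colony model on
discrete forage patches.  It is not intended to reproduce any existing
engine's numeric output; every constant lives in `AbmConfig` with
defaults chosen to give multi-year persistence on landscapes with intact
gardens.

* **Patches** have a location, area, habitat, per-m^2 daily nectar
  curve, corolla depth and sugar concentration.  Stocks replenish each
  day to that day's production (standing crop equals one day's
  secretion).
* **Queens** emerge Normal(1 April, sd 28 d), truncated to days 60-150,
  at random locations in the 1 km disc, and forage solo; a queen that
  accumulates 1.0 g of sugar within 21 days founds a colony at her
  location, otherwise she dies.  The founded fraction is the
  spring-queen survival endpoint.
* **Foraging** is central-place: each forager makes 10 trips per day;
  the destination is drawn from a multinomial with probability
  proportional to an exponential distance kernel (length scale 400 m)
  times current patch stock.  A trip collects min(crop capacity 0.06 g,
  the patch's remaining share); its cost is flight time (300 m min^-1,
  6e-4 g sugar min^-1) plus handling time (3 min at the 5 mm reference
  corolla, scaled by corolla depth and up to doubled on depleted
  patches, at 1.5e-4 g min^-1).  Within a day, allocation is
  single-pass: patch yields are capped by stock and shared among
  visitors pro rata, which makes daily sugar conservation exact
  (summed stock decrease equals summed gross intake).
* **Colonies** pay daily upkeep (worker 0.012 g, brood 0.006 g, queen
  0.05 g), initiate brood from surplus energy (egg 0.05 g, capped by
  care capacity 2 + 0.5 x workers, max 8/day), mature brood after 14
  days, cap workers at 250 with a 30-day mean lifespan, and die
  irreversibly when energy goes negative.  Stored energy is capped at
  75 g — a honeypot holds days, not months, of reserves — so late-season
  rearing depends on late-season income rather than a banked mid-summer
  glut.  From 1 August to mid-September (days 214-258) eggs are gynes
  (0.5 g each, max 6/day); after that laying stops and colonies wind
  down.
* **Years** chain through overwintering: surviving new queens (binomial,
  p = 0.3) found the next spring cohort, capped at the initial cohort
  size.  Endpoints (monthly colony density sampled on the 15th, maximum
  colonies, total bees produced, new queens, spring queen survival) are
  averaged over the simulated years.

The four landscape treatments transform garden patches only: left
intact, zeroed, given the pasture curve, or given the pasture curve
rescaled per patch to preserve its annual per-m^2 sugar integral (same
quantity, pasture timing — the treatment that isolates phenology).

Treatment effects are summarized by paired per-landscape percent changes
against the intact-garden baseline with a percentile bootstrap CI from
resampling landscapes (the landscape is the experiment's random factor);
this plays the role a mixed model would in a field analysis while
keeping the statistical procedure fully specified inside the package.

## Reach analysis

Distances from every raster cell centre to the nearest urban cell centre
are exact Euclidean distances (squared integer pixel arithmetic before
the final square root), computed via `scipy.ndimage`'s exact distance
transform with nearest-cell indices.  Urban cells are within reach at
every radius, as buffers are drawn around urban land.  Reach fractions
per landcover class exclude nodata cells from numerator and denominator
and are monotone in radius by construction.  Coordinates are planar;
the raster resolution is the approximation scale relative to vector
buffering.  Equating urban reach with garden reach rests on the
assumption that urban land carries a high, regular density of gardens;
the package reports urban reach only.

## The synthetic study system

The generator emulates a Southwest-UK farmland/garden system:

* ~8 farmland species with Gaussian bloom kernels clustered into a
  spring (peak days 105-138) and a summer (170-200) pulse, sd 8-12 d;
  one species is an ivy-like late bloomer (peak days 238-258) in
  hedgerows at a small share (~8% of hedgerow floral density), because
  real farmland retains a weak late nectar source — the August-October
  trough is low (~5% of peak) but not absolute zero, which also keeps
  garden-less simulated landscapes demographically viable rather than
  trivially extinct.
* 56 garden species with peaks spread over days 60-295 and wider kernels
  (sd 18-32 d), giving a flat curve whose March-October coefficient of
  variation is well below farmland's.
* Habitat floral densities (pasture 14, woodland 45, hedgerow 150,
  field margin 80, garden 95 units m^-2 at peak) and per-unit sugar
  (lognormal around 2 mg day^-1) put annual production at a few g sugar
  m^-2 yr^-1 per habitat and the garden share of landscape-scale annual
  nectar near 15%, rising to a majority share in early spring and
  autumn.
* Quadrat counts are negative binomial (dispersion 1.5) because field
  counts are clumped; Poisson would understate their variance.  Farmland
  is surveyed weekly and gardens monthly (59 gardens, mean 156.4 m^2),
  reproducing the unequal design the smoother must handle.
* Transect counts are Poisson per ~1 km section with a seasonal
  garden:farmland ratio (3.0 in March falling to ~1.1 mid-summer and
  rising to 9 in October), 493/168 km of farmland/garden effort per
  season, plus male records and 99 ambiguous sections for the filters to
  remove.
* The 12 model landscapes are 1 km-radius discs whose garden covers
  (0.2-5.9%, mean exactly 1.9%) are a synthetic stand-in list for the
  real study landscapes; other habitat fractions are jittered around
  pasture 50%, arable 24%, woodland 12%, hedgerow 3%, margin 2%.
  Patches are discrete records with 10 m-snapped centres; gardens
  cluster as ~4000 m^2 patches around one to three settlement points.
* Landcover rasters are thresholded smoothed Gaussian noise, which
  clusters urban cells into settlement-like blobs at an exactly realized
  urban fraction.

What passing tests on this system do **not** show: recovery of any real
taxon's phenology; correctness of the absolute demand-side constants;
that the simulator's endpoint magnitudes match any field system (the
synthetic farmland trough is deeper and more regular than real
landscapes', so treatment contrasts here are larger than a field
calibration would give); or anything about pollen, weather, predation or
nesting limitation, all deliberately held non-limiting.

## Problem sizes and numerics

Default problem sizes are chosen so the whole pipeline runs comfortably
on a single CPU: the treatment experiment uses 12 landscapes x 4
treatments x 5 replicate runs x 5 years with 200 founding queens
(~70-160 patches and up to ~200 colonies per landscape); the phenology
recovery study uses 20 generator seeds at 60 quadrats per visit.  The
GCV grid, spline clipping, stock floor (1 mg) below which a patch is not
worth a trip, and the exact-integer distance computation are the notable
numerical choices; ties in the multinomial foraging draw are resolved by
the seeded generator, and every public entry point that uses randomness
takes an explicit seed.
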