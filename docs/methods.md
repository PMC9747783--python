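# Methods

`forestdebt` implements the 'past habitat' route to detecting extinction debt:
if present-day species richness is better explained by *past* habitat extent
than by *current* habitat extent, part of the community is committed to
extinctions it has not yet paid. The package provides the four stages of that
argument — reconstructing an annual habitat record over centuries, turning
range maps into richness layers, scanning the years with a spatially corrected
correlation test, and stratifying the signal by biome and protection history —
plus a seeded generator of synthetic worlds on which every stage is testable
end to end.

## The habitat record

Land cover lives on a regular 0.5° lon/lat grid (half-open cells, row-major
from the south-west corner) as per-cell fractions of six classes: forest,
natural grassland, cropland, pasture, urban, other. Fractions close to 1 per
cell-year, and the record is annual and contiguous.

Historical reconstruction treats the anthropogenic classes (urban, cropland,
pasture) as prescribed by an external change series and solves only for the
natural side. Stepping one year at a time, the net anthropogenic change ΔA is
charged against forest f and natural grassland g in proportion to their
current fractions f/(f+g) and g/(f+g) — the proportional allocation rule.
Because this preserves the f:g ratio, the backward recursion (anchored on a
present-day map) is the *exact* inverse of the forward recursion (anchored on
a historical initial map) wherever no clipping occurs; the tests exploit this
as a round-trip oracle with a 1e-6 per-cell tolerance.

Numerical edge cases are resolved explicitly and logged per cell:

* a natural class driven below zero passes its deficit to the other natural
  class, then to "other" (with renormalization in the extreme case);
* a cell with f+g = 0 charges ΔA entirely to "other";
* prescribed anthropogenic fractions are clipped to [0, 1] (and the clip
  recorded) so closure always holds.

The allocation ratio is updated every recursion step rather than frozen at the
anchor year; since the rule preserves the ratio this matters only after
clipping events, but the choice is recorded here because both readings of
"existing" are defensible.

Independent reconstructions are combined by a per-cell, per-year ensemble mean
restricted to the members' common years; a 1500–2005 member and an 800–1992
member overlap on 1500–1992, i.e. 493 annual layers.

## Richness from range maps

Species records carry range parts (polygons with presence / origin /
seasonality codes), a primary-habitat code and a Red List category. The
inclusion rules keep species with forest as primary habitat, drop Extinct and
Extinct-in-the-Wild species, and keep only range parts that are extant, native
or reintroduced, and resident / breeding / non-breeding.

Rasterization marks a cell occupied iff the range overlaps the cell rectangle
with positive area; boundary-only contact does not count. This "any positive
overlap" rule is a deliberate design choice (the alternatives — centroid-in-
polygon or majority-area — are stricter); it is stable at 0.5° resolution and
simple to mirror in other languages. Multiple range parts are unioned first so
a species counts once per cell. Richness layers are cellwise sums per
taxonomic group (mammal, amphibian, reptile) and category set: each single
category CR/EN/VU/NT/LC/DD, the cumulative ALL (including DD), and the
threatened aggregate CR∪EN∪VU.

## The scan and its inference

For every year of the cover record the scan computes Pearson's r between the
static richness layer and that year's forested-habitat area (forest fraction ×
spherical cell area in km²; a flag switches to the raw fraction). Cell areas
use the exact spherical formula R²·Δλ·(sinφ_N − sinφ_S), so equal-angle cells
are properly down-weighted toward the poles.

Because both fields are spatially autocorrelated, the usual n-2 degrees of
freedom overstate the information content. Inference instead uses an
effective sample size (ESS) in the tradition of the modified t-test of
spatial ecology:

    ESS = 1 + tr(BΣ̂x)·tr(BΣ̂y) / tr(BΣ̂x B Σ̂y),   B = I − 11ᵀ/n,

with the t statistic r·sqrt((ESS−2)/(1−r²)) referred to a t distribution on
ESS−2 degrees of freedom. Σ̂x and Σ̂y are spatial correlation matrices
assembled from Moran's-I correlogram estimates over equal-width great-circle
distance classes (class count by Sturges' rule on the pair count, default).
With independent data Σ̂ ≈ I and ESS ≈ n exactly (the formula gives n when
every off-diagonal autocorrelation is zero); ESS is clipped to [2, n].

Two implementation notes. First, the trace identity
tr(BΣxBΣy) = Σᵢⱼ (BΣxB ∘ BΣyB) for idempotent B reduces the cost per test
from O(n³) to O(n²), which is what makes thousands of tests per scan and
Monte-Carlo calibration affordable.

Second, the raw correlogram plug-in is anticonservative when the
autocorrelation range is an appreciable fraction of the domain. Estimating
the mean from the same autocorrelated field biases Moran's-I estimates — the
whole empirical correlogram is attenuated and shifted (its pair-weighted sum
is −n by construction) — while the diagonal of Σ̂ stays pinned at 1; the
mismatch acts like a spurious white-noise ridge that inflates ESS. Both
distortions are removed at once by the default estimator: the expected
empirical correlogram of a mean-centred field is an exact *linear* function
of the true correlogram (computable per distance-class basis once per cell
set), and a stretched-exponential correlogram a·exp(−(d/b)^p) is fitted so
that its image under this map matches the observed estimates; Σ̂ is then
built from the fitted curve. Fitting a smooth parametric decay is standard
variogram practice and also suppresses the estimation noise that otherwise
inflates ESS through the convexity of the trace ratio. The raw plug-in
remains available (`correlogram_model="empirical"`). The Monte-Carlo
calibration suite measures the resulting type-I error directly: on 30×30
grids of independent Gaussian-smoothed fields (kernel σ = 5 cells) the
corrected test holds its nominal 5% size while the naive test rejects the
true null the great majority of the time; on white-noise fields ESS/n stays
within a few percent of 1.

No correction is applied across the 493 yearly tests: the scan is
descriptive, p-values are per-year, and the per-year cell count is reported so
pairwise drops are auditable.

Derived series:

* **Decadal change** Δr(d) = r(d) − r(d−10) at d = start+10, start+20, …;
  a 1500–1992 series yields 49 values.
* **Onset detection**: continuous two-segment piecewise-linear least squares
  (hinge model r ~ 1 + t + max(t−c, 0)) over a grid of candidate break years,
  excluding a margin (default 30 y) at each edge; the breakpoint minimizing
  the residual sum of squares wins, ties to the earliest year. If the best
  kink does not reduce RSS relative to a single line by at least 10%
  (configurable), no onset is declared. The rule recovers a noiseless kink
  exactly and abstains on single-slope series.
* **Covariate regression**: ordinary least squares of the yearly r on an
  annual external forcing series (e.g. greenhouse-gas emissions) over the
  year intersection; an 1850–2017 covariate against a 1500–1992 scan gives
  143 fitted points.

## Stratification

Cells are labelled with one biome each (majority-area rule for straddling
cells; seven forested biome labels — BF, TCF, TBMF, MFWS, TSCF, TSDBF, TSMBF —
plus "non-forested"). A cell is "protected" iff it positively-area-intersects
at least one protected area whose status year is at or before the cutoff
(default 1992); the earliest such year is recorded, protected areas without a
status year are excluded and logged. Per-stratum forest cover is the
area-weighted percentage Σ(fraction·area)/Σ(area)×100, so stratum covers
aggregate exactly to the union cover. The stratified scan runs the annual
correlation scan independently on every (biome × protected/never) mask;
combinations with fewer than 3 cells are reported as flagged-missing series
rather than dropped, keeping the output cardinality fixed at 2 × biomes.

## The synthetic world

The generator fabricates all five inputs with the statistical structure the
method assumes. Its defaults are the package's reference study conditions; a
16×16-cell window at 0.5°, years 1500–1992, 60 species per group, loss onset
1850 and a 50-year relaxation half-life.

* **Initial cover**: Gaussian-smoothed white noise (kernel σ = 3 cells),
  rank-transformed to uniform margins, mapped to forest ∈ [0.15, 0.85] with a
  complementary grassland share; small uniform anthropogenic seeds; "other"
  closes the budget. A `uniform_cover` switch flattens the field for
  construction-guaranteed ordering tests.
* **Conversion**: after the onset year, each cell's natural cover relaxes
  toward an unconverted floor natural₀·(1 − depth·pressure) with e-folding
  time θ = 10·depth/loss_rate (defaults: depth 0.6, loss_rate 0.10 per decade
  at peak pressure, hence θ = 60 y) — a saturating, historically motivated
  process: conversion is fastest when open frontier land is plentiful and
  slows as convertible land is taken up. Pressure blends a smoothed random
  field with the cell's initial forest rank (bias 0.6), since conversion
  targeted forested land. Both choices matter for detectability: they give
  the correlation trace a genuine negative slope at the onset rather than a
  purely second-order departure, which is what a breakpoint fit can locate.
  The change series is fed through the forward proportional-allocation rule,
  so generator truth and reconstruction share one arithmetic and the series
  is clip-free by construction.
* **Species**: ranges are contiguous cell blobs grown from seeds sampled
  (by default strongly) toward high-forest cells; each forest species draws a
  forest-fraction tolerance uniformly from (0.05, 0.35). A population whose
  cell falls below tolerance is committed and dies with constant per-year
  hazard ln2/τ, so survival after t whole years below threshold is exactly
  2^(−t/τ); τ = 0 kills immediately, τ = ∞ freezes the community, and there is
  no recolonization. The default tolerance band sits low in the cover range
  on purpose: extinction debt is the committed-but-not-yet-extinct minority,
  and the regime the method targets is *mostly unpaid* debt — present
  richness still resembles the pre-industrial pattern. Present-day range
  polygons are rebuilt from the cells still occupied in the final year (a
  species occupying none is recorded as EX, and the filter later drops it).
* **Protected areas**: 1–2-cell rectangles with status years drawn from an
  exponentially growing density from 1900, placed preferentially on forested
  cells; by default a protected cell stops converting from its status year
  ("freeze"). **Biomes**: seven latitudinal bands. **Emissions**: an
  exponential curve (~50-fold rise over 1850–2017) with small lognormal noise.

All randomness flows from one root SeedSequence with named child streams per
stage, so identical config + seed gives a bit-identical world and stage-level
reruns match pipeline runs.

### What the generator does and does not emulate

It reproduces the features the analysis is sensitive to: spatial
autocorrelation in cover and richness, habitat-biased ranges, graded species
sensitivity, a lagged extinction mechanism, monotone anthropogenic expansion,
and protection histories correlated with forest. It does not emulate range
shifts or recolonization ("immigration credits"), climate forcing, taxonomic
error, coastlines/projection artifacts, or the gross sub-grid land-use
transitions of real harmonized land-use data. Passing tests therefore show
that the statistical machinery behaves as designed under the assumed
data-generating process — not that real vertebrate data satisfy those
assumptions.

The relaxation mechanism itself is a modelling stand-in: the 'past habitat'
literature detects debt without committing to a functional form, and the
constant-hazard clock is simply the least-structured mechanism that produces
the lagged decoupling the scan must detect.

## Problem sizes and numerical choices

Defaults are desk-scale and chosen once: 256–900 cells, 180–600 species, 493
years. The onset-recovery suite runs 200 replicate worlds with r-only scans
(the breakpoint fit needs no ESS); the calibration suite runs 2000 Monte-Carlo
replicates on a 30×30 grid. Closure is enforced to 1e-9 after ensemble
averaging, rasterization uses a 1e-12 area epsilon against degenerate
slivers, correlations are clipped to [−1, 1] against float drift, and CSV
persistence writes 17 significant digits with round-trip float parsing so
world checksums reproduce exactly.

## Known limitations

* ESS estimation degrades when the autocorrelation range approaches the
  domain size; the clip to [2, n] then does real work and p-values become
  coarse.
* The onset estimator assumes one slope change; smooth curvature biases the
  fitted knee toward the middle of the bend (this drove the saturating
  conversion design above).
* Equal-width distance classes are a convention; the class scheme of the
  modified t-test is not standardized in the field, and results at small n
  are mildly sensitive to it.
* The stratified comparison is descriptive, as is the protected/never split;
  no causal claim (matching, synthetic control) is attempted.
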