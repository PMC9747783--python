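# forestdebt

Detection of extinction-debt signals in forest-dwelling vertebrate communities
from long-term habitat records.

## The problem

Habitat destruction commits species to extinctions that take decades or
centuries to play out. While the debt is unpaid, present-day species richness
matches *past* habitat better than *current* habitat — the 'past habitat'
signature. Given an annual record of forested-habitat area A(t) over centuries
and a static present-day richness layer S per grid cell, the diagnostic is the
trace of Pearson correlations

    r(t) = corr(S, A(t)),    t = 1500 … 1992,

computed across grid cells: a high, stable r before industrial-era forest loss
that declines toward the present indicates a community in disequilibrium with
its habitat, and the year the trace changes slope estimates when the debt
began to accumulate.

Because both fields are spatially autocorrelated, each year's test uses a
modified t-test: an effective sample size

    ESS = 1 + tr(BΣ̂x)·tr(BΣ̂y) / tr(BΣ̂x B Σ̂y),   B = I − 11ᵀ/n,

replaces n in the degrees of freedom, with Σ̂ built from distance-class
correlogram estimates (see `docs/methods.md` for estimation details).

The package provides, as importable modules and a thin CLI:

* `reconstruct` — annual land-cover reconstruction by the backward/forward
  proportional allocation rule, plus ensemble averaging of members;
* `rangegrid` — Red-List-style filtering of species range maps, polygon
  rasterization to a 0.5° grid, richness stacking by group and category;
* `debtscan` — the spatially corrected annual correlation scan, decadal
  differencing, piecewise-linear onset detection, covariate regression;
* `stratify` — biome labelling, protected-area history assignment and
  stratum-wise scans;
* `synthetic_world` — a seeded generator of complete synthetic study systems
  (cover history, species ranges with a lagged extinction mechanism,
  protected areas, biomes, an emissions covariate);
* `pipeline_io` — one-call orchestration with checksummed, reproducible
  artifacts.

## Worked example

```python
import forestdebt as fd

# a seeded synthetic study system: 16x16 cells at 0.5 deg, 1500-1992,
# habitat loss from 1850, 50-year relaxation half-life
world = fd.generate_world(fd.SyntheticWorldConfig(seed=1))

records = fd.filter_forest_dwelling(world.species)
stack = fd.rasterize_and_stack(records, world.grid)

series = fd.correlation_scan(stack, world.cover, "mammal", "ALL")
onset = fd.detect_onset(series, margin=30)
fit = fd.fit_covariate_model(series, world.emissions)

print(f"species kept: {len(records)} of {len(world.species)}")
print(f"scan: {len(series)} years, r(1500)={series.r[0]:.3f}, "
      f"r(1992)={series.r[-1]:.3f}")
print(f"ESS(1500)={series.ess[0]:.1f} of n={series.n[0]} cells")
print(f"onset year: {onset.onset_year} "
      f"(pre-slope {onset.slope_pre:.2e}, post-slope {onset.slope_post:.2e})")
print(f"emissions model: R^2={fit.r_squared:.2f} over {fit.n_overlap} years")
```

prints

```
species kept: 129 of 180
scan: 493 years, r(1500)=0.865, r(1992)=0.835
ESS(1500)=14.8 of n=256 cells
onset year: 1864 (pre-slope -9.88e-08, post-slope -2.46e-04)
emissions model: R^2=0.83 over 143 years
```

Reading: 129 extant forest-dwelling species survive the inclusion rules; the
correlation between present-day mammal richness and forested-habitat area is
flat for three and a half centuries, then declines from the fitted breakpoint
(1864, close to the engineered 1850 onset) to the present — the debt
signature. Spatial autocorrelation reduces the 256 cells to an effective
sample of ~15 independent observations, which is what the corrected p-values
are based on. The declining correlation tracks the accelerating emissions
covariate over their 143 common years.

The same analysis runs from the shell:

```bash
forestdebt simulate --out world/ --seed 1
forestdebt scan --world world/ --group mammal --out scan.csv
forestdebt onset --scan-csv scan.csv --out onset.json
forestdebt run --config run.yaml         # full pipeline with manifest
```

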