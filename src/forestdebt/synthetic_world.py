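"""Seeded generator of a synthetic study system for the debt-detection pipeline.

Real inputs to the analysis are expert range maps, half-millennium land-use
reconstructions, protected-area registers, biome polygons and an emissions
series.  This module fabricates all five with the statistical structure the
method assumes, so the whole pipeline is exercisable (and its statistical
behaviour measurable) without any external download:

* spatially autocorrelated initial land cover (Gaussian-smoothed noise);
* anthropogenic expansion beginning at a configurable onset year, heavier in
  high-pressure cells, run through the forward proportional-allocation rule so
  the "true" cover series is exactly the kind the reconstruction module
  produces;
* forest-dwelling species whose ranges are carved from high-forest cells, each
  with a forest-fraction tolerance; once local cover drops below tolerance the
  population is doomed and dies with a constant per-year hazard ln 2 / τ — the
  half-life τ is the extinction-debt lag.  Present-day ranges are the cells
  still occupied in the final year, so contemporary richness reflects past
  rather than current habitat wherever the lag is long;
* protected areas appearing from a start year (preferentially on forested
  cells) which, by default, freeze further anthropogenic expansion in the
  cells they cover from their status year on;
* seven latitudinal biome bands and an exponentially growing emissions series.

Identical config + seed gives a bit-identical world; all randomness flows from
one root ``numpy`` SeedSequence with named child streams per stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.ops import unary_union

from .grid import GridSpec
from .rangegrid import CATEGORIES, GROUPS, HABITATS, RangePart, SpeciesRecord
from .reconstruct import (ANTHRO_CLASSES, CLASSES, AnthropogenicChangeSeries,
                          LandCoverSeries, forward_reconstruct)

BIOME_LABELS = ("BF", "TCF", "TBMF", "MFWS", "TSCF", "TSDBF", "TSMBF")
_FOREST_IDX, _GRASS_IDX = 0, 1

# Red List category mix for generated species; EX/EW appear so the filter has
# something to drop, as in the real register.
_CATEGORY_PROBS = {"LC": 0.48, "NT": 0.10, "VU": 0.12, "EN": 0.10, "CR": 0.06,
                   "DD": 0.10, "EX": 0.02, "EW": 0.02}


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Knobs of the synthetic study system.

    Defaults describe a desk-scale world: a 16×16-cell 0.5° window, the full
    1500–1992 annual record, habitat loss starting in 1850 and a 50-year
    relaxation half-life — the regime in which a clear but lagged debt signal
    exists for the scan to find.
    """

    grid: GridSpec = GridSpec(-8.0, 0.0, -4.0, 4.0, 0.5)
    year_start: int = 1500
    year_end: int = 1992
    n_species_per_group: int = 60
    habitat_affinity_mix: float = 0.8   # share of species with forest as primary habitat
    range_size_cells: tuple[int, int] = (5, 40)
    range_forest_bias: float = 1.0      # how strongly forest species' ranges hug high-forest cells
    tolerance_range: tuple[float, float] = (0.05, 0.35)
    loss_onset_year: int = 1850
    loss_rate: float = 0.10             # initial fractional natural-cover loss per decade at peak pressure
    conversion_depth: float = 0.6       # fraction of natural cover ultimately convertible at peak pressure
    pressure_forest_bias: float = 0.6   # how strongly conversion targets forested cells
    relaxation_halflife: float = 50.0   # years; 0 = immediate, inf = frozen
    spatial_autocorr_range: float = 3.0  # Gaussian kernel sigma, in cells
    uniform_cover: bool = False          # flat initial cover (order-guaranteed PA worlds)
    n_protected_areas: int = 25
    pa_start_year: int = 1900
    pa_growth_rate: float = 0.03         # exponential growth of the PA count per year
    pa_effect: str = "freeze"            # "freeze" halts anthropogenic expansion; "none"
    emissions_years: tuple[int, int] = (1850, 2017)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.year_start >= self.year_end:
            raise ValueError("year_start must be < year_end")
        if not 0.0 <= self.loss_rate <= 1.0:
            raise ValueError("loss_rate must lie in [0, 1]")
        if not 0.0 <= self.conversion_depth <= 1.0:
            raise ValueError("conversion_depth must lie in [0, 1]")
        if not 0.0 <= self.pressure_forest_bias <= 1.0:
            raise ValueError("pressure_forest_bias must lie in [0, 1]")
        if not 0.0 <= self.range_forest_bias <= 1.0:
            raise ValueError("range_forest_bias must lie in [0, 1]")
        if self.relaxation_halflife < 0:
            raise ValueError("relaxation_halflife must be >= 0")
        if self.pa_effect not in ("freeze", "none"):
            raise ValueError("pa_effect must be 'freeze' or 'none'")
        if self.grid.n_cells == 0:
            raise ValueError("degenerate grid: zero cells")


@dataclass(frozen=True)
class ProtectedAreaRecord:
    pa_id: str
    polygon: shapely.Polygon
    status_year: int | None


@dataclass
class SyntheticWorld:
    """Everything one seeded call produces: the full synthetic study system."""

    config: SyntheticWorldConfig
    grid: GridSpec
    cover: LandCoverSeries
    initial_map: np.ndarray                  # (6, n_cells) cover at year_start
    changes: AnthropogenicChangeSeries
    species: list[SpeciesRecord]
    tolerances: dict[str, float]             # forest-fraction threshold per species
    range_masks: dict[str, np.ndarray]       # original (pre-relaxation) range per species
    occupancy: np.ndarray                    # (n_years, n_species, n_cells) bool
    species_order: list[str]                 # row order of the occupancy array
    protected_areas: list[ProtectedAreaRecord]
    protection_truth: np.ndarray             # per-cell earliest protection year (nan = never)
    biome_labels: np.ndarray                 # per-cell biome label (unicode array)
    biome_polygons: dict[str, shapely.Polygon]
    emissions: pd.Series                     # year-indexed covariate

    def species_by_id(self, species_id: str) -> SpeciesRecord:
        return next(s for s in self.species if s.species_id == species_id)


# ---------------------------------------------------------------------------
# building blocks


def smooth_uniform_field(shape: tuple[int, int], sigma: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Spatially autocorrelated field with ~uniform [0, 1] margins.

    Gaussian-smoothed white noise, rank-transformed so the marginal
    distribution stays uniform regardless of the kernel width.
    """
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma, mode="reflect")
    flat = z.ravel()
    ranks = np.argsort(np.argsort(flat))
    return ((ranks + 0.5) / flat.size).reshape(shape)


def cell_area(lat_south, lat_north, dlon: float, radius: float = 6371.0):
    """Spherical cell area in km² — see :func:`forestdebt.grid.cell_area`."""
    from .grid import cell_area as _impl
    return _impl(lat_south, lat_north, dlon, radius)


def apply_relaxation(occupancy: np.ndarray, cover: LandCoverSeries,
                     tolerances: np.ndarray, halflife: float,
                     seed: int | np.random.SeedSequence) -> np.ndarray:
    """Play the constant-hazard extinction clock over the cover record.

    ``occupancy`` is the (n_species, n_cells) boolean state at the first cover
    year.  Whenever a cell's forest fraction sits below a species' tolerance
    in year t, that local population dies that year with probability
    1 − 2^(−1/τ), so the survival of a population continuously below
    threshold is exactly 2^(−t/τ) after t whole years.  τ = 0 kills
    immediately; τ = inf freezes the community.  There is no recolonization:
    occupancy never increases.

    Returns the (n_years, n_species, n_cells) occupancy trajectory.
    """
    if halflife < 0:
        raise ValueError("halflife must be >= 0")
    rng = np.random.default_rng(seed)
    occ = np.asarray(occupancy, dtype=bool)
    tol = np.asarray(tolerances, dtype=float)[:, None]
    forest = cover.cover[:, cover.class_index("forest"), :]
    if math.isinf(halflife):
        p_die = 0.0
    elif halflife == 0:
        p_die = 1.0
    else:
        p_die = 1.0 - 2.0 ** (-1.0 / halflife)
    out = np.empty((cover.n_years,) + occ.shape, dtype=bool)
    state = occ.copy()
    for i in range(cover.n_years):
        below = forest[i][None, :] < tol
        if p_die >= 1.0:
            state &= ~below
        elif p_die > 0.0:
            dies = below & (rng.random(state.shape) < p_die)
            state &= ~dies
        out[i] = state
    return out


def _cells_to_polygon(grid: GridSpec, cells: np.ndarray) -> shapely.Polygon:
    boxes = [shapely.box(*grid.cell_bounds(c)) for c in np.flatnonzero(cells)
             ] if cells.dtype == bool else [shapely.box(*grid.cell_bounds(c)) for c in cells]
    return unary_union(boxes) if boxes else shapely.Polygon()


def _grow_range(grid: GridSpec, weight: np.ndarray, target_cells: int,
                rng: np.random.Generator) -> np.ndarray:
    """Grow a contiguous cell blob from a weight-sampled seed cell."""
    ny, nx = grid.shape
    w = weight.reshape(ny, nx)
    p = (w ** 2).ravel() + 1e-9
    p = p / p.sum()
    seed_cell = rng.choice(p.size, p=p)
    mask = np.zeros((ny, nx), dtype=bool)
    mask.ravel()[seed_cell] = True
    frontier = {int(seed_cell)}
    while mask.sum() < target_cells and frontier:
        cid = int(rng.choice(np.sort(np.fromiter(frontier, dtype=int))))
        frontier.discard(cid)
        iy, ix = divmod(cid, nx)
        nbrs = [(iy + dy, ix + dx) for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1))]
        for jy, jx in nbrs:
            if 0 <= jy < ny and 0 <= jx < nx and not mask[jy, jx]:
                if rng.random() < 0.3 + 0.7 * w[jy, jx]:
                    mask[jy, jx] = True
                    frontier.add(jy * nx + jx)
        if not frontier:
            break
    return mask.ravel()


# ---------------------------------------------------------------------------
# generation stages


def _initial_cover(cfg: SyntheticWorldConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.grid.n_cells
    cov = np.zeros((len(CLASSES), n))
    if cfg.uniform_cover:
        forest = np.full(n, 0.60)
        grass = np.full(n, 0.15)
    else:
        u = smooth_uniform_field(cfg.grid.shape, cfg.spatial_autocorr_range, rng).ravel()
        forest = 0.15 + 0.70 * u
        grass = 0.05 + 0.15 * (1.0 - u)
    cov[CLASSES.index("forest")] = forest
    cov[CLASSES.index("natural_grassland")] = grass
    cov[CLASSES.index("cropland")] = 0.02
    cov[CLASSES.index("pasture")] = 0.02
    cov[CLASSES.index("urban")] = 0.005
    cov[CLASSES.index("other")] = 1.0 - cov.sum(axis=0)
    if np.any(cov[CLASSES.index("other")] < 0):
        raise RuntimeError("initial cover violates closure")
    return cov


def _protected_areas(cfg: SyntheticWorldConfig, forest0: np.ndarray,
                     rng: np.random.Generator) -> tuple[list[ProtectedAreaRecord], np.ndarray]:
    """Place PAs (1–2 cell rectangles) with exponentially growing counts."""
    grid = cfg.grid
    ny, nx = grid.shape
    n_pa = cfg.n_protected_areas
    pas: list[ProtectedAreaRecord] = []
    truth = np.full(grid.n_cells, np.nan)
    if n_pa == 0 or cfg.pa_start_year > cfg.year_end:
        return pas, truth
    # status years: density ∝ exp(growth · (year − start)) on [start, end]
    span = np.arange(cfg.pa_start_year, cfg.year_end + 1)
    dens = np.exp(cfg.pa_growth_rate * (span - cfg.pa_start_year))
    years = rng.choice(span, size=n_pa, p=dens / dens.sum())
    years.sort()
    w = forest0 if not cfg.uniform_cover else np.ones_like(forest0)
    p = (w ** 2) / (w ** 2).sum()
    for k, year in enumerate(years):
        cid = int(rng.choice(grid.n_cells, p=p))
        iy, ix = divmod(cid, nx)
        h, wdt = rng.integers(1, 3), rng.integers(1, 3)
        cells = [(jy * nx + jx) for jy in range(iy, min(iy + h, ny))
                 for jx in range(ix, min(ix + wdt, nx))]
        poly = unary_union([shapely.box(*grid.cell_bounds(c)) for c in cells])
        pas.append(ProtectedAreaRecord(f"PA{k:04d}", poly, int(year)))
        for c in cells:
            truth[c] = min(truth[c], year) if np.isfinite(truth[c]) else year
    return pas, truth


def _change_series(cfg: SyntheticWorldConfig, initial: np.ndarray,
                   protection_year: np.ndarray,
                   rng: np.random.Generator) -> AnthropogenicChangeSeries:
    """Prescribe anthropogenic expansion after the loss onset year.

    Conversion is a saturating process: each cell's natural cover relaxes
    toward an unconverted floor natural₀ · (1 − depth · pressure) with an
    e-folding timescale θ = 10 · depth / loss_rate years, so the initial loss
    rate at peak pressure is ``loss_rate`` per decade and expansion slows as
    convertible land is taken up.  Pressure blends a spatially autocorrelated
    random field with the cell's initial forest rank (``pressure_forest_bias``)
    — conversion historically targeted forested land.  Cells under a frozen
    protected area stop expanding from the PA's status year.  The resulting
    series is clip-free by construction.
    """
    grid = cfg.grid
    years = np.arange(cfg.year_start, cfg.year_end + 1)
    n_tr = len(years) - 1
    delta = np.zeros((n_tr, len(ANTHRO_CLASSES), grid.n_cells))
    if cfg.loss_rate > 0 and cfg.conversion_depth > 0:
        field = smooth_uniform_field(grid.shape, cfg.spatial_autocorr_range,
                                     rng).ravel()
        if cfg.uniform_cover:
            pressure = np.full(grid.n_cells, 0.8)
        else:
            f0 = initial[0]
            forest_rank = (np.argsort(np.argsort(f0)) + 0.5) / f0.size
            b = cfg.pressure_forest_bias
            pressure = (1.0 - b) * field + b * forest_rank
        theta = 10.0 * cfg.conversion_depth / cfg.loss_rate  # e-folding time, years
        natural0 = initial[_FOREST_IDX] + initial[_GRASS_IDX]
        natural = natural0.copy()
        floor = natural0 * (1.0 - cfg.conversion_depth * pressure)
        split = np.array([0.5, 0.4, 0.1])  # cropland : pasture : urban
        frozen = np.zeros(grid.n_cells, dtype=bool)
        for i, year in enumerate(years[:-1]):  # transition year -> year+1
            if cfg.pa_effect == "freeze":
                frozen = np.isfinite(protection_year) & (protection_year <= year)
            if year + 1 > cfg.loss_onset_year:
                a = np.maximum(natural - floor, 0.0) / theta * ~frozen
                delta[i] = split[:, None] * a[None, :]
                natural = natural - a
    return AnthropogenicChangeSeries(grid, years, delta)


def _biomes(grid: GridSpec) -> tuple[np.ndarray, dict[str, shapely.Polygon]]:
    """Seven latitudinal biome bands (fewer if the grid has fewer rows)."""
    ny, nx = grid.shape
    n_bands = min(len(BIOME_LABELS), ny)
    edges = np.linspace(0, ny, n_bands + 1).astype(int)
    labels = np.empty(grid.n_cells, dtype="U12")
    polys: dict[str, shapely.Polygon] = {}
    lat_e = grid.lat_edges()
    for b in range(n_bands):
        name = BIOME_LABELS[b]
        rows = np.arange(edges[b], edges[b + 1])
        for iy in rows:
            labels[iy * nx:(iy + 1) * nx] = name
        polys[name] = shapely.box(grid.lon_min, lat_e[edges[b]],
                                  grid.lon_max, lat_e[edges[b + 1]])
    return labels, polys


def _species(cfg: SyntheticWorldConfig, forest0: np.ndarray,
             rng: np.random.Generator) -> tuple[list[SpeciesRecord], dict[str, float],
                                                dict[str, np.ndarray]]:
    grid = cfg.grid
    records: list[SpeciesRecord] = []
    tolerances: dict[str, float] = {}
    masks: dict[str, np.ndarray] = {}
    cats = list(_CATEGORY_PROBS)
    cat_p = np.array([_CATEGORY_PROBS[c] for c in cats])
    other_habitats = [h for h in HABITATS if h != "forest"]
    lo, hi = cfg.range_size_cells
    for group in GROUPS:
        for k in range(cfg.n_species_per_group):
            sid = f"{group}_{k:04d}"
            is_forest = rng.random() < cfg.habitat_affinity_mix
            habitat = "forest" if is_forest else str(rng.choice(other_habitats))
            affinity = forest0 if is_forest else (1.0 - forest0)
            b = cfg.range_forest_bias
            weight = (1.0 - b) + b * affinity
            target = int(rng.integers(lo, hi + 1))
            mask = _grow_range(grid, weight, target, rng)
            poly = _cells_to_polygon(grid, mask)
            parts = [RangePart(poly)]
            if rng.random() < 0.10:  # a non-qualifying part, as real ranges have
                extra = _cells_to_polygon(grid, _grow_range(grid, weight, 3, rng))
                parts.append(RangePart(extra, origin="introduced"))
            cat = str(rng.choice(cats, p=cat_p))
            records.append(SpeciesRecord(sid, group, parts, habitat, cat))
            tolerances[sid] = float(rng.uniform(*cfg.tolerance_range))
            masks[sid] = mask
    return records, tolerances, masks


def _emissions(cfg: SyntheticWorldConfig, rng: np.random.Generator) -> pd.Series:
    y0, y1 = cfg.emissions_years
    years = np.arange(y0, y1 + 1)
    growth = math.log(50.0) / max(y1 - y0, 1)  # ~50-fold rise over the record
    base = np.exp(growth * (years - y0))
    noise = np.exp(rng.normal(0.0, 0.03, size=len(years)))
    return pd.Series(base * noise, index=pd.Index(years, name="year"),
                     name="emissions")


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate the complete synthetic study system for one config + seed.

    The cover record is produced by running the generated anthropogenic change
    series through the forward proportional-allocation rule from the generated
    initial map, so reconstruction and truth share one arithmetic.  Species'
    present-day range polygons are rebuilt from the cells still occupied in
    the final year; a species occupying no cell by then is recorded as EX.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    children = dict(zip(("cover", "pa", "loss", "species", "relax", "emissions"),
                        root.spawn(6)))
    streams = {name: np.random.default_rng(child) for name, child in children.items()}

    initial = _initial_cover(cfg, streams["cover"])
    forest0 = initial[CLASSES.index("forest")]
    pas, protection_truth = _protected_areas(cfg, forest0, streams["pa"])
    changes = _change_series(cfg, initial, protection_truth, streams["loss"])
    cover, clip_log = forward_reconstruct(initial, changes, cfg.year_end)
    if clip_log.cells:
        raise RuntimeError("synthetic change series unexpectedly required clipping")

    records, tolerances, range_masks = _species(cfg, forest0, streams["species"])
    order = [r.species_id for r in records]
    tol = np.array([tolerances[s] for s in order])
    init_occ = np.stack([range_masks[s] for s in order]) & (forest0 >= tol[:, None])
    occupancy = apply_relaxation(init_occ, cover, tol, cfg.relaxation_halflife,
                                 children["relax"])

    # present-day ranges: cells still occupied in the final year
    final = occupancy[-1]
    species_out: list[SpeciesRecord] = []
    for i, rec in enumerate(records):
        poly = _cells_to_polygon(cfg.grid, final[i])
        cat = rec.category if final[i].any() else "EX"
        parts = [RangePart(poly)] + list(rec.parts[1:])
        species_out.append(SpeciesRecord(rec.species_id, rec.group, parts,
                                         rec.primary_habitat, cat))

    labels, biome_polys = _biomes(cfg.grid)
    emissions = _emissions(cfg, streams["emissions"])
    return SyntheticWorld(cfg, cfg.grid, cover, initial, changes, species_out,
                          tolerances, range_masks, occupancy, order, pas,
                          protection_truth, labels, biome_polys, emissions)


def equilibrium_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """The no-lag twin: identical world but with τ = 0 (instant extinction)."""
    return generate_world(replace(config, relaxation_halflife=0.0))
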