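"""Biome and protected-area stratification of the correlation scan.

Grid cells are labelled with one forested biome each (majority-area rule for
cells straddling boundaries) and split, per biome, into the cells that have
ever been covered by a protected area with a status year at or before the
cutoff versus the cells never covered.  The correlation scan then runs
independently on each (biome, stratum) mask; per-stratum forest cover is an
area-weighted percentage so that unequal spherical cell areas do not bias the
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.strtree import STRtree

from .debtscan import CorrelationSeries, correlation_scan
from .grid import GridSpec
from .rangegrid import RichnessStack, _grid_boxes
from .reconstruct import LandCoverSeries

log = logging.getLogger(__name__)

BIOMES = ("BF", "TCF", "TBMF", "MFWS", "TSCF", "TSDBF", "TSMBF", "non-forested")
STRATA = ("protected", "never")

_AREA_EPS = 1e-12


@dataclass
class ProtectionHistory:
    """Per-cell earliest protection year (NaN = never) and the PAs behind it."""

    grid: GridSpec
    earliest_year: np.ndarray           # float array, NaN for never-protected
    sources: dict[int, list[str]]       # cell_id -> PA ids intersecting it

    def protected_mask(self, as_of_year: int | None = None) -> np.ndarray:
        if as_of_year is None:
            return np.isfinite(self.earliest_year)
        return np.isfinite(self.earliest_year) & (self.earliest_year <= as_of_year)


@dataclass
class BiomeMap:
    """One biome label per cell."""

    grid: GridSpec
    labels: np.ndarray

    def __post_init__(self) -> None:
        unknown = set(np.unique(self.labels)) - set(BIOMES)
        if unknown:
            raise ValueError(f"unknown biome labels: {sorted(unknown)}")

    def mask(self, biome: str) -> np.ndarray:
        if biome not in BIOMES:
            raise ValueError(f"unknown biome label: {biome}")
        return self.labels == biome

    def present_biomes(self) -> list[str]:
        present = set(np.unique(self.labels))
        return [b for b in BIOMES[:-1] if b in present]


def assign_protection(grid: GridSpec, pas: list, cutoff_year: int) -> ProtectionHistory:
    """Earliest protection year per cell from PA polygons with status years.

    A cell counts as protected iff it overlaps (with positive area) at least
    one protected area whose status year is at or before ``cutoff_year``.
    PAs without a status year are excluded and logged.  ``pas`` is any
    iterable of objects with ``pa_id``, ``polygon`` and ``status_year``.
    """
    earliest = np.full(grid.n_cells, np.nan)
    sources: dict[int, list[str]] = {}
    usable = []
    for pa in pas:
        if pa.status_year is None:
            log.warning("protected area %s has no status year; excluded", pa.pa_id)
            continue
        if pa.status_year <= cutoff_year:
            usable.append(pa)
    if not usable:
        return ProtectionHistory(grid, earliest, sources)
    boxes = _grid_boxes(grid)
    tree = STRtree(boxes)
    for pa in usable:
        cand = tree.query(pa.polygon)
        if len(cand) == 0:
            continue
        areas = shapely.area(shapely.intersection(boxes[cand], pa.polygon))
        for cid in cand[areas > _AREA_EPS]:
            cid = int(cid)
            y = float(pa.status_year)
            if not np.isfinite(earliest[cid]) or y < earliest[cid]:
                earliest[cid] = y
            sources.setdefault(cid, []).append(pa.pa_id)
    return ProtectionHistory(grid, earliest, sources)


def assign_biomes(grid: GridSpec, biome_polygons: dict[str, shapely.Geometry],
                  fill: str = "non-forested") -> BiomeMap:
    """Label each cell with the biome holding the largest share of its area."""
    boxes = _grid_boxes(grid)
    best_area = np.zeros(grid.n_cells)
    labels = np.full(grid.n_cells, fill, dtype="U12")
    for name, poly in biome_polygons.items():
        if name not in BIOMES:
            raise ValueError(f"unknown biome label: {name}")
        areas = shapely.area(shapely.intersection(boxes, poly))
        take = areas > best_area
        labels[take] = name
        best_area[take] = areas[take]
    return BiomeMap(grid, labels)


def area_weighted_cover(cover: LandCoverSeries, mask: np.ndarray,
                        areas: np.ndarray | None = None,
                        cover_class: str = "forest") -> np.ndarray:
    """Area-weighted percent cover of one class over a cell subset, per year.

    Σ(fraction · area) / Σ(area) × 100 for every year of the series; ``areas``
    defaults to the spherical cell areas of the grid.
    """
    mask = np.asarray(mask)
    cells = np.flatnonzero(mask) if mask.dtype == bool else mask.astype(int)
    if len(cells) == 0:
        raise ValueError("empty cell mask")
    if areas is None:
        areas = cover.grid.cell_areas()
    w = areas[cells]
    frac = cover.cover[:, cover.class_index(cover_class), :][:, cells]
    return 100.0 * (frac @ w) / w.sum()


def stratified_scan(stack: RichnessStack, cover: LandCoverSeries,
                    biome_map: BiomeMap, protection: ProtectionHistory,
                    group: str, category_set: str = "ALL",
                    **scan_kwargs) -> dict[tuple[str, str], CorrelationSeries]:
    """Independent correlation scans per (biome, protection stratum).

    Returns one :class:`CorrelationSeries` per combination of present forested
    biome and stratum ("protected" = ever covered by a qualifying PA, "never"
    = never covered).  Combinations with fewer than 3 cells come back as
    flagged-missing series rather than being dropped, so the output cardinality
    is always 2 × the number of biomes present.
    """
    prot = protection.protected_mask()
    out: dict[tuple[str, str], CorrelationSeries] = {}
    for biome in biome_map.present_biomes():
        bmask = biome_map.mask(biome)
        for stratum, smask in (("protected", prot), ("never", ~prot)):
            out[(biome, stratum)] = correlation_scan(
                stack, cover, group, category_set, mask=bmask & smask, **scan_kwargs)
    return out
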