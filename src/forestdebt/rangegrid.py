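"""Species range filtering, rasterization and richness stacking.

Inputs are expert range maps: one record per species carrying a set of range
parts (polygons tagged with presence / origin / seasonality codes), a primary
habitat code and a Red List category.  The analysis keeps forest-dwelling,
extant species only, burns each surviving range onto the grid (a cell is
occupied iff the range overlaps it with positive area), and stacks the
per-species masks into richness layers by taxonomic group and category set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .grid import GridSpec

GROUPS = ("mammal", "amphibian", "reptile")
CATEGORIES = ("CR", "EN", "VU", "NT", "LC", "DD", "EX", "EW")
HABITATS = ("forest", "shrubland", "grassland", "desert", "freshwater", "marine")
PRESENCE_CODES = ("extant", "possibly_extinct", "extinct")
ORIGIN_CODES = ("native", "reintroduced", "introduced", "vagrant")
SEASONALITY_CODES = ("resident", "breeding", "non_breeding", "passage")

# layers of the richness stack: every single Red List category plus the
# cumulative layer (incl. DD) and the threatened aggregate CR∪EN∪VU
CATEGORY_SETS = ("ALL", "CR", "EN", "VU", "NT", "LC", "DD", "threatened")
THREATENED = frozenset({"CR", "EN", "VU"})

_KEEP_ORIGIN = frozenset({"native", "reintroduced"})
_KEEP_SEASONALITY = frozenset({"resident", "breeding", "non_breeding"})


@dataclass(frozen=True)
class RangePart:
    """One polygon of a species' range with its IUCN-style attribute codes."""

    polygon: BaseGeometry
    presence: str = "extant"
    origin: str = "native"
    seasonality: str = "resident"


@dataclass
class SpeciesRecord:
    """A species with its range parts, habitat affiliation and Red List status."""

    species_id: str
    group: str
    parts: list[RangePart]
    primary_habitat: str
    category: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.species_id}: unknown group {self.group!r}")
        if self.primary_habitat not in HABITATS:
            raise ValueError(f"{self.species_id}: unknown habitat code {self.primary_habitat!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.species_id}: unknown category {self.category!r}")
        for p in self.parts:
            if p.presence not in PRESENCE_CODES or p.origin not in ORIGIN_CODES \
                    or p.seasonality not in SEASONALITY_CODES:
                raise ValueError(f"{self.species_id}: unknown range-part code")

    @classmethod
    def from_polygon(cls, species_id: str, group: str, polygon: BaseGeometry,
                     primary_habitat: str, category: str, presence: str = "extant",
                     origin: str = "native", seasonality: str = "resident") -> "SpeciesRecord":
        """Whole-range constructor for the common single-attribute case."""
        return cls(species_id, group, [RangePart(polygon, presence, origin, seasonality)],
                   primary_habitat, category)

    def geometry(self) -> BaseGeometry:
        """Union of all range parts (a species counts once per cell)."""
        if not self.parts:
            return shapely.Polygon()
        return unary_union([p.polygon for p in self.parts])


def filter_forest_dwelling(records: list[SpeciesRecord]) -> list[SpeciesRecord]:
    """Apply the forest-dwelling inclusion rules.

    Keeps species whose *primary* habitat is forest (secondary habitats are
    irrelevant here), drops Extinct (EX) and Extinct-in-the-Wild (EW) species,
    and within each kept species retains only the range parts that are extant,
    native or reintroduced, and resident / breeding / non-breeding.  A species
    left with no qualifying part is dropped.
    """
    kept: list[SpeciesRecord] = []
    for rec in records:
        if rec.primary_habitat != "forest":
            continue
        if rec.category in ("EX", "EW"):
            continue
        parts = [p for p in rec.parts
                 if p.presence == "extant" and p.origin in _KEEP_ORIGIN
                 and p.seasonality in _KEEP_SEASONALITY]
        if not parts:
            continue
        kept.append(SpeciesRecord(rec.species_id, rec.group, parts,
                                  rec.primary_habitat, rec.category))
    return kept


@lru_cache(maxsize=8)
def _grid_boxes(grid: GridSpec) -> np.ndarray:
    lon_e, lat_e = grid.lon_edges(), grid.lat_edges()
    west = np.tile(lon_e[:-1], grid.n_lat)
    south = np.repeat(lat_e[:-1], grid.n_lon)
    r = grid.resolution
    return shapely.box(west, south, west + r, south + r)


_AREA_EPS = 1e-12


def rasterize_range(record: SpeciesRecord | BaseGeometry, grid: GridSpec,
                    rule: str = "area") -> np.ndarray:
    """Boolean presence mask (n_cells,) for one species range.

    With the default ``rule="area"`` a cell counts as occupied iff the range
    polygon overlaps the cell rectangle with positive area; touching a cell
    only along its boundary does not count.  ``rule="centroid"`` is the
    stricter sensitivity variant: the cell centre itself must fall inside the
    range.  Cells are half-open, row-major from the south-west.
    """
    geom = record.geometry() if isinstance(record, SpeciesRecord) else record
    mask = np.zeros(grid.n_cells, dtype=bool)
    if geom.is_empty:
        return mask
    if not geom.is_valid:
        raise ValueError("invalid geometry")
    if rule == "centroid":
        c = grid.centroids()
        return shapely.contains_xy(geom, c[:, 0], c[:, 1])
    if rule != "area":
        raise ValueError("rule must be 'area' or 'centroid'")
    boxes = _grid_boxes(grid)
    cand = np.flatnonzero(shapely.intersects(boxes, geom))
    if len(cand):
        areas = shapely.area(shapely.intersection(boxes[cand], geom))
        mask[cand[areas > _AREA_EPS]] = True
    return mask


@dataclass
class RichnessStack:
    """Per-cell species counts by (group, category set), plus an inverse index.

    ``counts[(group, cset)]`` is an int array of shape (n_cells,);
    ``species_index`` maps species_id -> the set of occupied cell ids.
    """

    grid: GridSpec
    counts: dict[tuple[str, str], np.ndarray]
    species_index: dict[str, frozenset] = field(default_factory=dict)

    def layer(self, group: str, category_set: str = "ALL") -> np.ndarray:
        return self.counts[(group, category_set)]

    def to_dataframe(self) -> pd.DataFrame:
        """Long table (cell_id, group, category_set, count)."""
        rows = []
        for (group, cset), arr in self.counts.items():
            rows.append(pd.DataFrame({
                "cell_id": np.arange(self.grid.n_cells),
                "group": group, "category_set": cset, "count": arr,
            }))
        return pd.concat(rows, ignore_index=True)


def _category_sets_of(category: str) -> list[str]:
    sets = ["ALL", category]
    if category in THREATENED:
        sets.append("threatened")
    return sets


def stack_richness(presences: dict[str, np.ndarray],
                   records: list[SpeciesRecord], grid: GridSpec) -> RichnessStack:
    """Sum per-species presence masks into richness layers.

    ``presences`` maps species_id -> boolean mask on ``grid``.  Every record
    must have a mask; masks must match the grid size.  The result carries one
    integer layer per (group, category set) and the inverse species -> cells
    index used by consistency checks and audits.
    """
    counts = {(g, cs): np.zeros(grid.n_cells, dtype=int)
              for g in GROUPS for cs in CATEGORY_SETS}
    index: dict[str, frozenset] = {}
    for rec in records:
        mask = presences[rec.species_id]
        if mask.shape != (grid.n_cells,):
            raise ValueError(f"{rec.species_id}: mask does not match grid")
        for cs in _category_sets_of(rec.category):
            counts[(rec.group, cs)][mask] += 1
        index[rec.species_id] = frozenset(np.flatnonzero(mask).tolist())
    return RichnessStack(grid, counts, index)


def rasterize_and_stack(records: list[SpeciesRecord], grid: GridSpec) -> RichnessStack:
    """Convenience: rasterize every record and stack in one call."""
    pres = {rec.species_id: rasterize_range(rec, grid) for rec in records}
    return stack_richness(pres, records, grid)
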