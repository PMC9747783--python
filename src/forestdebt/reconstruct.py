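"""Annual land-cover reconstruction by the proportional allocation rule.

The historical record of anthropogenic land use (urban, cropland, pasture) is
taken as prescribed: the reconstruction never solves for it.  What is solved
for is the natural side of the ledger.  Stepping one year at a time, the net
change in total anthropogenic area ΔA is charged against (or returned to) the
two natural classes — forest and natural grassland — in proportion to their
current fractions f/(f+g) and g/(f+g).  Because proportional allocation
preserves the f:g ratio, the backward recursion is the exact inverse of the
forward one wherever no clipping occurs, which the tests exploit as a
round-trip oracle.

Independent reconstructions (e.g., a backward run anchored on a present-day
map and a forward run from a historical initial map) are combined per cell and
year by an ensemble mean restricted to their common years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec

CLASSES = ("forest", "natural_grassland", "cropland", "pasture", "urban", "other")
ANTHRO_CLASSES = ("cropland", "pasture", "urban")
_FOREST, _GRASS = 0, 1
_ANTHRO = slice(2, 5)
_OTHER = 5

CLOSURE_TOL = 1e-9


@dataclass
class LandCoverSeries:
    """Fractional land cover per cell, class and year.

    ``cover`` has shape (n_years, 6, n_cells) with classes ordered as
    :data:`CLASSES`; fractions of each cell-year sum to 1.
    """

    grid: GridSpec
    years: np.ndarray
    cover: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.cover = np.asarray(self.cover, dtype=float)
        if self.years.ndim != 1 or np.any(np.diff(self.years) != 1):
            raise ValueError("years must be contiguous at 1-year steps")
        expected = (len(self.years), len(CLASSES), self.grid.n_cells)
        if self.cover.shape != expected:
            raise ValueError(f"cover shape {self.cover.shape} != {expected}")
        if np.any(self.cover < -CLOSURE_TOL) or np.any(self.cover > 1 + CLOSURE_TOL):
            raise ValueError("cover fractions must lie in [0, 1]")
        closure = self.cover.sum(axis=1)
        if np.any(np.abs(closure - 1.0) > 1e-6):
            raise ValueError("class fractions must sum to 1 per cell-year")

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year: int) -> int:
        idx = int(year) - int(self.years[0])
        if not 0 <= idx < self.n_years:
            raise KeyError(f"year {year} outside {self.years[0]}–{self.years[-1]}")
        return idx

    def class_index(self, name: str) -> int:
        return CLASSES.index(name)

    def fraction(self, cls: str, year: int) -> np.ndarray:
        """Per-cell fraction of one class in one year (flattened, row-major)."""
        return self.cover[self.year_index(year), self.class_index(cls)]

    def forest_fraction(self, year: int) -> np.ndarray:
        return self.fraction("forest", year)

    def select_years(self, start: int, end: int) -> "LandCoverSeries":
        i0, i1 = self.year_index(start), self.year_index(end)
        return LandCoverSeries(self.grid, self.years[i0:i1 + 1], self.cover[i0:i1 + 1])

    def to_dataframe(self) -> pd.DataFrame:
        """Long table (year, cell_id, class, fraction)."""
        ny, nc, ng = self.cover.shape
        return pd.DataFrame({
            "year": np.repeat(self.years, nc * ng),
            "class": np.tile(np.repeat(CLASSES, ng), ny),
            "cell_id": np.tile(np.arange(ng), ny * nc),
            "fraction": self.cover.ravel(),
        })


@dataclass
class AnthropogenicChangeSeries:
    """Prescribed annual net changes in urban, cropland and pasture fractions.

    ``delta`` has shape (n_years - 1, 3, n_cells), ordered (cropland, pasture,
    urban); ``delta[i]`` is cover(years[i] + 1) − cover(years[i]) in forward
    time.  The backward recursion consumes the same array with opposite sign.
    """

    grid: GridSpec
    years: np.ndarray  # full year range start..end inclusive
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.delta = np.asarray(self.delta, dtype=float)
        expected = (len(self.years) - 1, len(ANTHRO_CLASSES), self.grid.n_cells)
        if self.delta.shape != expected:
            raise ValueError(f"delta shape {self.delta.shape} != {expected}")
        if np.any(np.abs(self.delta) > 1.0 + CLOSURE_TOL):
            raise ValueError("|delta| must be <= 1")


@dataclass
class ClipLog:
    """Book-keeping of cells where mass balance forced clipping."""

    n_natural_clips: int = 0
    n_other_clips: int = 0
    n_anthro_clips: int = 0
    n_degenerate: int = 0
    cells: set = field(default_factory=set)

    def merge_mask(self, mask: np.ndarray, kind: str) -> None:
        n = int(mask.sum())
        if kind == "natural":
            self.n_natural_clips += n
        elif kind == "other":
            self.n_other_clips += n
        elif kind == "anthro":
            self.n_anthro_clips += n
        else:
            self.n_degenerate += n
        if n:
            self.cells.update(np.flatnonzero(mask).tolist())


def _allocate_step(state: np.ndarray, anthro_new: np.ndarray, log: ClipLog,
                   fixed_share: np.ndarray | None = None) -> np.ndarray:
    """Advance one year: replace anthropogenic classes, re-balance naturals.

    ``state`` is (6, n_cells); ``anthro_new`` the prescribed (3, n_cells)
    anthropogenic fractions for the target year.  Net anthropogenic growth is
    taken from forest and natural grassland pro rata; shrinkage is returned the
    same way.  Deficits cascade natural -> other natural -> "other".
    ``fixed_share`` overrides the forest share of the split (anchor-ratio
    sensitivity mode); by default the current f/(f+g) is used.
    """
    clipped = np.clip(anthro_new, 0.0, 1.0)
    log.merge_mask(np.any(clipped != anthro_new, axis=0), "anthro")
    anthro_new = clipped
    d_total = anthro_new.sum(axis=0) - state[_ANTHRO].sum(axis=0)

    f, g = state[_FOREST].copy(), state[_GRASS].copy()
    nat = f + g
    ok = nat > 0
    if fixed_share is None:
        share_f = np.where(ok, np.divide(f, nat, out=np.zeros_like(f), where=ok), 0.0)
    else:
        share_f = np.where(ok, fixed_share, 0.0)

    f_new = f - d_total * share_f
    g_new = g - d_total * (1.0 - share_f)
    # degenerate cells (no natural land): charge the change to "other"
    degen = (~ok) & (d_total != 0)
    log.merge_mask(degen, "degenerate")
    g_new = np.where(ok, g_new, 0.0)
    f_new = np.where(ok, f_new, 0.0)

    # cascade negative naturals onto the other natural class
    neg_f = f_new < 0
    g_new = np.where(neg_f, g_new + f_new, g_new)
    f_new = np.where(neg_f, 0.0, f_new)
    neg_g = g_new < 0
    f_new = np.where(neg_g, f_new + g_new, f_new)
    g_new = np.where(neg_g, 0.0, g_new)
    still_neg = f_new < 0
    f_new = np.where(still_neg, 0.0, f_new)
    log.merge_mask(neg_f | neg_g, "natural")

    out = np.empty_like(state)
    out[_FOREST], out[_GRASS] = f_new, g_new
    out[_ANTHRO] = anthro_new
    other = 1.0 - out[:_OTHER].sum(axis=0)
    short = other < 0
    if np.any(short):
        # residual "other" went negative: renormalize the remaining classes
        log.merge_mask(short, "other")
        scale = np.where(short, 1.0 / out[:_OTHER].sum(axis=0), 1.0)
        out[:_OTHER] *= scale
        other = np.where(short, 0.0, other)
    out[_OTHER] = np.clip(other, 0.0, 1.0)
    return out


def _check_anchor(anchor: np.ndarray, grid: GridSpec) -> np.ndarray:
    anchor = np.asarray(anchor, dtype=float)
    if anchor.shape != (len(CLASSES), grid.n_cells):
        raise ValueError(f"anchor map must have shape (6, {grid.n_cells})")
    if np.any(np.abs(anchor.sum(axis=0) - 1.0) > 1e-6):
        raise ValueError("anchor map violates closure")
    return anchor


def _anchor_share(anchor: np.ndarray, mode: str) -> np.ndarray | None:
    if mode == "updated":
        return None
    if mode != "anchor":
        raise ValueError("allocation_ratio must be 'updated' or 'anchor'")
    nat = anchor[_FOREST] + anchor[_GRASS]
    ok = nat > 0
    return np.where(ok, np.divide(anchor[_FOREST], nat,
                                  out=np.zeros_like(nat), where=ok), 0.0)


def backward_reconstruct(current: np.ndarray, changes: AnthropogenicChangeSeries,
                         start_year: int,
                         allocation_ratio: str = "updated") -> tuple[LandCoverSeries, ClipLog]:
    """Recursively reconstruct cover back in time from a present-day anchor map.

    ``current`` is the (6, n_cells) map at ``changes.years[-1]``; the result
    spans ``start_year``..that anchor year.  Returns the series and a clip log
    recording every cell where mass balance forced a departure from the pure
    proportional rule.  ``allocation_ratio`` is a sensitivity switch: the
    forest:grassland split ratio is re-read every recursion step ("updated",
    default) or frozen at the anchor map ("anchor"); the two agree exactly on
    clip-free trajectories because proportional allocation preserves the ratio.
    """
    grid = changes.grid
    current = _check_anchor(current, grid)
    share = _anchor_share(current, allocation_ratio)
    end_year = int(changes.years[-1])
    if not int(changes.years[0]) <= start_year < end_year:
        raise ValueError("start_year outside the change series range")
    n = end_year - start_year + 1
    cover = np.empty((n, len(CLASSES), grid.n_cells))
    cover[-1] = current
    log = ClipLog()
    for k in range(1, n):
        t_idx = changes.years.tolist().index(end_year - k)  # transition (t, t+1)
        anthro_past = cover[-k][_ANTHRO] - changes.delta[t_idx]
        cover[-k - 1] = _allocate_step(cover[-k], anthro_past, log, share)
    series = LandCoverSeries(grid, np.arange(start_year, end_year + 1), cover)
    return series, log


def forward_reconstruct(initial: np.ndarray, changes: AnthropogenicChangeSeries,
                        end_year: int,
                        allocation_ratio: str = "updated") -> tuple[LandCoverSeries, ClipLog]:
    """Run the allocation rule forward from an initial (historical) map.

    Mirror image of :func:`backward_reconstruct`: ``initial`` is the map at
    ``changes.years[0]`` and the result spans that year..``end_year``.
    """
    grid = changes.grid
    initial = _check_anchor(initial, grid)
    share = _anchor_share(initial, allocation_ratio)
    start_year = int(changes.years[0])
    if not start_year < end_year <= int(changes.years[-1]):
        raise ValueError("end_year outside the change series range")
    n = end_year - start_year + 1
    cover = np.empty((n, len(CLASSES), grid.n_cells))
    cover[0] = initial
    log = ClipLog()
    for k in range(1, n):
        anthro_next = cover[k - 1][_ANTHRO] + changes.delta[k - 1]
        cover[k] = _allocate_step(cover[k - 1], anthro_next, log, share)
    series = LandCoverSeries(grid, np.arange(start_year, end_year + 1), cover)
    return series, log


def ensemble_mean(members: list[LandCoverSeries],
                  weights: list[float] | None = None) -> LandCoverSeries:
    """Per-cell-year (weighted) mean of reconstructions over their common years.

    Members must share a grid; the result is restricted to the intersection of
    their year ranges.  Default weights are equal.
    """
    if not members:
        raise ValueError("ensemble requires at least one member")
    grid = members[0].grid
    if any(m.grid != grid for m in members):
        raise ValueError("ensemble members must share a grid")
    lo = max(int(m.years[0]) for m in members)
    hi = min(int(m.years[-1]) for m in members)
    if lo > hi:
        raise ValueError("ensemble members have no overlapping years")
    if weights is None:
        w = np.full(len(members), 1.0 / len(members))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(members) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("invalid ensemble weights")
        w = w / w.sum()
    stack = np.stack([m.select_years(lo, hi).cover for m in members])
    mean = np.tensordot(w, stack, axes=(0, 0))
    # guard closure against float accumulation
    mean /= mean.sum(axis=1, keepdims=True)
    return LandCoverSeries(grid, np.arange(lo, hi + 1), mean)
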