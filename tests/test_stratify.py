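"""Protection assignment, biome labelling and stratum-wise cover/scans."""

import dataclasses
from fractions import Fraction

import numpy as np
import pytest
import shapely

import forestdebt as fd
from forestdebt.synthetic_world import ProtectedAreaRecord

from conftest import constant_cover_series


def pa(pa_id, poly, year):
    return ProtectedAreaRecord(pa_id, poly, year)


class TestAssignProtection:
    def test_no_pas_all_unprotected(self, small_grid):
        hist = fd.assign_protection(small_grid, [], cutoff_year=1992)
        assert not np.any(np.isfinite(hist.earliest_year))

    def test_single_cell_pa(self, small_grid):
        poly = shapely.box(*small_grid.cell_bounds(55))
        hist = fd.assign_protection(small_grid, [pa("p", poly, 1900)], 1992)
        assert hist.earliest_year[55] == 1900
        assert np.isfinite(hist.earliest_year).sum() == 1
        assert hist.sources[55] == ["p"]

    def test_cutoff_excludes_late_pas(self, small_grid):
        poly = shapely.box(*small_grid.cell_bounds(0))
        hist = fd.assign_protection(small_grid, [pa("p", poly, 2000)], 1992)
        assert not np.any(np.isfinite(hist.earliest_year))

    def test_missing_status_year_excluded(self, small_grid, caplog):
        poly = shapely.box(*small_grid.cell_bounds(0))
        with caplog.at_level("WARNING"):
            hist = fd.assign_protection(small_grid, [pa("nodate", poly, None)], 1992)
        assert not np.any(np.isfinite(hist.earliest_year))
        assert "nodate" in caplog.text

    def test_earliest_year_wins_on_overlap(self, small_grid):
        poly = shapely.box(*small_grid.cell_bounds(7))
        hist = fd.assign_protection(
            small_grid, [pa("a", poly, 1950), pa("b", poly, 1910)], 1992)
        assert hist.earliest_year[7] == 1910

    def test_random_pas_match_brute_force_intersection(self, small_grid):
        # oracle: all-pairs polygon x cell intersection with positive area
        rng = np.random.default_rng(12)
        pas = []
        for k in range(50):
            cx = rng.uniform(small_grid.lon_min, small_grid.lon_max)
            cy = rng.uniform(small_grid.lat_min, small_grid.lat_max)
            w, h = rng.uniform(0.2, 1.5, size=2)
            pas.append(pa(f"p{k}", shapely.box(cx, cy, cx + w, cy + h),
                          int(rng.integers(1800, 1993))))
        hist = fd.assign_protection(small_grid, pas, 1992)
        expect = np.full(small_grid.n_cells, np.nan)
        for cid in range(small_grid.n_cells):
            cell = shapely.box(*small_grid.cell_bounds(cid))
            for p in pas:
                if cell.intersection(p.polygon).area > 1e-12:
                    y = float(p.status_year)
                    if not np.isfinite(expect[cid]) or y < expect[cid]:
                        expect[cid] = y
        assert np.array_equal(np.isnan(hist.earliest_year), np.isnan(expect))
        finite = np.isfinite(expect)
        assert np.array_equal(hist.earliest_year[finite], expect[finite])


class TestAssignBiomes:
    def test_majority_area_rule(self, small_grid):
        # split the grid down the middle of a cell column: each straddling
        # cell goes to whichever biome holds more of it
        mid = small_grid.lon_min + 2.7 * small_grid.resolution
        polys = {"BF": shapely.box(small_grid.lon_min, small_grid.lat_min,
                                   mid, small_grid.lat_max),
                 "TSMBF": shapely.box(mid, small_grid.lat_min,
                                      small_grid.lon_max, small_grid.lat_max)}
        bm = fd.assign_biomes(small_grid, polys)
        labels = bm.labels.reshape(small_grid.shape)
        assert set(labels[:, :2].ravel()) == {"BF"}      # fully inside BF
        assert set(labels[:, 2].ravel()) == {"BF"}       # 70% of cell in BF
        assert set(labels[:, 3:].ravel()) == {"TSMBF"}

    def test_unknown_label_rejected(self, small_grid):
        with pytest.raises(ValueError, match="unknown biome"):
            fd.assign_biomes(small_grid, {"JUNGLE": shapely.box(0, 0, 1, 1)})


class TestAreaWeightedCover:
    def test_uniform_fraction_ignores_weights(self, small_grid):
        cover = constant_cover_series(small_grid, np.arange(1900, 1910), forest=0.4)
        pct = fd.area_weighted_cover(cover, np.ones(small_grid.n_cells, dtype=bool))
        assert np.allclose(pct, 40.0)

    def test_two_cell_hand_arithmetic(self, small_grid):
        cover = constant_cover_series(small_grid, [1900, 1901], forest=0.0, grass=0.0)
        cover.cover[:, 0, 1] = 1.0
        cover.cover[:, 5, :] = 1.0 - cover.cover[:, :5, :].sum(axis=1)
        mask = np.zeros(small_grid.n_cells, dtype=bool)
        mask[:2] = True
        pct = fd.area_weighted_cover(cover, mask, areas=np.array([1.0, 3.0] + [0.0] * 98))
        assert np.allclose(pct, 75.0)

    def test_matches_exact_rational_arithmetic(self, small_grid):
        rng = np.random.default_rng(4)
        cover = constant_cover_series(small_grid, [1900], forest=0.0)
        fr_pct = rng.integers(0, 101, small_grid.n_cells)
        cover.cover[:, 0, :] = fr_pct / 100
        cover.cover[:, 5, :] = 1.0 - cover.cover[:, :5, :].sum(axis=1)
        areas = rng.integers(1, 1000, small_grid.n_cells).astype(float)
        got = fd.area_weighted_cover(cover, np.ones(small_grid.n_cells, bool),
                                     areas=areas)[0]
        num = sum(Fraction(int(f), 100) * Fraction(int(a))
                  for f, a in zip(fr_pct, areas))
        oracle = float(100 * num / Fraction(int(areas.sum())))
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_empty_mask_rejected(self, small_grid):
        cover = constant_cover_series(small_grid, [1900])
        with pytest.raises(ValueError, match="empty"):
            fd.area_weighted_cover(cover, np.zeros(small_grid.n_cells, bool))


@pytest.fixture(scope="module")
def guarded_world():
    """Uniform initial cover + frozen PA cells: ordering holds by construction."""
    cfg = fd.SyntheticWorldConfig(uniform_cover=True, pa_effect="freeze",
                                  pa_start_year=1880, n_protected_areas=20, seed=5)
    return fd.generate_world(cfg)


class TestStratifiedAnalysis:
    def test_union_cover_is_area_weighted_mean_of_strata(self, default_world):
        grid = default_world.grid
        areas = grid.cell_areas()
        prot = np.isfinite(default_world.protection_truth)
        assert prot.any() and not prot.all()
        full = fd.area_weighted_cover(default_world.cover, np.ones(grid.n_cells, bool))
        p = fd.area_weighted_cover(default_world.cover, prot)
        n = fd.area_weighted_cover(default_world.cover, ~prot)
        wa, wb = areas[prot].sum(), areas[~prot].sum()
        assert np.max(np.abs(full - (p * wa + n * wb) / (wa + wb))) < 1e-9

    def test_protected_cover_dominates_after_establishment(self, guarded_world):
        w = guarded_world
        prot = np.isfinite(w.protection_truth)
        assert prot.any() and not prot.all()
        p = fd.area_weighted_cover(w.cover, prot)
        n = fd.area_weighted_cover(w.cover, ~prot)
        first = int(np.nanmin(w.protection_truth))
        after = w.cover.years >= first
        assert np.all(p[after] >= n[after] - 1e-9)

    def test_partition_of_land_cells(self, default_world):
        protection = fd.assign_protection(default_world.grid,
                                          default_world.protected_areas, 1992)
        prot = protection.protected_mask()
        bm = fd.BiomeMap(default_world.grid, default_world.biome_labels)
        for biome in bm.present_biomes():
            m = bm.mask(biome)
            assert np.array_equal((m & prot) | (m & ~prot), m)
            assert not np.any(m & prot & ~prot)

    def test_assign_protection_matches_generator_truth(self, default_world):
        protection = fd.assign_protection(default_world.grid,
                                          default_world.protected_areas, 1992)
        truth = default_world.protection_truth
        finite = np.isfinite(truth)
        assert np.array_equal(np.isfinite(protection.earliest_year), finite)
        assert np.array_equal(protection.earliest_year[finite], truth[finite])

    def test_degenerate_stratification_equals_unstratified(self, default_world,
                                                           default_stack):
        grid = default_world.grid
        bm = fd.BiomeMap(grid, np.full(grid.n_cells, "BF", dtype="U12"))
        protection = fd.assign_protection(grid, [], 1992)
        res = fd.stratified_scan(default_stack, default_world.cover, bm, protection,
                                 "mammal", compute_ess=False)
        plain = fd.correlation_scan(default_stack, default_world.cover, "mammal",
                                    compute_ess=False)
        assert set(res) == {("BF", "protected"), ("BF", "never")}
        assert np.allclose(res[("BF", "never")].r, plain.r, equal_nan=True)
        assert np.all(np.isnan(res[("BF", "protected")].r))

    def test_output_cardinality_biomes_times_strata(self, default_world,
                                                    default_stack):
        protection = fd.assign_protection(default_world.grid,
                                          default_world.protected_areas, 1992)
        bm = fd.BiomeMap(default_world.grid, default_world.biome_labels)
        res = fd.stratified_scan(default_stack, default_world.cover, bm,
                                 protection, "amphibian", compute_ess=False)
        assert len(res) == 2 * len(bm.present_biomes()) == 14

    def test_composition_consistency_with_direct_scan(self, default_world,
                                                      default_stack):
        protection = fd.assign_protection(default_world.grid,
                                          default_world.protected_areas, 1992)
        bm = fd.BiomeMap(default_world.grid, default_world.biome_labels)
        res = fd.stratified_scan(default_stack, default_world.cover, bm,
                                 protection, "mammal", compute_ess=False)
        biome = bm.present_biomes()[3]
        mask = bm.mask(biome) & ~protection.protected_mask()
        direct = fd.correlation_scan(default_stack, default_world.cover, "mammal",
                                     "ALL", mask=mask, compute_ess=False)
        assert np.allclose(res[(biome, "never")].r, direct.r, equal_nan=True)
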