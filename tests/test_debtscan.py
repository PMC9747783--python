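"""The spatially corrected scan: Pearson identities, ESS behaviour, onset fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage

import forestdebt as fd
from forestdebt.debtscan import SpatialStructure, _pearson

from conftest import constant_cover_series


@pytest.fixture(scope="module")
def structure(small_grid):
    return SpatialStructure(small_grid.centroids())


class TestModifiedTTest:
    def test_perfect_correlation(self, small_grid):
        x = np.arange(small_grid.n_cells, dtype=float)
        res = fd.modified_ttest(x, x.copy(), small_grid.centroids())
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0)

    def test_r_equals_textbook_pearson(self, small_grid):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(small_grid.n_cells), rng.standard_normal(small_grid.n_cells)
        res = fd.modified_ttest(x, y, small_grid.centroids())
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_zero_variance_reported_missing_with_reason(self, small_grid):
        x = np.ones(small_grid.n_cells)
        y = np.arange(small_grid.n_cells, dtype=float)
        res = fd.modified_ttest(x, y, small_grid.centroids())
        assert np.isnan(res.r) and res.reason == "zero variance"

    def test_ess_bounded_by_n(self, structure, small_grid):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = ndimage.gaussian_filter(
                rng.standard_normal(small_grid.shape), 2.0).ravel()
            y = rng.standard_normal(small_grid.n_cells)
            ess = structure.effective_sample_size(x, y)
            assert 2.0 <= ess <= small_grid.n_cells

    def test_ess_equals_n_for_zero_correlograms(self, small_grid, monkeypatch):
        # the assembly formula itself: all-zero autocorrelation => ESS = n
        n = small_grid.n_cells
        structure = SpatialStructure(small_grid.centroids(),
                                     correlogram_model="empirical")
        monkeypatch.setattr(SpatialStructure, "correlogram",
                            lambda self, z: np.zeros(self.n_classes))
        x, y = np.random.default_rng(1).standard_normal((2, n))
        assert structure.effective_sample_size(x, y) == pytest.approx(n)

    def test_white_noise_ess_near_n(self, structure, small_grid):
        # with spatially independent fields the correction should be neutral
        rng = np.random.default_rng(2)
        n = small_grid.n_cells
        ratios = [structure.effective_sample_size(rng.standard_normal(n),
                                                  rng.standard_normal(n)) / n
                  for _ in range(300)]
        assert 0.9 <= np.mean(ratios) <= 1.1

    def test_autocorrelated_fields_shrink_ess(self, structure, small_grid):
        rng = np.random.default_rng(3)
        ess = []
        for _ in range(30):
            x = ndimage.gaussian_filter(rng.standard_normal(small_grid.shape), 3.0).ravel()
            y = ndimage.gaussian_filter(rng.standard_normal(small_grid.shape), 3.0).ravel()
            ess.append(structure.effective_sample_size(x, y))
        assert np.mean(ess) < 0.3 * small_grid.n_cells


class TestCorrelationScan:
    def test_constant_cover_gives_constant_r(self, default_stack, default_world):
        cover = constant_cover_series(default_world.grid, np.arange(1900, 1950))
        # vary forest across cells (r undefined on a flat field), constant in time
        cover.cover[:, 0, :] = np.linspace(0.2, 0.8, default_world.grid.n_cells)
        cover.cover[:, 5, :] = 1.0 - cover.cover[:, :5, :].sum(axis=1)
        series = fd.correlation_scan(default_stack, cover, "mammal", "ALL",
                                     compute_ess=False)
        assert len(series) == 50
        assert np.allclose(series.r, series.r[0])

    def test_scan_1500_1992_has_493_entries(self, default_world, default_stack):
        series = fd.correlation_scan(default_stack, default_world.cover,
                                     "mammal", "ALL", compute_ess=False)
        assert len(series) == 493

    def test_cell_order_and_affine_invariance(self, default_world, default_stack):
        base = fd.correlation_scan(default_stack, default_world.cover, "reptile",
                                   "ALL", compute_ess=False)
        # affine rescale of richness leaves Pearson's r untouched
        scaled = fd.RichnessStack(default_stack.grid,
                                  {k: 3 * v + 7 for k, v in default_stack.counts.items()},
                                  default_stack.species_index)
        re = fd.correlation_scan(scaled, default_world.cover, "reptile", "ALL",
                                 compute_ess=False)
        assert np.allclose(base.r, re.r, atol=1e-12)

    def test_small_mask_flagged_missing(self, default_world, default_stack):
        mask = np.zeros(default_world.grid.n_cells, dtype=bool)
        mask[:2] = True
        series = fd.correlation_scan(default_stack, default_world.cover,
                                     "mammal", "ALL", mask=mask)
        assert np.all(np.isnan(series.r))
        assert "fewer than 3" in next(iter(series.reasons.values()))


class TestDecadalChange:
    def test_constant_series_all_zero(self):
        years = np.arange(1500, 1993)
        s = fd.CorrelationSeries(years, np.full(len(years), 0.7),
                                 np.full(len(years), np.nan),
                                 np.full(len(years), np.nan),
                                 np.zeros(len(years), dtype=int), {})
        d = fd.decadal_change(s)
        assert len(d) == 49
        assert np.allclose(d, 0.0)

    @given(st.floats(-1e-3, 1e-3), st.floats(-0.5, 0.5))
    def test_linear_series_closed_form(self, b, a):
        years = np.arange(1500, 1993)
        s = fd.CorrelationSeries(years, a + b * (years - 1500),
                                 np.full(len(years), np.nan),
                                 np.full(len(years), np.nan),
                                 np.zeros(len(years), dtype=int), {})
        d = fd.decadal_change(s, step=10)
        assert np.allclose(d, 10 * b, atol=1e-9)


def _series(years, r):
    years = np.asarray(years)
    return fd.CorrelationSeries(years, np.asarray(r, dtype=float),
                                np.full(len(years), np.nan),
                                np.full(len(years), np.nan),
                                np.zeros(len(years), dtype=int), {})


class TestDetectOnset:
    def test_noiseless_kink_recovered_exactly(self):
        years = np.arange(1500, 1993)
        r = np.where(years <= 1850, 0.8, 0.8 - 0.002 * (years - 1850))
        res = fd.detect_onset(_series(years, r), margin=30)
        assert res.onset_year == 1850
        assert res.slope_pre == pytest.approx(0.0, abs=1e-10)
        assert res.slope_post == pytest.approx(-0.002, abs=1e-10)

    def test_single_slope_series_yields_no_onset(self):
        years = np.arange(1500, 1993)
        res = fd.detect_onset(_series(years, 0.9 - 1e-4 * (years - 1500)), margin=30)
        assert res.onset_year is None

    def test_ties_break_to_earliest_year(self):
        # piecewise-constant series: every breakpoint inside the flat segments
        # fits equally; earliest candidate must win among the exact minima
        years = np.arange(1500, 1993)
        r = np.where(years <= 1700, 0.5, 0.5 - 0.001 * (years - 1700))
        res = fd.detect_onset(_series(years, r), margin=30)
        assert res.onset_year == 1700

    def test_margin_excludes_edge_breakpoints(self):
        years = np.arange(1500, 1993)
        r = np.where(years <= 1972, 0.8, 0.8 - 0.01 * (years - 1972))
        res = fd.detect_onset(_series(years, r), margin=30)
        # the true kink (1972) lies inside the excluded margin
        assert res.onset_year is None or res.onset_year <= 1962


class TestCovariateModel:
    def test_overlap_count_1850_2017_vs_scan(self):
        years = np.arange(1500, 1993)
        s = _series(years, 0.9 - 1e-4 * (years - 1500))
        cov = pd.Series(np.arange(1850, 2018, dtype=float),
                        index=np.arange(1850, 2018))
        fit = fd.fit_covariate_model(s, cov)
        assert fit.n_overlap == 143

    def test_perfectly_linear_relationship(self):
        years = np.arange(1900, 1993)
        cov = pd.Series(np.exp(0.01 * (years - 1900)), index=years)
        s = _series(years, 0.9 - 0.05 * cov.to_numpy())
        fit = fd.fit_covariate_model(s, cov)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(-0.05)

    def test_against_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        years = np.arange(1850, 1950)
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        fit = fd.fit_covariate_model(_series(years, y), pd.Series(x, index=years))
        # closed-form simple OLS
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        r2 = 1 - ((y - intercept - slope * x) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-10)
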