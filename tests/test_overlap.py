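"""Dual upper-quartile overlap: thresholds, mask, fractions, sensitivity."""

import numpy as np
import pytest

import carbonfish as cf
from carbonfish.overlap import OverlapError, OverlapResult
from carbonfish.grid import UNITS_EXPORT, UNITS_FISHING

from conftest import band_field


class TestQuantileThreshold:
    def test_linear_interpolation_rule(self):
        """Position 1+(n-1)q on 1..8 at q=0.75 is 6.25."""
        assert cf.quantile_threshold(np.arange(1, 9), 0.75) == pytest.approx(6.25)

    def test_constant_sample(self):
        assert cf.quantile_threshold(np.full(10, 3.0), 0.75) == 3.0

    def test_two_point_interpolation(self):
        assert cf.quantile_threshold(np.array([0.0, 100.0]), 0.75) == pytest.approx(75.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=101)
        assert cf.quantile_threshold(x, 0.6) == cf.quantile_threshold(
            rng.permutation(x), 0.6)

    def test_empty_rejected(self):
        with pytest.raises(OverlapError):
            cf.quantile_threshold(np.array([]), 0.75)


class TestOverlapMask:
    def test_identical_rankings_give_top_quartile(self):
        """E == F with 100 distinct values: the mask is exactly the top 25 cells."""
        vals = np.random.default_rng(1).permutation(100).astype(float)[None, :]
        E = band_field(vals, units=UNITS_EXPORT, name="E")
        F = band_field(vals, units=UNITS_FISHING, name="F")
        res = cf.overlap_mask(E, F)
        assert res.mask.sum() == 25
        assert set(vals[res.mask]) == set(np.sort(vals.ravel())[-25:])

    def test_rank_inversion_gives_empty_mask(self):
        vals = np.arange(100, dtype=float)[None, :]
        E = band_field(vals, units=UNITS_EXPORT)
        F = band_field(-vals, units=UNITS_FISHING)
        assert cf.overlap_mask(E, F).mask.sum() == 0

    def test_row_by_column_single_cell(self):
        """E = row index, F = column index on 4x4: only the corner overlaps."""
        grid = cf.GeoGrid.regular(45.0)  # 4 x 8 -> take 4 x 4 sub-pattern via values
        # use a 4x4 world on a 45-degree grid (4 lat x 8 lon); fill the extra
        # columns with low distinct values so they never enter a top quartile
        rng = np.random.default_rng(2)
        jit = rng.uniform(0, 0.01, grid.shape)
        E = np.tile(np.arange(4, dtype=float)[:, None], (1, 8)) + jit
        F = np.tile(np.arange(8, dtype=float)[None, :], (4, 1)) + jit
        Ef = cf.GriddedField(grid, E, units=UNITS_EXPORT)
        Ff = cf.GriddedField(grid, F, units=UNITS_FISHING)
        res = cf.overlap_mask(Ef, Ff)
        # top quartile of E = top row (8 cells); of F = two rightmost columns
        expected = np.zeros(grid.shape, dtype=bool)
        expected[3, 6:] = True
        assert (res.mask == expected).all()

    def test_strict_inequality_excludes_ties(self):
        vals = np.full((1, 8), 2.0)
        E = band_field(vals, units=UNITS_EXPORT)
        F = band_field(vals, units=UNITS_FISHING)
        assert cf.overlap_mask(E, F).mask.sum() == 0

    def test_disjoint_domains_rejected(self):
        E = band_field([1.0, np.nan], units=UNITS_EXPORT,
                       valid=np.array([[True, False]]))
        F = band_field([np.nan, 1.0], units=UNITS_FISHING,
                       valid=np.array([[False, True]]))
        with pytest.raises(OverlapError):
            cf.overlap_mask(E, F)


class TestFractions:
    def _setup(self):
        E = band_field([1.0, 1.0, 1.0, 1.0], units=UNITS_EXPORT)
        F = band_field([0.0, 0.0, 0.0, 10.0], units=UNITS_FISHING)
        areas = cf.cell_areas(E.grid)
        return E, F, areas

    def test_hand_computed_equal_area_case(self):
        E, F, areas = self._setup()
        res = OverlapResult(q=0.75, q_export=0, q_fishing=0,
                            mask=np.array([[False, False, False, True]]))
        fr = cf.overlap_fractions(res, E, F, areas)
        assert fr == pytest.approx((0.25, 0.25, 1.0))

    def test_full_and_empty_mask(self):
        E, F, areas = self._setup()
        full = OverlapResult(0.75, 0, 0, np.ones((1, 4), dtype=bool))
        assert cf.overlap_fractions(full, E, F, areas) == pytest.approx((1, 1, 1))
        empty = OverlapResult(0.75, 0, 0, np.zeros((1, 4), dtype=bool))
        assert cf.overlap_fractions(empty, E, F, areas) == pytest.approx((0, 0, 0))

    def test_zero_domain_rejected(self):
        E, _, areas = self._setup()
        Z = band_field([0.0, 0.0, 0.0, 0.0], units=UNITS_FISHING)
        res = OverlapResult(0.75, 0, 0, np.zeros((1, 4), dtype=bool))
        with pytest.raises(OverlapError):
            cf.overlap_fractions(res, E, Z, areas)


class TestInvariances:
    def test_monotone_transform_leaves_mask(self, small_world):
        areas = cf.cell_areas(small_world.grid)
        E = small_world.inputs.npp
        F = small_world.fishing
        base = cf.overlap_mask(E, F)
        E2 = E.with_values(np.exp(E.values / E.values[E.valid].max()))
        warped = cf.overlap_mask(E2, F)
        assert (base.mask == warped.mask).all()

    def test_quantile_monotonicity(self, small_world):
        areas = cf.cell_areas(small_world.grid)
        ens = cf.compute_ensemble(small_world.inputs)
        E, F = ens.mean_export, small_world.fishing
        prev = None
        for q in (0.6, 0.75, 0.9):
            res = cf.compute_overlap(E, F, areas, q=q)
            if prev is not None:
                assert (res.mask <= prev.mask).all()  # set inclusion
                assert res.area_fraction <= prev.area_fraction
                assert res.export_fraction <= prev.export_fraction
                assert res.effort_fraction <= prev.effort_fraction
            prev = res

    def test_independent_fields_baseline(self):
        """Mean overlap area of independent fields sits near (1-q)^2."""
        fr = []
        for seed in range(60):
            w = cf.gen_fields(cf.SyntheticConfig(
                resolution=4.0, seed=seed, cross_correlation=0.0,
                coastal_boost=1.0))
            areas = cf.cell_areas(w.grid)
            fr.append(cf.compute_overlap(w.inputs.npp, w.fishing,
                                         areas).area_fraction)
        assert np.mean(fr) == pytest.approx(0.0625, abs=0.012)


class TestSensitivity:
    def test_identical_members_zero_width(self):
        vals = np.random.default_rng(5).uniform(1, 10, (1, 40))
        f = band_field(vals, units=UNITS_EXPORT)
        F = band_field(np.roll(vals, 3), units=UNITS_FISHING)
        ens = cf.ensemble_mean({"a": f, "b": f})
        res = cf.sensitivity(ens, F, cf.cell_areas(f.grid))
        for lo, hi in res.member_ranges().values():
            assert lo == pytest.approx(hi)

    def test_rescaled_member_same_fractions(self):
        vals = np.random.default_rng(6).uniform(1, 10, (1, 40))
        f = band_field(vals, units=UNITS_EXPORT)
        g = band_field(3.0 * vals, units=UNITS_EXPORT)
        F = band_field(np.roll(vals, 5), units=UNITS_FISHING)
        ens = cf.ensemble_mean({"a": f, "b": g})
        res = cf.sensitivity(ens, F, cf.cell_areas(f.grid))
        fa = res.member_fractions["a"]
        fb = res.member_fractions["b"]
        assert fa[0] == pytest.approx(fb[0])   # area fractions identical
        assert fa[2] == pytest.approx(fb[2])   # effort fractions identical

    def test_envelope_contains_members(self, small_world):
        areas = cf.cell_areas(small_world.grid)
        ens = cf.compute_ensemble(small_world.inputs)
        res = cf.sensitivity(ens, small_world.fishing, areas)
        ranges = res.member_ranges()
        for i, key in enumerate(("area_fraction", "export_fraction",
                                 "effort_fraction")):
            lo, hi = ranges[key]
            for frac in res.member_fractions.values():
                assert lo - 1e-12 <= frac[i] <= hi + 1e-12
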