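import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from defaunation import projection
from defaunation.hurdle import ModelFormula, fit_binomial_stage, fit_gaussian_stage
from defaunation.predictors import PredictorStack
from defaunation.projection import (SpeciesLayer, aggregate_di, combine_hurdle,
                                    hotspot_fraction, project_species,
                                    size_class, species_coverage_percent)
from defaunation.raster import Raster
from defaunation.simulate import SyntheticConfig, generate_database


class TestCombineHurdle:
    def test_intact(self):
        assert combine_hurdle(1.0, 0.0) == 0.0

    def test_certain_extirpation(self):
        assert combine_hurdle(0.0, 5.0) == 1.0
        assert combine_hurdle(0.0, -5.0) == 1.0

    def test_hand_arithmetic(self):
        assert combine_hurdle(0.8, np.log(0.5)) == pytest.approx(0.6)

    def test_increase_capped(self):
        # rr_hat > 0 -> DI = 1 - p_persist, never negative
        assert combine_hurdle(0.9, 2.0) == pytest.approx(0.1)
        assert combine_hurdle(1.0, 2.0) == 0.0

    def test_uncapped_switch(self):
        assert combine_hurdle(1.0, np.log(2.0), cap_increase=False) == 0.0

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            combine_hurdle(1.2, 0.0)

    @given(p=st.floats(0.0, 1.0), r1=st.floats(-3, 3), r2=st.floats(-3, 3))
    def test_monotone_in_rr(self, p, r1, r2):
        lo, hi = min(r1, r2), max(r1, r2)
        assert combine_hurdle(p, lo) >= combine_hurdle(p, hi) - 1e-12

    @given(p1=st.floats(0.0, 1.0), p2=st.floats(0.0, 1.0),
           r=st.floats(-3, 3))
    def test_monotone_in_p(self, p1, p2, r):
        lo, hi = min(p1, p2), max(p1, p2)
        assert combine_hurdle(lo, r) >= combine_hurdle(hi, r) - 1e-12

    @given(p=st.floats(0.0, 1.0), r=st.floats(-10, 10))
    def test_bounded(self, p, r):
        assert 0.0 <= combine_hurdle(p, r) <= 1.0


def _hand_stages():
    """Stages with hand-set coefficients via a quick fit then overwrite."""
    cfg = SyntheticConfig(n_countries=4, n_studies=8, n_species=10,
                          n_records=300)
    df, _ = generate_database(cfg, seed=41)
    b = fit_binomial_stage(df, ModelFormula("binomial", ("distance_access",)),
                           standardize=False)
    g = fit_gaussian_stage(df, ModelFormula("gaussian", ("distance_access",)),
                           standardize=False)
    for stg in (b, g):
        for f in stg.fit.u:
            stg.fit.u[f][:] = 0.0
    return b, g


@pytest.fixture(scope="module")
def hand_stages():
    return _hand_stages()


def _uniform_stack(value=5.0, shape=(6, 6)):
    layer = Raster(np.full(shape, value))
    return PredictorStack({"distance_access": layer})


class TestProjectSpecies:
    def test_uniform_landscape_constant_grid(self, hand_stages):
        b, g = hand_stages
        b.fit.beta[:] = [1.0, 0.05]
        g.fit.beta[:] = [-0.2, 0.01]
        stack = _uniform_stack(5.0)
        sp = SpeciesLayer("spX", 10.0, "herbivore",
                          np.ones((6, 6), dtype=bool))
        di = project_species(b, g, sp, stack)
        from scipy.special import expit
        p = expit(1.0 + 0.05 * 5.0)
        rr = -0.2 + 0.01 * 5.0
        expected = 1.0 - p * min(np.exp(rr), 1.0)
        np.testing.assert_allclose(di.data, expected, atol=1e-9)

    def test_monotone_along_distance_transect(self, hand_stages):
        b, g = hand_stages
        # positive distance effect on persistence, on RR -> DI decreasing
        b.fit.beta[:] = [0.5, 0.1]
        g.fit.beta[:] = [-0.5, 0.02]
        grad = np.tile(np.arange(8.0), (3, 1))
        stack = PredictorStack({"distance_access": Raster(grad)})
        sp = SpeciesLayer("spX", 5.0, "herbivore", np.ones((3, 8), dtype=bool))
        di = project_species(b, g, sp, stack).data
        assert (np.diff(di, axis=1) <= 1e-12).all()

    def test_empty_range_all_nodata(self, hand_stages):
        b, g = hand_stages
        sp = SpeciesLayer("spX", 5.0, "herbivore",
                          np.zeros((6, 6), dtype=bool))
        di = project_species(b, g, sp, _uniform_stack())
        assert np.isnan(di.data).all()

    def test_missing_layer_named(self, hand_stages):
        b, g = hand_stages
        stack = PredictorStack({"hpd": Raster(np.ones((6, 6)))})
        sp = SpeciesLayer("spX", 5.0, "herbivore", np.ones((6, 6), dtype=bool))
        with pytest.raises(KeyError, match="distance_access"):
            project_species(b, g, sp, stack)

    def test_out_of_range_cells_nodata(self, hand_stages):
        b, g = hand_stages
        mask = np.zeros((6, 6), dtype=bool)
        mask[2:4, 2:4] = True
        sp = SpeciesLayer("spX", 5.0, "herbivore", mask)
        di = project_species(b, g, sp, _uniform_stack())
        assert np.isfinite(di.data[mask]).all()
        assert np.isnan(di.data[~mask]).all()


def _layers_with_di(di_grids):
    layers = []
    for i, grid in enumerate(di_grids):
        sp = SpeciesLayer(f"sp{i}", 5.0, "herbivore",
                          np.isfinite(grid))
        sp.di = Raster(np.asarray(grid, dtype=float))
        layers.append(sp)
    return layers


class TestAggregate:
    def test_single_species_identity(self):
        grid = np.array([[0.2, 0.4], [np.nan, 0.8]])
        comp, s = aggregate_di(_layers_with_di([grid]))
        np.testing.assert_array_equal(np.isnan(comp.data), np.isnan(grid))
        np.testing.assert_allclose(comp.data[np.isfinite(grid)],
                                   grid[np.isfinite(grid)])

    def test_two_species_mean(self):
        comp, s = aggregate_di(_layers_with_di(
            [np.full((2, 2), 0.2), np.full((2, 2), 0.4)]))
        np.testing.assert_allclose(comp.data, 0.3)
        np.testing.assert_allclose(s.data, 2.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        grids = []
        for _ in range(5):
            g = rng.uniform(0, 1, (7, 7))
            g[rng.uniform(size=(7, 7)) < 0.3] = np.nan
            grids.append(g)
        comp, s = aggregate_di(_layers_with_di(grids))
        arr = np.stack(grids)
        for i in range(7):
            for j in range(7):
                vals = arr[:, i, j]
                vals = vals[np.isfinite(vals)]
                if len(vals) == 0:
                    assert np.isnan(comp.data[i, j])
                else:
                    assert comp.data[i, j] == pytest.approx(vals.mean())
                    assert s.data[i, j] == len(vals)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        grids = [rng.uniform(0, 1, (5, 5)) for _ in range(4)]
        layers = _layers_with_di(grids)
        a, _ = aggregate_di(layers)
        b, _ = aggregate_di(layers[::-1])
        np.testing.assert_array_equal(a.data, b.data)

    def test_composite_bounded_by_contributors(self):
        rng = np.random.default_rng(10)
        grids = [rng.uniform(0, 1, (5, 5)) for _ in range(4)]
        comp, _ = aggregate_di(_layers_with_di(grids))
        arr = np.stack(grids)
        assert (comp.data >= arr.min(axis=0) - 1e-12).all()
        assert (comp.data <= arr.max(axis=0) + 1e-12).all()

    def test_subset_filter_equals_subset_recomputation(self):
        rng = np.random.default_rng(11)
        grids = [rng.uniform(0, 1, (4, 4)) for _ in range(6)]
        layers = _layers_with_di(grids)
        for i, sp in enumerate(layers):
            sp.body_mass = 0.5 if i % 2 else 30.0
        sub, _ = aggregate_di(layers, subset=lambda s: s.body_mass > 20)
        direct, _ = aggregate_di([s for s in layers if s.body_mass > 20])
        np.testing.assert_array_equal(sub.data, direct.data)

    def test_geometry_mismatch(self):
        a = _layers_with_di([np.full((2, 2), 0.5)])
        b = _layers_with_di([np.full((3, 3), 0.5)])
        with pytest.raises(ValueError):
            aggregate_di(a + b)


class TestHotspots:
    def test_hand_count(self):
        frac, mask = hotspot_fraction(_layers_with_di(
            [np.full((1, 1), 0.8), np.full((1, 1), 0.6),
             np.full((1, 1), 0.9)]))
        assert frac.data[0, 0] == pytest.approx(2 / 3)
        assert mask.data[0, 0] == 1.0

    def test_all_below(self):
        frac, mask = hotspot_fraction(_layers_with_di(
            [np.full((1, 1), 0.5), np.full((1, 1), 0.7)]))
        assert frac.data[0, 0] == 0.0
        assert mask.data[0, 0] == 0.0

    def test_boundary_strict(self):
        frac, _ = hotspot_fraction(_layers_with_di([np.full((1, 1), 0.7)]))
        assert frac.data[0, 0] == 0.0   # exactly 0.7 excluded

    def test_brute_force(self):
        rng = np.random.default_rng(12)
        grids = [rng.uniform(0, 1, (5, 5)) for _ in range(7)]
        frac, _ = hotspot_fraction(_layers_with_di(grids))
        arr = np.stack(grids)
        expected = (arr > 0.7).sum(axis=0) / 7
        np.testing.assert_allclose(frac.data, expected)


class TestSizeAndCoverage:
    @pytest.mark.parametrize("mass,cls", [(0.5, "small"), (1.0, "medium"),
                                          (20.0, "medium"), (20.01, "large")])
    def test_size_class(self, mass, cls):
        assert size_class(mass) == cls

    def test_coverage_percent(self):
        assert species_coverage_percent(296, 3923) == 7.5

    def test_coverage_rejects_zero(self):
        with pytest.raises(ValueError):
            species_coverage_percent(10, 0)
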