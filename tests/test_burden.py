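"""Burden engine: attribution, Monte-Carlo contracts, aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

import pmburden as pb
from pmburden.burden import age_band_lower

from conftest import make_single_stratum_world, make_uniform_grid


def lri_curve(alpha=1.0, gamma=0.1, delta=1.0, z_cf=5.0, draw_id=0):
    return pb.RiskCurveDraw(
        cause="LRI", age_group="all", alpha=alpha, gamma=gamma, delta=delta,
        z_cf=z_cf, draw_id=draw_id,
    )


def rr2_curve(exposure=15.0, z_cf=5.0):
    """IER draw with RR(exposure) = 2 exactly: alpha=2, gamma = ln2/Δ."""
    return lri_curve(alpha=2.0, gamma=math.log(2.0) / (exposure - z_cf), z_cf=z_cf)


class TestAttributableDeathsOneDraw:
    def test_uniform_rr2_halves_the_deaths(self):
        grid = make_uniform_grid(exposure=15.0)
        got = pb.attributable_deaths_one_draw(grid, rr2_curve(15.0), 1000.0)
        assert got == pytest.approx(500.0, rel=1e-12)

    def test_below_counterfactual_attributes_nothing(self):
        grid = make_uniform_grid(exposure=4.0)
        assert pb.attributable_deaths_one_draw(grid, lri_curve(z_cf=5.0), 1000.0) == 0.0

    def test_mixed_cells_population_weighted(self):
        # two equal-population cells, RR 1 and RR 2 → 1000·(0.5·0 + 0.5·0.5)
        grid = pb.ExposureGrid(
            "XXX", ("a", "b"), np.array([4.0, 15.0]), np.array([100.0, 100.0])
        )
        got = pb.attributable_deaths_one_draw(grid, rr2_curve(15.0), 1000.0)
        assert got == pytest.approx(250.0, rel=1e-12)

    def test_stratum_mismatch_rejected(self):
        grid = make_uniform_grid()
        with pytest.raises(ValueError, match="cause"):
            pb.attributable_deaths_one_draw(grid, lri_curve(), 10.0, cause="IHD")
        with pytest.raises(ValueError, match="age band"):
            pb.attributable_deaths_one_draw(grid, lri_curve(), 10.0, age_group="25+")

    def test_never_reaches_baseline(self):
        grid = make_uniform_grid(exposure=500.0)
        got = pb.attributable_deaths_one_draw(
            grid, lri_curve(alpha=50.0, gamma=1.0), 1000.0
        )
        assert 0.0 <= got < 1000.0


class TestMortalityTable:
    def test_adult_cause_in_child_band_rejected(self):
        df = pd.DataFrame(
            [("XXX", "IHD", "male", "0-4", 10.0)],
            columns=["country_code", "cause", "sex", "age_group", "deaths"],
        )
        with pytest.raises(ValueError, match="25 years"):
            pb.MortalityTable(df, {"XXX": 1e6})

    def test_lri_allowed_in_all_ages(self):
        df = pd.DataFrame(
            [("XXX", "LRI", "female", "all", 10.0)],
            columns=["country_code", "cause", "sex", "age_group", "deaths"],
        )
        assert pb.MortalityTable(df, {"XXX": 1e6}).countries == ["XXX"]

    def test_unknown_cause_rejected(self):
        df = pd.DataFrame(
            [("XXX", "diabetes", "male", "25+", 10.0)],
            columns=["country_code", "cause", "sex", "age_group", "deaths"],
        )
        with pytest.raises(ValueError, match="cause"):
            pb.MortalityTable(df, {"XXX": 1e6})

    @pytest.mark.parametrize(
        "label, lower", [("all", 0.0), ("25-59", 25.0), ("60+", 60.0), ("0-4", 0.0)]
    )
    def test_age_band_parsing(self, label, lower):
        assert age_band_lower(label) == lower


class TestRunMonteCarlo:
    def test_degenerate_inputs_collapse_the_interval(self):
        grid, mortality = make_single_stratum_world(exposure=30.0)
        curves = {("LRI", "all"): [lri_curve(z_cf=3.0)]}
        cf = pb.CounterfactualSpec(3.0, 3.0)
        est = pb.run_monte_carlo({"UNI": grid}, mortality, curves, cf, 50, seed=1)
        stratum = next(iter(est.values()))
        assert np.ptp(stratum.draws) == 0.0  # every draw identical
        value = stratum.draws[0]
        assert stratum.ui_low == pytest.approx(value, rel=1e-12)
        assert stratum.point == pytest.approx(value, rel=1e-12)
        assert stratum.ui_high == pytest.approx(value, rel=1e-12)

    def test_fixed_seed_is_bit_identical(self):
        grid, mortality = make_single_stratum_world()
        curves = {("LRI", "all"): [lri_curve(draw_id=d, gamma=0.1 + 0.01 * d) for d in range(5)]}
        kw = dict(cf=pb.CounterfactualSpec(), n_draws=40, seed=123)
        a = pb.run_monte_carlo({"UNI": grid}, mortality, curves, **kw)
        b = pb.run_monte_carlo({"UNI": grid}, mortality, curves, **kw)
        for key in a:
            np.testing.assert_array_equal(a[key].draws, b[key].draws)

    def test_curve_draws_cycled_when_fewer_than_n_draws(self):
        grid, mortality = make_single_stratum_world()
        curves = {("LRI", "all"): [lri_curve(draw_id=0, alpha=0.5),
                                   lri_curve(draw_id=1, alpha=2.0)]}
        cf = pb.CounterfactualSpec(5.0, 5.0)  # pin z_cf: draws alternate exactly
        est = pb.run_monte_carlo({"UNI": grid}, mortality, curves, cf, 4, seed=0)
        draws = next(iter(est.values())).draws
        np.testing.assert_allclose(draws[::2], draws[0])
        np.testing.assert_allclose(draws[1::2], draws[1])
        assert draws[0] != draws[1]

    def test_empty_mortality_rejected(self):
        grid, mortality = make_single_stratum_world()
        empty = pd.DataFrame(columns=["country_code", "cause", "sex", "age_group", "deaths"])
        with pytest.raises(ValueError, match="empty"):
            pb.run_monte_carlo(
                {"UNI": grid}, pb.MortalityTable(empty, {}), {}, n_draws=10, seed=0
            )

    def test_invalid_n_draws_rejected(self):
        grid, mortality = make_single_stratum_world()
        with pytest.raises(ValueError, match="n_draws"):
            pb.run_monte_carlo({"UNI": grid}, mortality, {}, n_draws=0, seed=0)

    def test_gemm_curves_accepted(self):
        grid, mortality = make_single_stratum_world(exposure=30.0)
        gemm = pb.GemmCurveDraw(theta=0.143, se_theta=0.018, knot_alpha=1.6,
                                mu=15.5, nu=36.8, z_cf=2.4)
        est = pb.run_monte_carlo(
            {"UNI": grid}, mortality, {("LRI", "all"): [gemm]}, n_draws=30, seed=5
        )
        draws = next(iter(est.values())).draws
        assert np.all(draws >= 0) and np.all(draws < 1000.0)
        assert draws.std() > 0  # theta uncertainty propagates


class TestAggregate:
    def _estimates(self):
        key1 = pb.StratumKey("AAA", "LRI", "male", "all")
        key2 = pb.StratumKey("BBB", "LRI", "male", "all")
        return {
            key1: pb.BurdenEstimate("stratum", "AAA", np.array([100.0, 100.0])),
            key2: pb.BurdenEstimate("stratum", "BBB", np.array([200.0, 200.0])),
        }

    def test_constant_draws_sum(self):
        agg = pb.aggregate(self._estimates(), {"AAA": "EUR", "BBB": "EUR"})
        assert agg.region["EUR"].point == pytest.approx(300.0)
        np.testing.assert_array_equal(agg.world.draws, agg.region["EUR"].draws)

    def test_single_region_equals_world(self):
        agg = pb.aggregate(self._estimates(), {"AAA": "AFR", "BBB": "AFR"})
        np.testing.assert_array_equal(agg.region["AFR"].draws, agg.world.draws)

    def test_unmapped_country_rejected_with_code(self):
        with pytest.raises(ValueError, match="BBB"):
            pb.aggregate(self._estimates(), {"AAA": "EUR"})

    def test_ui_of_sum_narrower_than_sum_of_widths(self):
        # comonotone (perfectly positively correlated) draws: interval
        # width of the sum cannot exceed the summed widths
        rng = np.random.default_rng(0)
        base = rng.uniform(50, 150, 500)
        est = {
            pb.StratumKey("AAA", "LRI", "male", "all"): pb.BurdenEstimate(
                "stratum", "AAA", base
            ),
            pb.StratumKey("BBB", "LRI", "male", "all"): pb.BurdenEstimate(
                "stratum", "BBB", 2.0 * base + 10.0
            ),
        }
        agg = pb.aggregate(est, {"AAA": "EUR", "BBB": "EUR"})
        widths = [e.ui_high - e.ui_low for e in est.values()]
        assert agg.world.ui_high - agg.world.ui_low <= sum(widths) + 1e-9


class TestPercentReduction:
    def est(self, draws):
        return pb.BurdenEstimate("world", "World", np.asarray(draws, dtype=float))

    def test_identical_scenario_is_zero(self):
        cur = self.est([100.0, 200.0])
        red = pb.percent_reduction(cur, cur)
        assert red.point == 0.0 and red.ui_low == 0.0 and red.ui_high == 0.0

    def test_constant_halving(self):
        red = pb.percent_reduction(self.est([100.0, 100.0]), self.est([50.0, 50.0]))
        assert red.point == pytest.approx(50.0)

    def test_mean_of_per_draw_reductions_not_ratio_of_means(self):
        red = pb.percent_reduction(self.est([100.0, 200.0]), self.est([80.0, 120.0]))
        assert red.point == pytest.approx(30.0)  # mean of [20%, 40%], not 33.3%

    def test_zero_current_draw_is_undefined_not_zero(self):
        red = pb.percent_reduction(self.est([0.0, 100.0]), self.est([0.0, 50.0]))
        assert not red.defined
        assert math.isnan(red.point)


class TestDeathsPer100k:
    def test_rate_scaling(self):
        est = pb.BurdenEstimate("country", "XXX", np.array([500.0, 500.0]))
        rate = pb.deaths_per_100k(est, 1_000_000)
        assert rate.point == pytest.approx(50.0)
        assert rate.ui_low == pytest.approx(50.0)

    def test_zero_deaths_zero_rate(self):
        est = pb.BurdenEstimate("country", "XXX", np.zeros(3))
        assert pb.deaths_per_100k(est, 1e6).point == 0.0

    def test_avoided_rate_is_difference(self):
        cur = pb.deaths_per_100k(
            pb.BurdenEstimate("country", "XXX", np.array([820.0])), 1_000_000
        )
        capped = pb.deaths_per_100k(
            pb.BurdenEstimate("country", "XXX", np.array([700.0])), 1_000_000
        )
        assert cur.point - capped.point == pytest.approx(12.0)

    def test_zero_population_rejected(self):
        est = pb.BurdenEstimate("country", "XXX", np.array([1.0]))
        with pytest.raises(ValueError, match="population"):
            pb.deaths_per_100k(est, 0.0)
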