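"""Scenario orchestration: hybrid runs, sweeps, normalization, playback."""

import numpy as np
import pytest

from codfishsim import (
    AssessmentSeries,
    GeneratorSpec,
    NormalizedScores,
    ScenarioConfig,
    StockParameters,
    bulk_fleet,
    equilibrium,
    find_crossover,
    generate_assessment_series,
    normalize,
    playback_validation,
    run_scenario,
    sweep_q,
)
from codfishsim.impact_accounting import KG_PER_KT
from codfishsim.scenario_engine import ScenarioResult, sweep_frame


def _bulk_config(q=0.5, horizon=3, **kw):
    return ScenarioConfig(q=q, horizon=horizon, fleet=bulk_fleet(), **kw)


class TestRunScenario:
    def test_single_year_catch_equals_initial_tac(self):
        cfg = _bulk_config(horizon=1)
        res = run_scenario(cfg)
        assert res.total_catch_kt == pytest.approx(cfg.tac0, rel=1e-12)

    def test_totals_match_closed_form_annual_arithmetic(self):
        """Deterministic fleet: every year's catch per gear equals its
        allocation, so horizon totals are explicit sums over the TAC path."""
        cfg = _bulk_config(q=0.5, horizon=4)
        res = run_scenario(cfg)
        trawler = cfg.fleet.units[0][0]
        longliner = cfg.fleet.units[1][0]
        q = cfg.q
        exp_catch = sum(res.tac_by_year)
        exp_profit = sum(
            tac * q * KG_PER_KT * trawler.fish_value_per_kg * trawler.profit_ratio
            + tac
            * (1 - q)
            * KG_PER_KT
            * longliner.fish_value_per_kg
            * longliner.profit_ratio
            for tac in res.tac_by_year
        )
        exp_co2 = sum(
            tac * KG_PER_KT * (q * 5.14 + (1 - q) * 1.58) for tac in res.tac_by_year
        )
        assert res.total_catch_kt == pytest.approx(exp_catch, rel=1e-12)
        assert res.total_profit == pytest.approx(exp_profit, rel=1e-9)
        assert res.total_co2_kg == pytest.approx(exp_co2, rel=1e-9)

    def test_boundary_allocations_order_profit_and_co2(self):
        all_trawl = run_scenario(_bulk_config(q=1.0))
        all_longline = run_scenario(_bulk_config(q=0.0))
        assert all_trawl.total_profit > all_longline.total_profit
        assert all_longline.total_co2_kg < all_trawl.total_co2_kg

    def test_reproducible_given_seed_and_config(self):
        a = run_scenario(_bulk_config(seed=42))
        b = run_scenario(_bulk_config(seed=42))
        assert a.biomass_by_year == b.biomass_by_year
        assert a.tac_by_year == b.tac_by_year
        assert a.trip_records == b.trip_records
        assert a.total_profit == b.total_profit

    def test_tac_follows_control_rule_between_years(self, default_params):
        res = run_scenario(_bulk_config(horizon=3))
        # TAC_{y+1} = (a * B_{y+1} + TAC_y) / 2 with biomass at year start
        for y in range(2):
            expected = (
                default_params.a * res.biomass_by_year[y + 1] + res.tac_by_year[y]
            ) / 2.0
            assert res.tac_by_year[y + 1] == pytest.approx(expected, rel=1e-12)


class TestSweep:
    def test_single_point_grid(self):
        results = sweep_q([0.5], _bulk_config())
        assert len(results) == 1 and results[0].q == 0.5

    def test_boundary_grid(self):
        results = sweep_q([0.0, 1.0], _bulk_config())
        assert [r.q for r in results] == [0.0, 1.0]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_q([], _bulk_config())

    def test_co2_strictly_monotone_in_q(self):
        grid = np.linspace(0.0, 1.0, 11)
        results = sweep_q(grid, _bulk_config(horizon=3))
        co2 = [r.total_co2_kg for r in results]
        assert all(a < b for a, b in zip(co2, co2[1:]))

    def test_sweep_frame_columns(self):
        results = sweep_q([0.0, 0.5, 1.0], _bulk_config(horizon=2))
        frame = sweep_frame(results, normalize(results))
        assert len(frame) == 3
        assert {"q", "total_profit", "score_environmental"} <= set(frame.columns)


def _fake_result(q, profit, co2, jobs):
    from codfishsim.impact_accounting import AnnualImpacts
    from codfishsim.fleet_des import Gear

    imp = AnnualImpacts(
        year=0,
        catch_kt={Gear.BOTTOM_TRAWL: 1.0, Gear.LONGLINE: 0.0},
        profit={Gear.BOTTOM_TRAWL: profit, Gear.LONGLINE: 0.0},
        co2_kg={Gear.BOTTOM_TRAWL: co2, Gear.LONGLINE: 0.0},
        jobs={Gear.BOTTOM_TRAWL: jobs, Gear.LONGLINE: 0},
    )
    return ScenarioResult(
        q=q,
        annual=(imp,),
        tac_by_year=(1.0,),
        biomass_by_year=(100.0, 100.0),
        trip_records=(),
    )


class TestNormalize:
    def test_single_point_all_scores_one(self):
        scores = normalize([_fake_result(0.5, 100.0, 2.0, 10)])
        assert scores.economic == (1.0,)
        assert scores.environmental == (1.0,)
        assert scores.social == (1.0,)

    def test_profit_ratio_rule(self):
        scores = normalize(
            [_fake_result(0.0, 50.0, 2.0, 5), _fake_result(1.0, 100.0, 2.0, 5)]
        )
        assert scores.economic == pytest.approx((0.5, 1.0))

    def test_co2_inverse_ratio_rule(self):
        scores = normalize(
            [_fake_result(0.0, 10.0, 2.0, 5), _fake_result(1.0, 10.0, 4.0, 5)]
        )
        assert scores.environmental == pytest.approx((1.0, 0.5))

    def test_scores_bounded_and_best_is_one(self):
        results = [
            _fake_result(q, p, c, j)
            for q, p, c, j in [(0.0, 30, 2, 4), (0.5, 80, 3, 9), (1.0, 120, 5, 6)]
        ]
        scores = normalize(results)
        for cat in (scores.economic, scores.environmental, scores.social):
            assert all(0.0 < s <= 1.0 for s in cat)
            assert max(cat) == 1.0

    def test_all_negative_profit_falls_back_to_affine(self, caplog):
        with caplog.at_level("WARNING", logger="codfishsim.scenario_engine"):
            scores = normalize(
                [_fake_result(0.0, -50.0, 2.0, 5), _fake_result(1.0, -10.0, 2.0, 5)]
            )
        assert scores.economic_affine
        assert scores.economic == pytest.approx((0.0, 1.0))


class TestFindCrossover:
    @staticmethod
    def _scores(q, econ, env):
        n = len(q)
        return NormalizedScores(
            q=tuple(q),
            economic=tuple(econ),
            environmental=tuple(env),
            social=tuple([1.0] * n),
        )

    def test_symmetric_lines_cross_at_half(self):
        q = (0.0, 0.5, 1.0)
        scores = self._scores(q, q, tuple(1 - v for v in q))
        assert find_crossover(scores) == pytest.approx([0.5])

    def test_parallel_curves_never_cross(self):
        q = (0.0, 0.5, 1.0)
        scores = self._scores(q, (0.8, 0.85, 0.9), (0.3, 0.35, 0.4))
        assert find_crossover(scores) == []

    def test_generic_linear_pair_analytic_intersection(self):
        # econ = 0.2 + 0.6 q ; env = 0.9 - 0.5 q  ->  q* = 0.7 / 1.1
        q = tuple(np.linspace(0, 1, 6))
        econ = tuple(0.2 + 0.6 * v for v in q)
        env = tuple(0.9 - 0.5 * v for v in q)
        scores = self._scores(q, econ, env)
        assert find_crossover(scores) == pytest.approx([0.7 / 1.1])

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            find_crossover(self._scores((0.5,), (1.0,), (1.0,)))


class TestPlayback:
    def test_zero_catches_grow_toward_carrying_capacity(self, default_params):
        res = playback_validation(
            [0.0] * 40, default_params, x0=default_params.K / 10
        )
        x = res.biomass_sim_kt
        assert all(a < b for a, b in zip(x, x[1:]))
        # the final annual increment is tiny: effectively at K
        assert x[-1] == pytest.approx(default_params.K, rel=0.01)

    def test_equilibrium_catches_hold_stock_constant(self, default_params):
        b_star, tac_star = equilibrium(default_params)
        res = playback_validation(
            [tac_star] * 20, default_params, x0=b_star
        )
        np.testing.assert_allclose(res.biomass_sim_kt, b_star, rtol=1e-12)

    def test_replays_generator_truth_exactly(self):
        obs, truth = generate_assessment_series(GeneratorSpec(noise_sd=0.0))
        res = playback_validation(truth, StockParameters())
        np.testing.assert_allclose(res.biomass_sim_kt, truth.biomass_kt, rtol=1e-12)
        assert res.clamped_years == ()

    def test_overlarge_catch_clamped_and_recorded(self, default_params, caplog):
        with caplog.at_level("WARNING", logger="codfishsim.scenario_engine"):
            res = playback_validation(
                [5000.0, 0.0], default_params, x0=500.0
            )
        assert res.clamped_years == (0,)
        assert res.biomass_sim_kt[1] == 0.0
        assert res.catch_applied_kt[0] < 5000.0

    def test_continuous_mode_tracks_discrete_roughly(self, default_params):
        catches = [100.0] * 10
        disc = playback_validation(catches, default_params, x0=1000.0)
        cont = playback_validation(
            catches, default_params, x0=1000.0, mode="continuous"
        )
        np.testing.assert_allclose(
            cont.biomass_sim_kt, disc.biomass_sim_kt, rtol=0.05
        )

    def test_bare_sequence_requires_x0(self, default_params):
        with pytest.raises(ValueError, match="x0 required"):
            playback_validation([1.0, 2.0], default_params)

    def test_series_input_uses_its_first_biomass(self, default_params):
        series = AssessmentSeries([0, 1, 2], [800.0, 790.0, 780.0], [50.0] * 3)
        res = playback_validation(series, default_params)
        assert res.biomass_sim_kt[0] == 800.0


class TestScenarioConfigValidation:
    def test_q_out_of_range(self):
        with pytest.raises(ValueError):
            ScenarioConfig(q=1.2)

    def test_horizon_positive(self):
        with pytest.raises(ValueError):
            ScenarioConfig(q=0.5, horizon=0)

    def test_default_initial_tac_is_rule_fixed_point(self):
        cfg = ScenarioConfig(q=0.5, initial_biomass=1000.0)
        assert cfg.tac0 == pytest.approx(0.2 * 1000.0)
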