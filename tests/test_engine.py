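import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskpool.engine import (
    GameConfig,
    HIGH_VOLATILITY,
    LOW_VOLATILITY,
    PlayerState,
    ShockModel,
    earnings,
    growth,
    run_session,
    step_period,
    update_survival,
)
from riskpool.errors import ConfigError, ValidationError
from riskpool.strategies import NeedBasedPolicy, NoTransferPolicy


class TestGrowth:
    @pytest.mark.parametrize("regime", [HIGH_VOLATILITY, LOW_VOLATILITY])
    def test_zero_exactly_at_critical_values(self, regime):
        assert growth(regime.lower, regime) == 0.0
        assert growth(regime.upper, regime) == 0.0

    def test_hand_computed_increment(self):
        # 0.25 * 16 * (16/8 - 1) * (1 - 16/25) = 1.44
        assert growth(16.0, HIGH_VOLATILITY) == pytest.approx(1.44)

    def test_shrinks_below_lower_critical_value(self):
        assert growth(4.0, HIGH_VOLATILITY) < 0
        assert growth(30.0, HIGH_VOLATILITY) < 0

    @pytest.mark.parametrize(
        "regime,expected", [(HIGH_VOLATILITY, 18.37), (LOW_VOLATILITY, 17.02)]
    )
    def test_optimum_matches_grid_search(self, regime, expected):
        grid = np.arange(0.0, 25.0 + 1e-9, 0.01)
        values = [growth(s, regime) for s in grid]
        argmax = grid[int(np.argmax(values))]
        assert argmax == pytest.approx(regime.optimum, abs=0.01)
        assert round(regime.optimum, 2) == expected

    @given(st.floats(min_value=0.0, max_value=100.0))
    @settings(max_examples=200, deadline=None)
    def test_sign_structure(self, stock):
        from hypothesis import assume

        L, U = HIGH_VOLATILITY.lower, HIGH_VOLATILITY.upper
        assume(min(abs(stock - L), abs(stock - U), stock) > 1e-6)
        g = growth(stock, HIGH_VOLATILITY)
        if L < stock < U:
            assert g > 0
        else:
            assert g < 0

    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_rejects_invalid_stock(self, bad):
        with pytest.raises(ValidationError):
            growth(bad, HIGH_VOLATILITY)

    def test_regime_invariants_enforced(self):
        with pytest.raises(ConfigError):
            type(HIGH_VOLATILITY)(rate=0.25, lower=25.0, upper=8.0)
        with pytest.raises(ConfigError):
            type(HIGH_VOLATILITY)(rate=-0.1, lower=8.0, upper=25.0)


class TestStepPeriod:
    def _states(self, a=18.0, b=18.0):
        return [PlayerState(stock=a), PlayerState(stock=b)]

    def test_no_actions_at_lower_critical_value_keeps_stock(self):
        states = self._states(8.0, 8.0)
        new, recs = step_period(
            states, [(0, 0, 0), (0, 0, 0)], HIGH_VOLATILITY, (0.0, 0.0)
        )
        assert new[0].stock == 8.0 and new[1].stock == 8.0
        assert recs[0]["stock_post"] == 8.0

    def test_harvest_then_growth_hand_computed(self):
        # 18 - 2 = 16; 16 + growth(16) = 17.44
        states = self._states(18.0, 18.0)
        new, _ = step_period(
            states, [(2.0, 0, 0), (0, 0, 0)], HIGH_VOLATILITY, (0.0, 0.0)
        )
        assert new[0].stock == pytest.approx(17.44)
        assert new[0].harvested_total == pytest.approx(2.0)

    def test_transfers_conserve_total_stock(self):
        states = self._states(20.0, 10.0)
        new, _ = step_period(
            states, [(0, 0, 3.0), (0, 3.0, 0)], HIGH_VOLATILITY, (0.0, 0.0)
        )
        expected_growth = growth(20.0, HIGH_VOLATILITY) + growth(10.0, HIGH_VOLATILITY)
        total_change = (new[0].stock + new[1].stock) - 30.0
        assert total_change == pytest.approx(expected_growth)
        assert new[0].ledger_balance == pytest.approx(3.0)
        assert new[1].ledger_balance == pytest.approx(-3.0)

    def test_given_equals_partner_received(self):
        states = self._states()
        _, recs = step_period(
            states, [(0, 0, 5.0), (0, 5.0, 0)], HIGH_VOLATILITY, (1.0, -1.0)
        )
        assert recs[0]["given"] == recs[1]["received"] == 5.0
        assert recs[1]["given"] == recs[0]["received"] == 0.0

    def test_stock_floored_at_zero(self):
        states = self._states(9.0, 18.0)
        new, _ = step_period(
            states, [(0, 0, 0), (0, 0, 0)], HIGH_VOLATILITY, (-50.0, 0.0)
        )
        assert new[0].stock == 0.0

    def test_harvest_exceeding_stock_names_player(self):
        states = self._states(5.0, 18.0)
        with pytest.raises(ValidationError, match="player 0"):
            step_period(states, [(6.0, 0, 0), (0, 0, 0)], HIGH_VOLATILITY, (0, 0))

    def test_give_exceeding_available_rejected(self):
        states = self._states(18.0, 18.0)
        with pytest.raises(ValidationError, match="give"):
            step_period(states, [(0, 0, 50.0), (0, 0, 0)], HIGH_VOLATILITY, (0, 0))

    def test_dead_player_must_be_inactive(self):
        states = [PlayerState(stock=5.0, alive=False), PlayerState(stock=18.0)]
        with pytest.raises(ValidationError, match="out of the game"):
            step_period(states, [(1.0, 0, 0), (0, 0, 0)], HIGH_VOLATILITY, (0, 0))
        new, recs = step_period(
            states, [(0, 0, 0), (0, 0, 0)], HIGH_VOLATILITY, (3.0, 3.0)
        )
        assert new[0].stock == 5.0  # frozen: no growth, no shock
        assert recs[0]["shock"] == 0.0


class TestSurvivalRule:
    def test_consecutive_below_then_recovery_resets(self):
        s = PlayerState(stock=5.0)
        s = update_survival(s, threshold=8.0, grace=3)
        s = update_survival(s, threshold=8.0, grace=3)
        assert s.alive and s.consecutive_below == 2
        s = type(s)(stock=9.0, consecutive_below=s.consecutive_below)
        s = update_survival(s, threshold=8.0, grace=3)
        assert s.alive and s.consecutive_below == 0

    def test_three_consecutive_below_is_out(self):
        s = PlayerState(stock=5.0)
        for _ in range(2):
            s = update_survival(s, threshold=8.0, grace=3)
            assert s.alive
        s = update_survival(s, threshold=8.0, grace=3)
        assert not s.alive

    def test_at_threshold_counts_as_safe(self):
        s = PlayerState(stock=8.0, consecutive_below=2)
        s = update_survival(s, threshold=8.0, grace=3)
        assert s.alive and s.consecutive_below == 0

    def test_death_is_permanent(self):
        s = PlayerState(stock=20.0, alive=False)
        s = update_survival(s, threshold=8.0, grace=3)
        assert not s.alive


class TestEarnings:
    @pytest.mark.parametrize("harvested,dollars", [(0.0, 5.0), (30.0, 7.0), (15.0, 6.0)])
    def test_dollar_rule(self, harvested, dollars):
        state = PlayerState(stock=0.0, harvested_total=harvested)
        assert earnings(state, GameConfig()) == pytest.approx(dollars)


class TestShockModel:
    @pytest.mark.parametrize("dist", ["normal", "uniform", "discrete_uniform"])
    def test_sample_mean_near_zero(self, dist, rng):
        model = ShockModel(dist, scale=2.0)
        draws = model.draw(rng, size=100_000)
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean()) < 3 * se

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ConfigError):
            ShockModel("cauchy", 2.0)


class TestRunSession:
    def test_record_bookkeeping(self, rng):
        config = GameConfig(n_rounds=1, periods_per_round=20, practice_periods=0,
                            regimes_by_round=(HIGH_VOLATILITY,))
        log = run_session(config, [NeedBasedPolicy(), NeedBasedPolicy()], rng)
        assert len(log) == 2 * 20
        assert not log["practice"].any()

    def test_practice_block_flagged(self, rng):
        log = run_session(GameConfig(), [NeedBasedPolicy(), NeedBasedPolicy()], rng)
        assert len(log) == 2 * (7 + 4 * 20)
        assert log["practice"].sum() == 2 * 7

    def test_identical_seed_identical_log(self):
        config = GameConfig()
        logs = [
            run_session(config, [NeedBasedPolicy(), NeedBasedPolicy()],
                        np.random.default_rng(99))
            for _ in range(2)
        ]
        assert logs[0].equals(logs[1])

    def test_partner_rotation_distinct_over_rounds(self, rng):
        n = 40
        log = run_session(GameConfig(), [NoTransferPolicy() for _ in range(n)], rng)
        scored = log[~log["practice"]]
        partners = scored.groupby("player_id")["partner_id"].nunique()
        assert (partners == 4).all()

    def test_odd_player_count_rejected(self, rng):
        with pytest.raises(ConfigError):
            run_session(GameConfig(), [NeedBasedPolicy()] * 3, rng)

    def test_dead_player_frozen_for_rest_of_round(self):
        config = GameConfig(
            n_rounds=2, periods_per_round=20, practice_periods=0,
            regimes_by_round=(HIGH_VOLATILITY, HIGH_VOLATILITY),
            shock_model=ShockModel("normal", 8.0),
        )
        log = run_session(
            config, [NoTransferPolicy(), NoTransferPolicy()],
            np.random.default_rng(3),
        )
        died = log[~log["alive_post"]]
        assert not died.empty, "harsh shocks should kill an unaided player"
        for (_, rnd, pid), rows in log.groupby(["session", "round", "player_id"]):
            rows = rows.sort_values("period")
            dead = rows["alive_post"].shift(1, fill_value=True) == False  # noqa: E712
            after_death = rows[dead]
            assert (after_death[["harvest", "requested", "given"]] == 0).all().all()
            assert (after_death["stock_post"] == after_death["stock_pre"]).all()

    def test_earnings_exclude_practice(self, rng):
        config = GameConfig()
        log = run_session(config, [NeedBasedPolicy(), NeedBasedPolicy()], rng)
        harvested = log.attrs["harvested_total"]
        scored = log[~log["practice"]]
        for pid, total in harvested.items():
            assert total == pytest.approx(
                scored[scored["player_id"] == pid]["harvest"].sum()
            )
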