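"""Core dynamics of the two-player risk-pooling game.

Each player manages a resource stock that grows according to a strong-Allee
growth rule: stocks shrink below a lower critical value ``L``, grow between
``L`` and an upper critical value ``U``, and shrink again above ``U``.  Per
period a player may harvest (banking resources for earnings), request
resources from an anonymous partner, and respond to the partner's request.
A zero-mean random shock, independent of stock size, hits every period.
Players whose stock stays below a threshold for several consecutive periods
drop out for the remainder of the round.

The update order within a period is: harvest, natural growth on the
post-harvest stock, then transfers and the shock.  Growth acting on the
post-harvest stock is the one ordering constraint the game imposes; the
placement of transfers and shock after growth is a fixed convention of this
implementation (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

__all__ = [
    "VolatilityRegime",
    "HIGH_VOLATILITY",
    "LOW_VOLATILITY",
    "ShockModel",
    "GameConfig",
    "PlayerState",
    "Observation",
    "growth",
    "step_period",
    "update_survival",
    "run_session",
    "earnings",
    "LOG_COLUMNS",
]


# ---------------------------------------------------------------------------
# regimes and growth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolatilityRegime:
    """Growth-rule parameters for one volatility regime.

    Parameters
    ----------
    rate
        Dimensionless growth-rate multiplier per period.
    lower, upper
        Critical values ``L`` and ``U`` (resource units).  Stocks shrink
        below ``L`` and above ``U`` and grow strictly between them.
    label
        Human-readable tag, conventionally ``"high"`` or ``"low"``.
    """

    rate: float
    lower: float
    upper: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ConfigError(
                f"require 0 < lower < upper, got lower={self.lower}, upper={self.upper}"
            )
        if self.rate <= 0:
            raise ConfigError(f"rate must be positive, got {self.rate}")

    @property
    def optimum(self) -> float:
        """Stock level maximizing the growth increment (closed form).

        The cubic growth rule ``r s (s/L - 1)(1 - s/U)`` is maximized at
        ``(L + U + sqrt(U^2 - UL + L^2)) / 3``.
        """
        L, U = self.lower, self.upper
        return (L + U + math.sqrt(U * U - U * L + L * L)) / 3.0

    def growth(self, stock: float) -> float:
        return growth(stock, self)


#: The game's two standard regimes.
HIGH_VOLATILITY = VolatilityRegime(rate=0.25, lower=8.0, upper=25.0, label="high")
LOW_VOLATILITY = VolatilityRegime(rate=0.05, lower=2.0, upper=25.0, label="low")


def growth(stock: float, regime: VolatilityRegime) -> float:
    """Natural growth increment for a post-harvest stock level.

    Implements the strong-Allee cubic
    ``rate * s * (s/L - 1) * (1 - s/U)``: zero exactly at both critical
    values, positive strictly between them, negative below ``L`` and above
    ``U``.  May be negative; the caller floors stocks at zero.
    """
    if not math.isfinite(stock):
        raise ValidationError(f"stock must be finite, got {stock}")
    if stock < 0:
        raise ValidationError(f"stock must be non-negative, got {stock}")
    return (
        regime.rate
        * stock
        * (stock / regime.lower - 1.0)
        * (1.0 - stock / regime.upper)
    )


# ---------------------------------------------------------------------------
# shocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShockModel:
    """Zero-mean random shock applied to each player every period.

    ``scale`` is the standard deviation in resource units for the ``normal``
    and ``uniform`` distributions.  ``discrete_uniform`` draws integers
    uniformly from ``{-k, ..., k}`` with ``k = max(1, round(scale * sqrt(3)))``
    (the half-width matching a continuous uniform of that standard
    deviation).  Draws never depend on the player's stock.
    """

    distribution: str = "normal"
    scale: float = 2.0

    _DISTRIBUTIONS = ("normal", "uniform", "discrete_uniform")

    def __post_init__(self) -> None:
        if self.distribution not in self._DISTRIBUTIONS:
            raise ConfigError(
                f"unknown shock distribution {self.distribution!r}; "
                f"choose from {self._DISTRIBUTIONS}"
            )
        if self.scale < 0:
            raise ConfigError(f"scale must be >= 0, got {self.scale}")

    def draw(self, rng: np.random.Generator, size: Optional[int] = None):
        if self.distribution == "normal":
            return rng.normal(0.0, self.scale, size=size)
        if self.distribution == "uniform":
            half = self.scale * math.sqrt(3.0)
            return rng.uniform(-half, half, size=size)
        k = max(1, round(self.scale * math.sqrt(3.0)))
        draw = rng.integers(-k, k + 1, size=size)
        return float(draw) if size is None else draw.astype(float)


# ---------------------------------------------------------------------------
# configuration and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GameConfig:
    """Full parameterization of one session.

    Defaults follow the laboratory protocol: a seven-period practice block,
    then four rounds of twenty periods, half under the high-volatility
    regime and half under the low, with partners reassigned and stocks reset
    every round.  ``death_threshold=None`` uses each round's lower critical
    value ``L`` as the survival threshold.
    """

    n_rounds: int = 4
    periods_per_round: int = 20
    practice_periods: int = 7
    regimes_by_round: Optional[tuple] = None  # tuple[VolatilityRegime, ...]
    death_threshold: Optional[float] = None
    death_grace: int = 3
    initial_stock: float = 15.0
    units_per_dollar: float = 15.0
    show_up_fee: float = 5.0
    shock_model: ShockModel = field(default_factory=ShockModel)
    integer_stocks: bool = False
    high_first: bool = True

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.periods_per_round < 1:
            raise ConfigError("need at least one round of at least one period")
        if self.death_grace < 1:
            raise ConfigError("death_grace must be >= 1")
        if self.practice_periods < 0:
            raise ConfigError("practice_periods must be >= 0")
        if self.regimes_by_round is not None:
            if len(self.regimes_by_round) != self.n_rounds:
                raise ConfigError(
                    f"regimes_by_round has {len(self.regimes_by_round)} entries "
                    f"for {self.n_rounds} rounds"
                )
        for regime in self.regimes():
            threshold = self.threshold_for(regime)
            if self.initial_stock <= threshold:
                raise ConfigError(
                    f"initial_stock ({self.initial_stock}) must exceed the "
                    f"survival threshold ({threshold}, regime {regime.label!r})"
                )

    def regimes(self) -> tuple:
        """Regime for each round; default alternates high/low (or low/high)."""
        if self.regimes_by_round is not None:
            return tuple(self.regimes_by_round)
        order = (HIGH_VOLATILITY, LOW_VOLATILITY)
        if not self.high_first:
            order = (LOW_VOLATILITY, HIGH_VOLATILITY)
        return tuple(order[r % 2] for r in range(self.n_rounds))

    def threshold_for(self, regime: VolatilityRegime) -> float:
        return regime.lower if self.death_threshold is None else self.death_threshold


@dataclass
class PlayerState:
    """One player's mutable state within a round."""

    stock: float
    alive: bool = True
    consecutive_below: int = 0
    harvested_total: float = 0.0
    ledger_balance: float = 0.0  # net given minus received, current pairing


@dataclass(frozen=True)
class Observation:
    """What a policy may condition on: own stock, the partner's stock
    (holdings are mutually visible), the net transfer ledger with the
    current partner, and the round's regime and survival threshold."""

    stock: float
    partner_stock: float
    ledger_balance: float
    regime: VolatilityRegime
    death_threshold: float


# ---------------------------------------------------------------------------
# per-period update
# ---------------------------------------------------------------------------

def _validate_action(name: str, value: float, limit: float, player: str) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValidationError(f"player {player}: {name} must be finite and >= 0, got {value}")
    if value > limit + 1e-9:
        raise ValidationError(
            f"player {player}: {name} {value} exceeds available stock {limit}"
        )


def step_period(
    states: Sequence[PlayerState],
    actions: Sequence[tuple],
    regime: VolatilityRegime,
    shocks: Sequence[float],
    integer_stocks: bool = False,
):
    """Advance one period for a pair of players.

    ``actions`` holds ``(harvest, requested, given)`` per player; requests
    are informational (they drive the partner's giving decision upstream)
    and are validated only for sign.  The update per player is

        s'   = s - harvest
        s''  = s' + growth(s', regime)
        s''' = s'' + received - given + shock
        post = max(s''', 0)

    with ``given`` capped by ``s''`` (a player cannot give resources it does
    not hold after growth).  Dead players must submit all-zero actions and
    their stock is frozen.  Returns ``(new_states, records)`` where each
    record is a dict of the per-player period fields.
    """
    if len(states) != 2 or len(actions) != 2 or len(shocks) != 2:
        raise ValidationError("step_period operates on exactly two players")

    pre = [s.stock for s in states]
    mid = [0.0, 0.0]
    for i, (state, (harvest, requested, given)) in enumerate(zip(states, actions)):
        who = str(i)
        if not state.alive:
            if harvest or requested or given:
                raise ValidationError(
                    f"player {who} is out of the game but submitted a nonzero action"
                )
            mid[i] = state.stock
            continue
        _validate_action("harvest", harvest, state.stock, who)
        if not math.isfinite(requested) or requested < 0:
            raise ValidationError(f"player {who}: request must be finite and >= 0")
        after_harvest = state.stock - harvest
        mid[i] = after_harvest + growth(after_harvest, regime)

    for i, (state, (_, _, given)) in enumerate(zip(states, actions)):
        if state.alive:
            _validate_action("give", given, max(mid[i], 0.0), str(i))

    new_states = []
    records = []
    for i, (state, (harvest, requested, given)) in enumerate(zip(states, actions)):
        j = 1 - i
        received = actions[j][2]
        if not state.alive:
            post = state.stock
            shock = 0.0
            received = 0.0
        else:
            shock = float(shocks[i])
            post = mid[i] + received - given + shock
            post = max(post, 0.0)
            if integer_stocks:
                post = float(round(post))
        new_states.append(
            replace(
                state,
                stock=post,
                harvested_total=state.harvested_total + (harvest if state.alive else 0.0),
                ledger_balance=state.ledger_balance
                + ((given - received) if state.alive else 0.0),
            )
        )
        records.append(
            {
                "stock_pre": pre[i],
                "harvest": float(harvest),
                "requested": float(requested),
                "received": float(received),
                "given": float(given),
                "shock": shock,
                "stock_post": post,
            }
        )
    return new_states, records


def update_survival(state: PlayerState, threshold: float, grace: int) -> PlayerState:
    """Apply the drop-out rule after a period's stock update.

    The below-threshold counter increments while ``stock < threshold`` and
    resets to zero otherwise; once it reaches ``grace`` consecutive periods
    the player is out for the rest of the round (never revived within it).
    """
    if not state.alive:
        return state
    if state.stock < threshold:
        below = state.consecutive_below + 1
        return replace(state, consecutive_below=below, alive=below < grace)
    return replace(state, consecutive_below=0)


def earnings(state: PlayerState, config: GameConfig) -> float:
    """Dollar earnings: show-up fee plus one dollar per ``units_per_dollar``
    units harvested (fractional dollars retained)."""
    return config.show_up_fee + state.harvested_total / config.units_per_dollar


# ---------------------------------------------------------------------------
# session loop
# ---------------------------------------------------------------------------

LOG_COLUMNS = [
    "session",
    "round",
    "period",
    "practice",
    "player_id",
    "partner_id",
    "condition",
    "treatment",
    "regime_label",
    "stock_pre",
    "harvest",
    "requested",
    "received",
    "given",
    "shock",
    "stock_post",
    "alive_post",
]


def _round_robin_pairs(order: list, round_index: int) -> list:
    """Circle-method schedule: distinct partners across rounds whenever the
    number of rounds is below the number of players."""
    n = len(order)
    rest = order[1:]
    k = round_index % max(len(rest), 1)
    rotated = rest[k:] + rest[:k]
    arrangement = [order[0]] + rotated
    return [(arrangement[i], arrangement[n - 1 - i]) for i in range(n // 2)]


def run_session(
    config: GameConfig,
    policies: Sequence,
    rng: np.random.Generator,
    conditions: Optional[Sequence[str]] = None,
    treatments: Optional[Sequence[str]] = None,
    player_ids: Optional[Sequence[str]] = None,
    session_id=0,
) -> pd.DataFrame:
    """Simulate a full session and return the tidy per-player-period log.

    ``policies`` supplies one decision policy per player (even count).  The
    practice block (round 0, flagged ``practice=True``) uses the first
    round's pairing and regime; stocks, ledgers, and survival reset before
    scored play and again at every round boundary, with partners reshuffled
    each round.  All randomness flows through ``rng``, so identical seeds
    yield identical logs.

    Returns a :class:`pandas.DataFrame` with columns :data:`LOG_COLUMNS`.
    """
    n = len(policies)
    if n < 2 or n % 2:
        raise ConfigError(f"need an even number of players >= 2, got {n}")
    if player_ids is None:
        player_ids = [f"p{i:03d}" for i in range(n)]
    if conditions is None:
        conditions = ["unlabeled"] * n
    if treatments is None:
        treatments = list(conditions)
    if not (len(player_ids) == len(conditions) == len(treatments) == n):
        raise ConfigError("player_ids/conditions/treatments must match the player count")

    index_of = {pid: i for i, pid in enumerate(player_ids)}
    base_order = list(player_ids)
    rng.shuffle(base_order)
    regimes = config.regimes()

    columns: dict = {c: [] for c in LOG_COLUMNS}

    def play_block(round_label: int, pairs, regime, n_periods: int, practice: bool):
        threshold = config.threshold_for(regime)
        states = {pid: PlayerState(stock=config.initial_stock) for pid in player_ids}
        for period in range(1, n_periods + 1):
            shocks_all = config.shock_model.draw(rng, size=n)
            for k, (pa, pb) in enumerate(pairs):
                pair_states = [states[pa], states[pb]]
                pair_pol = [policies[index_of[pa]], policies[index_of[pb]]]
                obs = [
                    Observation(
                        stock=pair_states[i].stock,
                        partner_stock=pair_states[1 - i].stock,
                        ledger_balance=pair_states[i].ledger_balance,
                        regime=regime,
                        death_threshold=threshold,
                    )
                    for i in range(2)
                ]
                plans = []
                for i in range(2):
                    if pair_states[i].alive:
                        plans.append(pair_pol[i].harvest_and_request(obs[i], rng))
                    else:
                        plans.append((0.0, 0.0))
                mid = []
                for i in range(2):
                    if pair_states[i].alive:
                        s1 = pair_states[i].stock - plans[i][0]
                        mid.append(s1 + growth(s1, regime))
                    else:
                        mid.append(pair_states[i].stock)
                gives = []
                for i in range(2):
                    if pair_states[i].alive and pair_states[1 - i].alive:
                        mid_obs = Observation(
                            stock=mid[i],
                            partner_stock=mid[1 - i],
                            ledger_balance=pair_states[i].ledger_balance,
                            regime=regime,
                            death_threshold=threshold,
                        )
                        give = pair_pol[i].respond(mid_obs, plans[1 - i][1], rng)
                        gives.append(min(max(give, 0.0), max(mid[i], 0.0)))
                    else:
                        gives.append(0.0)
                actions = [
                    (plans[i][0], plans[i][1], gives[i]) for i in range(2)
                ]
                pair_shocks = [
                    float(shocks_all[index_of[pa]]),
                    float(shocks_all[index_of[pb]]),
                ]
                new_states, recs = step_period(
                    pair_states, actions, regime, pair_shocks, config.integer_stocks
                )
                for i, pid in enumerate((pa, pb)):
                    st = update_survival(new_states[i], threshold, config.death_grace)
                    states[pid] = st
                    rec = recs[i]
                    idx = index_of[pid]
                    columns["session"].append(session_id)
                    columns["round"].append(round_label)
                    columns["period"].append(period)
                    columns["practice"].append(practice)
                    columns["player_id"].append(pid)
                    columns["partner_id"].append((pa, pb)[1 - i])
                    columns["condition"].append(conditions[idx])
                    columns["treatment"].append(treatments[idx])
                    columns["regime_label"].append(regime.label)
                    for key in (
                        "stock_pre",
                        "harvest",
                        "requested",
                        "received",
                        "given",
                        "shock",
                        "stock_post",
                    ):
                        columns[key].append(rec[key])
                    columns["alive_post"].append(st.alive)
        if not practice:
            for pid in player_ids:
                harvested[pid] += states[pid].harvested_total

    harvested = {pid: 0.0 for pid in player_ids}
    if config.practice_periods > 0:
        pairs0 = _round_robin_pairs(base_order, 0)
        play_block(0, pairs0, regimes[0], config.practice_periods, practice=True)
    for r in range(config.n_rounds):
        pairs = _round_robin_pairs(base_order, r)
        play_block(r + 1, pairs, regimes[r], config.periods_per_round, practice=False)

    df = pd.DataFrame(columns)
    df.attrs["harvested_total"] = harvested
    return df
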