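"""Decision policies for the risk-pooling game.

Three archetypes mirror the transfer rules the game was built to compare:

* **need-based** — ask only from genuine need (stock below a need
  threshold), ask only for the amount needed (a top-up to a safe level),
  give whenever one can afford to without dropping below one's own safe
  level, and keep no accounts;
* **debt-based** — like need-based, but every gift creates a debt: a donor
  refuses to give again while the partner's previous gift is unrepaid, a
  debtor will not ask again before repaying, and debtors repay out of
  surplus without being asked;
* **no-transfer** — never ask, never give.

A fourth, stochastic policy layers per-player propensities (to ask, to
give, and to care about open debts) on the need-based skeleton; the
synthetic-data generator uses it to emulate heterogeneous human play.

All policies share the same harvest rule — harvest exactly the stock in
excess of the regime's growth optimum, holding the stock where it grows
fastest — so that survival differences between policies isolate the
transfer rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Observation
from .errors import ConfigError

__all__ = [
    "StrategyParams",
    "Policy",
    "NeedBasedPolicy",
    "DebtBasedPolicy",
    "NoTransferPolicy",
    "StochasticHumanPolicy",
    "make_policy",
    "POLICY_NAMES",
]


@dataclass(frozen=True)
class StrategyParams:
    """Tunable behavioral parameters.

    need_threshold
        Stock level (resource units) below which a player feels in need and
        may request help.
    safe_level
        Target stock after receiving help, and the floor a donor will not
        give below.  Must be >= ``need_threshold``.
    give_propensity
        Probability of answering a request positively (stochastic policy).
    debt_sensitivity
        Probability of suppressing an action because of an open debt —
        refusing to give to a partner who has not repaid, or declining to
        re-ask while one's own debt is unpaid (stochastic policy).
    ask_propensity
        Probability of actually emitting a request when in need
        (stochastic policy).
    """

    need_threshold: float = 10.0
    safe_level: float = 14.0
    give_propensity: float = 1.0
    debt_sensitivity: float = 0.0
    ask_propensity: float = 1.0

    def __post_init__(self) -> None:
        for name in ("give_propensity", "debt_sensitivity", "ask_propensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.need_threshold > self.safe_level:
            raise ConfigError(
                f"need_threshold ({self.need_threshold}) must not exceed "
                f"safe_level ({self.safe_level})"
            )


class Policy:
    """Base policy: harvest down to the growth optimum, never transfer."""

    def __init__(self, params: StrategyParams | None = None) -> None:
        self.params = params if params is not None else StrategyParams()

    # -- harvest ----------------------------------------------------------
    def _harvest(self, obs: Observation) -> float:
        return max(0.0, obs.stock - obs.regime.optimum)

    # -- request ----------------------------------------------------------
    def _need(self, stock_after_harvest: float) -> float:
        """Amount needed to top up to the safe level, zero if not in need."""
        p = self.params
        if stock_after_harvest < p.need_threshold:
            return max(0.0, p.safe_level - stock_after_harvest)
        return 0.0

    def harvest_and_request(
        self, obs: Observation, rng: np.random.Generator
    ) -> tuple:
        harvest = self._harvest(obs)
        return harvest, self._request(obs, obs.stock - harvest, rng)

    def _request(self, obs, stock_after_harvest, rng) -> float:
        return 0.0

    # -- respond ----------------------------------------------------------
    def _surplus(self, stock: float) -> float:
        return max(0.0, stock - self.params.safe_level)

    def respond(
        self, obs: Observation, requested: float, rng: np.random.Generator
    ) -> float:
        return 0.0


class NoTransferPolicy(Policy):
    """Never requests, never gives."""


class NeedBasedPolicy(Policy):
    """Ask only from need and only for the amount needed; give whatever is
    affordable above one's own safe level; ignore the ledger entirely."""

    def _request(self, obs, stock_after_harvest, rng) -> float:
        return self._need(stock_after_harvest)

    def respond(self, obs, requested, rng) -> float:
        return min(requested, self._surplus(obs.stock))


class DebtBasedPolicy(NeedBasedPolicy):
    """Account-keeping transfers.

    The net ledger balance (own given minus received within the current
    pairing) operationalizes debt: positive means the partner owes this
    player, negative means this player owes the partner.  The policy will
    not give while the partner's debt is open, will not ask while its own
    debt is open, and repays ``min(debt, surplus)`` out of surplus without
    being asked.
    """

    def _request(self, obs, stock_after_harvest, rng) -> float:
        if obs.ledger_balance < 0:  # own debt unpaid: do not re-ask
            return 0.0
        return self._need(stock_after_harvest)

    def respond(self, obs, requested, rng) -> float:
        surplus = self._surplus(obs.stock)
        repayment = 0.0
        if obs.ledger_balance < 0:
            repayment = min(-obs.ledger_balance, surplus)
            surplus -= repayment
        if obs.ledger_balance > 0:  # partner's debt open: no further credit
            return repayment
        return repayment + min(requested, surplus)


class StochasticHumanPolicy(NeedBasedPolicy):
    """Need-based play filtered through per-player propensities.

    A request in need is emitted with probability ``ask_propensity`` and,
    if the player's own debt is open, additionally suppressed with
    probability ``debt_sensitivity``.  A positive response to a request
    occurs with probability ``give_propensity`` and, if the asker's debt is
    open, is additionally suppressed with probability ``debt_sensitivity``.
    With ``give_propensity = ask_propensity = 1`` and
    ``debt_sensitivity = 0`` this reduces exactly to the need-based policy.
    """

    def _request(self, obs, stock_after_harvest, rng) -> float:
        amount = self._need(stock_after_harvest)
        if amount <= 0.0:
            return 0.0
        p = self.params
        # draw only when the outcome is actually random, so degenerate
        # propensities reproduce the deterministic policies draw-for-draw
        if p.ask_propensity < 1.0 and rng.random() >= p.ask_propensity:
            return 0.0
        if (
            obs.ledger_balance < 0
            and p.debt_sensitivity > 0.0
            and rng.random() < p.debt_sensitivity
        ):
            return 0.0
        return amount

    def respond(self, obs, requested, rng) -> float:
        if requested <= 0.0:
            return 0.0
        p = self.params
        if p.give_propensity < 1.0 and rng.random() >= p.give_propensity:
            return 0.0
        if (
            obs.ledger_balance > 0
            and p.debt_sensitivity > 0.0
            and rng.random() < p.debt_sensitivity
        ):
            return 0.0
        return min(requested, self._surplus(obs.stock))


POLICY_NAMES = {
    "need_based": NeedBasedPolicy,
    "debt_based": DebtBasedPolicy,
    "none": NoTransferPolicy,
    "stochastic": StochasticHumanPolicy,
}


def make_policy(name: str, params: StrategyParams | None = None) -> Policy:
    """Instantiate a policy by its registry name
    (``need_based | debt_based | none | stochastic``)."""
    try:
        cls = POLICY_NAMES[name]
    except KeyError:
        raise ConfigError(
            f"unknown strategy {name!r}; choose from {sorted(POLICY_NAMES)}"
        ) from None
    return cls(params)
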