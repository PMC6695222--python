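"""The seven behavioral variables, computed per player from a session log.

* repetitive giving — periods in which the player gave although the
  partner had not yet repaid an earlier gift;
* repetitive asking — periods in which the player asked although the
  player had not yet repaid an earlier gift received;
* mean amount requested / mean amount given — totals divided by the number
  of periods the player was in the game (request-free periods count as
  zeros; a per-event variant divides by the number of events instead);
* number of requests made;
* number of requests responded to positively — requests received that were
  met with a nonzero gift;
* matching — |total given − total received|.

"Repaid" uses net accounting within a pairing: a debt is open while the
net balance (given minus received, accumulated over earlier periods of the
same round's pairing) is nonzero in the relevant direction, and returning
the balance to zero closes it.  Gift-by-gift accounting with payments
retiring gifts in order reduces to the same openness criterion, since any
excess repayment immediately becomes a gift in the other direction.

Practice periods are excluded by default.  ``periods_survived`` counts the
non-practice periods a player finished alive, out of
``n_rounds * periods_per_round`` (players re-enter at each round reset).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "METRIC_VARIABLES",
    "metrics_table",
    "compute_repetitive_giving",
    "compute_repetitive_asking",
    "compute_mean_amounts",
    "compute_request_counts",
    "compute_matching",
]

#: The seven variables in the order the reproduction report uses.
METRIC_VARIABLES = [
    "repetitive_asking",
    "repetitive_giving",
    "mean_amount_requested",
    "mean_amount_given",
    "n_requests_made",
    "n_requests_answered_positively",
    "matching_abs_diff",
]


def _prepare(log: pd.DataFrame, include_practice: bool) -> pd.DataFrame:
    df = log if include_practice else log[~log["practice"].astype(bool)]
    if df.empty:
        raise ValidationError("log contains no scored periods")
    df = df.sort_values(["session", "round", "period", "player_id"], kind="stable")

    by_pairing = df.groupby(["session", "round", "player_id"], sort=False)
    # net balance with the current partner entering the period
    df = df.assign(
        _balance_before=by_pairing["given"].cumsum()
        - df["given"]
        - (by_pairing["received"].cumsum() - df["received"]),
        _alive_pre=by_pairing["alive_post"].shift(1, fill_value=True).astype(bool),
    )

    # partner's request in the same period
    partner_req = df.set_index(["session", "round", "period", "player_id"])["requested"]
    idx = pd.MultiIndex.from_arrays(
        [df["session"], df["round"], df["period"], df["partner_id"]]
    )
    df = df.assign(_partner_requested=partner_req.reindex(idx).to_numpy())
    return df


def metrics_table(
    log: pd.DataFrame,
    include_practice: bool = False,
    per_event: bool = False,
) -> pd.DataFrame:
    """Compute all behavioral variables for every player in the log.

    Parameters
    ----------
    log
        Tidy per-player-period session log (engine schema).
    include_practice
        Include the practice block in the totals (off by default).
    per_event
        Divide mean amounts by the number of request/give events instead of
        by the number of periods in the game.

    Returns
    -------
    pandas.DataFrame
        One row per ``player_id`` with the seven variables,
        ``periods_survived``, ``periods_in_game``, and the player's
        ``condition`` and ``treatment`` labels.
    """
    df = _prepare(log, include_practice)

    given = df["given"].to_numpy()
    requested = df["requested"].to_numpy()
    balance = df["_balance_before"].to_numpy()

    # vectorized counts via groupby-sum on indicator columns
    ind = pd.DataFrame(
        {
            "player_id": df["player_id"].to_numpy(),
            "rep_give": (given > 0) & (balance > 0),
            "rep_ask": (requested > 0) & (balance < 0),
            "req_made": requested > 0,
            "answered": (df["_partner_requested"].to_numpy() > 0) & (given > 0),
            "given": given,
            "received": df["received"].to_numpy(),
            "requested": requested,
            "in_game": df["_alive_pre"].to_numpy(),
            "alive_post": df["alive_post"].to_numpy(dtype=bool),
        }
    )
    sums = ind.groupby("player_id", sort=True).sum()

    periods_in_game = sums["in_game"].astype(int)
    if (periods_in_game == 0).any():
        dead = list(sums.index[periods_in_game == 0])
        warnings.warn(
            f"players with zero periods in game, mean amounts undefined: {dead}",
            stacklevel=2,
        )

    if per_event:
        req_den = sums["req_made"].replace(0, np.nan)
        give_den = (ind.groupby("player_id")["given"].apply(lambda s: (s > 0).sum())).replace(
            0, np.nan
        )
        mean_requested = (sums["requested"] / req_den).fillna(0.0)
        mean_given = (sums["given"] / give_den).fillna(0.0)
    else:
        den = periods_in_game.replace(0, np.nan)
        mean_requested = sums["requested"] / den
        mean_given = sums["given"] / den

    labels = df.groupby("player_id", sort=True)[["condition", "treatment"]].first()

    out = pd.DataFrame(
        {
            "repetitive_giving": sums["rep_give"].astype(int),
            "repetitive_asking": sums["rep_ask"].astype(int),
            "mean_amount_requested": mean_requested,
            "mean_amount_given": mean_given,
            "n_requests_made": sums["req_made"].astype(int),
            "n_requests_answered_positively": sums["answered"].astype(int),
            "matching_abs_diff": (sums["given"] - sums["received"]).abs(),
            "periods_survived": sums["alive_post"].astype(int),
            "periods_in_game": periods_in_game,
            "condition": labels["condition"],
            "treatment": labels["treatment"],
        }
    )
    out.index.name = "player_id"
    return out.reset_index()


def _one_player(log: pd.DataFrame, player, **kwargs) -> pd.Series:
    table = metrics_table(log, **kwargs)
    row = table[table["player_id"] == player]
    if row.empty:
        raise ValidationError(f"unknown player id {player!r}")
    return row.iloc[0]


def compute_repetitive_giving(log: pd.DataFrame, player, **kwargs) -> int:
    """Periods in which ``player`` gave while the partner's earlier gift
    balance was still unrepaid."""
    return int(_one_player(log, player, **kwargs)["repetitive_giving"])


def compute_repetitive_asking(log: pd.DataFrame, player, **kwargs) -> int:
    """Periods in which ``player`` asked while its own debt to the partner
    was still unrepaid."""
    return int(_one_player(log, player, **kwargs)["repetitive_asking"])


def compute_mean_amounts(log: pd.DataFrame, player, **kwargs) -> tuple:
    """(mean amount requested, mean amount given) for ``player``."""
    row = _one_player(log, player, **kwargs)
    return float(row["mean_amount_requested"]), float(row["mean_amount_given"])


def compute_request_counts(log: pd.DataFrame, player, **kwargs) -> tuple:
    """(requests made, requests received answered positively)."""
    row = _one_player(log, player, **kwargs)
    return int(row["n_requests_made"]), int(row["n_requests_answered_positively"])


def compute_matching(log: pd.DataFrame, player, **kwargs) -> float:
    """|total given − total received| for ``player`` over scored play."""
    return float(_one_player(log, player, **kwargs)["matching_abs_diff"])
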