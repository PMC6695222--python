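import numpy as np
import pandas as pd
import pytest

from riskpool.engine import LOG_COLUMNS


def two_player_log(periods, player_a="A", player_b="B", session=0):
    """Build a tidy two-player log from compact per-period event dicts.

    Each entry of ``periods`` may set ``req_a, give_a, req_b, give_b,
    round, practice, alive_a, alive_b``; received mirrors the partner's
    give.  Stock columns get placeholder values consistent with the schema
    (metrics never read them).
    """
    cols = {c: [] for c in LOG_COLUMNS}
    for t, ev in enumerate(periods, start=1):
        rnd = ev.get("round", 1)
        practice = ev.get("practice", False)
        for me, other, suffix, osuffix in (
            (player_a, player_b, "a", "b"),
            (player_b, player_a, "b", "a"),
        ):
            cols["session"].append(session)
            cols["round"].append(rnd)
            cols["period"].append(ev.get("period", t))
            cols["practice"].append(practice)
            cols["player_id"].append(me)
            cols["partner_id"].append(other)
            cols["condition"].append(ev.get(f"condition_{suffix}", "unlabeled"))
            cols["treatment"].append(ev.get(f"condition_{suffix}", "unlabeled"))
            cols["regime_label"].append("high")
            cols["stock_pre"].append(15.0)
            cols["harvest"].append(float(ev.get(f"harvest_{suffix}", 0.0)))
            cols["requested"].append(float(ev.get(f"req_{suffix}", 0.0)))
            cols["received"].append(float(ev.get(f"give_{osuffix}", 0.0)))
            cols["given"].append(float(ev.get(f"give_{suffix}", 0.0)))
            cols["shock"].append(0.0)
            cols["stock_post"].append(15.0)
            cols["alive_post"].append(bool(ev.get(f"alive_{suffix}", True)))
    return pd.DataFrame(cols)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_log_repetitive():
    """A gives 3 at t1 and again 2 at t4 with nothing repaid; B asks both
    times, the second time while still in debt."""
    return two_player_log(
        [
            {"req_b": 3, "give_a": 3},
            {},
            {},
            {"req_b": 2, "give_a": 2},
            {},
        ]
    )


@pytest.fixture
def toy_log_repaid():
    """B repays A's first gift in full before A gives again: no repetitive
    events anywhere."""
    return two_player_log(
        [
            {"req_b": 3, "give_a": 3},
            {"give_b": 3},
            {},
            {"req_b": 2, "give_a": 2},
            {},
        ]
    )


@pytest.fixture
def toy_log_no_transfers():
    """No scored transfers (one practice-only request) and a death: B's
    stock collapses and B is out from period 2 of the scored round."""
    return two_player_log(
        [
            {"round": 0, "practice": True, "req_b": 4, "give_a": 4, "period": 1},
            {"round": 1, "period": 1},
            {"round": 1, "period": 2, "alive_b": False},
            {"round": 1, "period": 3, "alive_b": False},
            {"round": 1, "period": 4, "alive_b": False},
        ]
    )
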