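"""Naive period-by-period replay oracle for the behavioral metrics.

Independent of the package's ledger implementation: debts are tracked as
explicit queues of individual gifts, with each payment retiring the oldest
outstanding gift and any excess becoming a counter-gift.  On logs where
every gift is repaid in full or not at all, this gift-by-gift accounting
and the package's net-balance accounting must agree.
"""

from collections import defaultdict, deque


def naive_metrics(log):
    """Compute the seven variables plus survival per player by brute-force
    replay.  Returns {player_id: {metric: value}}."""
    out = {}
    players = sorted(log["player_id"].unique())
    for p in players:
        out[p] = {
            "repetitive_giving": 0,
            "repetitive_asking": 0,
            "n_requests_made": 0,
            "n_requests_answered_positively": 0,
            "total_requested": 0.0,
            "total_given": 0.0,
            "total_received": 0.0,
            "periods_in_game": 0,
            "periods_survived": 0,
        }

    scored = log[~log["practice"].astype(bool)]
    for (_, _), block in scored.groupby(["session", "round"], sort=True):
        # outstanding gift queues per ordered pair (giver, receiver)
        owed = defaultdict(deque)
        alive = {p: True for p in block["player_id"].unique()}
        for _, period_rows in block.groupby("period", sort=True):
            rows = {r["player_id"]: r for _, r in period_rows.iterrows()}
            for p, row in rows.items():
                if not alive[p]:
                    continue
                q = row["partner_id"]
                m = out[p]
                m["periods_in_game"] += 1
                if row["requested"] > 0:
                    m["n_requests_made"] += 1
                    if owed[(q, p)]:  # an unrepaid gift from q to p exists
                        m["repetitive_asking"] += 1
                if row["given"] > 0:
                    if owed[(p, q)]:
                        m["repetitive_giving"] += 1
                    if rows[q]["requested"] > 0:
                        m["n_requests_answered_positively"] += 1
                m["total_requested"] += row["requested"]
                m["total_given"] += row["given"]
                m["total_received"] += row["received"]
            # settle this period's transfers against the queues
            for p, row in rows.items():
                amount = row["given"]
                if amount <= 0:
                    continue
                q = row["partner_id"]
                queue = owed[(q, p)]  # what p owes q from q's earlier gifts
                while amount > 0 and queue:
                    if amount >= queue[0] - 1e-12:
                        amount -= queue.popleft()
                    else:
                        queue[0] -= amount
                        amount = 0.0
                if amount > 1e-12:
                    owed[(p, q)].append(amount)
            for p, row in rows.items():
                if alive[p]:
                    if row["alive_post"]:
                        out[p]["periods_survived"] += 1
                    else:
                        alive[p] = False

    for p, m in out.items():
        n = m.pop("periods_in_game")
        m["periods_in_game"] = n
        m["mean_amount_requested"] = m.pop("total_requested") / n if n else 0.0
        m["mean_amount_given"] = m["total_given"] / n if n else 0.0
        m["matching_abs_diff"] = abs(m.pop("total_given") - m.pop("total_received"))
    return out
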