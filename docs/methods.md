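# Methods

This note records the modeling choices behind `riskpool`: the game
dynamics, the decision policies, the behavioral metrics and statistics,
what the synthetic-data generator does and does not emulate, and the
numerical conventions the implementation fixes.

## Resource dynamics

Each player's stock `s` (resource units) evolves once per period in a
fixed order:

1. **Harvest** — the player banks `h ≤ s` toward earnings; `s′ = s − h`.
2. **Growth** — `s″ = s′ + g(s′)` with the strong-Allee cubic
   `g(s) = r·s·(s/L − 1)·(1 − s/U)`.
3. **Transfers and shock** — `s‴ = s″ + received − given + shock`, floored
   at zero; a player can give at most `s″`.

The published description of the game constrains the growth rule to act on
the *post-harvest* stock, to be parameterized by a rate and two critical
values, to shrink stocks below `L` and above `U`, and to have its maximum
"around 17" (low volatility, `r = 0.05, L = 2, U = 25`) and "around 18"
(high volatility, `r = 0.25, L = 8, U = 25`).  The cubic above is the
minimal form satisfying all of these: it is zero exactly at `L` and `U`,
positive strictly between, negative outside, and its argmax
`(L + U + √(U² − UL + L²))/3` evaluates to 17.02 and 18.37 for the two
regimes.  The functional form is nevertheless a design decision — the
original lab software's exact rule is not published — so the regime object
is a plain dataclass that an alternative rule could replace.  The
placement of transfers and shock *after* growth is likewise a fixed
convention; only the harvest-before-growth ordering is externally
constrained.

Shocks are zero-mean and independent of stock size.  Three families are
provided (`normal`, `uniform`, `discrete_uniform`), parameterized by a
standard deviation `scale` in resource units.  The engine default is
normal with `scale = 2`; negative excursions are handled by flooring the
stock at zero rather than truncating the distribution.

**Survival.**  A stock below the threshold for `death_grace = 3`
consecutive periods removes the player for the remainder of the round
(no harvesting, requesting, or responding; stock frozen).  The threshold
itself is unpublished; the default is the active regime's lower critical
value `L`, the stated boundary where stocks begin to shrink, and it is
configurable.  Players re-enter at the next round's stock reset, since
stocks are reset and partners reassigned every round.  `periods_survived`
sums alive periods over the four scored rounds (max 80).

**Session structure.**  Defaults follow the lab protocol: a 7-period
practice block, then 4 rounds × 20 periods, half high- and half
low-volatility with the order configurable, stocks reset to
`initial_stock = 15` (inside the growth-positive band of both regimes;
the lab value is unpublished) and partners reshuffled each round by a
circle-method rotation that guarantees distinct partners across rounds.
Earnings are `$5 + harvested/15` in dollars; practice harvests do not
count.  Stocks are real-valued; an integer-stock mode exists because the
lab granularity is unpublished.

## Decision policies

All policies share one harvest rule — harvest exactly the stock in excess
of the regime's growth optimum — so that survival and transfer differences
between policies isolate the transfer rules themselves.  How human players
actually traded off harvesting against giving capacity is not documented;
this shared rule is an assumption, not a reconstruction.

* **Need-based**: request `safe_level − s` only when `s < need_threshold`;
  give `min(request, s − safe_level)`; ignore the ledger.
* **Debt-based**: as need-based, plus net-ledger accounting: no giving
  while the partner's debt is open, no asking while one's own debt is
  open, and unprompted repayment of `min(debt, surplus)`.  Repayment is
  exact-amount; over-repayment is not modeled.
* **No-transfer**: never asks, never gives.
* **Stochastic-human**: the need-based skeleton filtered through
  per-player propensities — requests emitted with probability
  `ask_propensity`, positive responses with probability `give_propensity`,
  and either suppressed with probability `debt_sensitivity` when the
  relevant debt is open.  Degenerate propensities (1, 1, 0) reproduce the
  need-based policy draw-for-draw.

Defaults `need_threshold = 10`, `safe_level = 14` place "need" above the
high regime's shrink boundary (8) and the help target below the growth
optimum, so a rescued player re-enters the growth-positive band without
the donor leaving it.

**Debt accounting.**  "Repaid" is operationalized by the net ledger
balance within the current pairing (given minus received); a debt is open
while the balance is nonzero in the relevant direction, and returning it
to zero (or past it) closes the debt.  Gift-by-gift accounting in which
payments retire the oldest outstanding gift and excess becomes a
counter-gift reduces to exactly the same openness criterion, which is why
the package implements the net rule; the test suite keeps an independent
queue-based replay oracle to check the equivalence on randomized logs.

## Behavioral metrics

Computed per player over scored (non-practice) play, pooled over rounds:
repetitive giving (periods giving while the partner's debt was open),
repetitive asking (periods asking while one's own debt was open), mean
amounts requested and given, requests made, requests answered positively,
and `|total given − total received|` (matching).  Mean amounts divide by
the periods the player was alive and in the game, counting request-free
periods as zeros; a `per_event` flag divides by event counts instead,
since the original analysis does not state which denominator it used.
The ledger resets at round boundaries with the pairing.

## Statistics

The headline analysis mirrors the original: independent-samples t-tests
(Student's pooled-variance, two-tailed, one row per player; Welch available
by flag and always included in the report), Cohen's d with `(n − 1)`
weights, and Bonferroni adjustment `0.05/7 ≈ 0.007`.  Sign conventions:
`t` is control − primed; `d` is primed − control; a variable elevated in
the primed group therefore shows negative `t` and positive `d`, and
`|t| = |d|·√(n₁n₂/(n₁+n₂))` for the pooled case.  Zero-variance inputs
yield flagged limiting values rather than NaNs.  A one-way ANOVA with
Scheffé pairwise contrasts across the primed sub-conditions backs the
decision to pool them.

## The synthetic-data generator

The generator emulates the study design, not priming psychology: it
*plants* a behavioral contrast rather than explaining one.  Its defaults
are the study conditions — 40 control players and 158 primed (four
sub-conditions of 40/40/40/38) — with each simulated player's propensities
drawn from truncated normals (sd 0.15, clipped to [0.01, 0.99]) so that
player-level metric variances are nonzero.  Primed players carry a higher
give propensity and lower debt sensitivity (default means 0.80/0.25
against control 0.55/0.50) and a near-identical ask propensity
(0.70 vs 0.65), the qualitative signature of the experimental findings.

Players are grouped into lab-style sessions of up to 20 per treatment
block, paired within session and **reassigned partners every round**, with
the high-first/low-first regime order alternating across sessions.  The
reassignment matters statistically, not just cosmetically: the matching
variable is identical for both members of a fixed pair, so isolated
two-player sessions would make the player-level t-test on it markedly
anti-conservative; rotating partners spreads each player's totals over
four partners and restores approximate calibration (a mild excess for the
matching test remains — see Limitations).

The generator's game differs from the engine default in one parameter:
shock scale 4 instead of 2.  At scale 2 players in this parameterization
almost never fall into need and session logs contain nearly no transfer
behavior; scale 4 makes needs arrive regularly and unpredictably — the
situation the game is about, and the stated driver of requests in the
original sessions — while a slim majority of simulated players still
survives all eighty periods, matching the reported ceiling effect.

**Effect-size calibration.**  `calibrate_to_effect_sizes` searches the
between-group gaps in give propensity and debt sensitivity so that
simulated Cohen's d per variable lands near requested targets: coordinate
descent on a coarse grid (5 replicate experiments per point, common random
seeds), a local refinement pass, and a response-surface step that fits a
linear model of d on the two gaps over all evaluated points and solves it
for the targets — pooling all evaluations makes the final choice far less
sensitive to single-point Monte-Carlo noise.  Targets the dynamics cannot
reach within ±0.15 are reported as unattained, never silently clipped.

**What the generator does not emulate.**  Real participants are not
stationary stochastic policies: no learning across rounds, no framing or
quiz effects, no demographic structure, no partner-specific reputation
beyond the ledger.  Passing tests therefore show that the *pipeline*
recovers planted contrasts of realistic size under the study's design and
noise level — not that the mechanism behind the human effect is the one
parameterized here.

## Problem sizes and numerical conventions

* Grid searches for the growth optimum use step 0.001 on [0, 25] and are
  cross-checked against the closed form.
* The strategy-pairing survival experiment runs 500 two-player sessions
  per pairing under four high-volatility rounds with shock scale 6 —
  large enough that unaided players commonly die, the regime in which the
  coordination structure is visible.
* Null calibration uses 300 replicate experiments at 24 players per group
  under the full session structure; replicate-level standard errors
  respect the correlation among the seven tests within an experiment.
* Planted-effect recovery averages 50 replicate experiments at the study
  sizes (40 vs 158).
* Validation tolerances: actions are validated with a 1e-9 slack for
  floating-point round-off; log transfer symmetry with 1e-6.
* All simulations flow from a single `numpy` Generator; identical seeds
  give byte-identical logs and reports.

## Known limitations

* The growth rule, survival threshold, initial stock, shock distribution,
  and stock granularity reconstruct unpublished lab details from their
  stated properties; all are configurable precisely because they are
  reconstructions.
* Player-level t-tests on session data ignore residual within-session
  dependence.  Under the null, the matching variable — a pair-level
  quantity — still rejects somewhat above nominal (≈0.09 at α = 0.05 in
  the package's calibration run) even with partner rotation, and the most
  zero-inflated count variables run conservative at small n.  The
  seven-test aggregate calibrates within Monte-Carlo error; per-variable
  calibration is design-limited, in this package as in any player-level
  analysis of paired-play data.
* The two calibration knobs (give-propensity and debt-sensitivity gaps)
  cannot hit seven effect-size targets exactly; the calibrated generator
  matches the profile jointly, trading small misses across variables.
* Strategy-pairing payoffs are reported as mean periods survived in this
  implementation's dynamics; they are not comparable numerically to
  survival percentages from other published models of the same norms.
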