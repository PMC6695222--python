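"""Group comparisons between control and primed players.

The headline analysis is a family of seven independent-samples t-tests
(one per behavioral variable, one row per player pooled over all rounds),
Cohen's d effect sizes, and a Bonferroni-adjusted alpha.  Sign
conventions: t is computed as control minus primed (so a variable elevated
in the primed group yields a negative t), while Cohen's d is primed minus
control over the pooled standard deviation (positive when primed exceeds
control).

A one-way ANOVA with Scheffé post-hoc contrasts across the primed
sub-conditions justifies pooling them into a single "primed" group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError
from .metrics import METRIC_VARIABLES

__all__ = [
    "ComparisonResult",
    "ttest_independent",
    "cohens_d",
    "bonferroni_alpha",
    "condition_pooling_check",
    "reproduce_report",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-group comparison.

    ``t`` is signed control − primed (group a − group b); ``cohens_d`` is
    signed primed − control.  ``degenerate`` flags a zero pooled variance,
    in which case ``t`` and ``p`` are the limiting values (0 and 1 for
    equal means, ±inf and 0 otherwise) rather than silent NaNs.
    """

    variable: str
    mean_control: float
    mean_primed: float
    t: float
    df: float
    p_two_tailed: float
    cohens_d: float
    alpha_used: float = 0.05
    significant_at_alpha: bool = field(default=False)
    n_control: int = 0
    n_primed: int = 0
    degenerate: bool = False


def _check_groups(a: np.ndarray, b: np.ndarray) -> None:
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError(
            f"each group needs n >= 2, got {len(a)} and {len(b)}"
        )
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DegenerateDataError("groups contain non-finite values")


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    return math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )


def ttest_independent(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
    variable: str = "",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-tailed independent-samples t-test (a = control, b = primed).

    Student's pooled-variance test by default (``df = n_a + n_b − 2``);
    Welch's unequal-variance test behind the ``welch`` flag.  A zero pooled
    variance is flagged via ``degenerate`` instead of returning NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    _check_groups(a, b)
    na, nb = len(a), len(b)
    d = cohens_d(a, b)

    sp = _pooled_sd(a, b)
    if sp == 0.0:
        diff = a.mean() - b.mean()
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0 else 0.0
        return ComparisonResult(
            variable, a.mean(), b.mean(), t, float(na + nb - 2), p, d,
            alpha, p < alpha, na, nb, degenerate=True,
        )

    res = sps.ttest_ind(a, b, equal_var=not welch)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    return ComparisonResult(
        variable, float(a.mean()), float(b.mean()), t, df, p, d,
        alpha, p < alpha, na, nb,
    )


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Standardized mean difference (b − a) / pooled SD, the pooled SD
    using (n − 1) weights.  Returns 0 for two identical constant groups and
    ±inf for distinct constant groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    _check_groups(a, b)
    sp = _pooled_sd(a, b)
    diff = b.mean() - a.mean()
    if sp == 0.0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return float(diff / sp)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Familywise-adjusted alpha: ``alpha / m`` (e.g. 0.05 over seven
    comparisons gives 0.00714…, conventionally reported as 0.007)."""
    if m < 1:
        raise DegenerateDataError(f"number of comparisons must be >= 1, got {m}")
    if not 0 < alpha <= 1:
        raise DegenerateDataError(f"alpha must lie in (0, 1], got {alpha}")
    return alpha / m


def condition_pooling_check(
    metrics: pd.DataFrame,
    variables: Optional[Sequence[str]] = None,
    group_col: str = "treatment",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA plus Scheffé pairwise contrasts per variable.

    Used to check whether the primed sub-conditions differ before pooling
    them.  Conditions with fewer than two observations are excluded with a
    warning.  Returns a tidy frame with one ANOVA row (``contrast="ANOVA"``)
    and one row per Scheffé pairwise contrast for each variable; the
    Scheffé p-value for the pair (i, j) is ``P(F_{k-1,N-k} >= F_ij/(k-1))``
    with ``F_ij = (m_i - m_j)^2 / (MSE (1/n_i + 1/n_j))``.
    """
    if variables is None:
        variables = METRIC_VARIABLES
    groups_all = {
        label: sub for label, sub in metrics.groupby(group_col, sort=True)
    }
    usable = {}
    for label, sub in groups_all.items():
        if len(sub) < 2:
            warnings.warn(
                f"condition {label!r} has n={len(sub)} < 2, excluded from ANOVA",
                stacklevel=2,
            )
        else:
            usable[label] = sub
    if len(usable) < 2:
        raise DegenerateDataError("need at least two conditions with n >= 2")

    labels = sorted(usable)
    rows: List[dict] = []
    for var in variables:
        samples = [usable[lab][var].to_numpy(dtype=float) for lab in labels]
        k = len(samples)
        ns = [len(s) for s in samples]
        N = sum(ns)
        grand = np.concatenate(samples).mean()
        ss_between = sum(n * (s.mean() - grand) ** 2 for n, s in zip(ns, samples))
        ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
        df1, df2 = k - 1, N - k
        mse = ss_within / df2
        if mse == 0.0:
            F = 0.0 if ss_between == 0 else math.inf
            p = 1.0 if ss_between == 0 else 0.0
        else:
            F = (ss_between / df1) / mse
            p = float(sps.f.sf(F, df1, df2))
        rows.append(
            {
                "variable": var,
                "contrast": "ANOVA",
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "significant": p < alpha,
            }
        )
        for i in range(k):
            for j in range(i + 1, k):
                if mse == 0.0:
                    diff = samples[i].mean() - samples[j].mean()
                    f_ij = 0.0 if diff == 0 else math.inf
                else:
                    f_ij = (samples[i].mean() - samples[j].mean()) ** 2 / (
                        mse * (1.0 / ns[i] + 1.0 / ns[j])
                    )
                p_ij = float(sps.f.sf(f_ij / df1, df1, df2)) if math.isfinite(f_ij) else 0.0
                rows.append(
                    {
                        "variable": var,
                        "contrast": f"{labels[i]} vs {labels[j]}",
                        "F": f_ij,
                        "df1": df1,
                        "df2": df2,
                        "p": p_ij,
                        "significant": p_ij < alpha,
                    }
                )
    return pd.DataFrame(rows)


def reproduce_report(
    metrics: pd.DataFrame,
    control_label: str = "control",
    primed_label: str = "primed",
    alpha: float = 0.05,
    per_variable: Optional[Sequence[str]] = None,
    group_col: str = "condition",
) -> pd.DataFrame:
    """Run the seven-comparison family and return the report table.

    One row per behavioral variable with group means, Student's t / df / p,
    Welch's t / df / p, Cohen's d, and significance flags at the nominal
    and Bonferroni-adjusted alphas.
    """
    variables = list(per_variable) if per_variable is not None else METRIC_VARIABLES
    adj = bonferroni_alpha(alpha, len(variables))
    control = metrics[metrics[group_col] == control_label]
    primed = metrics[metrics[group_col] == primed_label]
    if control.empty or primed.empty:
        raise DegenerateDataError(
            f"groups {control_label!r}/{primed_label!r} not found in column {group_col!r}"
        )
    rows = []
    for var in variables:
        a = control[var].to_numpy(dtype=float)
        b = primed[var].to_numpy(dtype=float)
        student = ttest_independent(a, b, welch=False, variable=var, alpha=alpha)
        welch = ttest_independent(a, b, welch=True, variable=var, alpha=alpha)
        rows.append(
            {
                "variable": var,
                "mean_control": student.mean_control,
                "mean_primed": student.mean_primed,
                "n_control": student.n_control,
                "n_primed": student.n_primed,
                "t": student.t,
                "df": student.df,
                "p_two_tailed": student.p_two_tailed,
                "t_welch": welch.t,
                "df_welch": welch.df,
                "p_welch": welch.p_two_tailed,
                "cohens_d": student.cohens_d,
                "alpha": alpha,
                "alpha_bonferroni": adj,
                "significant_unadjusted": student.p_two_tailed < alpha,
                "significant_bonferroni": student.p_two_tailed < adj,
                "degenerate": student.degenerate,
            }
        )
    return pd.DataFrame(rows)
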