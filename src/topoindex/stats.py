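"""One-way ANOVA, Fisher's LSD post hoc comparisons, and two-sample t tests.

The sums-of-squares decomposition, pooled-error t statistics and the F/t tail
probabilities are computed directly (tails via the regularized incomplete beta
function) rather than delegated to a packaged ANOVA routine, so each step can
be checked against independent closed forms:

* upper tail of F(df1, df2):  I_{df2/(df2 + df1 F)}(df2/2, df1/2)
* for df1 = 2 this reduces to (1 + 2F/df2)^(-df2/2)
* two-sided t tail with df:   I_{df/(df + t^2)}(df/2, 1/2)

Fisher's LSD is the unadjusted pairwise t comparison that reuses the pooled
error mean square and error degrees of freedom of the omnibus ANOVA; with
exactly two groups it coincides with the pooled two-sample t test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .errors import StatsError

_TINY = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class GroupStats:
    """Omnibus one-way ANOVA summary."""

    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]
    means: tuple[float, ...]
    F: float
    df1: int
    df2: int
    p: float
    mse: float


@dataclass(frozen=True)
class PairwiseComparison:
    """One unadjusted LSD contrast (two-sided)."""

    pair: tuple[str, str]
    t: float
    df: int
    p: float
    adjusted: str = "none"


def f_sf(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F(df1, df2) distribution at ``F``."""
    if df1 < 1 or df2 < 1:
        raise StatsError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    if F < 0:
        raise StatsError(f"F statistic must be >= 0, got {F}")
    x = df2 / (df2 + df1 * float(F))
    # clamp away from 0 so extreme statistics underflow to the smallest
    # positive float instead of an impossible p = 0
    return max(float(special.betainc(df2 / 2.0, df1 / 2.0, x)), _TINY)


def t_sf_two_sided(t: float, df: float) -> float:
    """Two-sided tail probability of Student's t with ``df`` at ``t``."""
    if df < 1:
        raise StatsError(f"degrees of freedom must be >= 1, got {df}")
    t = float(t)
    x = df / (df + t * t)
    return max(float(special.betainc(df / 2.0, 0.5, x)), _TINY)


def one_way_anova(
    table: pd.DataFrame, group_col: str = "group", value_col: str = "value"
) -> GroupStats:
    """Fixed-effects one-way ANOVA on a tidy (group, value) table."""
    groups = [str(g) for g in pd.unique(table[group_col])]
    if len(groups) < 2:
        raise StatsError("one-way ANOVA needs at least 2 groups")
    values = [np.asarray(table.loc[table[group_col] == g, value_col], dtype=float) for g in groups]
    ns = [len(v) for v in values]
    if any(n < 2 for n in ns):
        raise StatsError("each group needs n >= 2")
    means = [float(v.mean()) for v in values]
    grand = float(np.concatenate(values).mean())
    ss_between = sum(n * (m - grand) ** 2 for n, m in zip(ns, means))
    ss_within = sum(float(((v - m) ** 2).sum()) for v, m in zip(values, means))
    df1 = len(groups) - 1
    df2 = sum(ns) - len(groups)
    if ss_within == 0:
        raise StatsError("zero within-group variance; F is undefined")
    mse = ss_within / df2
    F = (ss_between / df1) / mse
    return GroupStats(
        groups=tuple(groups),
        n_per_group=tuple(ns),
        means=tuple(means),
        F=float(F),
        df1=df1,
        df2=df2,
        p=f_sf(F, df1, df2),
        mse=float(mse),
    )


def fisher_lsd(stats: GroupStats, pair: tuple[str, str]) -> PairwiseComparison:
    """Unadjusted pairwise comparison using the omnibus MSE and error df."""
    a, b = pair
    for g in (a, b):
        if g not in stats.groups:
            raise StatsError(f"group {g!r} not in {stats.groups}")
    ia, ib = stats.groups.index(a), stats.groups.index(b)
    na, nb = stats.n_per_group[ia], stats.n_per_group[ib]
    se = np.sqrt(stats.mse * (1.0 / na + 1.0 / nb))
    if se == 0:
        raise StatsError("zero pooled standard error; LSD t undefined")
    t = (stats.means[ia] - stats.means[ib]) / se
    return PairwiseComparison(pair=(a, b), t=float(t), df=stats.df2, p=t_sf_two_sided(t, stats.df2))


def all_pairwise_lsd(stats: GroupStats) -> list[PairwiseComparison]:
    return [fisher_lsd(stats, pair) for pair in itertools.combinations(stats.groups, 2)]


def two_sample_t(
    a: np.ndarray, b: np.ndarray, variant: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sided two-sample t test; returns (t, df, p).

    ``pooled`` is the classic equal-variance Student test; ``welch`` uses the
    Welch-Satterthwaite df.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise StatsError("each sample needs n >= 2")
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))
    diff = float(a.mean() - b.mean())
    if variant == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df: float = na + nb - 2
    elif variant == "welch":
        sa, sb = va / na, vb / nb
        se = np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1)) if (sa + sb) > 0 else 0.0
    else:
        raise StatsError(f"unknown t-test variant {variant!r}")
    if se == 0:
        raise StatsError("zero variance in both samples; t is undefined")
    t = diff / se
    return float(t), float(df), t_sf_two_sided(t, df)


def format_p(p: float) -> str:
    """Format to 4 decimals; very small values print as '< 0.0001'."""
    return "< 0.0001" if p < 1e-4 else f"{p:.4f}"


def format_anova(stats: GroupStats) -> str:
    return f"F({stats.df1},{stats.df2}) = {stats.F:.4g}; p = {format_p(stats.p)}"


def format_comparison(cmp: PairwiseComparison) -> str:
    return f"{cmp.pair[0]} vs {cmp.pair[1]}, p = {format_p(cmp.p)}"


def stats_report(
    table: pd.DataFrame, group_col: str = "group", value_col: str = "value"
) -> dict:
    """Omnibus ANOVA plus all pairwise LSD rows, machine-readable."""
    omnibus = one_way_anova(table, group_col, value_col)
    pairwise = all_pairwise_lsd(omnibus)
    return {
        "groups": list(omnibus.groups),
        "n_per_group": list(omnibus.n_per_group),
        "means": [float(m) for m in omnibus.means],
        "F": omnibus.F,
        "df1": omnibus.df1,
        "df2": omnibus.df2,
        "p": omnibus.p,
        "mse": omnibus.mse,
        "pairwise": [
            {"pair": list(c.pair), "t": c.t, "df": c.df, "p": c.p, "adjusted": c.adjusted}
            for c in pairwise
        ],
        "formatted": [format_anova(omnibus)] + [format_comparison(c) for c in pairwise],
    }
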