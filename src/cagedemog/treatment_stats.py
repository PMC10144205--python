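"""Treatment-comparison statistics for cage-trial summaries.

Implements the measurement statistic (parasitism percentage) and the
standard parametric comparisons used on trial summaries: one-way ANOVA,
Welch's heteroscedastic ANOVA and t test, the k-sample log-rank test for
adult survival, and a mixed (between-treatment x within-day) repeated
measures ANOVA for daily net reproduction.  Classical F / chi-square / t
machinery is delegated to scipy, lifelines and pingouin; every result is
returned in a uniform :class:`TestResult` container.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "parasitism_percentage",
    "one_way_anova",
    "welch_anova",
    "welch_t",
    "logrank_test",
    "repeated_measures_anova",
]


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its degrees of freedom and p-value."""

    statistic: float
    df: "float | tuple"
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def parasitism_percentage(n_parasitoids: int, n_flies: int) -> float:
    """Parasitism percentage: adult parasitoids x 100 over all adults
    emerged (flies plus parasitoids)."""
    if n_parasitoids < 0 or n_flies < 0:
        raise ValueError("counts must be nonnegative")
    total = n_parasitoids + n_flies
    if total == 0:
        raise ValueError("no adult emergence: parasitism percentage undefined")
    return 100.0 * n_parasitoids / total


def _check_groups(groups: Sequence[Sequence[float]], min_size: int = 2) -> list:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrs):
        if len(g) < min_size:
            raise ValueError(f"group {i} has fewer than {min_size} values")
    return arrs


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classical one-way fixed-effects ANOVA.

    ``F = MS_between / MS_within`` with df ``(k-1, N-k)``.  All-identical
    data yield F = 0 (p = 1), not an error.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    N = sum(len(g) for g in arrs)
    if np.ptp(np.concatenate(arrs)) == 0:
        return TestResult(0.0, (k - 1, N - k), 1.0, "one-way ANOVA")
    F, p = stats.f_oneway(*arrs)
    if np.isnan(F):  # zero within-group variance everywhere, identical means
        F, p = 0.0, 1.0
    return TestResult(float(F), (k - 1, N - k), float(p), "one-way ANOVA")


def welch_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA.

    Weights each group by ``n_i / s_i^2``; the denominator degrees of
    freedom follow Welch-Satterthwaite.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    n = np.array([len(g) for g in arrs], dtype=float)
    m = np.array([g.mean() for g in arrs])
    v = np.array([g.var(ddof=1) for g in arrs])
    if np.all(v == 0):
        if np.ptp(m) == 0:
            return TestResult(0.0, (k - 1.0, np.inf), 1.0, "Welch ANOVA")
        raise ValueError("zero within-group variance with unequal means")
    if np.any(v == 0):
        raise ValueError("a group has zero variance; Welch weights undefined")
    w = n / v
    mw = (w * m).sum() / w.sum()
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    lam = ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    F = num / (1 + 2 * (k - 2) * lam / (k * k - 1))
    df2 = (k * k - 1) / (3.0 * lam)
    p = float(stats.f.sf(F, k - 1, df2))
    return TestResult(float(F), (k - 1.0, float(df2)), p, "Welch ANOVA")


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Welch's two-sample t test (unequal variances), Welch-Satterthwaite df."""
    a, b = _check_groups([sample_a, sample_b])
    res = stats.ttest_ind(a, b, equal_var=False)
    t = 0.0 if np.isnan(res.statistic) else float(res.statistic)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    df = float(res.df) if np.isfinite(res.df) else float(len(a) + len(b) - 2)
    return TestResult(t, df, p, "Welch t test")


def logrank_test(
    durations: Sequence[Sequence[float]],
    events: "Sequence[Sequence[int]] | None" = None,
) -> TestResult:
    """k-sample log-rank test on per-group survival times.

    ``durations[i]`` holds the observed times of group ``i``;
    ``events[i]`` flags death (1) vs right-censoring (0), defaulting to all
    deaths.  Statistic is the usual chi-square with ``k - 1`` df.
    """
    from lifelines.statistics import multivariate_logrank_test

    k = len(durations)
    if k < 2:
        raise ValueError("need at least two groups")
    if events is None:
        events = [np.ones(len(d), dtype=int) for d in durations]
    total_events = sum(int(np.sum(e)) for e in events)
    if total_events == 0:
        raise ValueError("log-rank test undefined: no events in any group")
    dur = np.concatenate([np.asarray(d, dtype=float) for d in durations])
    ev = np.concatenate([np.asarray(e, dtype=int) for e in events])
    grp = np.concatenate(
        [np.full(len(d), i) for i, d in enumerate(durations)]
    )
    res = multivariate_logrank_test(dur, grp, ev)
    return TestResult(
        float(res.test_statistic), float(k - 1), float(res.p_value), "log-rank"
    )


def repeated_measures_anova(data: pd.DataFrame) -> dict[str, TestResult]:
    """Mixed ANOVA for daily net reproduction: treatment (between
    replicates) x day (repeated within replicate).

    ``data`` is tidy with columns ``replicate, treatment, day, value`` and a
    balanced layout (every replicate observed on every day).  Returns the
    three F tests keyed ``"treatment"``, ``"day"``, ``"interaction"``.
    """
    import pingouin as pg

    required = {"replicate", "treatment", "day", "value"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    counts = data.groupby(["replicate", "day"]).size()
    if counts.nunique() != 1 or counts.iloc[0] != 1:
        raise ValueError("unbalanced layout: need one value per replicate x day")
    per_day = data.groupby("replicate").size()
    if per_day.nunique() != 1:
        raise ValueError("unbalanced layout: replicates observed on different days")

    if data["value"].var(ddof=0) == 0:
        zero = lambda df: TestResult(0.0, df, 1.0, "mixed ANOVA")  # noqa: E731
        k = data["treatment"].nunique()
        d = data["day"].nunique()
        return {
            "treatment": zero(float(k - 1)),
            "day": zero(float(d - 1)),
            "interaction": zero(float((k - 1) * (d - 1))),
        }
    aov = pg.mixed_anova(
        data=data, dv="value", within="day", between="treatment",
        subject="replicate", correction=False,
    )
    out: dict[str, TestResult] = {}
    key_map = {"treatment": "treatment", "day": "day", "interaction": "Interaction"}
    for key, source in key_map.items():
        row = aov[aov["Source"] == source].iloc[0]
        F = float(row["F"])
        p = float(row["p_unc"])
        if np.isnan(F):
            F, p = 0.0, 1.0
        out[key] = TestResult(
            F, (float(row["DF1"]), float(row["DF2"])), p, "mixed ANOVA"
        )
    return out
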