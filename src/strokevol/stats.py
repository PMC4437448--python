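"""Two-group comparison of per-animal endpoints.

Implements the small-cohort toolkit the study design calls for: mean +/- SD
summaries, the classical pooled-variance Student t-test (with the Welch
variant always available, since with n = 8 per group the equal-variance
assumption is untestable in practice), a t-test computable from published
summary statistics alone, and the Mann-Whitney U test with an exact
two-sided p by full enumeration of rank assignments for small tie-free
samples. No multiple-testing correction is applied — a deliberate fidelity
choice for reproducing per-endpoint reports, documented as a limitation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize",
    "t_test_from_summary",
    "t_test",
    "mann_whitney_u",
    "compare_cohort",
    "comparisons_to_table",
    "format_report",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
#: Largest n1+n2 for which the exact Mann-Whitney null distribution is
#: enumerated (C(12,6) = 924 subsets; beyond this the normal approximation
#: with tie and continuity corrections takes over).
EXACT_MW_LIMIT = 12


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and SD (n-1 denominator) of one group's endpoint."""

    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("standard deviation cannot be negative")


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group test on one endpoint."""

    endpoint: str
    test: str
    statistic: float
    df: float | None
    p_two_sided: float
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_two_sided < self.alpha


def summarize(values: Sequence[float], group: str = "") -> GroupSummary:
    """Mean +/- sample SD summary of one group (n >= 2)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("summaries require at least two observations")
    return GroupSummary(group=group, n=int(arr.size),
                        mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


def t_test_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
    alpha: float = DEFAULT_ALPHA,
    endpoint: str = "",
) -> ComparisonResult:
    """Two-sample t-test from group summaries alone.

    ``pooled`` is the classical Student test: t = (m1-m2)/(sp*sqrt(1/n1+1/n2))
    with sp^2 the weighted average of the two variances and df = n1+n2-2.
    ``welch`` uses per-group variances and Satterthwaite degrees of freedom.
    Both SDs zero is degenerate: equal means give p = 1, different means give
    p = 0 with a warning.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("t-test requires n >= 2 in each group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations cannot be negative")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    diff = mean1 - mean2
    if sd1 == 0.0 and sd2 == 0.0:
        if diff == 0.0:
            return ComparisonResult(endpoint, f"t_{variant}", 0.0,
                                    float(n1 + n2 - 2), 1.0, alpha)
        logger.warning("both groups have zero variance but different means; p set to 0")
        return ComparisonResult(endpoint, f"t_{variant}", math.inf,
                                float(n1 + n2 - 2), 0.0, alpha)
    v1, v2 = sd1 ** 2, sd2 ** 2
    if variant == "pooled":
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se2_1, se2_2 = v1 / n1, v2 / n2
        se = math.sqrt(se2_1 + se2_2)
        df = (se2_1 + se2_2) ** 2 / (
            se2_1 ** 2 / (n1 - 1) + se2_2 ** 2 / (n2 - 1)
        )
    t = diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return ComparisonResult(endpoint, f"t_{variant}", float(t), df, min(p, 1.0), alpha)


def t_test(
    values1: Sequence[float], values2: Sequence[float],
    variant: str = "pooled", alpha: float = DEFAULT_ALPHA, endpoint: str = "",
) -> ComparisonResult:
    """Two-sample t-test on raw values; equals the summary-based test exactly."""
    s1, s2 = summarize(values1), summarize(values2)
    return t_test_from_summary(
        s1.mean, s1.sd, s1.n, s2.mean, s2.sd, s2.n,
        variant=variant, alpha=alpha, endpoint=endpoint,
    )


def _u_statistic(values1: np.ndarray, values2: np.ndarray) -> float:
    """U for the first sample, from midranks (handles ties)."""
    n1 = values1.size
    ranks = sps.rankdata(np.concatenate([values1, values2]))
    r1 = float(ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def _exact_mw_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating every assignment of ranks to group 1.

    p = 2 * min(P(U <= u), P(U >= u)), capped at 1 — the standard two-sided
    convention for a discrete symmetric-null statistic.
    """
    n = pooled.size
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    us = np.array([
        sum(ranks[i] for i in combo) - offset
        for combo in itertools.combinations(range(n), n1)
    ])
    total = us.size
    p_le = float(np.count_nonzero(us <= u_obs + 1e-9)) / total
    p_ge = float(np.count_nonzero(us >= u_obs - 1e-9)) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def _approx_mw_p(pooled: np.ndarray, n1: int, n2: int, u_obs: float) -> float:
    """Normal approximation with midrank tie correction and continuity correction."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts ** 3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    return min(1.0, 2.0 * float(sps.norm.sf(max(z, 0.0))))


def mann_whitney_u(
    values1: Sequence[float], values2: Sequence[float],
    method: str = "auto", alpha: float = DEFAULT_ALPHA, endpoint: str = "",
) -> ComparisonResult:
    """Mann-Whitney U test (two-sided), exact for small tie-free samples.

    ``method="auto"`` enumerates the exact null distribution when
    n1 + n2 <= 12 and the pooled data are tie-free, and otherwise uses the
    normal approximation with tie and continuity corrections; ``"exact"`` and
    ``"asymptotic"`` force the respective path. The reported statistic is U
    for the first sample.
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if v1.size == 0 or v2.size == 0:
        raise ValueError("Mann-Whitney test requires non-empty samples")
    pooled = np.concatenate([v1, v2])
    u_obs = _u_statistic(v1, v2)
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        use_exact = (pooled.size <= EXACT_MW_LIMIT) and not has_ties
    elif method == "exact":
        use_exact = True
    elif method == "asymptotic":
        use_exact = False
    else:
        raise ValueError(f"unknown method {method!r}")
    if use_exact:
        p = _exact_mw_p(pooled, v1.size, u_obs)
    else:
        p = _approx_mw_p(pooled, v1.size, v2.size, u_obs)
    return ComparisonResult(endpoint, "mann_whitney", float(u_obs), None, p, alpha)


def compare_cohort(
    table: pd.DataFrame,
    endpoints: Sequence[str],
    test_plan: Mapping[str, Sequence[str]] | None = None,
    group_col: str = "group",
    groups: tuple[str, str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[ComparisonResult]:
    """Run the configured tests on each endpoint column of a per-animal table.

    Parameters
    ----------
    table
        One row per animal, with a group column and endpoint columns.
    endpoints
        Column names to compare.
    test_plan
        Endpoint -> list of tests among {"t_pooled", "t_welch",
        "mann_whitney"}; endpoints not listed get ("t_pooled", "t_welch").
    groups
        The (first, second) group names; defaults to order of appearance.
        Signs of statistics follow first - second.
    """
    if group_col not in table.columns:
        raise KeyError(f"missing group column {group_col!r}")
    if groups is None:
        seen = list(dict.fromkeys(table[group_col]))
        if len(seen) != 2:
            raise ValueError(f"expected exactly two groups, found {seen}")
        groups = (seen[0], seen[1])
    missing = [e for e in endpoints if e not in table.columns]
    if missing:
        raise KeyError(f"missing endpoint columns {missing}")
    g1 = table.loc[table[group_col] == groups[0]]
    g2 = table.loc[table[group_col] == groups[1]]
    if g1.empty or g2.empty:
        raise ValueError("both groups must be present in the table")

    results: list[ComparisonResult] = []
    for endpoint in endpoints:
        v1 = g1[endpoint].to_numpy(dtype=float)
        v2 = g2[endpoint].to_numpy(dtype=float)
        tests = ("t_pooled", "t_welch")
        if test_plan and endpoint in test_plan:
            tests = tuple(test_plan[endpoint])
        for test in tests:
            if test == "t_pooled":
                results.append(t_test(v1, v2, "pooled", alpha, endpoint))
            elif test == "t_welch":
                results.append(t_test(v1, v2, "welch", alpha, endpoint))
            elif test == "mann_whitney":
                results.append(mann_whitney_u(v1, v2, alpha=alpha, endpoint=endpoint))
            else:
                raise ValueError(f"unknown test {test!r} for endpoint {endpoint!r}")
    return results


def comparisons_to_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "endpoint": r.endpoint,
                "test": r.test,
                "statistic": r.statistic,
                "df": r.df if r.df is not None else float("nan"),
                "p_two_sided": r.p_two_sided,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def format_report(results: Sequence[ComparisonResult]) -> str:
    """Human-readable per-endpoint report."""
    lines = []
    for r in results:
        df_txt = f", df={r.df:.2f}" if r.df is not None else ""
        verdict = "significant" if r.significant else "not significant"
        lines.append(
            f"{r.endpoint}: {r.test} statistic={r.statistic:.3f}{df_txt}, "
            f"p={r.p_two_sided:.4f} ({verdict} at alpha={r.alpha})"
        )
    return "\n".join(lines)
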