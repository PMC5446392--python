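"""Shared statistical kernels.

Welch's two-sample t-test (raw values or published summaries), Fisher's
exact test, chi-square with Yates continuity correction, Kruskal-Wallis,
clone-level methylation summaries, and the pooled tissue regression.
Established scipy/statsmodels routines back the standard tests; the
summary-statistics entry points exist so that printed tables (group mean,
SEM, n) can be re-analysed without the underlying raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "welch_t",
    "welch_t_from_summary",
    "fisher_exact_2x2",
    "chi2_yates_2x2",
    "kruskal_wallis",
    "clone_methylation",
    "tissue_regression",
]


@dataclass
class GroupComparison:
    """Welch comparison of two groups at one site.

    ``diff`` is always ``mean_a - mean_b`` (convention: a = case, b = control,
    so a negative difference means lower methylation in cases).
    """

    site_id: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    diff: float
    t: float
    df: float
    p: float
    degenerate: bool = False


def _welch_from_sems(site_id, mean_a, mean_b, sem_a, sem_b, n_a, n_b) -> GroupComparison:
    diff = mean_a - mean_b
    va, vb = sem_a**2, sem_b**2  # squared standard errors of the means
    if va + vb == 0:
        # no sampling variance: identical groups give p = 1, anything else
        # is flagged degenerate (infinite t)
        if diff == 0:
            return GroupComparison(site_id, mean_a, mean_b, sem_a, sem_b, n_a, n_b, 0.0, 0.0, float(n_a + n_b - 2), 1.0)
        return GroupComparison(
            site_id, mean_a, mean_b, sem_a, sem_b, n_a, n_b, diff, np.inf, float(n_a + n_b - 2), 0.0, degenerate=True
        )
    t = diff / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparison(site_id, mean_a, mean_b, sem_a, sem_b, n_a, n_b, diff, float(t), float(df), float(p))


def welch_t_from_summary(
    mean_a: float,
    sem_a: float,
    n_a: int,
    mean_b: float,
    sem_b: float,
    n_b: int,
    site_id: str = "",
) -> GroupComparison:
    """Welch's unpaired two-tailed t-test from published summaries.

    Inputs are the group means, standard errors of the mean and sample
    sizes, exactly as result tables print them ("mean ± SEM", n per group).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    return _welch_from_sems(site_id, float(mean_a), float(mean_b), float(sem_a), float(sem_b), int(n_a), int(n_b))


def welch_t(values_a, values_b, site_id: str = "") -> GroupComparison:
    """Welch's unpaired two-tailed t-test from raw per-sample values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    sem_a = a.std(ddof=1) / np.sqrt(a.size)
    sem_b = b.std(ddof=1) / np.sqrt(b.size)
    out = _welch_from_sems(site_id, a.mean(), b.mean(), sem_a, sem_b, a.size, b.size)
    if not out.degenerate and out.t != 0.0:
        # cross-check against the library route; they agree to rounding
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=False)
        assert abs(out.t - t_ref) < 1e-8 and abs(out.p - p_ref) < 1e-10
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for table [[a, b], [c, d]].

    Sums hypergeometric probabilities no larger than the observed table's,
    with all margins fixed. An all-zero table or a zero margin gives p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    if a + b + c + d == 0:
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def chi2_yates_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Chi-square test with Yates continuity correction on a 2x2 table.

    chi2 = N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)), clamped to 0 when
    |ad - bc| <= N/2; p from the upper tail of chi-square with 1 df.
    A zero margin yields statistic 0, p 1.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        return 0.0, 1.0
    num = abs(a * d - b * c) - n / 2.0
    if num <= 0:
        return 0.0, 1.0
    stat = n * num**2 / float(np.prod([float(m) for m in margins]))
    p = float(sps.chi2.sf(stat, df=1))
    return float(stat), p


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H across two or more groups.

    Returns ``(H, p)`` with p from the chi-square approximation (k - 1 df).
    All-identical values give H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("each group must be non-empty")
    if sum(a.size for a in arrs) < 3:
        raise ValueError("need total n >= 3")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrs)
    return float(h), float(p)


def kruskal_wallis_permutation_p(groups, n_perm: int = 20000, seed: int = 0) -> float:
    """Permutation reference p for the Kruskal-Wallis H (small samples)."""
    rng = np.random.default_rng(seed)
    arrs = [np.asarray(g, dtype=float) for g in groups]
    sizes = [a.size for a in arrs]
    pooled = np.concatenate(arrs)
    h_obs = kruskal_wallis(*arrs)[0]
    count = 0
    bounds = np.cumsum(sizes)[:-1]
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, bounds)
        if kruskal_wallis(*parts)[0] >= h_obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def clone_methylation(calls) -> float:
    """Overall methylation fraction of one sample's clone matrix.

    ``calls`` is a clones x CpGs matrix of 1 (methylated), 0 (unmethylated)
    or NaN (missing); the fraction pools every non-missing call.
    """
    m = np.asarray(calls, dtype=float)
    if m.size == 0:
        raise ValueError("empty clone matrix")
    valid = ~np.isnan(m)
    if not valid.any():
        raise ValueError("all clone calls missing")
    vals = m[valid]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("clone calls must be binary or missing")
    return float(vals.sum() / vals.size)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


def tissue_regression(blood, lip) -> RegressionResult:
    """OLS of lip-tissue methylation on blood methylation, pooled pairs.

    Accepts flat vectors or site x individual tables (flattened); returns
    slope, intercept, R^2 (= squared Pearson r) and the two-sided slope p.
    """
    x = np.asarray(blood, dtype=float).ravel()
    y = np.asarray(lip, dtype=float).ravel()
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in blood values: slope undefined")
    res = sps.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue), x.size)


def compare_clone_groups(fractions_by_group: dict[str, list[float]]) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis comparison of per-sample clone methylation fractions.

    Returns (H, p, summary) where summary holds per-group n, median and mean.
    """
    order = list(fractions_by_group)
    h, p = kruskal_wallis(*(fractions_by_group[g] for g in order))
    summary = pd.DataFrame(
        {
            "group": order,
            "n": [len(fractions_by_group[g]) for g in order],
            "median": [float(np.median(fractions_by_group[g])) for g in order],
            "mean": [float(np.mean(fractions_by_group[g])) for g in order],
        }
    )
    return h, p, summary
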