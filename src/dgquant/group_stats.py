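"""Group-level statistics: pooled t-tests (raw or from printed summaries),
D'Agostino-Pearson normality, two-factor Sholl ANOVA with Holm-Sidak
per-radius post hocs, and the pooled two-proportion z-test.

The pooled (Student) unpaired t-test is the default comparison — group
means +/- SEM with small n are the unit of analysis throughout — with a
Welch option. Because the pooled t depends on the data only through
(mean, SEM, n), tests can be recomputed exactly from printed summary
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import SummaryStats
from .morphometry import ShollProfile

__all__ = [
    "TestResult", "pooled_t_from_summary", "pooled_t_from_raw",
    "dagostino_pearson", "holm_sidak", "sholl_anova", "two_proportion_z",
]


@dataclass
class TestResult:
    statistic: float
    df: float
    p_two_tailed: float
    test: str
    inputs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.p_two_tailed) or 0.0 <= self.p_two_tailed <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def pooled_t_from_summary(
    a: SummaryStats, b: SummaryStats, welch: bool = False
) -> TestResult:
    """Unpaired two-sample t-test from (mean, SEM, n) summaries.

    SD is recovered as sem * sqrt(n); pooled-variance Student t with
    df = n_a + n_b - 2 by default, Welch with the flag.
    """
    res = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=not welch
    )
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        df = a.n + b.n - 2
    return TestResult(
        float(res.statistic),
        float(df),
        float(res.pvalue),
        "welch t" if welch else "pooled t",
        inputs={"a": a, "b": b},
    )


def pooled_t_from_raw(x, y, welch: bool = False) -> TestResult:
    """Classical unpaired t-test on raw samples.

    Agrees with :func:`pooled_t_from_summary` applied to the samples' own
    summaries to machine precision. Zero-variance degeneracies: equal
    means give t = 0, p = 1; unequal means with both samples constant give
    p = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    df = x.size + y.size - 2
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(0.0, df, 1.0, "pooled t")
        warnings.warn("both samples degenerate with unequal means; p -> 0")
        return TestResult(np.inf if np.mean(x) > np.mean(y) else -np.inf,
                          df, 0.0, "pooled t")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = df if not welch else float(res.df)
    return TestResult(
        float(res.statistic), float(df), float(res.pvalue),
        "welch t" if welch else "pooled t",
    )


def dagostino_pearson(x) -> TestResult:
    """D'Agostino-Pearson K^2 omnibus normality test.

    Combines the skewness and kurtosis z-transforms into
    K^2 = z_skew^2 + z_kurt^2, referred to chi^2 with 2 df. Small samples
    (n < 20) warn but still return a result.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("K^2 needs n >= 5")
    if np.var(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    if n < 20:
        warnings.warn(f"n = {n} < 20: K^2 normality test is unreliable")
    if n < 8:
        # the finite-sample z-transforms are undefined this small; fall back
        # to the large-sample normal approximations so a result still exists
        z_s = float(sps.skew(x) / np.sqrt(6.0 / n))
        z_k = float((sps.kurtosis(x, fisher=False) - 3.0) / np.sqrt(24.0 / n))
    else:
        z_s = _skew_z(x)
        z_k = _kurt_z(x)
    k2 = z_s**2 + z_k**2
    p = float(sps.chi2.sf(k2, df=2))
    return TestResult(float(k2), 2.0, p, "dagostino-pearson K2",
                      inputs={"n": n})


def _skew_z(x) -> float:
    # D'Agostino (1970) transformation of sample skewness
    n = x.size
    b1 = sps.skew(x)
    y = b1 * np.sqrt((n + 1.0) * (n + 3.0) / (6.0 * (n - 2.0)))
    beta2 = (
        3.0 * (n**2 + 27.0 * n - 70.0) * (n + 1.0) * (n + 3.0)
        / ((n - 2.0) * (n + 5.0) * (n + 7.0) * (n + 9.0))
    )
    w2 = -1.0 + np.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / np.sqrt(0.5 * np.log(w2))
    alpha = np.sqrt(2.0 / (w2 - 1.0))
    y = np.where(y == 0, 1e-30, y)
    return float(delta * np.log(y / alpha + np.sqrt((y / alpha) ** 2 + 1.0)))


def _kurt_z(x) -> float:
    # Anscombe & Glynn (1983) transformation of sample kurtosis
    n = x.size
    b2 = sps.kurtosis(x, fisher=False)
    e_b2 = 3.0 * (n - 1.0) / (n + 1.0)
    var_b2 = (
        24.0 * n * (n - 2.0) * (n - 3.0) / ((n + 1.0) ** 2 * (n + 3.0) * (n + 5.0))
    )
    xx = (b2 - e_b2) / np.sqrt(var_b2)
    sqrt_beta1 = (
        6.0 * (n**2 - 5.0 * n + 2.0) / ((n + 7.0) * (n + 9.0))
        * np.sqrt(6.0 * (n + 3.0) * (n + 5.0) / (n * (n - 2.0) * (n - 3.0)))
    )
    a = 6.0 + 8.0 / sqrt_beta1 * (
        2.0 / sqrt_beta1 + np.sqrt(1.0 + 4.0 / sqrt_beta1**2)
    )
    term = (1.0 - 2.0 / a) / (1.0 + xx * np.sqrt(2.0 / (a - 4.0)))
    return float(
        ((1.0 - 2.0 / (9.0 * a)) - np.cbrt(term)) / np.sqrt(2.0 / (9.0 * a))
    )


def holm_sidak(p_values, alpha: float = 0.05):
    """Holm-Sidak step-down adjustment.

    Returns (adjusted p-values, reject flags) in the input order. Sorted
    ascending, the k-th raw p (of m) is adjusted to 1 - (1-p)^(m-k+1) with
    a running maximum to keep adjusted values monotone; rejection stops at
    the first non-significant rank.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, val)
        adj_sorted[rank] = min(1.0, running)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if adj_sorted[rank] < alpha:
            reject[idx] = True
        else:
            break
    return adjusted, reject


def sholl_anova(
    profiles: list[ShollProfile],
    groups: list[str],
    alpha: float = 0.05,
):
    """Two-factor (treatment x radius) ANOVA over per-cell Sholl profiles,
    with per-radius pooled t-tests adjusted by Holm-Sidak.

    Every (cell, radius) intersection count is treated as an independent
    observation, matching per-radius mean +/- SEM reporting. Profiles must
    share a common radius grid over the compared range; shorter profiles
    are zero-padded (a cell with no dendrite at r contributes 0
    intersections there).

    Returns (anova_table: DataFrame, per_radius: DataFrame).
    """
    if len(profiles) != len(groups):
        raise ValueError("one group label per profile required")
    if len(set(groups)) < 2:
        raise ValueError("need at least two groups")
    step = float(profiles[0].radii_um[0])
    rmax = max(float(p.radii_um[-1]) for p in profiles)
    radii = np.arange(step, rmax + step / 2, step)
    mat = np.zeros((len(profiles), radii.size))
    for i, prof in enumerate(profiles):
        if abs(float(prof.radii_um[0]) - step) > 1e-9:
            raise ValueError("profiles must share a common radius grid")
        mat[i, : prof.intersections.size] = prof.intersections

    long = pd.DataFrame(
        {
            "intersections": mat.ravel(),
            "radius": np.tile(radii, len(profiles)),
            "group": np.repeat(groups, radii.size),
        }
    )
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols("intersections ~ C(group) * C(radius)", data=long).fit()
    table = sm.stats.anova_lm(model, typ=2)

    g1, g2 = sorted(set(groups))
    raw_p = []
    rows = []
    for j, r in enumerate(radii):
        x = mat[np.asarray(groups) == g1, j]
        y = mat[np.asarray(groups) == g2, j]
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and np.mean(x) == np.mean(y):
            res = TestResult(0.0, x.size + y.size - 2, 1.0, "pooled t")
        else:
            res = pooled_t_from_raw(x, y)
        raw_p.append(res.p_two_tailed)
        rows.append({"radius_um": r, "t": res.statistic, "p_raw": res.p_two_tailed})
    adjusted, reject = holm_sidak(raw_p, alpha=alpha)
    per_radius = pd.DataFrame(rows)
    per_radius["p_adjusted"] = adjusted
    per_radius["significant"] = reject
    return table, per_radius


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Pooled two-proportion z-test, two-tailed normal p."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= k <= n:
            raise ValueError("k must lie in [0, n]")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return TestResult(0.0, np.inf, 1.0, "two-proportion z")
    z = (p1 - p2) / se
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return TestResult(float(z), np.inf, p, "two-proportion z",
                      inputs={"k1": k1, "n1": n1, "k2": k2, "n2": n2})
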