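"""Group-level statistical comparisons.

Covers the comparisons run on histogram and regression outputs: a chi-square
test for homogeneity between two binned distributions (with small-expected
bin pooling), simple linear regression (e.g. HIF-1a% on pimo%), ANCOVA
comparison of regression slopes across datasets, and Holm-Bonferroni
adjustment of families of p-values. Standard fits are delegated to
scipy/statsmodels; the homogeneity test operates on raw counts — percent
scaling is display-only and would invalidate the sampling model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .histograms import HistogramND

__all__ = [
    "RegressionResult",
    "HomogeneityResult",
    "SlopeComparison",
    "chi2_homogeneity",
    "linear_regression",
    "compare_slopes",
    "holm_bonferroni",
]

ALPHA = 0.05  # conventional significance level used throughout


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_line: float  # two-sided p for slope != 0
    n: int


@dataclass(frozen=True)
class HomogeneityResult:
    chi2: float
    df: int
    p: float
    bins_pooled: tuple[tuple[int, ...], ...]  # groups of original bin indices

    @property
    def n_bins(self) -> int:
        return len(self.bins_pooled)


@dataclass(frozen=True)
class SlopeComparison:
    f_stat: float
    p_overall: float
    pairwise: dict[tuple[int, int], float]


def _counts(hist) -> np.ndarray:
    if isinstance(hist, HistogramND):
        return np.asarray(hist.counts, dtype=float).ravel()
    return np.asarray(hist, dtype=float).ravel()


def _pool_bins(a: np.ndarray, b: np.ndarray, min_expected: float = 5.0):
    """Merge adjacent bins until every expected cell count is >= min_expected.

    Expected counts come from the pooled margins of the 2 x k table. The bin
    with the smallest expected total is merged into its smaller-total
    neighbour first; the grouping of original bin indices is recorded.
    """
    groups = [[i] for i in range(a.size)]
    ga, gb = list(a.astype(float)), list(b.astype(float))
    na, nb = a.sum(), b.sum()
    n = na + nb
    if n == 0:
        raise ValueError("empty histograms")
    min_frac = min(na, nb) / n

    def min_expected_of(i: int) -> float:
        return (ga[i] + gb[i]) * min_frac

    while len(groups) > 2:
        worst = min(range(len(groups)), key=min_expected_of)
        if min_expected_of(worst) >= min_expected:
            break
        if worst == 0:
            j = 1
        elif worst == len(groups) - 1:
            j = worst - 1
        else:
            j = worst - 1 if (ga[worst - 1] + gb[worst - 1]) <= (ga[worst + 1] + gb[worst + 1]) else worst + 1
        lo, hi = sorted((worst, j))
        ga[lo] += ga[hi]
        gb[lo] += gb[hi]
        groups[lo] += groups[hi]
        del ga[hi], gb[hi], groups[hi]
    return np.array(ga), np.array(gb), tuple(tuple(g) for g in groups)


def chi2_homogeneity(hist_a, hist_b, min_expected: float = 5.0) -> HomogeneityResult:
    """Chi-square homogeneity test between two binned samples (raw counts).

    Builds the k x 2 contingency table, pools bins whose expected count falls
    below ``min_expected`` (recorded in the result), and tests the standard
    statistic sum (O - E)^2 / E with df = bins_after_pooling - 1. The test is
    symmetric in its two arguments.
    """
    a, b = _counts(hist_a), _counts(hist_b)
    if a.shape != b.shape:
        raise ValueError("histograms must share the same bins")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    if not (np.allclose(a, np.round(a)) and np.allclose(b, np.round(b))):
        raise ValueError("homogeneity test needs raw counts, not percents")
    pa, pb, groups = _pool_bins(a, b, min_expected)
    if len(groups) < 2:
        raise ValueError("fewer than 2 bins remain after pooling")
    table = np.vstack([pa, pb])
    # drop bins empty in both samples (expected count zero)
    nonzero = table.sum(axis=0) > 0
    table = table[:, nonzero]
    if table.shape[1] < 2:
        raise ValueError("fewer than 2 non-empty bins")
    chi2, p, df, _ = scipy.stats.chi2_contingency(table, correction=False)
    return HomogeneityResult(chi2=float(chi2), df=int(df), p=float(p), bins_pooled=groups)


def linear_regression(x, y) -> RegressionResult:
    """OLS fit of y on x with the two-sided t-test p-value for the slope."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    res = scipy.stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_line=float(res.pvalue),
        n=int(x.size),
    )


def compare_slopes(datasets: list[tuple[np.ndarray, np.ndarray]]) -> SlopeComparison:
    """ANCOVA comparison of regression slopes across datasets.

    Fits a pooled linear model with a group x covariate interaction; the
    overall F-test asks whether any slopes differ, and each dataset pair is
    additionally compared with its own interaction test.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    frames = []
    for i, (x, y) in enumerate(datasets):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size < 3 or np.ptp(x) == 0:
            raise ValueError(f"dataset {i} is too small or has constant x")
        frames.append(pd.DataFrame({"x": x, "y": y, "g": i}))
    data = pd.concat(frames, ignore_index=True)

    def interaction_p(df: pd.DataFrame):
        full = smf.ols("y ~ x * C(g)", data=df).fit()
        reduced = smf.ols("y ~ x + C(g)", data=df).fit()
        # noise-free data fit both models exactly; the 0/0 F-ratio means no
        # detectable slope difference
        scale = float((df.y**2).sum()) + 1.0
        if reduced.ssr <= 1e-12 * scale:
            return 0.0, 1.0
        f, p, _ = full.compare_f_test(reduced)
        if not (np.isfinite(f) and np.isfinite(p)):
            return 0.0, 1.0
        return float(f), float(p)

    f_stat, p_overall = interaction_p(data)
    pairwise: dict[tuple[int, int], float] = {}
    for i in range(len(datasets)):
        for j in range(i + 1, len(datasets)):
            sub = data[data.g.isin((i, j))]
            _, p = interaction_p(sub)
            pairwise[(i, j)] = p
    return SlopeComparison(f_stat=f_stat, p_overall=p_overall, pairwise=pairwise)


def holm_bonferroni(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, in the original order.

    Sort ascending; adjusted_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)).
    Monotone, >= the raw p-values, and <= the plain Bonferroni m*p.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
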