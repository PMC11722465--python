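"""Independent oracles used by the test suite.

These deliberately avoid the implementation's code paths: rectangle
probabilities by one-dimensional numerical integration instead of the
bivariate CDF, grid search instead of a bounded scalar optimizer, and
hand-rolled rank correlation / ANOVA arithmetic.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats


def spearman_by_hand(x, y) -> float:
    """Tie-corrected Spearman: rank-transform, then Pearson."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def polychoric_grid_ml(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray
) -> float:
    """Grid-search ML polychoric estimate with quad-integrated cell
    probabilities (conditional-normal integration, not the bivariate CDF)."""
    def cuts(v):
        levels, counts = np.unique(v, return_counts=True)
        cum = np.cumsum(counts)[:-1] / counts.sum()
        return levels, np.r_[-np.inf, stats.norm.ppf(cum), np.inf]

    lx, ax = cuts(x)
    ly, ay = cuts(y)
    table = np.zeros((len(lx), len(ly)))
    np.add.at(table, (np.searchsorted(lx, x), np.searchsorted(ly, y)), 1.0)

    def cell(r, i, j):
        s = np.sqrt(1 - r * r)
        f = lambda u: stats.norm.pdf(u) * (
            stats.norm.cdf((ay[j + 1] - r * u) / s) - stats.norm.cdf((ay[j] - r * u) / s)
        )
        lo, hi = max(ax[i], -8.0), min(ax[i + 1], 8.0)
        return integrate.quad(f, lo, hi, limit=100)[0]

    def loglik(r):
        return sum(
            table[i, j] * np.log(max(cell(r, i, j), 1e-300))
            for i in range(len(lx))
            for j in range(len(ly))
            if table[i, j] > 0
        )

    lls = [loglik(r) for r in grid]
    return float(grid[int(np.argmax(lls))])


def anova_by_hand(values, groups) -> dict:
    """Brute-force one-way ANOVA sums of squares, F and p."""
    y = np.asarray(values, float)
    g = np.asarray(groups)
    grand = y.mean()
    ss_b = ss_w = 0.0
    k = 0
    for label in np.unique(g):
        sub = y[g == label]
        ss_b += len(sub) * (sub.mean() - grand) ** 2
        ss_w += ((sub - sub.mean()) ** 2).sum()
        k += 1
    df_b, df_w = k - 1, len(y) - k
    f = (ss_b / df_b) / (ss_w / df_w)
    return {
        "ss_between": ss_b,
        "ss_within": ss_w,
        "df_between": df_b,
        "df_within": df_w,
        "f": f,
        "p": float(stats.f.sf(f, df_b, df_w)),
    }
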