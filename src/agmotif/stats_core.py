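"""Statistical primitives shared by the pipeline stages.

Thin, contract-checked wrappers: ordinary least squares with the slope
F-test (the rate-fit model), Benjamini–Hochberg FDR, Wilcoxon tests with an
exact small-sample path, and Welch's t-test.  Hypothesis-test machinery is
delegated to scipy/statsmodels; the OLS solution is closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: sample sizes up to this use the exact null distribution in wilcoxon()
EXACT_CUTOFF = 25


@dataclass
class LinearFit:
    """Least-squares line y = slope*x + intercept.

    ``p_slope`` is the F(1, n-2) test of slope == 0 (equivalently the squared
    t-test); it is defined only for n >= 3.  A perfect fit (rss == 0) reports
    p_slope == 0 by convention, since the F statistic diverges.
    """

    slope: float
    intercept: float
    rss: float
    n: int
    p_slope: float
    se_slope: float


def ols_fit(x, y) -> LinearFit:
    """Fit y = a*x + b by ordinary least squares.

    Requires equal lengths >= 2 and non-degenerate x.  The slope p-value
    (F-test against slope = 0) is NaN when n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: x has {x.size}, y has {y.size}")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 points")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("degenerate x: all values identical")
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    rss = float((resid ** 2).sum())
    if n >= 3:
        sigma2 = rss / (n - 2)
        se_slope = float(np.sqrt(sigma2 / sxx)) if sigma2 > 0 else 0.0
        p_slope = _slope_f_pvalue(slope, sxx, rss, n)
    else:
        se_slope = float("nan")
        p_slope = float("nan")
    return LinearFit(slope=slope, intercept=intercept, rss=rss, n=n,
                     p_slope=p_slope, se_slope=se_slope)


def _slope_f_pvalue(slope: float, sxx: float, rss: float, n: int) -> float:
    if rss <= 0.0:
        # perfect fit: F diverges for a nonzero slope (p = 0); a perfectly
        # flat perfect fit carries no evidence against slope = 0 (p = 1)
        return 0.0 if slope != 0.0 else 1.0
    f_stat = slope ** 2 * sxx / (rss / (n - 2))
    return float(stats.f.sf(f_stat, 1, n - 2))


def f_test_slope(fit: LinearFit) -> float:
    """p-value of the F(1, n-2) test of H0: slope == 0 for a LinearFit."""
    if fit.n < 3:
        raise ValueError("slope F-test requires n >= 3")
    sxx = _sxx_from_fit(fit)
    return _slope_f_pvalue(fit.slope, sxx, fit.rss, fit.n)


def _sxx_from_fit(fit: LinearFit) -> float:
    # se_slope^2 = (rss/(n-2))/sxx; recover sxx when residuals are nonzero
    if fit.rss > 0 and fit.se_slope > 0:
        return (fit.rss / (fit.n - 2)) / fit.se_slope ** 2
    return 1.0  # unused: rss == 0 path returns p = 0


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon(x, y, mode: str = "paired",
             exact_cutoff: int = EXACT_CUTOFF) -> float:
    """Two-sided Wilcoxon test p-value.

    ``mode='paired'``: signed-rank test on x - y, dropping zero differences
    (Wilcoxon's method); all-zero differences are an error.  ``mode=
    'unpaired'``: Mann–Whitney U rank-sum test.  The exact null distribution
    is used for effective sample sizes up to ``exact_cutoff``, the normal
    approximation (with continuity/tie correction) above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if mode == "paired":
        if x.shape != y.shape:
            raise ValueError("paired mode requires equal lengths")
        d = x - y
        d = d[d != 0]
        if d.size == 0:
            raise ValueError("all differences zero")
        method = "exact" if d.size <= exact_cutoff else "approx"
        try:
            res = stats.wilcoxon(d, zero_method="wilcox",
                                 alternative="two-sided", method=method)
        except ValueError:
            # ties prevent the exact distribution; fall back to approximation
            res = stats.wilcoxon(d, zero_method="wilcox",
                                 alternative="two-sided", method="approx")
        return float(res.pvalue)
    if mode == "unpaired":
        if x.size == 0 or y.size == 0:
            raise ValueError("empty group")
        method = ("exact" if max(x.size, y.size) <= exact_cutoff
                  and np.unique(np.concatenate([x, y])).size == x.size + y.size
                  else "asymptotic")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


def t_test_two_tailed(x, y) -> float:
    """Two-tailed unpaired t-test (Welch, unequal variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.pvalue)
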