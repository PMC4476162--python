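"""Shared statistics used throughout the pipeline.

Goodman–Kruskal gamma with a permutation p-value, partial Spearman rank
correlation, a loess smoother, Mann–Whitney U and the exact binomial test.
Standard tests are delegated to scipy/statsmodels; gamma and partial Spearman
are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "GammaResult",
    "goodman_kruskal_gamma",
    "goodman_kruskal_gamma_perm",
    "spearman",
    "partial_spearman",
    "loess_fit",
    "mann_whitney_u",
    "exact_binomial_p",
]


@dataclass
class GammaResult:
    """Goodman–Kruskal gamma and its one-sided permutation p-value."""

    gamma: float
    p_perm: float
    n_permutations: int
    n_greater_or_equal: int


def _concordance_counts(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(C - D, C + D) over pairs untied in both variables.

    C - D comes from Kendall's tau-b (O(n log n)); C + D from tie bookkeeping:
    total pairs minus pairs tied in x or y, adding back pairs tied in both.
    """
    n = len(x)
    n0 = n * (n - 1) / 2.0

    def tie_pairs(v):
        _, counts = np.unique(v, return_counts=True)
        return float((counts * (counts - 1) // 2).sum())

    tx = tie_pairs(x)
    ty = tie_pairs(y)
    txy = tie_pairs(np.rec.fromarrays([x, y]))
    c_plus_d = n0 - tx - ty + txy
    if c_plus_d <= 0:
        return 0.0, 0.0
    tau = stats.kendalltau(x, y).statistic  # tau-b
    # C - D and C + D are integer counts; remove float error from the sqrt
    c_minus_d = round(tau * np.sqrt((n0 - tx) * (n0 - ty)))
    return float(c_minus_d), float(c_plus_d)


def goodman_kruskal_gamma(x, y) -> float:
    """Gamma = (C - D)/(C + D) over concordant/discordant untied pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    cmd, cpd = _concordance_counts(x, y)
    if cpd == 0:
        raise ValueError("all pairs tied; gamma undefined")
    return cmd / cpd


def goodman_kruskal_gamma_perm(x, y, m: int = 1000, seed=None) -> GammaResult:
    """Gamma with a one-sided permutation p-value p = (n + 1)/(m + 1).

    x is shuffled against y m times; n counts permuted gammas >= the observed
    value (ties counted, conservatively).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = goodman_kruskal_gamma(x, y)
    rng = np.random.default_rng(seed)
    n_ge = 0
    xs = x.copy()
    for _ in range(m):
        rng.shuffle(xs)
        cmd, cpd = _concordance_counts(xs, y)
        g = cmd / cpd if cpd > 0 else 0.0
        if g >= obs - 1e-12:
            n_ge += 1
    return GammaResult(obs, (n_ge + 1) / (m + 1), m, n_ge)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-tailed p (average ranks, t-approximation).

    Constant input yields (0.0, 1.0) rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0, 1.0
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def partial_spearman(x, y, controls) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given one or more controls.

    All vectors are rank-transformed (average ranks); x and y ranks are
    residualized on the control ranks (with intercept) by least squares and
    the Pearson correlation of the residuals is returned with a two-tailed
    t-approximate p on n - k - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.atleast_2d(np.asarray(controls, dtype=float))
    if z.shape[0] == len(x) and z.ndim == 2 and z.shape[1] != len(x):
        z = z.T  # accept (n, k) or (k, n)
    k = z.shape[0]
    n = len(x)
    if len(y) != n or z.shape[1] != n:
        raise ValueError("all vectors must have equal length")
    if n <= k + 2:
        raise ValueError("too few observations for partial correlation")
    for v in (x, y, *z):
        if np.all(v == v[0]):
            raise ValueError("constant vector supplied")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rz = np.column_stack([stats.rankdata(v) for v in z])
    design = np.column_stack([np.ones(n), rz])
    bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
    by, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ bx
    ey = ry - design @ by
    denom = np.sqrt((ex ** 2).sum() * (ey ** 2).sum())
    if denom == 0:
        return 0.0, 1.0
    rho = float((ex * ey).sum() / denom)
    rho = min(1.0, max(-1.0, rho))
    df = n - k - 2
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


def loess_fit(x, y, span: float = 0.75, degree: int = 1):
    """Locally weighted (tricube) linear regression.

    Returns (fitted, residuals) aligned with the input order. Only degree 1 is
    supported (local linear); span is the fraction of points in each local
    neighbourhood.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree != 1:
        raise ValueError("only degree-1 (local linear) loess is supported")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 10:
        raise ValueError("need at least 10 points for loess")
    if np.all(x == x[0]):
        raise ValueError("all x equal; loess undefined")
    fitted = _sm_lowess(y, x, frac=span, it=0, return_sorted=False)
    return fitted, y - fitted


def mann_whitney_u(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann–Whitney U statistic and p-value.

    Exact enumeration for small tie-free samples (n <= 20 per group), normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def exact_binomial_p(k: int, n: int, p: float = 0.5,
                     alternative: str = "two-sided") -> float:
    """Exact binomial test p-value."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(stats.binomtest(k, n, p, alternative=alternative).pvalue)
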