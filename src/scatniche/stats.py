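"""Classical tests used across the analysis, implemented from first principles.

Pearson chi-square for r x c independence, two-sided Fisher's exact test by
hypergeometric enumeration, one-way ANOVA with Tukey-Kramer honestly
significant differences (own studentized-range CDF by Gauss-Legendre
quadrature), paired and two-sample t, the extra-sum-of-squares F test for
equality of two regression slopes, and simple least-squares regression.
Only distribution tail functions are delegated to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "TestResult",
    "chi_square_independence",
    "fisher_exact_2x2",
    "one_way_anova",
    "tukey_hsd",
    "paired_t",
    "two_sample_t",
    "slope_equality_f",
    "simple_ols",
    "OLSFit",
    "studentized_range_sf",
]


class DegenerateDataError(ValueError):
    """Raised when a test's input admits no meaningful statistic."""


@dataclass
class TestResult:
    statistic: float
    df: float | tuple
    p_value: float
    method: str
    effect_detail: dict = field(default_factory=dict)
    degenerate: bool = False


# ---------------------------------------------------------------------------
# contingency tables


def chi_square_independence(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction; expected counts from the product of margins
    over the grand total; df = (r-1)(c-1).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D non-negative matrix")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise DegenerateDataError("zero row or column margin")
    n = obs.sum()
    expected = np.outer(row, col) / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return TestResult(chi2, df, p, "pearson_chi_square", {"expected": expected})


def _hypergeom_logpmf_support(r1: int, r2: int, c1: int):
    """Log-pmf of the first cell over its support for fixed 2x2 margins."""
    n = r1 + r2
    a = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logp = (
        gammaln(r1 + 1)
        - gammaln(a + 1)
        - gammaln(r1 - a + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - a + 1)
        - gammaln(r2 - (c1 - a) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    return a, logp


def fisher_exact_2x2(table, alternative: str = "two_sided") -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Enumerates the hypergeometric distribution over all tables with the
    observed margins; the two-sided p-value is the total probability of
    tables no more likely than the observed one (probability-mass method,
    with a 1e-7 relative slack on the comparison).  The reported odds ratio
    is the sample odds ratio ad/bc.
    """
    if alternative != "two_sided":
        raise ValueError("only the two-sided alternative is implemented")
    obs = np.asarray(table, dtype=int)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("table must be a 2x2 non-negative integer matrix")
    (a, b), (c, d) = obs
    n = obs.sum()
    if n == 0:
        raise DegenerateDataError("empty table")
    support, logp = _hypergeom_logpmf_support(a + b, c + d, a + c)
    pmf = np.exp(logp)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(p, 1.0)
    if b * c == 0:
        oddsratio = np.inf if a * d > 0 else np.nan
    else:
        oddsratio = a * d / (b * c)
    return TestResult(
        float(oddsratio), np.nan, p, "fisher_exact_2x2", {"table": obs.tolist()}
    )


# ---------------------------------------------------------------------------
# means


def _anova_decomposition(groups):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    N = int(ns.sum())
    grand = sum(g.sum() for g in groups) / N
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    return k, N, ns, means, ss_between, ss_within


def one_way_anova(groups) -> TestResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within."""
    k, N, ns, means, ssb, ssw = _anova_decomposition(groups)
    df = (k - 1, N - k)
    if ssw == 0.0:
        degenerate = ssb == 0.0
        return TestResult(
            np.inf if ssb > 0 else 0.0,
            df,
            0.0 if ssb > 0 else 1.0,
            "one_way_anova",
            {"group_means": means.tolist()},
            degenerate=True,
        )
    f = (ssb / df[0]) / (ssw / df[1])
    p = float(sps.f.sf(f, *df))
    return TestResult(float(f), df, p, "one_way_anova", {"group_means": means.tolist()})


# -- studentized range distribution ----------------------------------------

_GL_NODES = 96


def _gauss_legendre(a, b, n=_GL_NODES):
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (b - a) * x + 0.5 * (a + b), 0.5 * (b - a) * w


def _range_cdf(r, k: int) -> np.ndarray:
    """P(range of k iid standard normals <= r), vectorised over r >= 0.

    One Gauss-Legendre rule per r, all evaluated as a single array:
    P(R <= r) = k * int phi(z) [Phi(z) - Phi(z - r)]^(k-1) dz.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    x, w = np.polynomial.legendre.leggauss(160)
    lo, hi = -8.5, r[:, None] + 8.5  # integrand support per r
    z = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    wz = 0.5 * (hi - lo) * w
    inner = sps.norm.cdf(z) - sps.norm.cdf(z - r[:, None])
    out = k * (wz * sps.norm.pdf(z) * inner ** (k - 1)).sum(axis=1)
    return np.clip(out, 0.0, 1.0)


def studentized_range_sf(q: float, k: int, df: float) -> float:
    """Upper tail of the studentized range distribution Q(k, df).

    F(q) = E_S[ P(range <= q S) ] with S = sqrt(chi2_df / df), evaluated by
    nested Gauss-Legendre quadrature (absolute accuracy ~1e-6 over the
    ranges used in Tukey-Kramer comparisons).
    """
    if q <= 0:
        return 1.0
    if k < 2 or df < 1:
        raise ValueError("need k >= 2 and df >= 1")
    s_lo = np.sqrt(sps.chi2.ppf(1e-12, df) / df)
    s_hi = np.sqrt(sps.chi2.ppf(1 - 1e-12, df) / df)
    s, ws = _gauss_legendre(max(s_lo, 1e-12), s_hi, 128)
    # chi density of S: f(s) = 2 * (df/2)^{df/2} / Gamma(df/2) * s^{df-1} e^{-df s^2/2}
    log_fs = (
        np.log(2.0)
        + 0.5 * df * np.log(df / 2.0)
        - gammaln(df / 2.0)
        + (df - 1) * np.log(s)
        - df * s**2 / 2.0
    )
    fs = np.exp(log_fs)
    cdf = float((ws * fs * _range_cdf(q * s, k)).sum())
    return float(min(1.0, max(0.0, 1.0 - cdf)))


def tukey_hsd(groups, labels=None) -> list[TestResult]:
    """Tukey-Kramer all-pairs comparisons after a one-way ANOVA.

    q_ij = |mean_i - mean_j| / sqrt(MS_within (1/n_i + 1/n_j) / 2), referred
    to the studentized range distribution with (k, N-k).
    """
    k, N, ns, means, ssb, ssw = _anova_decomposition(groups)
    if ssw == 0.0:
        raise DegenerateDataError("zero within-group variance")
    msw = ssw / (N - k)
    labels = labels if labels is not None else [str(i) for i in range(k)]
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[j]) / 2.0)
            q = abs(means[i] - means[j]) / se
            p = studentized_range_sf(q, k, N - k)
            out.append(
                TestResult(
                    float(q),
                    (k, N - k),
                    p,
                    "tukey_kramer_hsd",
                    {
                        "pair": (labels[i], labels[j]),
                        "mean_difference": float(means[i] - means[j]),
                    },
                )
            )
    return out


def paired_t(x, y) -> TestResult:
    """Paired t test on matched observations; df = n - 1, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length vectors with n >= 2")
    d = y - x
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        return TestResult(
            0.0 if d.mean() == 0 else np.inf,
            n - 1,
            1.0 if d.mean() == 0 else 0.0,
            "paired_t",
            {"mean_difference": float(d.mean())},
            degenerate=True,
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return TestResult(float(t), n - 1, p, "paired_t", {"mean_difference": float(d.mean())})


def two_sample_t(x, y) -> TestResult:
    """Pooled-variance two-sample t test (equal variances assumed)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("need >= 2 values per sample")
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (nx + ny - 2)
    if sp2 == 0.0:
        raise DegenerateDataError("zero pooled variance")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    df = nx + ny - 2
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(float(t), df, p, "two_sample_t")


# ---------------------------------------------------------------------------
# regression


@dataclass
class OLSFit:
    slope: float
    intercept: float
    se_slope: float
    t: float
    p: float
    r_squared: float
    n: int
    residual_ss: float


def simple_ols(x, y) -> OLSFit:
    """Simple least-squares regression of y on x with slope inference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx == 0.0:
        raise DegenerateDataError("x has zero variance")
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    rss = float((resid**2).sum())
    n = x.size
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    syy = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / syy if syy > 0 else 1.0
    if se == 0.0:
        t, p = (np.inf if slope != 0 else 0.0), (0.0 if slope != 0 else 1.0)
    else:
        t = slope / se
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return OLSFit(float(slope), float(intercept), float(se), float(t), p, float(r2), n, rss)


def slope_equality_f(line_a, line_b) -> TestResult:
    """Extra-sum-of-squares F test for equality of two regression slopes.

    Compares the full model (separate slopes and intercepts) against the
    reduced model (common slope, separate intercepts); F has df
    (1, nA + nB - 4).  Used for immunoassay parallelism checks.
    """
    xa, ya = (np.asarray(v, dtype=float) for v in line_a)
    xb, yb = (np.asarray(v, dtype=float) for v in line_b)
    if xa.size < 3 or xb.size < 3:
        raise ValueError("need >= 3 points per line")
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise DegenerateDataError("collinear x within a line")

    def _rss_sep(x, y):
        fit = simple_ols(x, y)
        return fit.residual_ss

    rss_full = _rss_sep(xa, ya) + _rss_sep(xb, yb)
    # reduced: common slope b, intercepts per line -> b from pooled centred data
    xca, xcb = xa - xa.mean(), xb - xb.mean()
    yca, ycb = ya - ya.mean(), yb - yb.mean()
    b = ((xca * yca).sum() + (xcb * ycb).sum()) / ((xca**2).sum() + (xcb**2).sum())
    rss_red = float(((yca - b * xca) ** 2).sum() + ((ycb - b * xcb) ** 2).sum())
    df2 = xa.size + xb.size - 4
    scale = float((yca**2).sum() + (ycb**2).sum())
    if rss_full <= 1e-12 * max(scale, 1e-300):
        # both lines fit exactly: any slope gap shows up in the reduced RSS
        exceeds = (rss_red - rss_full) > 1e-12 * max(scale, 1e-300)
        f = np.inf if exceeds else 0.0
        p = 0.0 if exceeds else 1.0
        return TestResult(f, (1, df2), p, "slope_equality_f", degenerate=not exceeds)
    f = max(0.0, (rss_red - rss_full) / (rss_full / df2))
    p = float(sps.f.sf(f, 1, df2))
    return TestResult(float(f), (1, df2), p, "slope_equality_f", {"common_slope": float(b)})
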