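"""Heteroscedasticity-robust group comparisons and correlation.

Implements the inferential toolkit used throughout the analyses:

* Welch's one-way ANOVA (unequal variances) with the Welch-Satterthwaite
  denominator degrees of freedom;
* Dunnett's T3 post hoc test: pairwise Welch t statistics referred to the
  studentized maximum modulus (SMM) distribution with per-pair
  Welch-Satterthwaite df;
* weighted one-way ANOVA (WLS F test) with Tukey-adjusted pairwise
  comparisons of weighted marginal means;
* Pearson correlation / simple linear regression.

The SMM tail probability is computed by numerical quadrature over the
scaled-chi mixing density; a Monte-Carlo cross-check lives in the test
suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.integrate import quad
import statsmodels.api as sm

__all__ = [
    "GroupSample",
    "PairwiseComparison",
    "GroupComparisonResult",
    "RegressionResult",
    "welch_anova",
    "dunnett_t3",
    "weighted_one_way_anova",
    "pearson",
    "smm_cdf",
    "smm_sf",
    "significance_stars",
]


@dataclass(frozen=True)
class GroupSample:
    """A labelled sample of measurements from one experimental group."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError(f"group '{self.label}' needs >= 2 observations")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group '{self.label}' has non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def var(self) -> float:
        return float(np.var(self.values, ddof=1))


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    mean_diff: float
    statistic: float
    df: float
    p_unadjusted: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupComparisonResult:
    """Omnibus test outcome plus optional post-hoc pairs."""

    test: str
    statistic: float  # W (Welch) or F (weighted)
    df_num: float
    df_den: float
    p_value: float
    degenerate: bool = False
    posthoc: list[PairwiseComparison] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p_value": self.p_value,
            "posthoc": [
                {
                    "pair": list(c.pair),
                    "mean_diff": c.mean_diff,
                    "statistic": c.statistic,
                    "df": c.df,
                    "p_unadjusted": c.p_unadjusted,
                    "p_adjusted": c.p_adjusted,
                    "stars": significance_stars(c.p_adjusted),
                }
                for c in self.posthoc
            ],
        }


def significance_stars(p: float) -> str:
    """Render the conventional significance stars (0.05/0.01/0.001/0.0001)."""
    for thresh, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p <= thresh:
            return stars
    return "ns"


def welch_anova(groups: list[GroupSample]) -> GroupComparisonResult:
    """Welch's heteroscedasticity-robust one-way ANOVA.

    W is referred to an F distribution with df_num = k - 1 and the
    Welch-Satterthwaite denominator df.  Groups with zero variance
    throughout and equal means give W = 0, p = 1; zero variance with unequal
    means is flagged degenerate (p = 0).
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    w = np.array([g.n / g.var if g.var > 0 else np.inf for g in groups])
    means = np.array([g.mean for g in groups])
    if np.any(~np.isfinite(w)):
        if np.allclose(means, means[0]):
            return GroupComparisonResult("welch_anova", 0.0, k - 1.0, math.inf, 1.0)
        return GroupComparisonResult("welch_anova", math.inf, k - 1.0, math.inf, 0.0, degenerate=True)
    w_sum = float(np.sum(w))
    grand = float(np.sum(w * means) / w_sum)
    a = float(np.sum(w * (means - grand) ** 2)) / (k - 1)
    h = np.array([(1 - wi / w_sum) ** 2 / (g.n - 1) for wi, g in zip(w, groups)])
    b = 1.0 + (2.0 * (k - 2) / (k**2 - 1)) * float(np.sum(h))
    w_stat = a / b
    df_den = (k**2 - 1) / (3.0 * float(np.sum(h)))
    p = float(sps.f.sf(w_stat, k - 1, df_den))
    return GroupComparisonResult("welch_anova", float(w_stat), float(k - 1), float(df_den), p)


def _scaled_chi_pdf(s: np.ndarray, df: float) -> np.ndarray:
    """Density of S = chi_df / sqrt(df) (the studentizing denominator)."""
    return sps.chi.pdf(s, df, scale=1.0 / math.sqrt(df))


def smm_cdf(q: float, m: int, df: float) -> float:
    """CDF of the studentized maximum modulus with m means and df.

    P(max_i |Z_i| / S <= q) for m independent standard normals Z_i and a
    common S = chi_df/sqrt(df), computed by adaptive quadrature:
    integral over s of [2 Phi(q s) - 1]^m  f_S(s) ds.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if q <= 0:
        return 0.0

    def integrand(s):
        return (2.0 * sps.norm.cdf(q * s) - 1.0) ** m * _scaled_chi_pdf(s, df)

    val, _ = quad(integrand, 0.0, np.inf, limit=200)
    return float(min(max(val, 0.0), 1.0))


def smm_sf(q: float, m: int, df: float) -> float:
    """Upper tail 1 - CDF of the studentized maximum modulus."""
    return 1.0 - smm_cdf(q, m, df)


def _welch_pair(a: GroupSample, b: GroupSample) -> tuple[float, float, float]:
    """(t, df, mean_diff) of the unequal-variance two-sample comparison."""
    se2 = a.var / a.n + b.var / b.n
    if se2 == 0:
        raise ValueError(f"pair ({a.label}, {b.label}) has zero variance")
    t = (a.mean - b.mean) / math.sqrt(se2)
    df = se2**2 / ((a.var / a.n) ** 2 / (a.n - 1) + (b.var / b.n) ** 2 / (b.n - 1))
    return t, df, a.mean - b.mean


def dunnett_t3(
    groups: list[GroupSample], reference: str | None = None
) -> list[PairwiseComparison]:
    """Dunnett's T3 post hoc test for unequal variances.

    Each pair gets a Welch t statistic with Welch-Satterthwaite df; the
    adjusted p is the SMM tail probability at |t| with m = the number of
    comparisons performed (all pairs, or all-vs-reference when ``reference``
    is given).  With m = 1 the adjusted p equals the two-sided Welch t-test
    p-value.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    by_label = {g.label: g for g in groups}
    if reference is not None:
        if reference not in by_label:
            raise ValueError(f"reference '{reference}' not among groups")
        pairs = [(by_label[reference], g) for g in groups if g.label != reference]
    else:
        pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    if m == 0:
        raise ValueError("no comparisons to perform")
    out = []
    for a, b in pairs:
        t, df, diff = _welch_pair(a, b)
        p_un = float(2.0 * sps.t.sf(abs(t), df))
        p_adj = smm_sf(abs(t), m, df) if m > 1 else p_un
        out.append(PairwiseComparison((a.label, b.label), diff, t, df, p_un, min(p_adj, 1.0)))
    return out


def weighted_one_way_anova(
    groups: list[GroupSample], weights: list[np.ndarray]
) -> GroupComparisonResult:
    """Weighted one-way ANOVA with Tukey-adjusted weighted marginal means.

    The omnibus F is the WLS comparison of the group-means model against the
    grand-mean model (df = k-1, N-k).  Pairwise comparisons use the weighted
    marginal means with SE from the WLS mean-squared error and the
    studentized-range (Tukey) adjustment.  With all weights equal this is
    the ordinary one-way ANOVA, and duplicating an observation is equivalent
    to doubling its weight.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if len(weights) != k:
        raise ValueError("one weight array per group required")
    y, w, labels = [], [], []
    for g, gw in zip(groups, weights):
        gw = np.asarray(gw, dtype=float)
        if gw.shape != g.values.shape:
            raise ValueError(f"weights for group '{g.label}' must match its values")
        if np.any(gw <= 0):
            raise ValueError("weights must be > 0")
        y.append(g.values)
        w.append(gw)
        labels.extend([g.label] * g.n)
    y = np.concatenate(y)
    w = np.concatenate(w)
    n_obs = y.size

    design = np.zeros((n_obs, k))
    for j, g in enumerate(groups):
        design[np.array(labels) == g.label, j] = 1.0
    fit_full = sm.WLS(y, design, weights=w).fit()
    fit_null = sm.WLS(y, np.ones((n_obs, 1)), weights=w).fit()
    df_num, df_den = float(k - 1), float(n_obs - k)
    f_stat = ((fit_null.ssr - fit_full.ssr) / df_num) / (fit_full.ssr / df_den)
    p = float(sps.f.sf(f_stat, df_num, df_den))

    mse = fit_full.ssr / df_den
    w_totals = {g.label: float(np.sum(gw)) for g, gw in zip(groups, weights)}
    wmeans = {
        g.label: float(np.average(g.values, weights=gw)) for g, gw in zip(groups, weights)
    }
    posthoc = []
    for a, b in itertools.combinations(groups, 2):
        diff = wmeans[a.label] - wmeans[b.label]
        se = math.sqrt(mse * (1.0 / w_totals[a.label] + 1.0 / w_totals[b.label]))
        t = diff / se
        q = abs(t) * math.sqrt(2.0)
        p_adj = float(sps.studentized_range.sf(q, k, df_den))
        p_un = float(2.0 * sps.t.sf(abs(t), df_den))
        posthoc.append(
            PairwiseComparison((a.label, b.label), diff, t, df_den, p_un, min(p_adj, 1.0))
        )
    return GroupComparisonResult(
        "weighted_anova", float(f_stat), df_num, df_den, p, posthoc=posthoc
    )


@dataclass(frozen=True)
class RegressionResult:
    r: float
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    n: int


def pearson(x, y) -> RegressionResult:
    """Pearson correlation with OLS slope/intercept.

    Two-sided p from t = r sqrt(n-2)/sqrt(1-r^2) with df = n - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("x and y must be non-constant")
    r, p = sps.pearsonr(x, y)
    lr = sps.linregress(x, y)
    return RegressionResult(float(r), float(r**2), float(p), float(lr.slope), float(lr.intercept), int(x.size))
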