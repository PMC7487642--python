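"""Statistical layer: normality, paired/unpaired t-tests (raw and
summary-statistic forms), linear regression in the group-table shape,
reliability (ICC, Dahlberg's method error) and two-sample power.

Everything standard is delegated to scipy; what is implemented here is
the exact report shape the volumetric study tables use, the
summary-statistic entry points (the clinical tables only print n, mean
and SD), the two-way mixed-effects absolute-agreement single-measure
ICC from ANOVA mean squares, Dahlberg's duplicate-measurement error
``sqrt(sum d_i^2 / 2n)``, and the noncentral-t power of the pooled
two-sample test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateTest, SampleSizeError

__all__ = [
    "GroupSummary",
    "RegressionReport",
    "ReliabilityReport",
    "shapiro_wilk",
    "paired_t",
    "unpaired_t",
    "unpaired_t_summary",
    "linear_regression",
    "icc",
    "dahlberg",
    "power_two_sample",
]


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise SampleSizeError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_sample(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(n=len(x), mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass
class RegressionReport:
    r: float
    r_squared: float
    coefficient_b: float
    beta_standardized: float
    std_error: float
    ci_lower: float
    ci_upper: float
    intercept: float
    p_value: float


@dataclass
class ReliabilityReport:
    icc: float
    dahlberg: float


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p; admissible for 3 <= n <= 5000, non-constant."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise SampleSizeError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise SampleSizeError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def paired_t(x1, x2) -> tuple[float, float, float]:
    """Two-sided paired Student's t on T1/T2 measurements.

    Returns (t, p, mean_diff) with the difference taken as x2 - x1, the
    direction of a post-treatment change.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("paired samples must have equal length")
    if len(x1) < 2:
        raise SampleSizeError("paired t needs n >= 2")
    d = x2 - x1
    sd = d.std(ddof=1)
    mean_diff = float(d.mean())
    if sd == 0:
        raise DegenerateTest(f"zero difference variance (mean_diff = {mean_diff})")
    n = len(d)
    t = mean_diff / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), float(p), mean_diff


def unpaired_t(x1, x2, equal_var: bool = True) -> tuple[float, float, float]:
    """Two-sided unpaired t on raw samples (pooled by default, Welch by flag)."""
    g1 = GroupSummary.from_sample(x1)
    g2 = GroupSummary.from_sample(x2)
    return unpaired_t_summary(g1, g2, equal_var=equal_var)


def unpaired_t_summary(
    g1: GroupSummary, g2: GroupSummary, equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sided unpaired Student's t from group summaries.

    Pooled-variance (classical Student) by default; ``equal_var=False``
    switches to the Welch form with Satterthwaite degrees of freedom.
    Returns (t, p, mean_diff) with mean_diff = g2.mean - g1.mean.
    """
    if g1.sd == 0 and g2.sd == 0:
        raise DegenerateTest("both group variances are zero")
    t, p = sps.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=equal_var
    )
    return float(t), float(p), float(g2.mean - g1.mean)


def linear_regression(x, y, alpha: float = 0.05) -> RegressionReport:
    """OLS of y on x with the group-table report shape.

    r is the Pearson correlation, ``beta_standardized = b sd(x)/sd(y)``,
    and the CI for the slope comes from the t distribution on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise SampleSizeError("regression needs n >= 3")
    if x.std(ddof=1) == 0:
        raise DegenerateTest("zero predictor variance")
    res = sps.linregress(x, y)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, n - 2)
    sy = y.std(ddof=1)
    beta = res.slope * x.std(ddof=1) / sy if sy > 0 else 0.0
    r = float(res.rvalue)
    return RegressionReport(
        r=abs(r),
        r_squared=r * r,
        coefficient_b=float(res.slope),
        beta_standardized=float(beta),
        std_error=float(res.stderr),
        ci_lower=float(res.slope - tcrit * res.stderr),
        ci_upper=float(res.slope + tcrit * res.stderr),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
    )


def icc(ratings) -> float:
    """Two-way mixed-effects, absolute-agreement, single-measure ICC.

    ``ratings`` is an (n_subjects, k_raters) table; the coefficient is
    ICC(A,1) from the two-way ANOVA mean squares (McGraw & Wong):

        (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n x k table with k >= 2")
    n, k = x.shape
    if n < 5:
        raise SampleSizeError("ICC needs at least 5 subjects")
    if np.ptp(x) == 0:
        raise DegenerateTest("zero total variance")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0:
        raise DegenerateTest("degenerate ANOVA decomposition")
    return float((msr - mse) / denom)


def dahlberg(pairs) -> float:
    """Dahlberg's method error sqrt(sum d_i^2 / 2n) over duplicate readings."""
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2 or len(x) < 1:
        raise ValueError("pairs must be an n x 2 table with n >= 1")
    d = x[:, 0] - x[:, 1]
    return float(np.sqrt((d**2).sum() / (2.0 * len(d))))


def reliability(ratings) -> ReliabilityReport:
    """Convenience bundle of ICC and Dahlberg error on an n x 2 table."""
    x = np.asarray(ratings, dtype=float)
    return ReliabilityReport(icc=icc(x), dahlberg=dahlberg(x))


def power_two_sample(g1: GroupSummary, g2: GroupSummary, alpha: float = 0.05) -> float:
    """Power of the two-sided pooled-variance two-sample t-test.

    Noncentral-t computation at the stated per-group sizes:
    ``delta = |mu1 - mu2| / (s_pooled sqrt(1/n1 + 1/n2))``; power is the
    probability that |T| exceeds the alpha critical value under the
    noncentral t with n1 + n2 - 2 df.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    se = np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    diff = abs(g1.mean - g2.mean)
    if se > 0:
        delta = diff / se
    else:
        delta = np.inf if diff > 0 else 0.0
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    if not np.isfinite(delta):
        return 1.0
    power = sps.nct.sf(tcrit, df, delta) + sps.nct.cdf(-tcrit, df, delta)
    return float(power)
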