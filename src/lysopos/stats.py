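"""Two-sample testing machinery with a normality-driven dispatcher.

The dispatch rule mirrors common practice for per-cell microscopy readouts:
for samples large enough to test normality (n >= 8 per group) the
D'Agostino-Pearson omnibus test is applied to each group with p > 0.05
defining normality; normal pairs are compared by Student's t-test after an
F-test of equal variances (Welch's correction when the F-test rejects), and
non-normal pairs by the Mann-Whitney test.  Smaller samples fall back to the
t-test branch directly, since the omnibus test is undefined there.  The
Brunner-Munzel test - a studentized rank test of stochastic superiority
P(A < B) + 0.5 P(A = B) = 0.5 that is robust to unequal variances and
distribution shapes - is provided for cohort-level comparisons.

All tests are two-sided.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateSampleError, ParameterError, SampleSizeError

#: p-value threshold above which a group is considered normally distributed
NORMALITY_ALPHA = 0.05
#: p-value threshold of the F-test below which Welch's correction is used
VARIANCE_ALPHA = 0.05
#: per-group size below which normality is considered untestable
SMALL_SAMPLE_N = 8
#: total size up to which the Mann-Whitney p-value is computed exactly
MWU_EXACT_TOTAL_N = 12


@dataclasses.dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: float | None = None
    estimate: float | None = None  # mean difference, U, or p-hat


@dataclasses.dataclass
class DispatchTrace:
    """Record of the decisions taken by :func:`compare_groups`."""

    normality_p: dict | None
    variance_p: float | None
    chosen_method: str
    result: TestResult
    warnings: list


def _clean(sample, min_n=2, name="sample"):
    x = np.asarray(sample, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ParameterError(f"{name} contains non-finite values")
    if x.size < min_n:
        raise SampleSizeError(f"{name} needs at least {min_n} observations")
    return x


def dagostino_pearson(sample) -> TestResult:
    """D'Agostino-Pearson omnibus normality test (K^2 against chi^2 with 2 df)."""
    x = _clean(sample, min_n=2)
    if x.size < SMALL_SAMPLE_N:
        raise SampleSizeError(
            f"omnibus normality test needs n >= {SMALL_SAMPLE_N} "
            "(use the small-sample t branch instead)"
        )
    with warnings.catch_warnings():
        # the kurtosis z-approximation warning for 8 <= n < 20 is accepted here
        warnings.simplefilter("ignore")
        stat, p = sps.normaltest(x)
    return TestResult("dagostino_pearson", float(stat), float(p), df=2.0)


def f_test_variances(a, b) -> TestResult:
    """Two-sided F-test of equal variances (larger variance in the numerator)."""
    x, y = _clean(a, name="a"), _clean(b, name="b")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DegenerateSampleError("both samples have zero variance")
    if vx >= vy:
        num, den, dfn, dfd = vx, vy, x.size - 1, y.size - 1
    else:
        num, den, dfn, dfd = vy, vx, y.size - 1, x.size - 1
    if den == 0:
        return TestResult("f_test", float("inf"), 0.0, df=float(dfn))
    f = num / den
    p = min(1.0, 2.0 * sps.f.sf(f, dfn, dfd))
    return TestResult("f_test", float(f), float(p), df=float(dfn))


def two_sample_t(a, b, welch: bool = False) -> TestResult:
    """Student's (pooled) or Welch's t-test; estimate is mean(a) - mean(b)."""
    x, y = _clean(a, name="a"), _clean(b, name="b")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        raise DegenerateSampleError("both samples constant and equal")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return TestResult(
        "welch_t" if welch else "student_t",
        float(res.statistic),
        float(res.pvalue),
        df=float(res.df),
        estimate=float(x.mean() - y.mean()),
    )


def mann_whitney(a, b) -> TestResult:
    """Mann-Whitney U test with midrank ties.

    The p-value is exact (full enumeration) when the total sample size is at
    most 12 and the data are tie-free; otherwise the tie-corrected normal
    approximation with continuity correction is used.  The statistic is U for
    sample a (number of (a, b) pairs with a > b, ties counted half); the
    estimate is the stochastic-superiority p-hat = P(a < b) + 0.5 P(a = b).
    """
    x, y = _clean(a, name="a"), _clean(b, name="b")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = (
        "exact" if (combined.size <= MWU_EXACT_TOTAL_N and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    u_a = float(res.statistic)
    p_hat = 1.0 - u_a / (x.size * y.size)
    return TestResult("mann_whitney", u_a, float(res.pvalue), estimate=p_hat)


def brunner_munzel(a, b, min_n_warn: int = 10) -> TestResult:
    """Brunner-Munzel test of stochastic superiority.

    Estimates p-hat = P(a < b) + 0.5 P(a = b) from midranks and studentizes
    it with a Welch-Satterthwaite-type t approximation.  The statistic is
    positive when b tends to exceed a.

    Raises
    ------
    DegenerateSampleError
        When both samples have zero rank variance (complete tied
        separation); the exception carries ``p_hat`` (0 or 1) since no
        p-value is defined there.
    """
    x, y = _clean(a, name="a"), _clean(b, name="b")
    nx, ny = x.size, y.size
    if min(nx, ny) < min_n_warn:
        warnings.warn(
            "Brunner-Munzel t-approximation is unreliable below "
            f"n = {min_n_warn} per group",
            stacklevel=2,
        )
    rank_c = sps.rankdata(np.concatenate([x, y]))
    rank_cx, rank_cy = rank_c[:nx], rank_c[nx:]
    rank_x, rank_y = sps.rankdata(x), sps.rankdata(y)
    mx, my = rank_cx.mean(), rank_cy.mean()
    p_hat = (my - (ny + 1) / 2.0) / nx
    sx2 = np.sum((rank_cx - rank_x - mx + (nx + 1) / 2.0) ** 2) / (nx - 1)
    sy2 = np.sum((rank_cy - rank_y - my + (ny + 1) / 2.0) ** 2) / (ny - 1)
    pooled = nx * sx2 + ny * sy2
    if pooled == 0:
        raise DegenerateSampleError(
            "zero rank variance in both samples (complete tied separation)",
            p_hat=float(np.clip(p_hat, 0.0, 1.0)),
        )
    stat = nx * ny * (my - mx) / ((nx + ny) * np.sqrt(pooled))
    df = pooled**2 / ((nx * sx2) ** 2 / (nx - 1) + (ny * sy2) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(stat), df)
    return TestResult(
        "brunner_munzel", float(stat), float(min(p, 1.0)), df=float(df),
        estimate=float(p_hat),
    )


def compare_groups(a, b, method: str = "auto", policy: str = "t") -> DispatchTrace:
    """Normality-driven two-sample comparison.

    With ``method='auto'``: if either group has fewer than 8 observations the
    t branch is taken directly (``policy`` names the small-sample branch;
    only ``'t'`` is implemented) with a recorded warning; otherwise both
    groups are tested with the D'Agostino-Pearson omnibus and, if both pass
    (p > 0.05), Student's or Welch's t-test is chosen by the F-test, else the
    Mann-Whitney test is used.  Any other ``method`` value
    (``t``/``welch``/``mwu``/``bm``) forces that test.
    """
    x, y = _clean(a, name="a"), _clean(b, name="b")
    notes: list[str] = []

    if method != "auto":
        forced = {
            "t": lambda: two_sample_t(x, y, welch=False),
            "welch": lambda: two_sample_t(x, y, welch=True),
            "mwu": lambda: mann_whitney(x, y),
            "bm": lambda: brunner_munzel(x, y),
        }
        if method not in forced:
            raise ParameterError(f"unknown method {method!r}")
        result = forced[method]()
        return DispatchTrace(None, None, result.method, result, notes)

    def _t_branch():
        ftest = f_test_variances(x, y)
        welch = ftest.p_value <= VARIANCE_ALPHA
        return ftest.p_value, two_sample_t(x, y, welch=welch)

    if min(x.size, y.size) < SMALL_SAMPLE_N:
        if policy != "t":
            raise ParameterError(f"unknown small-sample policy {policy!r}")
        notes.append(
            f"normality untestable (n < {SMALL_SAMPLE_N}); small-sample t branch"
        )
        variance_p, result = _t_branch()
        return DispatchTrace(None, variance_p, result.method, result, notes)

    pa = dagostino_pearson(x).p_value
    pb = dagostino_pearson(y).p_value
    normality = {"a": pa, "b": pb}
    if pa > NORMALITY_ALPHA and pb > NORMALITY_ALPHA:
        variance_p, result = _t_branch()
        return DispatchTrace(normality, variance_p, result.method, result, notes)
    result = mann_whitney(x, y)
    return DispatchTrace(normality, None, result.method, result, notes)


def significance_stars(p: float) -> str:
    """Render a p-value in the conventional ns/*/**/*** notation."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in all reports)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted
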