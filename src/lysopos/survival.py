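"""Expression-stratified survival and lymph-node metastasis comparison.

Patients are stratified by gene expression with rank-based quantile cuts: a
single-gene "high" group is the top fraction of expressors (ties at the
threshold included), and a combined two-gene group is formed by further
ranking the high stratum by a second gene until a target share of the whole
cohort is reached.  Survival is summarized with the Kaplan-Meier
product-limit estimator and compared across strata with the logrank test;
lymph-node involvement (positive/total examined nodes per patient) is
compared with the Brunner-Munzel test.

Kaplan-Meier estimation and the logrank test are delegated to lifelines.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from . import stats
from .exceptions import (
    DegenerateStratificationError,
    ParameterError,
    UndefinedTestError,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class StrataAssignment:
    """Per-patient stratum labels plus the thresholds that produced them."""

    labels: pd.Series  # aligned with the cohort index
    thresholds: dict  # gene -> expression threshold

    def group(self, label) -> pd.Index:
        return self.labels.index[self.labels == label]


@dataclasses.dataclass
class SurvivalCurve:
    """Kaplan-Meier step function."""

    times: np.ndarray  # distinct observed times (events and censorings)
    at_risk: np.ndarray
    events: np.ndarray  # deaths at each time
    censored: np.ndarray  # censorings at each time
    survival: np.ndarray  # S(t) just after each time

    def probability_at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else float("inf")


def _expression(cohort: pd.DataFrame, gene: str) -> pd.Series:
    if gene not in cohort.columns:
        raise ParameterError(f"gene {gene!r} not present in the cohort table")
    return cohort[gene].astype(float)


def _top_threshold(values: np.ndarray, k: int) -> float:
    """Value of the k-th largest observation (ties included via >=)."""
    return float(np.sort(values)[-k])


def stratify_top_fraction(
    cohort: pd.DataFrame, gene: str, fraction: float
) -> StrataAssignment:
    """Split the cohort at the empirical (1 - fraction) expression quantile.

    Patients with expression >= the threshold are labeled ``high`` (ties at
    the threshold are included, so the high group holds at least
    ceil(fraction * n) patients); the rest are ``low``.
    """
    if not 0 < fraction < 1:
        raise ParameterError("fraction must be in (0, 1)")
    values = _expression(cohort, gene)
    if values.nunique() <= 1:
        raise DegenerateStratificationError(
            f"all {gene!r} expression values are identical"
        )
    k = math.ceil(fraction * len(values))
    threshold = _top_threshold(values.to_numpy(), k)
    labels = pd.Series(
        np.where(values >= threshold, "high", "low"), index=cohort.index
    )
    return StrataAssignment(labels=labels, thresholds={gene: threshold})


def stratify_combined(
    cohort: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    fraction_a: float,
    target_total_fraction: float,
) -> StrataAssignment:
    """Two-gene combined-high stratification.

    First stratify by ``gene_a`` at ``fraction_a``; within that high stratum
    take the top ``gene_b`` expressors until the combined group is the
    smallest set of at least ``target_total_fraction`` of all patients (ties
    included).  Labels are ``combined_high`` / ``rest``.
    """
    if not 0 < target_total_fraction <= fraction_a:
        raise ParameterError(
            "require 0 < target_total_fraction <= fraction_a"
        )
    primary = stratify_top_fraction(cohort, gene_a, fraction_a)
    high_idx = primary.group("high")
    sub = _expression(cohort.loc[high_idx], gene_b)
    if sub.nunique() <= 1:
        raise DegenerateStratificationError(
            f"{gene_b!r} expression is constant within the {gene_a!r}-high stratum"
        )
    m = min(math.ceil(target_total_fraction * len(cohort)), len(sub))
    threshold_b = _top_threshold(sub.to_numpy(), m)
    combined = sub.index[sub >= threshold_b]
    labels = pd.Series("rest", index=cohort.index)
    labels.loc[combined] = "combined_high"
    thresholds = dict(primary.thresholds)
    thresholds[gene_b] = threshold_b
    return StrataAssignment(labels=labels, thresholds=thresholds)


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator (deaths before censorings at ties)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size < 1:
        raise ParameterError("at least one observation is required")
    if np.any(t <= 0):
        raise ParameterError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    # drop the t=0 anchor row lifelines inserts
    table = kmf.event_table[kmf.event_table.index > 0]
    grid = table.index.to_numpy(dtype=float)
    survival = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    return SurvivalCurve(
        times=grid,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        censored=table["censored"].to_numpy(dtype=int),
        survival=survival,
    )


def logrank_test(times_a, events_a, times_b, events_b) -> stats.TestResult:
    """Two-group logrank test (chi-square with 1 df)."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if ea.sum() + eb.sum() == 0:
        raise UndefinedTestError("no events observed in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return stats.TestResult(
        "logrank", float(res.test_statistic), float(res.p_value), df=1.0
    )


def node_metastasis_score(nodes_positive, nodes_total):
    """Per-patient ratio of positive to examined lymph nodes.

    Patients with no examined nodes get NaN (excluded, logged).  Scalar
    inputs return a float.
    """
    pos = np.asarray(nodes_positive, dtype=float)
    tot = np.asarray(nodes_total, dtype=float)
    scalar = pos.ndim == 0
    pos, tot = np.atleast_1d(pos), np.atleast_1d(tot)
    if np.any(pos < 0) or np.any(pos > tot):
        raise ParameterError("require 0 <= nodes_positive <= nodes_total")
    undefined = tot == 0
    if undefined.any():
        logger.warning(
            "%d patient(s) with zero examined nodes excluded from the "
            "metastasis score", int(undefined.sum()),
        )
    score = np.full(pos.shape, np.nan)
    np.divide(pos, tot, out=score, where=~undefined)
    return float(score[0]) if scalar else score


def compare_metastasis(scores_high, scores_rest) -> stats.TestResult:
    """Brunner-Munzel comparison of node-metastasis scores (NaNs dropped)."""
    a = np.asarray(scores_high, dtype=float)
    b = np.asarray(scores_rest, dtype=float)
    return stats.brunner_munzel(a[~np.isnan(a)], b[~np.isnan(b)])


@dataclasses.dataclass
class SurvivalAnalysis:
    strata: StrataAssignment
    curves: dict  # label -> SurvivalCurve
    logrank: stats.TestResult
    metastasis: stats.TestResult | None


def survival_analysis(
    cohort: pd.DataFrame,
    gene_a: str,
    gene_b: str | None = None,
    fraction: float = 0.15,
    target_total_fraction: float = 0.03,
    time_col: str = "time",
    event_col: str = "event",
) -> SurvivalAnalysis:
    """Stratify a cohort, fit per-stratum KM curves, and compare outcomes.

    With ``gene_b`` given, the combined two-gene rule is used (labels
    ``combined_high``/``rest``); otherwise the single-gene top-fraction rule
    (labels ``high``/``low``).  The metastasis comparison is included when
    node-count columns are present.
    """
    if gene_b is None:
        strata = stratify_top_fraction(cohort, gene_a, fraction)
        hi, lo = "high", "low"
    else:
        strata = stratify_combined(
            cohort, gene_a, gene_b, fraction, target_total_fraction
        )
        hi, lo = "combined_high", "rest"
    idx_hi, idx_lo = strata.group(hi), strata.group(lo)
    curves = {
        label: km_estimate(
            cohort.loc[idx, time_col], cohort.loc[idx, event_col]
        )
        for label, idx in ((hi, idx_hi), (lo, idx_lo))
    }
    lr = logrank_test(
        cohort.loc[idx_hi, time_col], cohort.loc[idx_hi, event_col],
        cohort.loc[idx_lo, time_col], cohort.loc[idx_lo, event_col],
    )
    metastasis = None
    if {"nodes_positive", "nodes_total"} <= set(cohort.columns):
        scores = node_metastasis_score(
            cohort["nodes_positive"], cohort["nodes_total"]
        )
        scores = pd.Series(scores, index=cohort.index)
        metastasis = compare_metastasis(scores.loc[idx_hi], scores.loc[idx_lo])
    return SurvivalAnalysis(
        strata=strata, curves=curves, logrank=lr, metastasis=metastasis
    )
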