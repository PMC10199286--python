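"""Reporting completeness per indicator-month, with a pre/pandemic contrast.

Completeness of an indicator in a month is the share of *expected*
reporting units that submitted a non-missing value.  Master facility
lists are rarely current, so the expected denominator is taken from the
data itself: the maximum number of units reporting the indicator in any
single month of the study period.  By construction at least one month
scores exactly 100%.

A reported zero counts as reporting — that is the point of the death
zero-imputation upstream.

The pre-pandemic vs pandemic contrast treats the monthly completeness
percentages as observations (15 vs 9 by default) and tests the period
difference with a two-sided two-sample t-test, Welch's by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedDenominatorError
from .panel_model import CountryConfig, Panel, PeriodSplit

__all__ = [
    "CompletenessResult",
    "expected_units",
    "monthly_completeness",
    "completeness_series",
    "period_contrast",
    "benchmark_flags",
    "completeness_table",
]

logger = logging.getLogger(__name__)


@dataclass
class CompletenessResult:
    indicator_id: str
    expected_units: int
    monthly_pct: pd.Series  # index = month 1..T, values in [0, 100]
    pre_mean_pct: float
    pandemic_mean_pct: float
    diff_pp: float
    p_value: float  # NaN when a period has < 2 months
    benchmark_flags: dict[str, bool]


def _reporters_by_month(panel: Panel, indicator_id: str) -> pd.Series:
    """Count of units with a non-missing value, per month 1..T."""
    sub = panel.indicator(indicator_id)
    counts = (
        sub[sub["value"].notna()]
        .groupby("month_index")["unit_id"]
        .nunique()
        .reindex(range(1, panel.T + 1), fill_value=0)
    )
    counts.index.name = "month_index"
    return counts


def expected_units(panel: Panel, indicator_id: str) -> int:
    """Denominator: the maximum monthly count of reporting units.

    Raises :class:`UndefinedDenominatorError` if the indicator has no
    non-missing value in any month (nothing distinguishes "not
    collected" from 0% completeness, so the indicator is not scored).
    """
    counts = _reporters_by_month(panel, indicator_id)
    peak = int(counts.max())
    if peak == 0:
        raise UndefinedDenominatorError(
            f"indicator {indicator_id!r} has no reported value in any month"
        )
    return peak


def monthly_completeness(panel: Panel, indicator_id: str, month: int) -> float:
    """Percent of expected units reporting ``indicator_id`` in ``month``."""
    denom = expected_units(panel, indicator_id)
    n = int(_reporters_by_month(panel, indicator_id).loc[month])
    return 100.0 * n / denom


def completeness_series(panel: Panel, indicator_id: str) -> pd.Series:
    """Monthly completeness percentages for months 1..T (one call, all months)."""
    counts = _reporters_by_month(panel, indicator_id)
    denom = expected_units(panel, indicator_id)
    return 100.0 * counts / denom


def period_contrast(
    monthly_pct: pd.Series,
    split: PeriodSplit,
    pooled: bool = False,
) -> tuple[float, float, float, float]:
    """Pre/pandemic means, their difference, and a two-sided t-test p-value.

    Period means are unweighted means of the monthly percentages.
    ``diff_pp`` is pandemic minus pre, in percentage points.  The test
    is Welch's two-sample t-test (``pooled=True`` switches to the
    pooled-variance variant).  With fewer than two months in either
    period the p-value is NaN; the means are still returned.  Two
    zero-variance samples yield p = 1.0 when their means agree and
    p = 0.0 otherwise (the t statistic is 0/0 there).
    """
    pre = monthly_pct.loc[list(split.pre_months)].to_numpy(dtype=float)
    pand = monthly_pct.loc[list(split.pandemic_months)].to_numpy(dtype=float)
    pre_mean = float(pre.mean())
    pand_mean = float(pand.mean())
    diff = pand_mean - pre_mean

    if len(pre) < 2 or len(pand) < 2:
        return pre_mean, pand_mean, diff, float("nan")
    if pre.std() == 0.0 and pand.std() == 0.0:
        return pre_mean, pand_mean, diff, 1.0 if diff == 0.0 else 0.0
    with warnings.catch_warnings():
        # near-identical samples trigger scipy's catastrophic-cancellation
        # notice; the 0/0 cases are already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        p = float(stats.ttest_ind(pand, pre, equal_var=pooled).pvalue)
    return pre_mean, pand_mean, diff, p


def benchmark_flags(
    value_pct: float, benchmarks: tuple[float, ...] = (80.0, 90.0)
) -> tuple[bool, ...]:
    """Meets-or-exceeds flag per benchmark (>= convention)."""
    return tuple(value_pct >= b for b in benchmarks)


def assess_indicator(
    panel: Panel, indicator_id: str, config: CountryConfig
) -> CompletenessResult:
    """Full completeness result for one indicator."""
    series = completeness_series(panel, indicator_id)
    pre, pand, diff, p = period_contrast(
        series, config.period_split, pooled=config.pooled_t_test
    )
    flags = {
        f"{period}_ge_{int(b)}": ok
        for period, mean in (("pre", pre), ("pandemic", pand))
        for b, ok in zip(
            config.completeness_benchmarks,
            benchmark_flags(mean, config.completeness_benchmarks),
        )
    }
    return CompletenessResult(
        indicator_id=indicator_id,
        expected_units=expected_units(panel, indicator_id),
        monthly_pct=series,
        pre_mean_pct=pre,
        pandemic_mean_pct=pand,
        diff_pp=diff,
        p_value=p,
        benchmark_flags=flags,
    )


def completeness_table(
    panel: Panel,
    config: CountryConfig,
    indicator_ids: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[CompletenessResult]]:
    """One completeness row per indicator, skipping never-reported ones.

    An indicator with no reported value in any month is dropped with a
    logged warning rather than scored 0% — its denominator is undefined.
    Returns the report table (full precision) and the per-indicator
    results carrying the monthly series for time-series export.
    """
    rows = []
    results = []
    for ind in indicator_ids or panel.indicator_ids:
        try:
            res = assess_indicator(panel, ind, config)
        except UndefinedDenominatorError:
            logger.warning(
                "indicator %r never reported; dropped from completeness table", ind
            )
            continue
        results.append(res)
        rows.append(
            {
                "country": config.country_label,
                "indicator_id": ind,
                "expected_units": res.expected_units,
                "pre_pct": res.pre_mean_pct,
                "pandemic_pct": res.pandemic_mean_pct,
                "diff_pp": res.diff_pp,
                "p_value": res.p_value,
                "significant": bool(res.p_value < alpha)
                if not np.isnan(res.p_value)
                else False,
                **res.benchmark_flags,
            }
        )
    return pd.DataFrame(rows), results
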