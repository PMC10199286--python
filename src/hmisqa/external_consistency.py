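"""External consistency: HMIS c-section rates vs a household-survey benchmark.

Routine systems report the *numerators* (facility deliveries, cesarean
sections) but not the population denominator (all births).  The
triangulation recovers it from a population-representative survey (DHS
or MICS):

    estimated births   = HMIS deliveries / survey facility-delivery rate
    HMIS c-section rate = 100 * HMIS c-sections / estimated births

under the assumptions that the HMIS captures all facility deliveries
and all c-sections in its scope, and that the survey's facility-delivery
rate is accurate and unchanged since fieldwork.  The second assumption
is probed by recomputing the rate with the facility-delivery rate moved
up and down by a few percentage points (default 3), giving an
uncertainty interval: a *higher* delivery rate implies *fewer* total
births and hence a *higher* c-section rate, so the +delta arm is the
interval's upper end.

Only pre-pandemic (reference-year) totals feed the estimator, so
pandemic shifts in facility delivery cannot bias it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportions_ztest

from .errors import ConfigError
from .internal_consistency import annual_total
from .panel_model import CountryConfig, Panel

__all__ = [
    "SurveyBenchmark",
    "ExternalConsistencyEstimate",
    "estimate_total_births",
    "hmis_csection_rate",
    "sensitivity_interval",
    "compare_to_survey",
    "assess_external_consistency",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurveyBenchmark:
    """Pre-extracted survey estimates used as the gold standard.

    ``scope_note`` records what population the rates describe (national,
    one province, public-sector facilities only, ...); the caller must
    supply rates scope-matched to the HMIS extract — e.g. a
    public-facility delivery rate when the HMIS covers only public
    facilities.
    """

    survey_label: str
    facility_delivery_rate: float  # proportion of births in facilities, (0, 1]
    csection_rate: float  # population c-section proportion, [0, 1)
    n_births_surveyed: int | None = None
    scope_note: str = "national"

    def __post_init__(self) -> None:
        if not 0 < self.facility_delivery_rate <= 1:
            raise ConfigError("facility_delivery_rate must lie in (0, 1]")
        if not 0 <= self.csection_rate < 1:
            raise ConfigError("csection_rate must lie in [0, 1)")
        if not self.survey_label:
            raise ConfigError("survey_label is required (provenance of the benchmark)")
        if self.csection_rate > self.facility_delivery_rate:
            logger.warning(
                "survey c-section rate (%.3f) exceeds facility delivery rate "
                "(%.3f); c-sections outside facilities are implausible",
                self.csection_rate,
                self.facility_delivery_rate,
            )


@dataclass
class ExternalConsistencyEstimate:
    hmis_deliveries: int
    hmis_csections: int
    estimated_births: float
    hmis_csection_rate: float  # percent
    survey_csection_rate: float  # percent
    diff_pp: float  # HMIS minus survey, percentage points
    sensitivity_interval: tuple[float, float]  # (low %, high %)
    p_value: float | None
    survey_label: str


def estimate_total_births(
    hmis_deliveries: float, facility_delivery_rate: float
) -> float:
    """Total births implied by HMIS deliveries and the survey delivery rate."""
    if not 0 < facility_delivery_rate <= 1:
        raise ConfigError("facility_delivery_rate must lie in (0, 1]")
    if hmis_deliveries < 0:
        raise ConfigError("hmis_deliveries must be non-negative")
    return hmis_deliveries / facility_delivery_rate


def hmis_csection_rate(hmis_csections: float, births: float) -> float:
    """Population c-section rate (percent) implied by HMIS counts."""
    if births <= 0:
        raise ConfigError("births must be positive")
    return 100.0 * hmis_csections / births


def sensitivity_interval(
    hmis_deliveries: float,
    hmis_csections: float,
    facility_delivery_rate: float,
    delta_pp: float = 3.0,
) -> tuple[float, float]:
    """C-section rate recomputed at the delivery rate -/+ ``delta_pp``.

    Returns (low %, high %).  Since births = deliveries / rate, raising
    the delivery rate lowers estimated births and raises the c-section
    rate: the -delta arm is the low end, the +delta arm the high end.
    Perturbed rates are clipped into (0, 1] with a warning.
    """
    delta = delta_pp / 100.0
    arms = []
    for sign in (-1.0, +1.0):
        rate = facility_delivery_rate + sign * delta
        clipped = min(max(rate, 1e-9), 1.0)
        if clipped != rate:
            logger.warning(
                "perturbed facility delivery rate %.4f clipped to %.4f", rate, clipped
            )
        arms.append(
            hmis_csection_rate(
                hmis_csections, estimate_total_births(hmis_deliveries, clipped)
            )
        )
    low, high = sorted(arms)
    return low, high


def compare_to_survey(
    hmis_rate_pct: float,
    estimated_births: float,
    hmis_csections: float,
    benchmark: SurveyBenchmark,
) -> tuple[float, float | None]:
    """Difference (pp) from the survey rate and a two-sided proportion test.

    The test is the standard large-sample two-sample z-test for
    proportions, with the estimated births and the survey's birth sample
    size as denominators.  Without a survey sample size the difference
    is still reported but the p-value is None.
    """
    survey_pct = 100.0 * benchmark.csection_rate
    diff = hmis_rate_pct - survey_pct
    if benchmark.n_births_surveyed is None:
        logger.info("no survey sample size supplied; proportion test skipped")
        return diff, None
    n_hmis = max(int(round(estimated_births)), 1)
    n_survey = int(benchmark.n_births_surveyed)
    counts = np.array([hmis_csections, benchmark.csection_rate * n_survey])
    nobs = np.array([n_hmis, n_survey])
    if counts.sum() == 0 or (counts == nobs).all():
        return diff, 1.0 if diff == 0 else None
    _, p = proportions_ztest(counts, nobs, alternative="two-sided")
    return diff, float(p)


def assess_external_consistency(
    panel: Panel,
    benchmark: SurveyBenchmark,
    config: CountryConfig,
) -> ExternalConsistencyEstimate | None:
    """Full triangulation from a panel's reference-year totals.

    Requires the config's deliveries and c-section indicators to be
    present in the panel; returns None (with a logged reason) otherwise.
    The c-section panel should already have passed the non-provider
    exclusion rule.
    """
    needed = (config.deliveries_id, config.csection_id)
    if any(ind is None or ind not in panel.indicator_ids for ind in needed):
        logger.warning(
            "%s: deliveries/c-section indicators unavailable; external "
            "consistency skipped",
            config.country_label,
        )
        return None
    months = config.reference_year_months
    deliveries = annual_total(panel, config.deliveries_id, months)
    csections = annual_total(panel, config.csection_id, months)
    births = estimate_total_births(deliveries, benchmark.facility_delivery_rate)
    rate = hmis_csection_rate(csections, births)
    interval = sensitivity_interval(
        deliveries,
        csections,
        benchmark.facility_delivery_rate,
        config.sensitivity_delta_pp,
    )
    diff, p = compare_to_survey(rate, births, csections, benchmark)
    return ExternalConsistencyEstimate(
        hmis_deliveries=deliveries,
        hmis_csections=csections,
        estimated_births=births,
        hmis_csection_rate=rate,
        survey_csection_rate=100.0 * benchmark.csection_rate,
        diff_pp=diff,
        sensitivity_interval=interval,
        p_value=p,
        survey_label=benchmark.survey_label,
    )
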