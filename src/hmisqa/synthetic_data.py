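"""Synthetic facility-month panel generator with known ground truth.

Country extracts of routine health data are held by ministries of health
and are rarely public, so every stage of the assessment pipeline is
exercised against generated panels that emulate their structure:

* 24 monthly observations per reporting unit, with per-period reporting
  probabilities that may shift at the pandemic boundary;
* non-negative service counts with unit-specific scale (lognormal
  across units) and Poisson or negative-binomial month-to-month noise,
  optionally damped by a pandemic volume multiplier;
* institutional death counts as binomial thinnings of their linked
  service counts, reported only in months where the service was
  reported, with optional zero-as-missing corruption reproducing the
  0-vs-blank ambiguity of real systems;
* a five-antigen infant vaccine series sharing a per-unit monthly birth
  cohort, with small per-antigen completion differences;
* a maternity block (catchment births -> facility deliveries and
  c-sections) whose realized totals define the survey truth used by the
  external-consistency stage, including non-provider units that report
  structural zeros for c-sections;
* rare planted high/low spikes of stated magnitude (in SD units).

Counts are generated first (including planted spikes), corruption
(missingness, zero-as-missing) second, in a fixed order; the emitted
:class:`GroundTruth` refers to pre-corruption counts.  One seeded
substream per indicator keeps draws independent of which other
indicators are configured.  Identical (seed, config) give a
byte-identical panel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import stable_stream_key
from .errors import ConfigError
from .external_consistency import SurveyBenchmark
from .internal_consistency import VaccineMap
from .panel_model import (
    CountryConfig,
    IndicatorMeta,
    IndicatorRegistry,
    Panel,
    PeriodSplit,
)

__all__ = [
    "ServiceSpec",
    "DeathSpec",
    "VaccineSpec",
    "MaternitySpec",
    "GeneratorConfig",
    "GroundTruth",
    "generate_panel",
    "make_registry",
    "generate_survey_benchmark",
    "default_vaccine_map",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ServiceSpec:
    """Volume model of one service indicator.

    ``mean_volume`` is the mean monthly count across units; unit scales
    are lognormal around it with spread ``unit_scale_sigma``.  Month
    noise is Poisson, or negative-binomial when ``dispersion`` (the NB
    size parameter; smaller = more overdispersed) is given.
    """

    indicator_id: str
    mean_volume: float = 100.0
    unit_scale_sigma: float = 0.5
    dispersion: float | None = None
    domain: str = "other"


@dataclass(frozen=True)
class DeathSpec:
    """Institutional deaths as a binomial thinning of a linked service."""

    indicator_id: str
    linked_service_id: str
    death_prob: float = 0.01


@dataclass(frozen=True)
class VaccineSpec:
    """Infant vaccine series sharing one per-unit monthly birth cohort.

    ``completion_probs`` maps antigen indicator id to the probability
    that a cohort child receives that (final) dose; small differences
    between antigens produce the near-100% anchor ratios seen in real
    systems.
    """

    cohort_mean: float = 40.0
    cohort_sigma: float = 0.5
    completion_probs: dict[str, float] = field(
        default_factory=lambda: {
            "bcg": 0.95,
            "penta3": 0.90,
            "pneumococcal3": 0.89,
            "oral_polio3": 0.88,
            "rotavirus2": 0.87,
        }
    )
    anchor_id: str = "penta3"


@dataclass(frozen=True)
class MaternitySpec:
    """Catchment births feeding deliveries and c-sections.

    Each unit's catchment produces Poisson monthly births.  A mother
    needing a c-section always delivers in a facility and every
    c-section is recorded, so the deliveries indicator is the c-sections
    plus a binomial share of the remaining births that brings the
    overall facility-delivery proportion to ``facility_delivery_prop``.
    Only a ``provider_frac`` share of units performs c-sections; the
    rest report structural zeros for the indicator (exercising the
    non-provider exclusion rule).
    """

    births_mean: float = 60.0
    births_sigma: float = 0.5
    facility_delivery_prop: float = 0.60
    csection_prop: float = 0.05
    provider_frac: float = 0.3
    deliveries_id: str = "deliveries"
    csection_id: str = "csection"


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic country panel."""

    n_units: int = 100
    T: int = 24
    seed: int = 0
    period_split: PeriodSplit | None = None  # default split for T
    reporting_prob_pre: float = 0.95
    reporting_prob_pandemic: float = 0.95
    reporting_prob_overrides: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )
    pandemic_volume_multiplier: float = 0.9
    outlier_rate: float = 0.002
    outlier_magnitude_sd: float = 8.0
    outlier_pos_frac: float = 0.5
    zero_as_missing_rate: float = 0.0
    unit_level: str = "facility"
    services: tuple[ServiceSpec, ...] = (
        ServiceSpec("outpatient_visits", mean_volume=400.0, domain="other"),
        ServiceSpec("anc_visits", mean_volume=80.0, domain="RMNH"),
        ServiceSpec("inpatient_visits", mean_volume=120.0, domain="other"),
    )
    deaths: tuple[DeathSpec, ...] = (
        DeathSpec("inpatient_deaths", "inpatient_visits", death_prob=0.02),
        DeathSpec("maternal_deaths", "deliveries", death_prob=0.003),
        DeathSpec("stillbirths", "deliveries", death_prob=0.015),
        DeathSpec("newborn_deaths", "deliveries", death_prob=0.01),
    )
    vaccines: VaccineSpec | None = field(default_factory=VaccineSpec)
    maternity: MaternitySpec | None = field(default_factory=MaternitySpec)
    reference_year_months: tuple[int, ...] = tuple(range(1, 13))

    def __post_init__(self) -> None:
        probs = [
            self.reporting_prob_pre,
            self.reporting_prob_pandemic,
            self.outlier_rate,
            self.outlier_pos_frac,
            self.zero_as_missing_rate,
        ]
        probs += [p for pair in self.reporting_prob_overrides.values() for p in pair]
        if self.maternity is not None:
            probs += [
                self.maternity.facility_delivery_prop,
                self.maternity.csection_prop,
                self.maternity.provider_frac,
            ]
        if self.vaccines is not None:
            probs += list(self.vaccines.completion_probs.values())
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if self.outlier_magnitude_sd <= 0:
            raise ConfigError("outlier magnitude must be positive")
        if self.n_units < 1 or self.T < 2:
            raise ConfigError("need at least one unit and two months")
        for d in self.deaths:
            known = {s.indicator_id for s in self.services}
            if self.maternity is not None:
                known |= {self.maternity.deliveries_id}
            if d.linked_service_id not in known:
                raise ConfigError(
                    f"death indicator {d.indicator_id!r} links to "
                    f"unconfigured service {d.linked_service_id!r}"
                )

    @property
    def split(self) -> PeriodSplit:
        return self.period_split or PeriodSplit.default(self.T)

    def reporting_probs(self, indicator_id: str) -> tuple[float, float]:
        return self.reporting_prob_overrides.get(
            indicator_id, (self.reporting_prob_pre, self.reporting_prob_pandemic)
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Pre-corruption facts about a generated panel."""

    seed: int
    reporting_probs: dict[str, tuple[float, float]]
    realized_completeness: dict[str, tuple[float, float]]  # (pre %, pandemic %)
    planted_outliers: pd.DataFrame  # indicator_id, unit_id, month_index, direction
    vaccine_totals: dict[str, int]  # reference-year totals per antigen
    true_births: int
    true_facility_deliveries: int
    true_csections: int
    facility_delivery_rate: float  # realized, reference year
    csection_rate: float  # realized population proportion, reference year


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _stream(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, stable_stream_key(label)])


def _unit_scales(
    rng: np.random.Generator, n: int, mean: float, sigma: float
) -> np.ndarray:
    """Lognormal unit scales with the requested arithmetic mean."""
    return mean * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))


def _plant_spikes(
    rng: np.random.Generator,
    counts: np.ndarray,
    rate: float,
    magnitude: float,
    pos_frac: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Replace a random sparse set of cells with mean +/- magnitude*SD spikes.

    SD is the unit's own sample SD before planting; rows with zero
    variance are skipped.  Returns (counts, unit_idx, month_idx, direction).
    """
    if rate == 0.0:
        empty = np.empty(0, dtype=int)
        return counts, empty, empty, empty
    mean = counts.mean(axis=1, keepdims=True)
    sd = counts.std(axis=1, ddof=1, keepdims=True)
    hit = rng.random(counts.shape) < rate
    positive = rng.random(counts.shape) < pos_frac
    hit &= sd > 0
    counts = counts.copy()
    spikes = np.where(
        positive, mean + magnitude * sd, np.maximum(mean - magnitude * sd, 0.0)
    )
    counts[hit] = np.rint(spikes[hit]).astype(counts.dtype)
    ui, mi = np.nonzero(hit)
    direction = np.where(positive[ui, mi], 1, -1)
    return counts, ui, mi, direction


def _period_prob_row(config: GeneratorConfig, indicator_id: str) -> np.ndarray:
    p_pre, p_pand = config.reporting_probs(indicator_id)
    probs = np.empty(config.T)
    probs[np.array(config.split.pre_months) - 1] = p_pre
    probs[np.array(config.split.pandemic_months) - 1] = p_pand
    return probs


def _realized_completeness(
    mask: np.ndarray, split: PeriodSplit
) -> tuple[float, float]:
    """Mean monthly completeness per period from a reporting mask, using
    the max-month denominator rule (NaN-pair when nothing reported)."""
    reporters = mask.sum(axis=0)
    denom = reporters.max()
    if denom == 0:
        return float("nan"), float("nan")
    pct = 100.0 * reporters / denom
    pre = np.array(split.pre_months) - 1
    pand = np.array(split.pandemic_months) - 1
    return float(pct[pre].mean()), float(pct[pand].mean())


def generate_panel(config: GeneratorConfig) -> tuple[Panel, GroundTruth]:
    """Generate one panel and its ground truth.

    Deterministic in (seed, config); each indicator consumes its own
    named substream so the draw sequence of one indicator is unaffected
    by adding or removing others.
    """
    n, T = config.n_units, config.T
    seed = config.seed
    split = config.split
    unit_ids = np.array([f"u{i + 1:04d}" for i in range(n)])
    pandemic_cols = np.array(config.split.pandemic_months) - 1
    mult = np.ones(T)
    mult[pandemic_cols] = config.pandemic_volume_multiplier

    counts_by_ind: dict[str, np.ndarray] = {}
    mask_by_ind: dict[str, np.ndarray] = {}
    planted_records: list[pd.DataFrame] = []

    def plant_and_mask(
        ind: str, counts: np.ndarray, rng: np.random.Generator,
        force_report: np.ndarray | None = None,
    ) -> None:
        """Shared tail of every indicator: spikes, reporting, corruption."""
        counts, ui, mi, direction = _plant_spikes(
            rng, counts, config.outlier_rate,
            config.outlier_magnitude_sd, config.outlier_pos_frac,
        )
        if len(ui):
            planted_records.append(
                pd.DataFrame(
                    {
                        "indicator_id": ind,
                        "unit_id": unit_ids[ui],
                        "month_index": mi + 1,
                        "direction": direction,
                    }
                )
            )
        probs = _period_prob_row(config, ind)
        mask = rng.random((n, T)) < probs[None, :]
        if force_report is not None:
            mask &= force_report
        if config.zero_as_missing_rate > 0:
            corrupt = (counts == 0) & (
                rng.random((n, T)) < config.zero_as_missing_rate
            )
            mask &= ~corrupt
        counts_by_ind[ind] = counts
        mask_by_ind[ind] = mask

    # --- plain services ----------------------------------------------------
    for spec in config.services:
        rng = _stream(seed, spec.indicator_id)
        scales = _unit_scales(rng, n, spec.mean_volume, spec.unit_scale_sigma)
        lam = scales[:, None] * mult[None, :]
        if spec.dispersion is not None:
            lam = rng.gamma(spec.dispersion, lam / spec.dispersion)
        counts = rng.poisson(lam)
        plant_and_mask(spec.indicator_id, counts, rng)

    # --- maternity block ---------------------------------------------------
    true_births = np.zeros((n, T), dtype=np.int64)
    if config.maternity is not None:
        mat = config.maternity
        rng = _stream(seed, "__maternity__")
        scales = _unit_scales(rng, n, mat.births_mean, mat.births_sigma)
        true_births = rng.poisson(scales[:, None] * mult[None, :])
        provider = rng.random(n) < mat.provider_frac
        if not provider.any():
            provider[0] = True  # at least one surgical facility
        csections = np.where(
            provider[:, None], rng.binomial(true_births, mat.csection_prop), 0
        )
        # Facility deliveries = c-sections (always in-facility) plus a
        # share of the remaining births matching the overall proportion.
        p_extra = (
            (mat.facility_delivery_prop - mat.csection_prop)
            / (1.0 - mat.csection_prop)
            if mat.csection_prop < 1.0
            else 0.0
        )
        deliveries = csections + rng.binomial(true_births - csections, max(p_extra, 0.0))
        plant_and_mask(mat.deliveries_id, deliveries, _stream(seed, mat.deliveries_id))
        # c-section spikes are not planted: non-provider rows are
        # structural zeros and provider series feed a rate, not a screen.
        cs_rng = _stream(seed, mat.csection_id)
        probs = _period_prob_row(config, mat.csection_id)
        cs_mask = cs_rng.random((n, T)) < probs[None, :]
        if config.zero_as_missing_rate > 0:
            corrupt = (csections == 0) & (
                cs_rng.random((n, T)) < config.zero_as_missing_rate
            )
            cs_mask &= ~corrupt
        counts_by_ind[mat.csection_id] = csections
        mask_by_ind[mat.csection_id] = cs_mask

    # --- vaccines ----------------------------------------------------------
    vaccine_totals: dict[str, int] = {}
    if config.vaccines is not None:
        vac = config.vaccines
        rng = _stream(seed, "__vaccine_cohort__")
        scales = _unit_scales(rng, n, vac.cohort_mean, vac.cohort_sigma)
        cohort = rng.poisson(np.broadcast_to(scales[:, None], (n, T)))
        ref_cols = np.array(config.reference_year_months) - 1
        for antigen in sorted(vac.completion_probs):
            arng = _stream(seed, antigen)
            counts = arng.binomial(cohort, vac.completion_probs[antigen])
            vaccine_totals[antigen] = int(counts[:, ref_cols].sum())
            plant_and_mask(antigen, counts, arng)

    # --- deaths (need their linked service's counts and mask) --------------
    for spec in config.deaths:
        link = spec.linked_service_id
        if link not in counts_by_ind:
            continue
        rng = _stream(seed, spec.indicator_id)
        counts = rng.binomial(counts_by_ind[link], spec.death_prob)
        # Deaths ride the service report: reported exactly in months
        # where the linked service was reported.
        mask = mask_by_ind[link].copy()
        if config.zero_as_missing_rate > 0:
            corrupt = (counts == 0) & (
                rng.random((n, T)) < config.zero_as_missing_rate
            )
            mask &= ~corrupt
        counts_by_ind[spec.indicator_id] = counts
        mask_by_ind[spec.indicator_id] = mask

    # --- assemble ----------------------------------------------------------
    frames = []
    for ind in counts_by_ind:
        values = counts_by_ind[ind].astype(float)
        values[~mask_by_ind[ind]] = np.nan
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": np.repeat(unit_ids, T),
                    "unit_level": config.unit_level,
                    "indicator_id": ind,
                    "month_index": np.tile(np.arange(1, T + 1), n),
                    "value": values.ravel(),
                }
            )
        )
    panel = Panel(pd.concat(frames, ignore_index=True), T=T)

    # --- ground truth ------------------------------------------------------
    ref_cols = np.array(config.reference_year_months) - 1
    if config.maternity is not None:
        births_total = int(true_births[:, ref_cols].sum())
        deliveries_total = int(
            counts_by_ind[config.maternity.deliveries_id][:, ref_cols].sum()
        )
        cs_total = int(counts_by_ind[config.maternity.csection_id][:, ref_cols].sum())
    else:
        births_total = deliveries_total = cs_total = 0

    planted = (
        pd.concat(planted_records, ignore_index=True)
        if planted_records
        else pd.DataFrame(columns=["indicator_id", "unit_id", "month_index", "direction"])
    )
    truth = GroundTruth(
        seed=seed,
        reporting_probs={ind: config.reporting_probs(ind) for ind in counts_by_ind},
        realized_completeness={
            ind: _realized_completeness(mask_by_ind[ind], split)
            for ind in counts_by_ind
        },
        planted_outliers=planted,
        vaccine_totals=vaccine_totals,
        true_births=births_total,
        true_facility_deliveries=deliveries_total,
        true_csections=cs_total,
        facility_delivery_rate=(
            deliveries_total / births_total if births_total else float("nan")
        ),
        csection_rate=cs_total / births_total if births_total else float("nan"),
    )
    return panel, truth


def make_registry(config: GeneratorConfig) -> IndicatorRegistry:
    """Registry matching a generator configuration."""
    metas = [
        IndicatorMeta(s.indicator_id, domain=s.domain) for s in config.services
    ]
    if config.maternity is not None:
        metas.append(IndicatorMeta(config.maternity.deliveries_id, domain="RMNH"))
        metas.append(IndicatorMeta(config.maternity.csection_id, domain="RMNH"))
    if config.vaccines is not None:
        metas.extend(
            IndicatorMeta(a, domain="child") for a in sorted(config.vaccines.completion_probs)
        )
    known = {m.indicator_id for m in metas}
    for d in config.deaths:
        if d.linked_service_id in known:
            metas.append(
                IndicatorMeta(
                    d.indicator_id,
                    domain="deaths",
                    kind="death",
                    linked_service_id=d.linked_service_id,
                )
            )
    return IndicatorRegistry(metas)


def default_vaccine_map(config: GeneratorConfig) -> VaccineMap | None:
    """Vaccine role map for a generated panel (None without vaccines)."""
    if config.vaccines is None:
        return None
    comparators = {
        a: a for a in config.vaccines.completion_probs if a != config.vaccines.anchor_id
    }
    return VaccineMap(anchor_id=config.vaccines.anchor_id, comparators=comparators)


def generate_survey_benchmark(
    truth: GroundTruth,
    bias_fdr_pp: float = 0.0,
    bias_csection_pp: float = 0.0,
    n_births_surveyed: int | None = None,
    survey_label: str = "synthetic household survey",
) -> SurveyBenchmark:
    """Survey benchmark equal to the generator's realized truth.

    Optional biases (percentage points) perturb the facility-delivery
    rate or the c-section rate, for probing the sensitivity of the
    external-consistency comparison.
    """
    return SurveyBenchmark(
        survey_label=survey_label,
        facility_delivery_rate=truth.facility_delivery_rate + bias_fdr_pp / 100.0,
        csection_rate=truth.csection_rate + bias_csection_pp / 100.0,
        n_births_surveyed=n_births_surveyed,
        scope_note="synthetic catchment population",
    )
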