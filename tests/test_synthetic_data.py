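"""Generator determinism, closed-loop recovery and ground-truth coherence."""

import numpy as np
import pandas as pd
import pytest

from hmisqa import (
    CountryConfig,
    DeathSpec,
    GeneratorConfig,
    MaternitySpec,
    ServiceSpec,
    completeness_series,
    default_vaccine_map,
    generate_panel,
    generate_survey_benchmark,
    impute_death_zeros,
    make_registry,
)
from hmisqa.errors import ConfigError
from hmisqa.internal_consistency import annual_total


def test_identical_seed_and_config_give_identical_output():
    gen = GeneratorConfig(n_units=25, seed=42)
    p1, t1 = generate_panel(gen)
    p2, t2 = generate_panel(gen)
    assert p1.equals(p2)
    assert t1.vaccine_totals == t2.vaccine_totals
    pd.testing.assert_frame_equal(t1.planted_outliers, t2.planted_outliers)
    p3, _ = generate_panel(GeneratorConfig(n_units=25, seed=43))
    assert not p1.equals(p3)


def test_indicator_substreams_stable_under_added_services():
    """Adding a service must not perturb the draws of existing indicators."""
    base = GeneratorConfig(n_units=15, seed=5)
    extended = GeneratorConfig(
        n_units=15,
        seed=5,
        services=base.services + (ServiceSpec("tb_screening", mean_volume=30.0),),
    )
    p1, _ = generate_panel(base)
    p2, _ = generate_panel(extended)
    for ind in p1.indicator_ids:
        pd.testing.assert_frame_equal(
            p1.indicator(ind).reset_index(drop=True),
            p2.indicator(ind).reset_index(drop=True),
        )


def test_full_reporting_no_planting_gives_100pct_completeness_everywhere():
    # c-section non-providers report structural zeros, which is a
    # reporting pattern rather than missingness, so they too score 100%.
    gen = GeneratorConfig(
        n_units=20,
        seed=3,
        reporting_prob_pre=1.0,
        reporting_prob_pandemic=1.0,
        outlier_rate=0.0,
    )
    panel, truth = generate_panel(gen)
    for ind in panel.indicator_ids:
        series = completeness_series(panel, ind)
        assert (series == 100.0).all(), ind
        assert truth.realized_completeness[ind] == (100.0, 100.0)


def test_vaccine_totals_match_exhaustive_panel_sums_under_full_reporting():
    gen = GeneratorConfig(
        n_units=30, seed=9, reporting_prob_pre=1.0, reporting_prob_pandemic=1.0,
        outlier_rate=0.0,
    )
    panel, truth = generate_panel(gen)
    for antigen, total in truth.vaccine_totals.items():
        assert annual_total(panel, antigen, gen.reference_year_months) == total


def test_planted_outliers_are_recorded_with_valid_locations(generated):
    gen, panel, truth = generated
    planted = truth.planted_outliers
    assert set(planted["direction"].unique()) <= {1, -1}
    assert planted["month_index"].between(1, gen.T).all()
    assert set(planted["indicator_id"]) <= set(panel.indicator_ids)
    # Planting replaces counts, so every visible planted cell is non-missing
    merged = planted.merge(
        panel.data, on=["indicator_id", "unit_id", "month_index"], how="left"
    )
    assert len(merged) == len(planted)


def test_deaths_reported_exactly_where_linked_service_reported(generated):
    gen, panel, _ = generated
    svc = panel.matrix("inpatient_visits")
    death = panel.matrix("inpatient_deaths")
    # zero_as_missing_rate is 0 by default, so the masks coincide exactly
    assert (svc.isna() == death.isna()).all().all()


def test_zero_as_missing_corruption_hits_only_zero_cells():
    base = GeneratorConfig(
        n_units=40, seed=6, reporting_prob_pre=1.0, reporting_prob_pandemic=1.0,
        outlier_rate=0.0,
    )
    corrupted_cfg = GeneratorConfig(
        n_units=40, seed=6, reporting_prob_pre=1.0, reporting_prob_pandemic=1.0,
        outlier_rate=0.0, zero_as_missing_rate=0.8,
    )
    clean, _ = generate_panel(base)
    corrupted, _ = generate_panel(corrupted_cfg)
    newly_missing = corrupted.data["value"].isna() & clean.data["value"].notna()
    assert newly_missing.any()
    assert (clean.data.loc[newly_missing, "value"] == 0).all()


def test_imputation_recovers_corrupted_death_zeros():
    """The zero-as-missing ambiguity the generator plants is exactly what
    the death imputation rule repairs when the linked service reported."""
    gen = GeneratorConfig(
        n_units=40, seed=6, reporting_prob_pre=1.0, reporting_prob_pandemic=1.0,
        outlier_rate=0.0, zero_as_missing_rate=0.8,
    )
    panel, _ = generate_panel(gen)
    registry = make_registry(gen)
    death_ids = [m.indicator_id for m in registry.death_indicators()]
    assert panel.data[
        panel.data["indicator_id"].isin(death_ids)
    ]["value"].isna().any()
    repaired, log = impute_death_zeros(panel, registry)
    # services reported everywhere with positive volumes, so all death
    # blanks are imputable
    death_rows = repaired.data["indicator_id"].isin(death_ids)
    still_missing = repaired.data.loc[death_rows, "value"].isna().sum()
    assert log.n_changed > 0
    # remaining blanks can only sit where the linked service count was 0
    svc0 = {
        m.indicator_id: panel.matrix(m.linked_service_id).eq(0)
        for m in registry.death_indicators()
    }
    assert still_missing <= sum(v.to_numpy().sum() for v in svc0.values())


def test_survey_benchmark_equals_realized_truth_and_biases_shift_it(generated):
    _, _, truth = generated
    bench = generate_survey_benchmark(truth)
    assert bench.facility_delivery_rate == pytest.approx(truth.facility_delivery_rate)
    assert bench.csection_rate == pytest.approx(truth.csection_rate)
    biased = generate_survey_benchmark(truth, bias_fdr_pp=3.0, bias_csection_pp=1.0)
    assert biased.facility_delivery_rate == pytest.approx(
        truth.facility_delivery_rate + 0.03
    )
    assert biased.csection_rate == pytest.approx(truth.csection_rate + 0.01)


def test_registry_matches_generated_panel(generated):
    gen, panel, _ = generated
    registry = make_registry(gen)
    assert set(panel.indicator_ids) == set(registry.ids)
    for meta in registry.death_indicators():
        assert meta.linked_service_id in registry


def test_infeasible_configs_rejected():
    with pytest.raises(ConfigError):
        GeneratorConfig(reporting_prob_pre=1.2)
    with pytest.raises(ConfigError):
        GeneratorConfig(outlier_magnitude_sd=0.0)
    with pytest.raises(ConfigError):
        # death indicator linking to an unconfigured service
        GeneratorConfig(deaths=(DeathSpec("x_deaths", "no_such_service"),))


def test_maternity_truth_is_internally_coherent(generated):
    _, _, truth = generated
    assert truth.true_csections <= truth.true_facility_deliveries
    assert truth.true_facility_deliveries <= truth.true_births
    assert truth.facility_delivery_rate == pytest.approx(
        truth.true_facility_deliveries / truth.true_births
    )
    assert truth.csection_rate == pytest.approx(
        truth.true_csections / truth.true_births
    )
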