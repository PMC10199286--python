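"""Contracts of the two cleaning rules: death zero-imputation and
c-section non-provider exclusion."""

import numpy as np
import pandas as pd
import pytest

from hmisqa import (
    IndicatorMeta,
    IndicatorRegistry,
    Panel,
    exclude_nonproviding_csection_units,
    impute_death_zeros,
)

from conftest import build_panel


@pytest.fixture()
def registry():
    return IndicatorRegistry(
        [
            IndicatorMeta("deliveries", domain="RMNH"),
            IndicatorMeta(
                "maternal_deaths",
                domain="deaths",
                kind="death",
                linked_service_id="deliveries",
            ),
            IndicatorMeta("orphan_deaths", domain="deaths", kind="death"),
        ]
    )


def _value(panel, unit, ind, month):
    sub = panel.indicator(ind)
    return sub[(sub["unit_id"] == unit) & (sub["month_index"] == month)][
        "value"
    ].iloc[0]


class TestImputeDeathZeros:
    def test_missing_death_with_provided_service_becomes_zero(self, registry):
        panel = build_panel(
            [("u", "deliveries", 1, 14), ("u", "maternal_deaths", 1, None)]
        )
        out, log = impute_death_zeros(panel, registry)
        assert _value(out, "u", "maternal_deaths", 1) == 0
        assert log.per_indicator == {"maternal_deaths": 1}

    def test_missing_service_leaves_death_missing(self, registry):
        panel = build_panel(
            [("u", "deliveries", 1, None), ("u", "maternal_deaths", 1, None)]
        )
        out, log = impute_death_zeros(panel, registry)
        assert np.isnan(_value(out, "u", "maternal_deaths", 1))
        assert log.n_changed == 0

    def test_reported_death_never_altered(self, registry):
        panel = build_panel(
            [("u", "deliveries", 1, None), ("u", "maternal_deaths", 1, 2)]
        )
        out, _ = impute_death_zeros(panel, registry)
        assert _value(out, "u", "maternal_deaths", 1) == 2

    def test_zero_service_imputes_only_in_strict_mode(self, registry):
        panel = build_panel(
            [("u", "deliveries", 1, 0), ("u", "maternal_deaths", 1, None)]
        )
        out, _ = impute_death_zeros(panel, registry)
        assert np.isnan(_value(out, "u", "maternal_deaths", 1))
        strict, _ = impute_death_zeros(panel, registry, strict=True)
        assert _value(strict, "u", "maternal_deaths", 1) == 0

    def test_death_without_link_never_imputed(self, registry):
        panel = build_panel(
            [("u", "deliveries", 1, 5), ("u", "orphan_deaths", 1, None)]
        )
        out, _ = impute_death_zeros(panel, registry)
        assert np.isnan(_value(out, "u", "orphan_deaths", 1))


class TestCsectionExclusion:
    def test_all_zero_or_missing_unit_fully_blanked(self):
        cells = [("u", "csection", m, 0 if m % 3 else None) for m in range(1, 25)]
        panel = build_panel(cells)
        out, log = exclude_nonproviding_csection_units(panel, "csection")
        assert out.indicator("csection")["value"].isna().all()
        assert log.excluded_units == ["u"]

    def test_single_positive_month_keeps_unit(self):
        cells = [("u", "csection", m, 3 if m == 5 else 0) for m in range(1, 25)]
        panel = build_panel(cells)
        out, log = exclude_nonproviding_csection_units(panel, "csection")
        assert out.equals(panel)
        assert log.excluded_units == []

    def test_all_missing_unit_flagged_excluded(self):
        cells = [("u", "csection", m, None) for m in range(1, 25)]
        panel = build_panel(cells)
        out, log = exclude_nonproviding_csection_units(panel, "csection")
        assert out.indicator("csection")["value"].isna().all()
        assert log.excluded_units == ["u"]
        assert log.n_changed == 0  # nothing was reported to blank

    def test_other_indicators_untouched(self):
        cells = [("u", "csection", m, 0) for m in range(1, 25)]
        cells += [("u", "deliveries", m, 10) for m in range(1, 25)]
        panel = build_panel(cells)
        out, _ = exclude_nonproviding_csection_units(panel, "csection")
        assert (out.indicator("deliveries")["value"] == 10).all()

    def test_absent_indicator_is_noop(self):
        panel = build_panel([("u", "deliveries", 1, 10)])
        out, log = exclude_nonproviding_csection_units(panel, "csection")
        assert out.equals(panel)
        assert any("no-op" in n for n in log.notes)


def _random_panel(rng) -> Panel:
    """Small randomized panel with services, linked deaths and c-sections."""
    T = 6
    n_units = rng.integers(2, 5)
    units = [f"u{i}" for i in range(n_units)]
    rows = []
    for u in units:
        for m in range(1, T + 1):
            svc = rng.choice([np.nan, 0.0, float(rng.integers(0, 30))])
            death = rng.choice([np.nan, 0.0, float(rng.integers(0, 3))])
            cs = rng.choice([np.nan, 0.0, float(rng.integers(0, 4))], p=[0.3, 0.5, 0.2])
            rows += [
                ("%s" % u, "deliveries", m, svc),
                (u, "maternal_deaths", m, death),
                (u, "csection", m, cs),
            ]
    return build_panel(rows, T=T)


def test_cleaning_rules_idempotent_and_nondestructive_on_random_panels(registry):
    """Both rules are idempotent, keep the key set fixed, and only ever
    convert missing->0 (imputation) or csection values->missing (exclusion)."""
    rng = np.random.default_rng(2024)
    for _ in range(60):
        panel = _random_panel(rng)
        keys = panel.data[["unit_id", "indicator_id", "month_index"]]

        once, _ = impute_death_zeros(panel, registry)
        twice, log2 = impute_death_zeros(once, registry)
        assert once.equals(twice) and log2.n_changed == 0

        # Imputation: non-missing values unchanged, services untouched.
        before, after = panel.data["value"], once.data["value"]
        changed = before.fillna(-1) != after.fillna(-1)
        assert (after[changed] == 0).all() and before[changed].isna().all()
        assert (
            panel.data.loc[changed, "indicator_id"] == "maternal_deaths"
        ).all()

        excl1, _ = exclude_nonproviding_csection_units(once, "csection")
        excl2, _ = exclude_nonproviding_csection_units(excl1, "csection")
        assert excl1.equals(excl2)

        # Exclusion: only csection cells change, and only towards missing.
        changed = once.data["value"].fillna(-1) != excl1.data["value"].fillna(-1)
        assert excl1.data.loc[changed, "value"].isna().all()
        assert (once.data.loc[changed, "indicator_id"] == "csection").all()

        assert excl1.data[["unit_id", "indicator_id", "month_index"]].equals(keys)
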