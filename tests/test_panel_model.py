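"""Panel container, ingest/round-trip, registry and config validation."""

import numpy as np
import pandas as pd
import pytest

from hmisqa import (
    CountryConfig,
    IndicatorMeta,
    IndicatorRegistry,
    Panel,
    PeriodSplit,
    read_panel,
    read_registry,
    write_panel,
)
from hmisqa.errors import ConfigError, PanelIntegrityError, PanelParseError

from conftest import build_panel


def _write(tmp_path, text, name="panel.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadPanel:
    def test_empty_cell_is_missing_and_zero_is_reported(self, tmp_path):
        path = _write(
            tmp_path,
            "unit_id,unit_level,indicator_id,month_index,value\n"
            "u1,facility,deliveries,1,10\n"
            "u1,facility,deliveries,2,\n"
            "u1,facility,deliveries,3,12\n"
            "u1,facility,deliveries,4,0\n",
        )
        panel = read_panel(path)
        vals = panel.indicator("deliveries").set_index("month_index")["value"]
        assert vals.loc[1] == 10 and vals.loc[3] == 12
        assert np.isnan(vals.loc[2])
        assert vals.loc[4] == 0  # reported zero, distinct from missing

    def test_duplicate_key_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            "unit_id,unit_level,indicator_id,month_index,value\n"
            "u1,facility,deliveries,1,10\n"
            "u1,facility,deliveries,1,11\n",
        )
        with pytest.raises(PanelIntegrityError, match="duplicate"):
            read_panel(path)

    def test_negative_value_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            "unit_id,unit_level,indicator_id,month_index,value\nu1,facility,x,1,-4\n",
        )
        with pytest.raises(PanelIntegrityError, match="negative"):
            read_panel(path)

    def test_malformed_value_names_row(self, tmp_path):
        path = _write(
            tmp_path,
            "unit_id,unit_level,indicator_id,month_index,value\n"
            "u1,facility,x,1,5\nu1,facility,x,2,five\n",
        )
        with pytest.raises(PanelParseError, match="row 3"):
            read_panel(path)

    def test_month_out_of_range_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            "unit_id,unit_level,indicator_id,month_index,value\nu1,facility,x,25,5\n",
        )
        with pytest.raises(PanelIntegrityError, match="month_index"):
            read_panel(path)

    def test_calendar_agnostic_schema_maps(self, tmp_path):
        """Two files labelling the same periods differently yield equal panels."""
        a = _write(
            tmp_path,
            "unit_id,unit_level,indicator_id,month_index,value\n"
            "u1,facility,x,1,5\nu1,facility,x,13,7\n",
            "a.csv",
        )
        b = _write(
            tmp_path,
            "site,level,ind,annee,mois,n\n"
            "u1,facility,x,2019,1,5\nu1,facility,x,2020,1,7\n",
            "b.csv",
        )
        pa = read_panel(a)
        pb = read_panel(
            b,
            schema={
                "unit_id": "site",
                "unit_level": "level",
                "indicator_id": "ind",
                "year": "annee",
                "month": "mois",
                "value": "n",
                "origin": (2019, 1),
            },
        )
        assert pa.equals(pb)

    def test_round_trip_preserves_values_and_missingness(self, tmp_path):
        panel = build_panel(
            [("u1", "x", 1, 4), ("u1", "x", 2, None), ("u2", "x", 1, 0)]
        )
        write_panel(panel, tmp_path / "rt.csv")
        again = read_panel(tmp_path / "rt.csv")
        assert panel.equals(again)


class TestRegistry:
    def test_death_with_valid_link(self):
        reg = IndicatorRegistry(
            [
                IndicatorMeta("inpatient_visits"),
                IndicatorMeta(
                    "inpatient_deaths",
                    domain="deaths",
                    kind="death",
                    linked_service_id="inpatient_visits",
                ),
            ]
        )
        assert reg.get("inpatient_deaths").linked_service_id == "inpatient_visits"
        assert [m.indicator_id for m in reg.death_indicators()] == ["inpatient_deaths"]

    def test_death_linking_absent_indicator_rejected(self):
        with pytest.raises(PanelIntegrityError, match="absent"):
            IndicatorRegistry(
                [
                    IndicatorMeta(
                        "maternal_deaths",
                        domain="deaths",
                        kind="death",
                        linked_service_id="deliveries",
                    )
                ]
            )

    def test_service_with_link_rejected(self):
        with pytest.raises(PanelIntegrityError):
            IndicatorMeta("x", kind="service", linked_service_id="y")

    def test_registry_file_round_trip(self, tmp_path):
        reg = IndicatorRegistry(
            [
                IndicatorMeta("deliveries", domain="RMNH"),
                IndicatorMeta(
                    "stillbirths",
                    domain="deaths",
                    kind="death",
                    linked_service_id="deliveries",
                ),
            ]
        )
        reg.to_file(tmp_path / "reg.yaml")
        again = read_registry(tmp_path / "reg.yaml")
        assert set(again.ids) == set(reg.ids)
        assert again.get("stillbirths").linked_service_id == "deliveries"


class TestPeriodSplitAndConfig:
    def test_default_and_nepal_boundaries(self):
        d = PeriodSplit.default()
        assert d.pre_months == tuple(range(1, 16))
        assert d.pandemic_months == tuple(range(16, 25))
        n = PeriodSplit.nepal()
        assert len(n.pre_months) == 14 and len(n.pandemic_months) == 10

    def test_overlapping_periods_rejected(self):
        with pytest.raises(ConfigError):
            PeriodSplit((1, 2, 3), (3, 4))

    def test_non_contiguous_cover_rejected(self):
        with pytest.raises(ConfigError):
            PeriodSplit((1, 2), (5, 6))

    def test_config_file_round_trip(self, tmp_path):
        cfg = CountryConfig(country_label="nepal", period_split=PeriodSplit.nepal())
        cfg.to_file(tmp_path / "cfg.yaml")
        again = CountryConfig.from_file(tmp_path / "cfg.yaml")
        assert again == cfg

    def test_invalid_settings_rejected(self):
        with pytest.raises(ConfigError):
            CountryConfig(outlier_z=0)
        with pytest.raises(ConfigError):
            CountryConfig(completeness_benchmarks=(0.0,))
        with pytest.raises(ConfigError):
            CountryConfig(reference_year_months=(0, 1))


def test_relabel_and_reorder_leave_panel_semantics_unchanged():
    cells = [("u1", "x", 1, 5), ("u2", "x", 1, None), ("u1", "x", 2, 3)]
    panel = build_panel(cells)
    shuffled = build_panel(list(reversed(cells)))
    assert panel.equals(shuffled)
    mat = panel.matrix("x")
    assert mat.loc["u1", 1] == 5 and np.isnan(mat.loc["u2", 1])
    assert mat.shape == (2, 24)
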