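"""End-to-end assessment: clean, then run all four quality metrics.

The orchestration mirrors how a data-quality review is actually run on
one country extract: cleaning rules first (death zero-imputation, then
c-section non-provider exclusion), then completeness, outlier screening,
internal consistency (only when a vaccine role map is supplied) and
external consistency (only when a survey benchmark is supplied).
Sections whose inputs are unavailable are skipped with a logged reason,
never a crash, so a partial extract still yields a partial report.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .cleaning import exclude_nonproviding_csection_units, impute_death_zeros
from .completeness import completeness_table
from .external_consistency import SurveyBenchmark, assess_external_consistency
from .internal_consistency import (
    VaccineMap,
    consistency_row,
    consistency_table,
    summarize_consistency,
)
from .outliers import outlier_table
from .panel_model import CountryConfig, IndicatorRegistry, Panel, read_panel, read_registry
from .report import AssessmentReport, write_report

__all__ = [
    "assess",
    "run_assessment",
    "read_benchmark",
    "read_vaccine_map",
]

logger = logging.getLogger(__name__)


def read_benchmark(path: str | Path) -> SurveyBenchmark:
    """Load a survey benchmark from a YAML key-value file."""
    with open(path) as fh:
        return SurveyBenchmark(**(yaml.safe_load(fh) or {}))


def read_vaccine_map(path: str | Path) -> VaccineMap:
    """Load a vaccine role map from a YAML key-value file."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    if "exclude_from_gap" in payload:
        payload["exclude_from_gap"] = tuple(payload["exclude_from_gap"])
    return VaccineMap(**payload)


def assess(
    panel: Panel,
    registry: IndicatorRegistry,
    config: CountryConfig,
    benchmark: SurveyBenchmark | None = None,
    vaccine_map: VaccineMap | None = None,
) -> AssessmentReport:
    """Run cleaning and all applicable quality metrics on one panel."""
    report = AssessmentReport()
    meta: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_records_in": len(panel),
        "cleaning": [],
        "sections_skipped": {},
    }

    panel, log_impute = impute_death_zeros(
        panel, registry, strict=config.strict_death_imputation
    )
    meta["cleaning"].append(log_impute.to_dict())
    if config.csection_id is not None:
        panel, log_cs = exclude_nonproviding_csection_units(panel, config.csection_id)
        meta["cleaning"].append(log_cs.to_dict())

    known = [i for i in panel.indicator_ids if i in registry]
    unknown = sorted(set(panel.indicator_ids) - set(known))
    if unknown:
        logger.warning("panel indicators missing from registry, skipped: %s", unknown)
        meta["indicators_without_registry_entry"] = unknown

    report.completeness, _ = completeness_table(panel, config, indicator_ids=known)
    report.outliers, _ = outlier_table(panel, config, indicator_ids=known)

    if vaccine_map is not None:
        row = consistency_row(panel, vaccine_map, config)
        rows = [row] if row is not None else []
        report.internal_consistency = consistency_table(rows, vaccine_map)
        if rows:
            meta["internal_consistency_summary"] = summarize_consistency(
                rows, vaccine_map.exclude_from_gap
            )
        else:
            meta["sections_skipped"]["internal_consistency"] = (
                "anchor vaccine indicator absent from panel"
            )
    else:
        meta["sections_skipped"]["internal_consistency"] = "no vaccine map supplied"

    if benchmark is not None:
        est = assess_external_consistency(panel, benchmark, config)
        if est is not None:
            report.external_consistency.loc[0] = {
                "country": config.country_label,
                "hmis_deliveries": est.hmis_deliveries,
                "hmis_csections": est.hmis_csections,
                "estimated_births": est.estimated_births,
                "hmis_csection_rate_pct": est.hmis_csection_rate,
                "survey_csection_rate_pct": est.survey_csection_rate,
                "diff_pp": est.diff_pp,
                "sensitivity_low_pct": est.sensitivity_interval[0],
                "sensitivity_high_pct": est.sensitivity_interval[1],
                "p_value": est.p_value,
                "survey_label": est.survey_label,
            }
        else:
            meta["sections_skipped"]["external_consistency"] = (
                "deliveries/c-section indicators unavailable"
            )
    else:
        meta["sections_skipped"]["external_consistency"] = "no survey benchmark supplied"

    report.metadata = meta
    return report


def run_assessment(
    panel_path: str | Path,
    registry_path: str | Path,
    config_path: str | Path,
    out_dir: str | Path,
    benchmark_path: str | Path | None = None,
    vaccine_map_path: str | Path | None = None,
    schema: Mapping[str, object] | None = None,
) -> AssessmentReport:
    """File-based entry point: read inputs, assess, write report tables."""
    config = CountryConfig.from_file(config_path)
    panel = read_panel(panel_path, schema=schema, T=config.T)
    registry = read_registry(registry_path)
    benchmark = read_benchmark(benchmark_path) if benchmark_path else None
    vaccine_map = read_vaccine_map(vaccine_map_path) if vaccine_map_path else None
    report = assess(panel, registry, config, benchmark, vaccine_map)
    report.metadata["inputs"] = {
        "panel": str(panel_path),
        "registry": str(registry_path),
        "config": str(config_path),
        "benchmark": str(benchmark_path) if benchmark_path else None,
        "vaccine_map": str(vaccine_map_path) if vaccine_map_path else None,
    }
    write_report(report, out_dir)
    return report
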