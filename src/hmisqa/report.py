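"""Assessment report container and writer.

One assessment run produces four tables — completeness, outliers,
internal consistency, external consistency — plus run metadata (config
echo, cleaning change-log counts, warnings).  The writer emits each
table as CSV and the metadata as JSON, so a rerun on identical inputs
is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import round_half_up

__all__ = ["AssessmentReport", "write_report", "REPORT_TABLE_COLUMNS"]

# Canonical column order per table; header-only files are written when a
# section is empty so downstream mergers always see the same schema.
REPORT_TABLE_COLUMNS = {
    "completeness": [
        "country", "indicator_id", "expected_units",
        "pre_pct", "pandemic_pct", "diff_pp", "p_value", "significant",
    ],
    "outliers": [
        "country", "indicator_id", "n_obs", "pos_pct", "neg_pct",
        "pos_pct_pre", "pos_pct_pandemic", "neg_pct_pre", "neg_pct_pandemic",
    ],
    "internal_consistency": [
        "country", "comparator", "indicator_id", "total",
        "anchor_total", "pct_of_anchor",
    ],
    "external_consistency": [
        "country", "hmis_deliveries", "hmis_csections", "estimated_births",
        "hmis_csection_rate_pct", "survey_csection_rate_pct", "diff_pp",
        "sensitivity_low_pct", "sensitivity_high_pct", "p_value",
        "survey_label",
    ],
}

# Columns display-rounded half-up to integers on output (full precision
# is retained in the in-memory tables).
_ROUNDED = {
    "completeness": ["pre_pct", "pandemic_pct", "diff_pp"],
    "internal_consistency": ["pct_of_anchor"],
}


@dataclass
class AssessmentReport:
    """The four result tables of one assessment run plus metadata."""

    completeness: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=REPORT_TABLE_COLUMNS["completeness"])
    )
    outliers: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=REPORT_TABLE_COLUMNS["outliers"])
    )
    internal_consistency: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=REPORT_TABLE_COLUMNS["internal_consistency"]
        )
    )
    external_consistency: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=REPORT_TABLE_COLUMNS["external_consistency"]
        )
    )
    metadata: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "completeness": self.completeness,
            "outliers": self.outliers,
            "internal_consistency": self.internal_consistency,
            "external_consistency": self.external_consistency,
        }


def _display(table_name: str, df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in _ROUNDED.get(table_name, []):
        if col in out.columns and len(out):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else round_half_up(float(v))
            )
    return out


def write_report(report: AssessmentReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the four tables (CSV) and run metadata (JSON) to ``out_dir``.

    Percentage columns are display-rounded half-up to integers, matching
    the convention of published completeness/consistency tables; the
    in-memory report keeps full precision.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in report.tables().items():
        cols = REPORT_TABLE_COLUMNS[name]
        body = df.reindex(columns=cols) if len(df) else pd.DataFrame(columns=cols)
        path = out / f"{name}.csv"
        _display(name, body).to_csv(path, index=False)
        paths[name] = path
    meta_path = out / "run_metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(report.metadata, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    paths["metadata"] = meta_path
    return paths
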