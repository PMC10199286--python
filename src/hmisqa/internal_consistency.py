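"""Internal consistency of co-administered infant vaccine indicators.

BCG is given at or near birth; pentavalent, pneumococcal and oral polio
are three-dose courses typically administered on the same visit days
starting at 6 weeks; rotavirus is a two-dose course given with the first
two of those visits.  Annual national totals of these antigens should
therefore be close to one another.  The third pentavalent dose (penta3)
serves as the anchor: each comparator's annual total is expressed as a
percentage of the penta3 total.

BCG legitimately diverges from the 6-week series (home births missing
BCG, drop-out after the birth dose, separate recording at maternities),
so cross-antigen gap summaries exclude it by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ._util import round_half_up
from .errors import UndefinedRatioError
from .panel_model import CountryConfig, Panel

__all__ = [
    "VaccineMap",
    "ConsistencyRow",
    "annual_total",
    "penta3_ratio",
    "consistency_row",
    "consistency_table",
    "summarize_consistency",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VaccineMap:
    """Which panel indicators play which antigen role.

    ``comparators`` maps a role name (``bcg``, ``pneumococcal3``,
    ``oral_polio3``, ``rotavirus2``) to the indicator id carrying it;
    roles absent from a country's extract are simply omitted, never
    zero-filled.  ``exclude_from_gap`` lists roles ignored by the
    max-pairwise-gap summary (BCG by default, see module docstring).
    """

    anchor_id: str = "penta3"
    comparators: dict[str, str] = field(
        default_factory=lambda: {
            "bcg": "bcg",
            "pneumococcal3": "pneumococcal3",
            "oral_polio3": "oral_polio3",
            "rotavirus2": "rotavirus2",
        }
    )
    exclude_from_gap: tuple[str, ...] = ("bcg",)


def annual_total(
    panel: Panel, indicator_id: str, months: tuple[int, ...]
) -> int:
    """Sum of non-missing values over all units and the given months."""
    sub = panel.indicator(indicator_id)
    total = sub.loc[sub["month_index"].isin(months), "value"].sum()
    if pd.isna(total) or total == 0:
        logger.warning("annual total of %r over %d months is 0", indicator_id, len(months))
        return 0
    return int(total)


def penta3_ratio(comparator_total: float, penta3_total: float) -> float:
    """Comparator total as a percentage of the anchor (penta3) total."""
    if penta3_total <= 0:
        raise UndefinedRatioError("anchor (penta3) total must be positive")
    return 100.0 * comparator_total / penta3_total


@dataclass
class ConsistencyRow:
    """Annual totals and anchor percentages for one country/panel."""

    country_label: str
    penta3_total: int
    totals: dict[str, int]  # role -> annual total (available roles only)
    pct_of_penta3: dict[str, float]  # role -> full-precision percentage

    def display_pct(self) -> dict[str, int]:
        """Half-up integer percentages, as printed in report tables."""
        return {k: round_half_up(v) for k, v in self.pct_of_penta3.items()}


def consistency_row(
    panel: Panel,
    vaccine_map: VaccineMap,
    config: CountryConfig,
) -> ConsistencyRow | None:
    """Build the consistency row for one panel, or None without an anchor.

    A panel lacking the anchor indicator (no vaccine-specific
    indicators in the extract) yields no row, with a logged reason.
    Comparator roles whose indicator is absent are skipped.
    """
    months = config.reference_year_months
    if vaccine_map.anchor_id not in panel.indicator_ids:
        logger.warning(
            "%s: anchor indicator %r absent; excluded from internal consistency",
            config.country_label,
            vaccine_map.anchor_id,
        )
        return None
    penta3 = annual_total(panel, vaccine_map.anchor_id, months)
    totals: dict[str, int] = {}
    pcts: dict[str, float] = {}
    for role, ind in vaccine_map.comparators.items():
        if ind not in panel.indicator_ids:
            logger.info("%s: comparator %r absent; skipped", config.country_label, role)
            continue
        totals[role] = annual_total(panel, ind, months)
        pcts[role] = penta3_ratio(totals[role], penta3)
    return ConsistencyRow(
        country_label=config.country_label,
        penta3_total=penta3,
        totals=totals,
        pct_of_penta3=pcts,
    )


def summarize_consistency(
    rows: list[ConsistencyRow], exclude_from_gap: tuple[str, ...] = ("bcg",)
) -> dict:
    """Cross-row summary on display (integer) percentages.

    Returns the minimum and maximum comparator percentage over all rows
    and, per row, the maximum pairwise absolute gap among the anchor
    (100 by definition) and the non-excluded comparators.
    """
    all_pcts = [p for row in rows for p in row.display_pct().values()]
    gaps = {}
    for row in rows:
        vals = [100] + [
            p
            for role, p in row.display_pct().items()
            if role not in exclude_from_gap
        ]
        gaps[row.country_label] = max(
            abs(a - b) for a in vals for b in vals
        ) if len(vals) > 1 else 0
    return {
        "min_pct": min(all_pcts) if all_pcts else None,
        "max_pct": max(all_pcts) if all_pcts else None,
        "max_gap_excluding_bcg": gaps,
    }


def consistency_table(
    rows: list[ConsistencyRow], vaccine_map: VaccineMap
) -> pd.DataFrame:
    """Long-format report table: one line per (country, comparator)."""
    records = []
    for row in rows:
        for role, total in row.totals.items():
            records.append(
                {
                    "country": row.country_label,
                    "comparator": role,
                    "indicator_id": vaccine_map.comparators[role],
                    "total": total,
                    "anchor_total": row.penta3_total,
                    "pct_of_anchor": row.pct_of_penta3[role],
                }
            )
    return pd.DataFrame(records)
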