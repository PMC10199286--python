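"""Pre-analysis cleaning rules for facility-month panels.

Two rules, both motivated by the zero-vs-missing ambiguity of routine
reporting systems:

1. **Death zero-imputation.**  Small facilities rarely record deaths and
   often leave the cell blank in months when none occurred.  If the unit
   demonstrably provided the linked service that month (a positive
   reported count of deliveries, inpatient admissions, ...), a blank
   death cell is read as "zero deaths" and imputed to 0.  If the linked
   service itself was not reported, nothing can be inferred and the
   death cell stays missing.  Reported death values are never altered.

2. **C-section provider exclusion.**  Facilities without surgical
   capacity sometimes report the cesarean-section indicator as 0 rather
   than leaving it blank.  Any unit whose c-section values sum to zero
   over the whole study period (or are entirely missing) is treated as a
   non-provider: all its c-section values are set to missing, excluding
   the unit from c-section analyses.  Other indicators are untouched.

Both rules change cell values only — never the set of (unit, indicator,
month) keys — and both are idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_model import IndicatorRegistry, Panel

__all__ = ["ChangeLog", "impute_death_zeros", "exclude_nonproviding_csection_units"]


@dataclass
class ChangeLog:
    """Audit record of one cleaning rule application."""

    rule: str
    n_changed: int = 0
    per_indicator: dict[str, int] = field(default_factory=dict)
    excluded_units: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "n_changed": self.n_changed,
            "per_indicator": dict(self.per_indicator),
            "excluded_units": list(self.excluded_units),
            "notes": list(self.notes),
        }


def impute_death_zeros(
    panel: Panel,
    registry: IndicatorRegistry,
    strict: bool = False,
) -> tuple[Panel, ChangeLog]:
    """Impute missing death counts to 0 where the linked service was provided.

    For each death indicator with a ``linked_service_id``, a missing
    value at (unit, month) becomes 0 when the linked service value at
    the same (unit, month) is reported and positive.  With
    ``strict=True`` a reported service value of exactly 0 also triggers
    imputation (i.e. any non-missing service report counts as "the unit
    reported on the service").  The default treats a reported service
    zero as "service not provided that month", from which a zero death
    count cannot be distinguished from non-observation.

    Death indicators without a linked service are never imputed.
    """
    df = panel.data
    values = df["value"].copy()
    log = ChangeLog(rule="impute_death_zeros")

    # (unit, month) -> service value lookups, one per linked service.
    service_lookup: dict[str, pd.Series] = {}

    for meta in registry.death_indicators():
        link = meta.linked_service_id
        if link is None:
            continue
        if link not in service_lookup:
            sub = df[df["indicator_id"] == link]
            service_lookup[link] = sub.set_index(["unit_id", "month_index"])["value"]
        service = service_lookup[link]

        is_death = (df["indicator_id"] == meta.indicator_id).to_numpy()
        if not is_death.any():
            continue
        keys = pd.MultiIndex.from_frame(
            df.loc[is_death, ["unit_id", "month_index"]]
        )
        linked_vals = service.reindex(keys).to_numpy()
        provided = (
            ~np.isnan(linked_vals) if strict
            else np.nan_to_num(linked_vals, nan=0.0) > 0
        )
        target = is_death & values.isna().to_numpy()
        target[is_death] &= provided
        n = int(target.sum())
        if n:
            values[target] = 0.0
            log.per_indicator[meta.indicator_id] = n
            log.n_changed += n
    return panel.with_values(values), log


def exclude_nonproviding_csection_units(
    panel: Panel, csection_id: str
) -> tuple[Panel, ChangeLog]:
    """Blank out the c-section series of units that never performed one.

    A unit whose non-missing c-section values sum to 0 over the full
    study period — which includes units whose series is entirely missing
    — is flagged as a non-provider and every one of its c-section values
    is set to missing.  A no-op (with a note) if the indicator is absent
    from the panel.
    """
    log = ChangeLog(rule="exclude_nonproviding_csection_units")
    df = panel.data
    is_cs = (df["indicator_id"] == csection_id).to_numpy()
    if not is_cs.any():
        log.notes.append(f"indicator {csection_id!r} absent from panel; no-op")
        return panel.copy(), log

    cs = df[is_cs]
    unit_sums = cs.groupby("unit_id")["value"].sum(min_count=0)
    excluded = unit_sums[unit_sums.fillna(0) == 0].index
    log.excluded_units = sorted(excluded)

    values = df["value"].copy()
    target = is_cs & df["unit_id"].isin(excluded).to_numpy()
    n = int((target & values.notna().to_numpy()).sum())
    values[target] = np.nan
    log.n_changed = n
    if n or len(excluded):
        log.per_indicator[csection_id] = n
    return panel.with_values(values), log
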