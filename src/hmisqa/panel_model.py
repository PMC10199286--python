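"""Data model and I/O for facility-month count panels.

The central container is :class:`Panel`: a long-format table of
(reporting unit, indicator, month) cells holding a non-negative integer
count or a missing value.  Reporting units may be individual health
facilities or administrative areas (districts) that aggregate small
facilities; all metrics treat both identically as "reporting units".

Months are a 1-based contiguous index 1..T (T = 24 for a two-year
extract).  Calendar conversion (Gregorian, Ethiopian, Nepali fiscal
months) happens once at ingest through the schema map and never
downstream, so every metric works on the same internal convention.

A reported zero and a missing cell are distinct states: several routine
reporting systems conflate them, and the cleaning rules exist precisely
to reason about that ambiguity, so the model must represent both.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, PanelIntegrityError, PanelParseError

__all__ = [
    "UNIT_LEVELS",
    "PANEL_COLUMNS",
    "Panel",
    "IndicatorMeta",
    "IndicatorRegistry",
    "PeriodSplit",
    "CountryConfig",
    "read_panel",
    "write_panel",
    "read_registry",
    "write_report",
]

UNIT_LEVELS = ("facility", "district")
PANEL_COLUMNS = ["unit_id", "unit_level", "indicator_id", "month_index", "value"]

INDICATOR_DOMAINS = ("RMNH", "child", "infectious", "NCD", "other", "deaths")


# ---------------------------------------------------------------------------
# Period split and country configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeriodSplit:
    """Partition of the month axis into a pre-pandemic and a pandemic window.

    The two windows must be disjoint and together cover 1..T exactly.
    The default split puts months 1-15 before the pandemic onset and
    16-24 after; countries whose fiscal calendar shifts the boundary by
    one month (e.g. a mid-January month start) use 1-14 / 15-24.
    """

    pre_months: tuple[int, ...] = tuple(range(1, 16))
    pandemic_months: tuple[int, ...] = tuple(range(16, 25))

    def __post_init__(self) -> None:
        pre, pand = set(self.pre_months), set(self.pandemic_months)
        if pre & pand:
            raise ConfigError("pre and pandemic months overlap")
        months = pre | pand
        if months != set(range(1, len(months) + 1)):
            raise ConfigError("period split must cover a contiguous 1..T range")

    @property
    def T(self) -> int:
        return len(self.pre_months) + len(self.pandemic_months)

    @classmethod
    def from_boundary(cls, first_pandemic_month: int, T: int = 24) -> "PeriodSplit":
        """Split 1..T at ``first_pandemic_month`` (inclusive on the pandemic side)."""
        if not 2 <= first_pandemic_month <= T:
            raise ConfigError("pandemic boundary must lie strictly inside 1..T")
        return cls(
            tuple(range(1, first_pandemic_month)),
            tuple(range(first_pandemic_month, T + 1)),
        )

    @classmethod
    def default(cls, T: int = 24) -> "PeriodSplit":
        return cls.from_boundary(16, T)

    @classmethod
    def nepal(cls, T: int = 24) -> "PeriodSplit":
        """One-month-earlier boundary used for a mid-January month start."""
        return cls.from_boundary(15, T)


@dataclass(frozen=True)
class CountryConfig:
    """Per-country assessment settings.

    Parameters
    ----------
    country_label
        Free-text label echoed into every report table.
    T
        Number of months in the panel (24 = two calendar years).
    period_split
        Pre-pandemic vs pandemic month windows.
    completeness_benchmarks
        Percent thresholds flagged in the completeness table (WHO DQR
        convention: 80 and 90).
    outlier_z
        Number of within-unit standard deviations beyond which a count
        is an outlier (3.5).
    min_outlier_months
        Minimum non-missing months required before a unit's SD is
        considered stable enough to flag outliers.
    reference_year_months
        Month window for annual consistency analyses (calendar 2019 =
        months 1..12 of a Jan-2019 panel).
    sensitivity_delta_pp
        Half-width, in percentage points, of the facility-delivery-rate
        perturbation used for the external-consistency uncertainty
        interval.
    deliveries_id, csection_id
        Indicator ids used by the cleaning and external-consistency
        stages; either may be absent from a given extract.
    pooled_t_test
        Use the pooled-variance two-sample t-test instead of Welch's.
    strict_death_imputation
        Impute a zero death count whenever the linked service is
        non-missing, even if the service count is itself zero.
    """

    country_label: str = "synthetic"
    T: int = 24
    period_split: PeriodSplit = field(default_factory=PeriodSplit.default)
    completeness_benchmarks: tuple[float, ...] = (80.0, 90.0)
    outlier_z: float = 3.5
    min_outlier_months: int = 4
    reference_year_months: tuple[int, ...] = tuple(range(1, 13))
    sensitivity_delta_pp: float = 3.0
    deliveries_id: str | None = "deliveries"
    csection_id: str | None = "csection"
    pooled_t_test: bool = False
    strict_death_imputation: bool = False

    def __post_init__(self) -> None:
        if self.outlier_z <= 0:
            raise ConfigError("outlier_z must be positive")
        if not all(0 < b <= 100 for b in self.completeness_benchmarks):
            raise ConfigError("benchmarks must lie in (0, 100]")
        if self.period_split.T != self.T:
            raise ConfigError("period split does not cover 1..T")
        if not set(self.reference_year_months) <= set(range(1, self.T + 1)):
            raise ConfigError("reference_year_months must be within 1..T")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["period_split"] = {
            "pre_months": list(self.period_split.pre_months),
            "pandemic_months": list(self.period_split.pandemic_months),
        }
        d["completeness_benchmarks"] = list(self.completeness_benchmarks)
        d["reference_year_months"] = list(self.reference_year_months)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CountryConfig":
        d = dict(d)
        if "period_split" in d:
            ps = d["period_split"]
            if isinstance(ps, Mapping):
                d["period_split"] = PeriodSplit(
                    tuple(ps["pre_months"]), tuple(ps["pandemic_months"])
                )
        for key in ("completeness_benchmarks", "reference_year_months"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "CountryConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Indicator registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndicatorMeta:
    """Metadata for one indicator.

    ``kind`` distinguishes service-volume indicators from institutional
    death indicators; a death indicator may name the service whose
    provision implies the deaths would have been observed (inpatient
    admissions for inpatient deaths, deliveries for maternal deaths,
    stillbirths and newborn deaths).  That link drives the
    zero-imputation cleaning rule.
    """

    indicator_id: str
    display_name: str = ""
    domain: str = "other"
    kind: str = "service"
    linked_service_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("service", "death"):
            raise PanelIntegrityError(f"unknown indicator kind {self.kind!r}")
        if self.domain not in INDICATOR_DOMAINS:
            raise PanelIntegrityError(f"unknown indicator domain {self.domain!r}")
        if self.kind == "service" and self.linked_service_id is not None:
            raise PanelIntegrityError(
                f"service indicator {self.indicator_id!r} cannot have a linked service"
            )
        if not self.display_name:
            object.__setattr__(self, "display_name", self.indicator_id)


class IndicatorRegistry:
    """Collection of :class:`IndicatorMeta`, validated on construction.

    Every death indicator's ``linked_service_id`` must refer to a
    service indicator present in the registry (or be ``None``, in which
    case the imputation rule never fires for it).
    """

    def __init__(self, indicators: Iterable[IndicatorMeta]):
        self._by_id: dict[str, IndicatorMeta] = {}
        for meta in indicators:
            if meta.indicator_id in self._by_id:
                raise PanelIntegrityError(
                    f"duplicate indicator id {meta.indicator_id!r}"
                )
            self._by_id[meta.indicator_id] = meta
        for meta in self._by_id.values():
            link = meta.linked_service_id
            if link is None:
                continue
            target = self._by_id.get(link)
            if target is None:
                raise PanelIntegrityError(
                    f"death indicator {meta.indicator_id!r} links to absent "
                    f"indicator {link!r}"
                )
            if target.kind != "service":
                raise PanelIntegrityError(
                    f"death indicator {meta.indicator_id!r} must link to a "
                    f"service indicator, not {link!r}"
                )

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._by_id

    def __iter__(self) -> Iterator[IndicatorMeta]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def get(self, indicator_id: str) -> IndicatorMeta:
        try:
            return self._by_id[indicator_id]
        except KeyError:
            raise PanelIntegrityError(f"unknown indicator {indicator_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def death_indicators(self) -> list[IndicatorMeta]:
        return [m for m in self if m.kind == "death"]

    def to_file(self, path: str | Path) -> None:
        payload = {
            "indicators": [
                {k: v for k, v in dataclasses.asdict(m).items() if v is not None}
                for m in self
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def read_registry(path: str | Path) -> IndicatorRegistry:
    """Load an indicator registry from a YAML file.

    Expected layout::

        indicators:
          - indicator_id: deliveries
            domain: RMNH
            kind: service
          - indicator_id: maternal_deaths
            domain: deaths
            kind: death
            linked_service_id: deliveries
    """
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    entries = payload.get("indicators", payload if isinstance(payload, list) else [])
    metas = []
    for i, entry in enumerate(entries):
        try:
            metas.append(IndicatorMeta(**entry))
        except TypeError as exc:
            raise PanelParseError(f"registry entry {i}: {exc}") from None
    return IndicatorRegistry(metas)


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------


class Panel:
    """A validated long-format facility-month count panel.

    Wraps a :class:`pandas.DataFrame` with columns ``unit_id``,
    ``unit_level``, ``indicator_id``, ``month_index``, ``value``.
    Values are stored as float64 with NaN encoding "missing"; every
    non-missing value is an integer >= 0.  (unit, indicator, month) keys
    are unique, month indices lie in 1..T.
    """

    def __init__(self, data: pd.DataFrame, T: int = 24, _validated: bool = False):
        self.T = int(T)
        df = data.loc[:, PANEL_COLUMNS].copy()
        df["unit_id"] = df["unit_id"].astype(str)
        df["indicator_id"] = df["indicator_id"].astype(str)
        df["month_index"] = df["month_index"].astype(np.int64)
        df["value"] = df["value"].astype(np.float64)
        if not _validated:
            self._validate(df)
        df = df.sort_values(["indicator_id", "unit_id", "month_index"]).reset_index(
            drop=True
        )
        self.data = df

    def _validate(self, df: pd.DataFrame) -> None:
        bad_level = ~df["unit_level"].isin(UNIT_LEVELS)
        if bad_level.any():
            raise PanelIntegrityError(
                f"unknown unit_level values: {sorted(df.loc[bad_level, 'unit_level'].unique())}"
            )
        months = df["month_index"]
        if ((months < 1) | (months > self.T)).any():
            raise PanelIntegrityError(f"month_index outside 1..{self.T}")
        vals = df["value"]
        obs = vals.dropna()
        if (obs < 0).any():
            raise PanelIntegrityError("negative count value")
        if not np.array_equal(obs, np.floor(obs)):
            raise PanelIntegrityError("non-integer count value")
        dup = df.duplicated(["unit_id", "indicator_id", "month_index"])
        if dup.any():
            first = df.loc[dup, ["unit_id", "indicator_id", "month_index"]].iloc[0]
            raise PanelIntegrityError(
                "duplicate key "
                f"({first.unit_id!r}, {first.indicator_id!r}, month {first.month_index})"
            )

    # -- convenience accessors ---------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def indicator_ids(self) -> list[str]:
        return sorted(self.data["indicator_id"].unique())

    @property
    def unit_ids(self) -> list[str]:
        return sorted(self.data["unit_id"].unique())

    def indicator(self, indicator_id: str) -> pd.DataFrame:
        """Rows for one indicator."""
        return self.data[self.data["indicator_id"] == indicator_id]

    def matrix(self, indicator_id: str) -> pd.DataFrame:
        """Unit x month value matrix for one indicator.

        Columns are the full 1..T month range; cells with no record are
        NaN, indistinguishable from recorded-missing on purpose: both
        mean "no count reported".
        """
        sub = self.indicator(indicator_id)
        mat = sub.pivot(index="unit_id", columns="month_index", values="value")
        return mat.reindex(columns=range(1, self.T + 1))

    def with_values(self, values: pd.Series) -> "Panel":
        """Copy of the panel with ``value`` replaced (same row order/keys)."""
        df = self.data.copy()
        df["value"] = values.astype(np.float64).to_numpy()
        return Panel(df, T=self.T, _validated=False)

    def copy(self) -> "Panel":
        return Panel(self.data.copy(), T=self.T, _validated=True)

    def equals(self, other: "Panel") -> bool:
        if self.T != other.T or len(self) != len(other):
            return False
        return self.data.equals(other.data)


def _month_index_from_year_month(
    years: pd.Series, months: pd.Series, origin: tuple[int, int]
) -> pd.Series:
    oy, om = origin
    return 12 * (years.astype(int) - oy) + (months.astype(int) - om) + 1


def read_panel(
    path: str | Path,
    schema: Mapping[str, object] | None = None,
    T: int = 24,
) -> Panel:
    """Read a delimited-text panel extract.

    Parameters
    ----------
    path
        CSV file with one row per (unit, indicator, month) cell.
    schema
        Optional column-name map from canonical names (``unit_id``,
        ``unit_level``, ``indicator_id``, ``month_index``, ``value``) to
        the file's column names.  Instead of ``month_index`` the file
        may carry calendar columns: supply ``year`` and ``month`` plus
        ``origin`` = (year, month) of period 1; the month index is then
        computed at ingest, which is the single place calendar systems
        are reconciled.
    T
        Panel length in months.

    Empty value cells become missing; a literal ``0`` is a reported
    zero.  Malformed values raise :class:`PanelParseError` naming the
    row; duplicate keys and negative counts raise
    :class:`PanelIntegrityError`.
    """
    schema = dict(schema or {})
    origin = schema.pop("origin", None)
    rename = {v: k for k, v in schema.items()}

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.rename(columns=rename)

    if "month_index" not in raw.columns:
        if {"year", "month"} <= set(raw.columns):
            if origin is None:
                raise PanelParseError(
                    "year/month columns require schema['origin'] = (year, month) of period 1"
                )
            raw["month_index"] = _month_index_from_year_month(
                raw["year"], raw["month"], tuple(origin)
            )
        else:
            raise PanelParseError("no month_index (or year+month) column found")

    missing_cols = set(PANEL_COLUMNS) - set(raw.columns)
    if missing_cols:
        raise PanelParseError(f"missing columns: {sorted(missing_cols)}")

    values = raw["value"].astype(str).str.strip()
    parsed = pd.to_numeric(values.replace({"": None, "NA": None, "nan": None}),
                           errors="coerce")
    bad = parsed.isna() & ~values.isin(["", "NA", "nan"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise PanelParseError(
            f"row {row + 2}: value {values.iloc[row]!r} is not an integer count"
        )
    raw = raw.assign(value=parsed)
    try:
        raw["month_index"] = raw["month_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise PanelParseError(f"month_index not integer: {exc}") from None
    return Panel(raw, T=T)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel as CSV; missing values become empty cells."""
    df = panel.data.copy()
    df["value"] = df["value"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False)


# Report writing lives in hmisqa.report; re-exported here because the
# panel model owns all package I/O surfaces.
from .report import write_report  # noqa: E402  (deliberate tail import)
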