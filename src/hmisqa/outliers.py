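"""Outlier screening of facility-month counts.

A count is an outlier when it lies more than ``z`` standard deviations
(default 3.5) from its own unit's mean over the study period — the plain
mean +/- z*SD rule applied per (unit, indicator) series, with the
candidate point included in its own mean and SD.  Positive outliers
(above the band) usually indicate data-entry or unit errors; negative
outliers can also reflect genuine service collapse, so the two
directions are tabulated separately, overall and by pre/pandemic period.

Units with a zero-variance series, or with fewer than a minimum number
of observed months (default 4, below which the SD is too unstable),
produce no flags.  Missing values are never flagged and are excluded
from frequency denominators: a missing cell can be neither an outlier
nor a normal observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .panel_model import CountryConfig, Panel, PeriodSplit

__all__ = [
    "OutlierResult",
    "unit_series_stats",
    "flag_outliers",
    "outlier_frequency",
    "outlier_table",
]


@dataclass
class OutlierResult:
    indicator_id: str
    n_obs: int  # non-missing unit-months
    pos_pct: float
    neg_pct: float
    pos_pct_pre: float
    pos_pct_pandemic: float
    neg_pct_pre: float
    neg_pct_pandemic: float
    flags: pd.DataFrame  # columns unit_id, month_index, direction (+1/-1)


def unit_series_stats(
    panel: Panel, unit_id: str, indicator_id: str
) -> tuple[float, float, int]:
    """Mean, sample SD (ddof=1) and count of a unit's observed months.

    NaN mean/SD when nothing is observed; SD is NaN with a single
    observation.
    """
    sub = panel.indicator(indicator_id)
    vals = sub.loc[sub["unit_id"] == unit_id, "value"].dropna().to_numpy()
    n = len(vals)
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
    return mean, sd, n


def flag_outliers(
    panel: Panel,
    indicator_id: str,
    z: float = 3.5,
    min_months: int = 4,
    mask_candidate: bool = False,
) -> pd.DataFrame:
    """Flag unit-months beyond z SDs of the unit's series mean.

    Returns a frame with columns ``unit_id``, ``month_index``,
    ``direction`` (+1 above the band, -1 below).  The inequality is
    strict (``> mean + z*sd`` / ``< mean - z*sd``), so a value exactly
    on the band edge is not flagged.

    ``mask_candidate=True`` switches to the leave-one-out variant where
    each point is compared against the mean/SD of the *other* observed
    months; the default includes the candidate, the convention of
    standard data-quality review tooling for full-series screening.
    """
    if z <= 0:
        raise ConfigError("z must be positive")
    mat = panel.matrix(indicator_id).to_numpy(dtype=float)
    units = panel.matrix(indicator_id).index
    obs = ~np.isnan(mat)
    n = obs.sum(axis=1)

    with np.errstate(invalid="ignore"):
        if mask_candidate:
            # Leave-one-out mean/SD from sums: for each point i,
            # mean_-i = (S - x_i)/(n-1), ss_-i = Q - x_i^2 - (S-x_i)^2/(n-1).
            S = np.nansum(mat, axis=1, keepdims=True)
            Q = np.nansum(mat**2, axis=1, keepdims=True)
            ncol = n[:, None].astype(float)
            mean = (S - np.nan_to_num(mat)) / (ncol - 1)
            ss = Q - np.nan_to_num(mat) ** 2 - (ncol - 1) * mean**2
            sd = np.sqrt(np.maximum(ss, 0.0) / (ncol - 2))
            eligible = (n[:, None] - 1) >= max(min_months, 3)
        else:
            # nanmean/nanstd warn on all-NaN or single-value rows; such
            # rows are ineligible anyway, so silence and let NaN flow.
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(mat, axis=1, keepdims=True)
                sd = np.nanstd(mat, axis=1, ddof=1, keepdims=True)
            eligible = (n >= min_months)[:, None]

        band = z * sd
        pos = obs & eligible & (sd > 0) & (mat > mean + band)
        neg = obs & eligible & (sd > 0) & (mat < mean - band)

    ui, mi = np.nonzero(pos | neg)
    direction = np.where(pos[ui, mi], 1, -1)
    return pd.DataFrame(
        {
            "unit_id": units.to_numpy()[ui],
            "month_index": mi + 1,
            "direction": direction,
        }
    )


def outlier_frequency(
    panel: Panel,
    indicator_id: str,
    flags: pd.DataFrame,
    split: PeriodSplit,
) -> OutlierResult:
    """Outlier percentages, overall and per period.

    Denominators are non-missing unit-months in the relevant stratum;
    an empty stratum reports 0.0%.
    """
    sub = panel.indicator(indicator_id)
    observed = sub[sub["value"].notna()]
    pre = set(split.pre_months)

    def pct(n_flag: int, n_obs: int) -> float:
        return 100.0 * n_flag / n_obs if n_obs else 0.0

    n_obs = len(observed)
    obs_pre = int(observed["month_index"].isin(pre).sum())
    obs_pand = n_obs - obs_pre

    in_pre = flags["month_index"].isin(pre) if len(flags) else pd.Series(dtype=bool)
    pos = flags["direction"].eq(1) if len(flags) else pd.Series(dtype=bool)
    n_pos = int(pos.sum())
    n_neg = len(flags) - n_pos
    n_pos_pre = int((pos & in_pre).sum())
    n_neg_pre = int((~pos & in_pre).sum())

    return OutlierResult(
        indicator_id=indicator_id,
        n_obs=n_obs,
        pos_pct=pct(n_pos, n_obs),
        neg_pct=pct(n_neg, n_obs),
        pos_pct_pre=pct(n_pos_pre, obs_pre),
        pos_pct_pandemic=pct(n_pos - n_pos_pre, obs_pand),
        neg_pct_pre=pct(n_neg_pre, obs_pre),
        neg_pct_pandemic=pct(n_neg - n_neg_pre, obs_pand),
        flags=flags,
    )


def outlier_table(
    panel: Panel,
    config: CountryConfig,
    indicator_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, list[OutlierResult]]:
    """One outlier-frequency row per indicator."""
    rows = []
    results = []
    for ind in indicator_ids or panel.indicator_ids:
        flags = flag_outliers(
            panel, ind, z=config.outlier_z, min_months=config.min_outlier_months
        )
        res = outlier_frequency(panel, ind, flags, config.period_split)
        results.append(res)
        rows.append(
            {
                "country": config.country_label,
                "indicator_id": ind,
                "n_obs": res.n_obs,
                "pos_pct": res.pos_pct,
                "neg_pct": res.neg_pct,
                "pos_pct_pre": res.pos_pct_pre,
                "pos_pct_pandemic": res.pos_pct_pandemic,
                "neg_pct_pre": res.neg_pct_pre,
                "neg_pct_pandemic": res.neg_pct_pandemic,
            }
        )
    return pd.DataFrame(rows), results
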