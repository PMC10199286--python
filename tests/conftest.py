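"""Shared fixtures and panel-building helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hmisqa import CountryConfig, GeneratorConfig, Panel, generate_panel


def build_panel(cells, T: int = 24) -> Panel:
    """Panel from (unit_id, indicator_id, month_index, value) tuples.

    ``value=None`` marks a missing cell; unit level defaults to facility.
    """
    rows = [
        {
            "unit_id": u,
            "unit_level": "facility",
            "indicator_id": i,
            "month_index": m,
            "value": np.nan if v is None else float(v),
        }
        for u, i, m, v in cells
    ]
    return Panel(pd.DataFrame(rows), T=T)


def series_panel(values, indicator_id: str = "svc", unit_id: str = "u1") -> Panel:
    """Single-unit, single-indicator panel from a length-T value list."""
    return build_panel(
        [(unit_id, indicator_id, m + 1, v) for m, v in enumerate(values)],
        T=len(values),
    )


@pytest.fixture(scope="session")
def default_config() -> CountryConfig:
    return CountryConfig()


@pytest.fixture(scope="session")
def generated():
    """One full default-condition synthetic panel, shared across tests."""
    gen = GeneratorConfig(n_units=60, seed=7)
    panel, truth = generate_panel(gen)
    return gen, panel, truth
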