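"""WHO-region and income-group assignment for recipient countries.

Regions follow the WHO regional groupings; income groups follow the
World Bank classification, with a per-capita-income fallback for
territories absent from the World Bank list: the territory's per-capita
figure is placed in one of the four groups by the configured cut-off
thresholds. The thresholds are configuration, never hard-coded; the
shipped defaults are the World Bank FY2016/17 Atlas boundaries. The
World Bank cut-offs are defined on GNI per capita while a desk search
for an unlisted territory typically yields GDP per capita; the fallback
treats whichever per-capita figure is supplied generically.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .data_model import CountryTable, GrantRecord

log = logging.getLogger(__name__)

#: Low/lower-middle, lower-middle/upper-middle, upper-middle/high boundaries
#: (currency units per person per year).
DEFAULT_INCOME_CUTOFFS = (1025.0, 4035.0, 12475.0)


def _check_cutoffs(cutoffs: Sequence[float]) -> tuple[float, float, float]:
    t1, t2, t3 = cutoffs
    if not (t1 < t2 < t3):
        raise ValueError(f"income cutoffs must be strictly ascending, got {cutoffs}")
    return float(t1), float(t2), float(t3)


def group_from_per_capita(value: float, cutoffs: Sequence[float]) -> str:
    """Interval rule: <=t1 low; (t1,t2] lower-middle; (t2,t3] upper-middle; >t3 high."""
    t1, t2, t3 = _check_cutoffs(cutoffs)
    if value <= t1:
        return "low"
    if value <= t2:
        return "lower_middle"
    if value <= t3:
        return "upper_middle"
    return "high"


def assign_income_group(
    country: str,
    table: CountryTable,
    cutoffs: Sequence[float] = DEFAULT_INCOME_CUTOFFS,
    gdp_per_capita: float | None = None,
) -> str:
    """Income group for a country.

    A listed country gets its listed group. An unlisted territory falls
    back to the per-capita cut-off rule when a per-capita figure is
    available (either passed explicitly or carried in the table);
    otherwise the group is "unspecified".
    """
    _check_cutoffs(cutoffs)
    info = table.get(country)
    if info is not None and info.income_group != "unspecified":
        return info.income_group
    per_capita = gdp_per_capita
    if per_capita is None and info is not None:
        per_capita = info.gdp_per_capita
    if per_capita is not None:
        return group_from_per_capita(per_capita, cutoffs)
    return "unspecified"


def assign_region(country: str, table: CountryTable) -> str:
    """WHO region via case-insensitive lookup; misses are logged."""
    info = table.get(country)
    if info is None:
        log.warning("country %r not in metadata table; region unspecified", country)
        return "unspecified"
    return info.who_region


def annotate_geo(
    grants: Iterable[GrantRecord],
    table: CountryTable,
    cutoffs: Sequence[float] = DEFAULT_INCOME_CUTOFFS,
) -> pd.DataFrame:
    """Per-grant region and income group of the recipient country."""
    rows = [
        (
            g.grant_id,
            g.recipient_country,
            assign_region(g.recipient_country, table),
            assign_income_group(g.recipient_country, table, cutoffs),
        )
        for g in grants
    ]
    frame = pd.DataFrame(
        rows, columns=["grant_id", "recipient_country", "who_region", "income_group"]
    ).sort_values("grant_id")
    return frame.reset_index(drop=True)
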