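"""Portfolio descriptive analytics.

Every aggregation here carries an explicit denominator policy, because a
portfolio report legitimately mixes denominators: category shares are
usually quoted out of the classified grants only, while cross-cutting
flags (neglected tropical diseases, blueprint pathogens) are quoted out
of all grants. Making the policy a parameter of every table prevents
silent misreporting.

All percentages are rounded half-up (see :mod:`grantminer._rounding`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._rounding import ratio_percent, round_half_up
from .data_model import (
    INCOME_GROUPS,
    CollaborationRecord,
    CountryTable,
    GrantRecord,
)
from .geo_income import DEFAULT_INCOME_CUTOFFS, assign_income_group

log = logging.getLogger(__name__)

DENOMINATOR_POLICIES = ("all_grants", "classified_grants", "category_subset")

#: Mean days per calendar month (365.25 / 12); used to convert durations.
DAYS_PER_MONTH = 30.4375


def share_of_corpus(count: int, denominator: int, decimals: int = 0) -> float:
    """Percentage ``100*count/denominator`` rounded half-up.

    >>> share_of_corpus(52928, 69420, 0)
    76.0
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= denominator:
        raise ValueError("count must lie in [0, denominator]")
    return ratio_percent(count, denominator, decimals)


@dataclass(frozen=True)
class DistributionTable:
    """Key -> (count, percent) rows with an explicit denominator."""

    rows: tuple[tuple[str, int, float], ...]
    denominator_policy: str
    denominator: int
    decimals: int = 0
    n_unclassified: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["key", "count", "percent"])

    def counts(self) -> dict[str, int]:
        return {k: c for k, c, _ in self.rows}


def distribution(
    frame: pd.DataFrame,
    key: str,
    policy: str = "all_grants",
    decimals: int = 0,
) -> DistributionTable:
    """Distribution of a labelled corpus over the values of ``key``.

    Null labels (and the sentinel "none") count as unclassified. Under
    the ``all_grants`` and ``category_subset`` policies the denominator
    is the full frame; under ``classified_grants`` it is the labelled
    rows only, with the unclassified count reported alongside. Rows are
    sorted by descending count, then key.
    """
    if policy not in DENOMINATOR_POLICIES:
        raise ValueError(f"unknown denominator policy {policy!r}")
    labels = frame[key]
    labelled = labels[labels.notna() & (labels != "none")]
    n_unclassified = len(frame) - len(labelled)
    denominator = len(labelled) if policy == "classified_grants" else len(frame)
    if denominator == 0:
        raise ValueError("empty denominator")
    counts = labelled.value_counts()
    rows = tuple(
        (str(k), int(c), ratio_percent(int(c), denominator, decimals))
        for k, c in sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    )
    return DistributionTable(rows, policy, denominator, decimals, n_unclassified)


def distribution_from_counts(
    counts: Mapping[str, int],
    policy: str,
    denominator: int | None = None,
    decimals: int = 0,
) -> DistributionTable:
    """Build a distribution directly from pre-tabulated counts.

    ``denominator`` defaults to the sum of the counts; pass it explicitly
    for all-grants shares of a subset (e.g. flagged diseases out of the
    whole corpus).
    """
    if policy not in DENOMINATOR_POLICIES:
        raise ValueError(f"unknown denominator policy {policy!r}")
    denom = sum(counts.values()) if denominator is None else denominator
    if denom <= 0:
        raise ValueError("empty denominator")
    rows = tuple(
        (str(k), int(c), ratio_percent(int(c), denom, decimals))
        for k, c in sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    )
    return DistributionTable(rows, policy, denom, decimals)


def top_recipients(
    grants: Sequence[GrantRecord], level: str = "country", n: int = 10
) -> pd.DataFrame:
    """Top-``n`` recipient countries (or institutions) by grant count.

    Ties are broken alphabetically. At country level the single most
    frequent institution within each country is attached.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if level not in ("country", "institution"):
        raise ValueError(f"unknown level {level!r}")
    attr = "recipient_country" if level == "country" else "recipient_institution"
    counts: dict[str, int] = {}
    for g in grants:
        key = getattr(g, attr)
        counts[key] = counts.get(key, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    rows = []
    for key, count in ranked:
        row = {level: key, "n_grants": count}
        if level == "country":
            inst: dict[str, int] = {}
            for g in grants:
                if g.recipient_country == key:
                    inst[g.recipient_institution] = inst.get(g.recipient_institution, 0) + 1
            top_inst, top_n = sorted(inst.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            row["top_institution"] = top_inst
            row["top_institution_grants"] = top_n
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Duration:
    """An average grant duration, kept in months and displayed as Y/M."""

    months_total: float
    years: int
    months: int

    @property
    def display(self) -> str:
        year_word = "year" if self.years == 1 else "years"
        month_word = "month" if self.months == 1 else "months"
        return f"{self.years} {year_word}, {self.months} {month_word}"

    @classmethod
    def from_months(cls, months_total: float) -> "Duration":
        if months_total < 0:
            raise ValueError("duration cannot be negative")
        years = math.floor(months_total / 12)
        months = int(round_half_up(months_total - 12 * years))
        if months == 12:  # 11.5+ months rounds up into the next year
            years, months = years + 1, 0
        return cls(months_total=months_total, years=years, months=months)


def average_duration(grants: Iterable[GrantRecord]) -> Duration:
    """Mean grant duration over the grants that carry both dates.

    Durations are measured in days and converted at 30.4375 days/month;
    grants missing either date are excluded (and logged), and an empty
    contributing subset is an error.
    """
    day_lengths = []
    excluded = 0
    for g in grants:
        if g.start_date is None or g.end_date is None:
            excluded += 1
            continue
        day_lengths.append((g.end_date - g.start_date).days)
    if excluded:
        log.info("average_duration: excluded %d grant(s) without both dates", excluded)
    if not day_lengths:
        raise ValueError("no dated grants")
    mean_months = (sum(day_lengths) / len(day_lengths)) / DAYS_PER_MONTH
    return Duration.from_months(mean_months)


@dataclass(frozen=True)
class CollabCrossTab:
    """Direct-grant recipient income group x collaborator income group."""

    matrix: pd.DataFrame  # rows: recipient group, cols: collaborator group
    direct_counts: pd.Series  # recipient group -> direct grants with >=1 collab
    total_direct: int
    total_collaborations: int
    n_unresolved: int = 0

    def row_totals(self) -> pd.Series:
        return self.matrix.sum(axis=1)


def collaboration_crosstab(
    grants: Sequence[GrantRecord],
    collaborations: Sequence[CollaborationRecord],
    countries: CountryTable,
    cutoffs: Sequence[float] = DEFAULT_INCOME_CUTOFFS,
) -> CollabCrossTab:
    """Cross-tabulate collaborations by income group on both sides.

    Each collaboration record contributes one cell count; each direct
    grant with at least one resolved collaboration contributes once to
    its recipient group's direct count, however many collaborations it
    spawned. Unresolved collaborations are excluded and counted.
    """
    recipient_group = {
        g.grant_id: assign_income_group(g.recipient_country, countries, cutoffs)
        for g in grants
    }
    matrix = pd.DataFrame(0, index=list(INCOME_GROUPS), columns=list(INCOME_GROUPS))
    contributing: dict[str, set[str]] = {grp: set() for grp in INCOME_GROUPS}
    n_unresolved = 0
    for c in collaborations:
        if not c.resolved or c.direct_grant_id not in recipient_group:
            n_unresolved += 1
            continue
        r = recipient_group[c.direct_grant_id]
        col = assign_income_group(c.collab_country, countries, cutoffs)
        matrix.loc[r, col] += 1
        contributing[r].add(c.direct_grant_id)
    direct_counts = pd.Series(
        {grp: len(ids) for grp, ids in contributing.items()}, name="n_direct_grants"
    ).reindex(list(INCOME_GROUPS))
    return CollabCrossTab(
        matrix=matrix,
        direct_counts=direct_counts,
        total_direct=int(direct_counts.sum()),
        total_collaborations=int(matrix.to_numpy().sum()),
        n_unresolved=n_unresolved,
    )
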