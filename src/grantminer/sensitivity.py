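"""Accuracy audit of the health classifier on a funder-weighted sample.

The protocol: stratify the corpus by funder, allocate a sample of about
``base_n`` records proportionally to each funder's share of all direct
grants with every stratum rounded *up* (ceiling allocation — so every
contributing funder is represented by at least one record), draw the
per-funder strata at random, have two reviewers code each sampled grant
(classified? accurate? why not?), and summarise the post-consensus
coding: percentage classified, percentage accurate overall and per
source field, and the distribution of failure reasons over the pooled
misclassified-or-unclassified grants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._rounding import ratio_percent
from .data_model import GrantRecord

log = logging.getLogger(__name__)

#: Reasons a grant may be misclassified or left unclassified.
REASONS = (
    "unspecific_technical_language",
    "general_topic_no_disease",
    "new_synonym_discovered",
    "disease_not_first_mentioned",
    "multiple_diseases",
    "abstract_unavailable",
)


@dataclass(frozen=True)
class SampleAllocation:
    """Per-funder sample sizes under ceiling allocation."""

    per_funder: Mapping[str, int]
    base_n: int
    capped_funders: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return sum(self.per_funder.values())


def allocate_sample(funder_counts: Mapping[str, int], base_n: int) -> SampleAllocation:
    """Ceiling allocation of a target sample over funder strata.

    Each funder with at least one grant receives
    ``ceil(base_n * count / total)`` records — never zero — capped at the
    funder's own grant count (the cap is reported). The realised total
    therefore meets or exceeds ``base_n`` unless caps bite.
    """
    if base_n < 1:
        raise ValueError("base_n must be >= 1")
    total = sum(funder_counts.values())
    if total <= 0:
        raise ValueError("all funder counts are zero")
    sizes: dict[str, int] = {}
    capped = []
    for funder, count in funder_counts.items():
        if count < 0:
            raise ValueError(f"negative grant count for {funder!r}")
        if count == 0:
            sizes[funder] = 0
            continue
        size = math.ceil(base_n * count / total)
        if size > count:
            capped.append(funder)
            size = count
        sizes[funder] = size
    return SampleAllocation(per_funder=sizes, base_n=base_n, capped_funders=tuple(capped))


def draw_sample(
    grants: Sequence[GrantRecord],
    allocation: SampleAllocation,
    seed: int,
) -> list[GrantRecord]:
    """Draw the stratified sample: SRS without replacement per funder.

    The input must contain only direct grants (collaborations share their
    direct grant's title and abstract, so sampling them would double-count
    text). Reproducible for a given seed; allocations larger than a
    stratum are capped with a warning.
    """
    strata: dict[str, list[GrantRecord]] = {}
    for g in grants:
        strata.setdefault(g.funder, []).append(g)
    unknown = [f for f, n in allocation.per_funder.items() if n > 0 and f not in strata]
    if unknown:
        raise KeyError(f"allocation references funders absent from corpus: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    sample: list[GrantRecord] = []
    for funder in sorted(strata):
        k = allocation.per_funder.get(funder, 0)
        if k == 0:
            continue
        stratum = sorted(strata[funder], key=lambda g: g.grant_id)
        if k > len(stratum):
            log.warning(
                "funder %r: allocated %d > stratum size %d; drawing whole stratum",
                funder, k, len(stratum),
            )
            k = len(stratum)
        idx = rng.choice(len(stratum), size=k, replace=False)
        sample.extend(stratum[i] for i in sorted(idx))
    return sample


@dataclass(frozen=True)
class ReviewRecord:
    """Post-consensus reviewer coding of one sampled grant."""

    grant_id: str
    was_classified: bool
    accurate: bool | None = None  # only meaningful when classified
    source_field: str | None = None  # "title" | "abstract" when classified
    reason: str = "none"

    def __post_init__(self):
        if self.was_classified:
            if self.accurate is None:
                raise ValueError(f"record {self.grant_id}: classified but no accuracy flag")
            if self.source_field not in ("title", "abstract"):
                raise ValueError(f"record {self.grant_id}: classified but no source field")
        else:
            if self.accurate is not None:
                raise ValueError(f"record {self.grant_id}: accuracy flag without classification")
        needs_reason = (not self.was_classified) or (self.accurate is False)
        if needs_reason and self.reason == "none":
            raise ValueError(f"record {self.grant_id}: missing failure reason")
        if not needs_reason and self.reason != "none":
            raise ValueError(f"record {self.grant_id}: reason given for an accurate record")
        if self.reason != "none" and self.reason not in REASONS:
            raise ValueError(f"record {self.grant_id}: unknown reason {self.reason!r}")


@dataclass(frozen=True)
class AccuracySummary:
    """The audit's arithmetic, all percentages rounded half-up to integers."""

    n_total: int
    n_classified: int
    pct_classified: float
    n_accurate: int
    pct_accurate: float
    title_reviewed: int
    title_accurate: int
    pct_title: float | None
    abstract_reviewed: int
    abstract_accurate: int
    pct_abstract: float | None
    pool_size: int  # misclassified + unclassified
    reason_counts: Mapping[str, int] = field(default_factory=dict)
    reason_pcts: Mapping[str, float] = field(default_factory=dict)


def accuracy_summary(reviews: Iterable[ReviewRecord]) -> AccuracySummary:
    """Summarise reviewer coding into the audit table.

    Accuracy is quoted out of the classified records; per-field accuracy
    out of the records classified from that field; failure reasons out of
    the pooled misclassified-or-unclassified records.
    """
    reviews = list(reviews)
    if not reviews:
        raise ValueError("no review records")
    n_total = len(reviews)
    classified = [r for r in reviews if r.was_classified]
    n_classified = len(classified)
    accurate = [r for r in classified if r.accurate]
    by_field = {"title": [0, 0], "abstract": [0, 0]}  # [reviewed, accurate]
    for r in classified:
        by_field[r.source_field][0] += 1
        if r.accurate:
            by_field[r.source_field][1] += 1
    pool = [r for r in reviews if (not r.was_classified) or (r.accurate is False)]
    reason_counts: dict[str, int] = {}
    for r in pool:
        reason_counts[r.reason] = reason_counts.get(r.reason, 0) + 1
    reason_counts = dict(
        sorted(reason_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    reason_pcts = {
        k: ratio_percent(v, len(pool)) for k, v in reason_counts.items()
    }
    return AccuracySummary(
        n_total=n_total,
        n_classified=n_classified,
        pct_classified=ratio_percent(n_classified, n_total),
        n_accurate=len(accurate),
        pct_accurate=ratio_percent(len(accurate), n_classified) if n_classified else 0.0,
        title_reviewed=by_field["title"][0],
        title_accurate=by_field["title"][1],
        pct_title=(
            ratio_percent(by_field["title"][1], by_field["title"][0])
            if by_field["title"][0]
            else None
        ),
        abstract_reviewed=by_field["abstract"][0],
        abstract_accurate=by_field["abstract"][1],
        pct_abstract=(
            ratio_percent(by_field["abstract"][1], by_field["abstract"][0])
            if by_field["abstract"][0]
            else None
        ),
        pool_size=len(pool),
        reason_counts=reason_counts,
        reason_pcts=reason_pcts,
    )


def reviews_from_tallies(
    n_total: int,
    title_reviewed: int,
    title_accurate: int,
    abstract_reviewed: int,
    abstract_accurate: int,
    reason_tallies: Mapping[str, int],
) -> list[ReviewRecord]:
    """Expand audit tallies into a consistent set of review records.

    Useful for re-running the summary arithmetic from a published audit
    table: inaccurate-then-unclassified records are assigned the tallied
    reasons in order. The tallies must be mutually consistent.
    """
    n_classified = title_reviewed + abstract_reviewed
    n_inaccurate = (title_reviewed - title_accurate) + (abstract_reviewed - abstract_accurate)
    n_unclassified = n_total - n_classified
    pool = n_inaccurate + n_unclassified
    if sum(reason_tallies.values()) != pool:
        raise ValueError(
            f"reason tallies sum to {sum(reason_tallies.values())}, expected pool {pool}"
        )
    reasons = [r for r, k in reason_tallies.items() for _ in range(k)]
    records = []
    i = 0
    for fld, reviewed, acc in (
        ("title", title_reviewed, title_accurate),
        ("abstract", abstract_reviewed, abstract_accurate),
    ):
        for j in range(reviewed):
            ok = j < acc
            records.append(
                ReviewRecord(
                    grant_id=f"R{i:04d}",
                    was_classified=True,
                    accurate=ok,
                    source_field=fld,
                    reason="none" if ok else reasons.pop(0),
                )
            )
            i += 1
    for _ in range(n_unclassified):
        records.append(
            ReviewRecord(grant_id=f"R{i:04d}", was_classified=False, reason=reasons.pop(0))
        )
        i += 1
    return records
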