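"""Single-label health-category classification by earliest synonym match.

The classifier scans the normalised grant title for any synonym in the
disease lexicon and assigns the disease whose synonym starts closest to
the beginning of the field. Only if the title contains no synonym at all
is the abstract searched, under the same earliest-occurrence rule. The
rationale is empirical: the primary disease focus of a grant is almost
always the disease mentioned first, especially in titles. Stopping at
the first match also guarantees a single label per grant.

Matches respect word boundaries: a synonym never matches inside a longer
alphanumeric token ("flu" does not match "fluid"). Ties at the same
offset are broken by longest synonym (preferring the more specific
"breast cancer" over "cancer") and then lexicographically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from ._text import normalize_text  # noqa: F401  (re-exported: public surface)
from .data_model import GrantRecord
from .lexicon import Lexicon, SynonymHit

log = logging.getLogger(__name__)

RESULT_COLUMNS = (
    "grant_id",
    "source_field",
    "offset",
    "matched_synonym",
    "disease",
    "subcategory",
    "category",
    "ntd",
    "blueprint",
)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of classifying one grant.

    ``source_field`` is ``"none"`` exactly when no synonym occurred in
    either field; then every other attribute is ``None``.
    """

    source_field: str  # "title" | "abstract" | "none"
    offset: int | None = None
    matched_synonym: str | None = None
    disease: str | None = None
    subcategory: str | None = None
    category: str | None = None
    ntd: bool | None = None
    blueprint: bool | None = None

    @property
    def classified(self) -> bool:
        return self.source_field != "none"


UNCLASSIFIED = MatchResult(source_field="none")


def find_first_match(text: str, lexicon: Lexicon) -> SynonymHit | None:
    """Earliest boundary-respecting synonym occurrence in normalised text.

    ``text`` is assumed normalised already; ties at equal offset go to the
    longest synonym, then lexicographic order.
    """
    return lexicon.first_match(text)


def _result_from_hit(hit: SynonymHit, field: str) -> MatchResult:
    e = hit.entry
    return MatchResult(
        source_field=field,
        offset=hit.offset,
        matched_synonym=hit.synonym,
        disease=e.disease,
        subcategory=e.subcategory,
        category=e.category,
        ntd=e.ntd,
        blueprint=e.blueprint,
    )


def classify_health(grant: GrantRecord, lexicon: Lexicon) -> MatchResult:
    """Assign at most one disease to a grant: title first, then abstract.

    On any title match the abstract is never consulted. An absent
    abstract is treated as empty (the search trivially fails), so grants
    with an unmatched title and no abstract come back unclassified.
    """
    hit = lexicon.first_match(normalize_text(grant.title))
    if hit is not None:
        return _result_from_hit(hit, "title")
    hit = lexicon.first_match(normalize_text(grant.abstract))
    if hit is not None:
        return _result_from_hit(hit, "abstract")
    return UNCLASSIFIED


def classify_corpus(
    grants: Iterable[GrantRecord], lexicon: Lexicon
) -> pd.DataFrame:
    """Classify every grant; returns one row per grant in RESULT_COLUMNS.

    The output is sorted by grant_id, so it is identical for any input
    permutation. Classified/unclassified counts are logged.
    """
    rows = []
    for g in grants:
        r = classify_health(g, lexicon)
        rows.append(
            (
                g.grant_id,
                r.source_field,
                r.offset,
                r.matched_synonym,
                r.disease,
                r.subcategory,
                r.category,
                r.ntd,
                r.blueprint,
            )
        )
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS).sort_values("grant_id")
    frame = frame.reset_index(drop=True)
    n_classified = int((frame["source_field"] != "none").sum()) if len(frame) else 0
    log.info(
        "classified %d/%d grants (%d unclassified)",
        n_classified, len(frame), len(frame) - n_classified,
    )
    return frame


def results_as_mapping(frame: pd.DataFrame) -> Mapping[str, MatchResult]:
    """View a classification table as grant_id -> :class:`MatchResult`."""
    out = {}
    for row in frame.itertuples(index=False):
        if row.source_field == "none":
            out[row.grant_id] = UNCLASSIFIED
        else:
            out[row.grant_id] = MatchResult(
                source_field=row.source_field,
                offset=int(row.offset),
                matched_synonym=row.matched_synonym,
                disease=row.disease,
                subcategory=row.subcategory,
                category=row.category,
                ntd=bool(row.ntd),
                blueprint=bool(row.blueprint),
            )
    return out
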