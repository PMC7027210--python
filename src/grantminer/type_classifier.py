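"""Grant-type assignment with research as the universal fallback.

Uses the same scanning discipline as the health classifier — normalised
title first, then abstract, earliest boundary-respecting occurrence wins
— over the grant-type synonym lists (core institutional funding,
training, capacity strengthening, meetings, networking). A grant whose
text contains no type synonym anywhere is research: research is defined
by exclusion, not by its own synonym list.

Type and health classification are independent passes: a training grant
can still carry a disease label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from ._text import boundary_ok, normalize_text
from .data_model import GrantRecord
from .lexicon import TYPE_ORDER, TypeLexicon

TYPE_RESULT_COLUMNS = ("grant_id", "grant_type", "source", "matched_synonym", "source_field")


@dataclass(frozen=True)
class GrantType:
    """One grant's type; ``source`` is "fallback" exactly for research."""

    value: str
    source: str  # "matched" | "fallback"
    matched_synonym: str | None = None
    source_field: str | None = None  # "title" | "abstract" when matched

    def __post_init__(self):
        if (self.source == "fallback") != (self.value == "research"):
            raise ValueError("fallback source is reserved for research and vice versa")


RESEARCH_FALLBACK = GrantType(value="research", source="fallback")

_PRIORITY = {t: i for i, t in enumerate(TYPE_ORDER)}


def _best_type_hit(text: str, type_lexicon: TypeLexicon):
    """Earliest type-synonym occurrence; ties by longest synonym then the
    fixed priority order core_funding > training > capacity_strengthening >
    meetings > networking."""
    best = None
    for gtype, syn in type_lexicon.all_synonyms():
        if not syn:
            continue
        start = 0
        while True:
            i = text.find(syn, start)
            if i < 0:
                break
            if boundary_ok(text, i, i + len(syn)):
                cand = (i, -len(syn), _PRIORITY[gtype], syn, gtype)
                if best is None or cand < best:
                    best = cand
                break  # later occurrences of the same synonym cannot win
            start = i + 1
    return best


def classify_type(grant: GrantRecord, type_lexicon: TypeLexicon) -> GrantType:
    """Assign exactly one grant type; research when nothing matches."""
    for field_name, raw in (("title", grant.title), ("abstract", grant.abstract)):
        hit = _best_type_hit(normalize_text(raw), type_lexicon)
        if hit is not None:
            _, _, _, syn, gtype = hit
            return GrantType(
                value=gtype, source="matched", matched_synonym=syn, source_field=field_name
            )
    return RESEARCH_FALLBACK


def classify_types_corpus(
    grants: Iterable[GrantRecord], type_lexicon: TypeLexicon
) -> pd.DataFrame:
    """One row per grant, sorted by grant_id; every grant gets a type."""
    rows = []
    for g in grants:
        t = classify_type(g, type_lexicon)
        rows.append((g.grant_id, t.value, t.source, t.matched_synonym, t.source_field))
    frame = pd.DataFrame(rows, columns=TYPE_RESULT_COLUMNS).sort_values("grant_id")
    return frame.reset_index(drop=True)
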