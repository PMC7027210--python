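"""Text normalisation shared by the health- and type-classifiers.

All matching is performed on normalised text so that offsets, word
boundaries and tie-breaks are well defined regardless of how a funder's
export spells or punctuates a title.
"""

from __future__ import annotations

import re
import unicodedata

# Unicode dash variants folded to ASCII hyphen before the keep/drop decision.
_DASHES = dict.fromkeys(
    map(ord, "‐‑‒–—―−"), "-"
)

_NON_KEPT = re.compile(r"[^a-z0-9\- ]")
_LONE_HYPHEN = re.compile(r"(?<![a-z0-9])-|-(?![a-z0-9])")
_WS = re.compile(r"\s+")

_ALNUM = frozenset("abcdefghijklmnopqrstuvwxyz0123456789")


def normalize_text(raw: str | None) -> str:
    """Normalise free text for synonym matching.

    The result is case-folded, accent-stripped, with every punctuation
    character replaced by a space except hyphens joining two alphanumeric
    characters, and with whitespace runs collapsed to single spaces.
    ``None`` is treated as the empty string.

    >>> normalize_text("  Breast‐Cancer   Genomics ")
    'breast-cancer genomics'
    >>> normalize_text("HIV/AIDS cohort")
    'hiv aids cohort'
    """
    if raw is None:
        return ""
    text = unicodedata.normalize("NFKD", str(raw))
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    text = text.translate(_DASHES).casefold()
    text = _NON_KEPT.sub(" ", text)
    text = _LONE_HYPHEN.sub(" ", text)
    return _WS.sub(" ", text).strip()


def boundary_ok(text: str, start: int, end: int) -> bool:
    """True when ``text[start:end]`` is not flanked by a letter or digit.

    This is the word-boundary rule used throughout: a synonym may not be
    embedded inside a longer alphanumeric token ("flu" never matches
    inside "fluid"), but punctuation and hyphens do not block a match.
    """
    if start > 0 and text[start - 1] in _ALNUM:
        return False
    if end < len(text) and text[end] in _ALNUM:
        return False
    return True
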