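"""Independent brute-force oracles for the earliest-match classifiers.

These deliberately avoid the compiled-regex path used by the package:
``oracle_first_match`` scans every synonym with str.find and an explicit
boundary predicate; ``naive_first_match`` is the fully naive quadratic
scan (every synonym at every offset). Both apply the documented
tie-break (min offset, then longest synonym, then lexicographic) by
explicit key comparison.
"""

from __future__ import annotations


def _boundary(text: str, start: int, end: int) -> bool:
    before = text[start - 1] if start > 0 else " "
    after = text[end] if end < len(text) else " "
    return not before.isalnum() and not after.isalnum()


def oracle_first_match(text: str, synonyms) -> tuple[int, str] | None:
    """Earliest boundary-respecting occurrence over all synonyms (find-based)."""
    best = None
    for syn in synonyms:
        if not syn:
            continue
        start = 0
        while True:
            i = text.find(syn, start)
            if i < 0:
                break
            if _boundary(text, i, i + len(syn)):
                cand = (i, -len(syn), syn)
                if best is None or cand < best:
                    best = cand
                break  # earliest valid occurrence of this synonym found
            start = i + 1
    return None if best is None else (best[0], best[2])


def naive_first_match(text: str, synonyms) -> tuple[int, str] | None:
    """Fully naive scan: every synonym tested at every offset."""
    hits = [
        (i, -len(syn), syn)
        for syn in synonyms
        if syn
        for i in range(len(text) + 1)
        if text.startswith(syn, i) and _boundary(text, i, i + len(syn))
    ]
    if not hits:
        return None
    i, _, syn = min(hits)
    return (i, syn)


def oracle_classify(title: str, abstract: str | None, synonyms) -> tuple[str, int, str] | None:
    """Field-priority oracle: title first, then abstract; None if no match."""
    hit = oracle_first_match(title, synonyms)
    if hit is not None:
        return ("title", hit[0], hit[1])
    hit = oracle_first_match(abstract or "", synonyms)
    if hit is not None:
        return ("abstract", hit[0], hit[1])
    return None
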