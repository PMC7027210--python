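"""Hierarchical disease-synonym lexicon and grant-type synonym lists.

The disease lexicon is the classifier's knowledge base: each synonym maps
to exactly one disease, each disease to exactly one (subcategory,
category) pair in the four-way health-category split, with two orthogonal
flags marking membership of the WHO neglected-tropical-disease list and
of the R&D-blueprint priority-pathogen list.

Two interchange formats are accepted: a flat CSV (the canonical form,
columns ``synonym, disease, subcategory, category, ntd, blueprint``) and
a nested JSON (category -> subcategory -> disease -> {synonyms, ntd,
blueprint}).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from ._text import boundary_ok, normalize_text

#: The closed four-value set of top-level health categories.
CATEGORIES = (
    "Non-communicable",
    "Communicable, maternal, perinatal and nutritional conditions",
    "Injuries",
    "Others",
)

#: Grant types with synonym lists; "research" is the fallback and never keyed.
TYPE_ORDER = (
    "core_funding",
    "training",
    "capacity_strengthening",
    "meetings",
    "networking",
)

_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


class LexiconError(ValueError):
    """Raised when a lexicon file fails validation; carries all problems."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid lexicon:\n" + "\n".join(self.problems))


@dataclass(frozen=True)
class LexiconEntry:
    """One synonym with its disease and position in the category hierarchy."""

    synonym: str
    disease: str
    subcategory: str
    category: str
    ntd: bool = False
    blueprint: bool = False


@dataclass(frozen=True)
class SynonymHit:
    """One occurrence of a synonym in a normalised text."""

    offset: int
    synonym: str
    entry: LexiconEntry


class Lexicon:
    """A validated set of :class:`LexiconEntry` plus a compiled match index.

    The index behaves as a simultaneous multi-pattern search over all
    synonyms, respecting word boundaries; :meth:`first_match` returns the
    occurrence with the smallest start offset, breaking offset ties by
    longest synonym and then lexicographically.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        entries = list(entries)
        problems = _validate_entries(entries)
        if problems:
            raise LexiconError(problems)
        self.entries: tuple[LexiconEntry, ...] = tuple(entries)
        self._by_synonym = {e.synonym: e for e in entries}
        # Alternation order = tie-break order: longest first, then lexicographic.
        ordered = sorted(self._by_synonym, key=lambda s: (-len(s), s))
        self._regex = re.compile(
            "|".join(
                rf"(?<![a-z0-9]){re.escape(s)}(?![a-z0-9])" for s in ordered
            )
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries)

    @property
    def synonyms(self) -> tuple[str, ...]:
        return tuple(self._by_synonym)

    def diseases_by_category(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for e in self.entries:
            bucket = out.setdefault(e.category, [])
            if e.disease not in bucket:
                bucket.append(e.disease)
        return out

    def synonyms_for_disease(self, disease: str) -> list[str]:
        return [e.synonym for e in self.entries if e.disease == disease]

    def first_match(self, text: str) -> SynonymHit | None:
        """Earliest boundary-respecting synonym occurrence in ``text``.

        ``text`` must already be normalised (see
        :func:`grantminer.health_classifier.normalize_text`).
        """
        m = self._regex.search(text)
        if m is None:
            return None
        syn = m.group(0)
        return SynonymHit(m.start(), syn, self._by_synonym[syn])

    def find_all(self, text: str) -> list[SynonymHit]:
        """Every boundary-respecting occurrence of every synonym, sorted.

        Occurrences may overlap (e.g. "cancer" inside "breast cancer");
        sort order is (offset, longest synonym, synonym).
        """
        hits: list[SynonymHit] = []
        for syn, entry in self._by_synonym.items():
            start = 0
            while True:
                i = text.find(syn, start)
                if i < 0:
                    break
                if boundary_ok(text, i, i + len(syn)):
                    hits.append(SynonymHit(i, syn, entry))
                start = i + 1
        hits.sort(key=lambda h: (h.offset, -len(h.synonym), h.synonym))
        return hits


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of lexicon validation: hard errors and informational notes."""

    errors: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()

    @property
    def is_valid(self) -> bool:
        return not self.errors


def _validate_entries(entries: Sequence[LexiconEntry]) -> list[str]:
    problems: list[str] = []
    if not entries:
        problems.append("empty lexicon")
        return problems
    syn_to_diseases: dict[str, set[str]] = {}
    disease_to_hier: dict[str, set[tuple[str, str]]] = {}
    for e in entries:
        if not e.synonym:
            problems.append(f"synonym empty after normalisation (disease {e.disease!r})")
        if e.category not in CATEGORIES:
            problems.append(f"unknown category {e.category!r} for disease {e.disease!r}")
        syn_to_diseases.setdefault(e.synonym, set()).add(e.disease)
        disease_to_hier.setdefault(e.disease, set()).add((e.subcategory, e.category))
    for syn, diseases in sorted(syn_to_diseases.items()):
        if len(diseases) > 1:
            problems.append(
                f"synonym {syn!r} maps to multiple diseases: {sorted(diseases)}"
            )
    for disease, hiers in sorted(disease_to_hier.items()):
        if len(hiers) > 1:
            problems.append(
                f"disease {disease!r} placed under multiple hierarchies: {sorted(hiers)}"
            )
    return problems


def validate_lexicon(lexicon: Lexicon) -> ValidationReport:
    """Re-validate a lexicon and report substring overlaps between synonyms.

    Overlaps ("cancer" and "breast cancer" both present) are reported as
    notes, not errors: the first-match tie-break handles them, but an
    author may want to know they exist.
    """
    errors = _validate_entries(list(lexicon.entries))
    notes = []
    syns = sorted(lexicon.synonyms)
    for a in syns:
        for b in syns:
            if a is not b and a != b and a in b:
                notes.append(f"synonym {a!r} is a substring of {b!r}")
    return ValidationReport(tuple(errors), tuple(notes))


def _parse_flag(raw: str, row: int, col: str) -> bool:
    low = str(raw).strip().lower()
    if low in _TRUTHY:
        return True
    if low in _FALSY:
        return False
    raise LexiconError([f"row {row}: cannot parse {col}={raw!r} as boolean"])


def load_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a disease-synonym lexicon from CSV or JSON.

    All synonyms are normalised on load so the compiled index and the
    classifiers agree on offsets; validation problems are aggregated and
    raised together as :class:`LexiconError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        entries = _entries_from_json(json.loads(path.read_text(encoding="utf-8")))
    else:
        entries = _entries_from_csv(path)
    # Collapse exact duplicates (same normalised synonym, same disease).
    seen: dict[tuple[str, str], LexiconEntry] = {}
    for e in entries:
        seen.setdefault((e.synonym, e.disease), e)
    return Lexicon(seen.values())


def _entries_from_csv(path: Path) -> list[LexiconEntry]:
    entries = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"synonym", "disease", "subcategory", "category"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise LexiconError([f"missing columns: {missing}"])
        for i, row in enumerate(reader, start=2):
            entries.append(
                LexiconEntry(
                    synonym=normalize_text(row["synonym"]),
                    disease=row["disease"].strip(),
                    subcategory=row["subcategory"].strip(),
                    category=row["category"].strip(),
                    ntd=_parse_flag(row.get("ntd", ""), i, "ntd"),
                    blueprint=_parse_flag(row.get("blueprint", ""), i, "blueprint"),
                )
            )
    return entries


def _entries_from_json(tree: Mapping) -> list[LexiconEntry]:
    entries = []
    for category, subcats in tree.items():
        for subcategory, diseases in subcats.items():
            for disease, spec in diseases.items():
                if isinstance(spec, list):
                    spec = {"synonyms": spec}
                for syn in spec.get("synonyms", []):
                    entries.append(
                        LexiconEntry(
                            synonym=normalize_text(syn),
                            disease=disease,
                            subcategory=subcategory,
                            category=category,
                            ntd=bool(spec.get("ntd", False)),
                            blueprint=bool(spec.get("blueprint", False)),
                        )
                    )
    return entries


def write_lexicon_csv(lexicon: Lexicon, path: str | Path) -> None:
    """Write the flat-CSV canonical interchange form."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["synonym", "disease", "subcategory", "category", "ntd", "blueprint"])
        for e in lexicon.entries:
            writer.writerow(
                [e.synonym, e.disease, e.subcategory, e.category, int(e.ntd), int(e.blueprint)]
            )


@dataclass(frozen=True)
class TypeLexicon:
    """Synonym lists for the five matched grant types.

    ``research`` never appears as a key: it is the fallback assigned to
    every grant that matches no type synonym anywhere.
    """

    synonyms: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        bad = set(self.synonyms) - set(TYPE_ORDER)
        if "research" in self.synonyms:
            raise LexiconError(
                ["'research' may not be keyed in a type lexicon: it is the fallback"]
            )
        if bad:
            raise LexiconError([f"unknown grant types: {sorted(bad)}"])

    def items(self):
        return self.synonyms.items()

    def all_synonyms(self) -> list[tuple[str, str]]:
        """(grant_type, synonym) pairs in priority order."""
        return [(t, s) for t in TYPE_ORDER for s in self.synonyms.get(t, ())]


def load_type_lexicon(path: str | Path) -> TypeLexicon:
    """Load a grant-type synonym list from JSON ({type: [synonyms]}) or CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text(encoding="utf-8"))
    else:
        raw = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                raw.setdefault(row["grant_type"].strip(), []).append(row["synonym"])
    cleaned = {
        t: tuple(dict.fromkeys(normalize_text(s) for s in syns))
        for t, syns in raw.items()
    }
    return TypeLexicon(cleaned)
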